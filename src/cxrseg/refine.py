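"""Iterative bounding-box adjustment by greedy neighborhood search.

Initial detections from a text-grounded detector are often displaced from
the anatomy they name.  This stage refines a box by hill climbing: at each
iteration the objective is evaluated for every move in a translation (and
optionally scaling) neighborhood of the current box, the best move is
adopted, and the loop stops when the best available improvement falls
below a tolerance or the iteration budget runs out.  Because the identity
move is always in the neighborhood, the objective trace is non-decreasing
and the final box is never worse than the initial one.

Three objectives are available:

* ``segmenter_score`` (default) — the best candidate quality score a
  promptable segmenter reports for the box.
* ``detector_confidence`` — the confidence a detector assigns to the box
  (the detector must expose ``box_confidence(image, box, phrase)``).
* ``bpiou_vs_reference`` — BPIoU of the selected mask against a supplied
  reference mask.

Ties between equally good moves break toward the identity move, then the
smallest offset magnitude, then moves along x before y — a fixed order
that guarantees termination and bit-reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .detection import BoundingBox
from .metrics import bpiou
from .segmentation import Segmenter, segment, select_candidate

__all__ = ["RefineConfig", "IterationRecord", "RefineTrace", "refine_box", "refine_all"]

Move = tuple[int, int, float]  # (dx, dy, scale)


@dataclass(frozen=True)
class RefineConfig:
    """Search schedule and objective for box refinement.

    ``translation_steps`` are offset magnitudes applied as {0, ±s} per
    axis; ``scale_steps`` are multiplicative factors applied about the box
    center (default translations only).  The identity move (0, 0, 1.0)
    must be representable.  ``min_improvement`` is the convergence
    tolerance on the objective.
    """

    translation_steps: tuple[int, ...] = (0, 2, 5, 10)
    scale_steps: tuple[float, ...] = (1.0,)
    max_iterations: int = 10
    objective: str = "segmenter_score"
    min_improvement: float = 1e-6
    candidate_policy: str = "best_score"
    reference_mask: Optional[np.ndarray] = None
    bpiou_threshold: float = 0.5

    def __post_init__(self) -> None:
        if 0 not in self.translation_steps:
            raise ValueError("translation_steps must include 0 (identity move)")
        if 1.0 not in self.scale_steps:
            raise ValueError("scale_steps must include 1.0 (identity move)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.objective not in (
            "segmenter_score",
            "detector_confidence",
            "bpiou_vs_reference",
        ):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.objective == "bpiou_vs_reference" and self.reference_mask is None:
            raise ValueError("bpiou_vs_reference objective needs reference_mask")

    def offsets(self) -> list[int]:
        mags = sorted({abs(s) for s in self.translation_steps})
        out = [0]
        for m in mags:
            if m > 0:
                out.extend([m, -m])
        return out

    def moves(self) -> list[Move]:
        """Neighborhood in deterministic tie-break order.

        Identity first; then ascending squared offset magnitude; for equal
        magnitude, moves along x before y; scale changes last.
        """
        moves = [
            (dx, dy, s)
            for s in sorted(self.scale_steps, key=lambda v: (v != 1.0, v))
            for dx in self.offsets()
            for dy in self.offsets()
        ]

        def key(m: Move):
            dx, dy, s = m
            identity = dx == 0 and dy == 0 and s == 1.0
            return (
                0 if identity else 1,
                dx * dx + dy * dy,
                abs(dy),  # pure-x moves before pure-y at equal magnitude
                abs(dx),
                dy,
                dx,
                abs(s - 1.0),
                s,
            )

        return sorted(moves, key=key)


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    box: BoundingBox
    objective: float
    move: Optional[Move]  # None for the initial evaluation

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "box": self.box.to_dict(),
            "objective": self.objective,
            "move": list(self.move) if self.move is not None else None,
        }


@dataclass
class RefineTrace:
    """Audit trail of one refinement run: per-iteration adopted state."""

    records: list[IterationRecord] = field(default_factory=list)
    converged: bool = False

    @property
    def final_box(self) -> BoundingBox:
        return self.records[-1].box

    @property
    def initial_objective(self) -> float:
        return self.records[0].objective

    @property
    def final_objective(self) -> float:
        return self.records[-1].objective

    @property
    def objectives(self) -> list[float]:
        return [r.objective for r in self.records]

    @property
    def n_sweeps(self) -> int:
        """Number of neighborhood sweeps performed (excludes the initial eval)."""
        return len(self.records) - 1

    def to_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.to_dict()) + "\n")


def _apply_move(box: BoundingBox, move: Move, shape: tuple[int, int]) -> Optional[BoundingBox]:
    dx, dy, s = move
    if s != 1.0:
        cx = (box.x_min + box.x_max) / 2.0
        cy = (box.y_min + box.y_max) / 2.0
        hw = box.width * s / 2.0
        hh = box.height * s / 2.0
        box = replace(
            box,
            x_min=int(round(cx - hw)),
            x_max=int(round(cx + hw)),
            y_min=int(round(cy - hh)),
            y_max=int(round(cy + hh)),
        )
    return box.translate(dx, dy).clip_to(shape)


def _make_objective(
    image: np.ndarray,
    segmenter: Optional[Segmenter],
    config: RefineConfig,
    detector=None,
    phrase: str = "",
) -> Callable[[BoundingBox], float]:
    if config.objective == "segmenter_score":
        if segmenter is None:
            raise ValueError("segmenter_score objective needs a segmenter")

        def obj(box: BoundingBox) -> float:
            return segment(segmenter, image, box).candidates[0][1]

    elif config.objective == "detector_confidence":
        if detector is None or not hasattr(detector, "box_confidence"):
            raise ValueError(
                "detector_confidence objective needs a detector exposing box_confidence()"
            )

        def obj(box: BoundingBox) -> float:
            return float(detector.box_confidence(image, box, phrase))

    else:  # bpiou_vs_reference
        if segmenter is None:
            raise ValueError("bpiou_vs_reference objective needs a segmenter")
        reference = np.asarray(config.reference_mask, dtype=bool)

        def obj(box: BoundingBox) -> float:
            mask = select_candidate(
                segment(segmenter, image, box), policy=config.candidate_policy
            )
            return bpiou(mask, reference, config.bpiou_threshold)

    return obj


def refine_box(
    image: np.ndarray,
    initial_box: BoundingBox,
    segmenter: Optional[Segmenter],
    config: RefineConfig | None = None,
    detector=None,
    phrase: str = "",
) -> RefineTrace:
    """Greedy refinement of one box; returns the full iteration trace.

    Each sweep evaluates the objective for every move in the neighborhood
    (boxes clipped to image bounds, degenerate results skipped), adopts
    the best move under the fixed tie order, and stops early — with the
    converged flag set — once the best improvement drops below
    ``min_improvement``.  If an objective evaluation raises, the partial
    trace gathered so far is attached to the error.
    """
    config = config or RefineConfig()
    image = np.asarray(image)
    shape = image.shape[:2]
    phrase = phrase or initial_box.phrase
    objective = _make_objective(image, segmenter, config, detector, phrase)
    trace = RefineTrace()

    current = initial_box.clip_to(shape)
    if current is None:
        raise ValueError("initial box lies fully outside the image")
    try:
        value = objective(current)
    except Exception as exc:
        raise RefinementError("objective failed on the initial box", trace) from exc
    trace.records.append(IterationRecord(0, current, value, None))

    moves = config.moves()
    for it in range(1, config.max_iterations + 1):
        best_move, best_box, best_value = None, None, -np.inf
        seen: set[tuple[int, int, int, int]] = set()
        for move in moves:
            cand = _apply_move(current, move, shape)
            if cand is None:
                continue
            key = (cand.x_min, cand.y_min, cand.x_max, cand.y_max)
            if key in seen:
                continue
            seen.add(key)
            try:
                v = objective(cand)
            except Exception as exc:
                raise RefinementError(f"objective failed at iteration {it}", trace) from exc
            if v > best_value:
                best_move, best_box, best_value = move, cand, v
        # Identity is always evaluable, so best_* are set.
        improvement = best_value - value
        if improvement < config.min_improvement:
            trace.records.append(IterationRecord(it, current, value, (0, 0, 1.0)))
            trace.converged = True
            break
        current, value = best_box, best_value
        trace.records.append(IterationRecord(it, current, value, best_move))
    return trace


class RefinementError(RuntimeError):
    """Objective evaluation failed; carries the partial trace."""

    def __init__(self, message: str, trace: RefineTrace) -> None:
        super().__init__(message)
        self.partial_trace = trace


def refine_all(
    image: np.ndarray,
    boxes: list[BoundingBox],
    segmenter: Optional[Segmenter],
    config: RefineConfig | None = None,
    detector=None,
) -> list[RefineTrace]:
    """Refine each box independently; per-box errors carry the index."""
    if not boxes:
        raise ValueError("refine_all needs at least one box")
    traces = []
    for i, box in enumerate(boxes):
        try:
            traces.append(refine_box(image, box, segmenter, config, detector))
        except (ValueError, RefinementError) as exc:
            raise RefinementError(f"box {i}: {exc}", getattr(exc, "partial_trace", RefineTrace())) from exc
    return traces
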
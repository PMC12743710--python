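"""Segmenter contract and multi-candidate handling.

A *segmenter* turns an image plus a bounding-box prompt into one or more
candidate masks, each with a self-reported quality score in [0, 1] (for
SAM-style backends this slot carries the model's predicted IoU; for the
oracle it carries the captured-fraction score).  Promptable segmenters
produce several candidates when a prompt is ambiguous — e.g. nested or
overlapping anatomy — and the final mask is chosen by an explicit policy
standing in for the clinician's manual pick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Protocol, runtime_checkable

import numpy as np

from .detection import BoundingBox

__all__ = [
    "SegmentationResult",
    "Segmenter",
    "SegmentationBackendError",
    "segment",
    "segment_multi",
    "select_candidate",
]


class SegmentationBackendError(RuntimeError):
    """A segmentation backend failed."""


@dataclass
class SegmentationResult:
    """Candidate masks for one box prompt.

    ``candidates`` is an ordered list of (boolean mask, quality score)
    pairs; all masks share the full image shape.  ``backend_id`` records
    which model produced them (e.g. "oracle", "vit_b", "vit_h").
    """

    candidates: list[tuple[np.ndarray, float]]
    box_used: BoundingBox
    backend_id: str = "oracle"

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("a segmentation result needs at least one candidate")
        shape = np.asarray(self.candidates[0][0]).shape
        for i, (mask, score) in enumerate(self.candidates):
            if np.asarray(mask).shape != shape:
                raise ValueError(f"candidate {i} mask shape {np.asarray(mask).shape} != {shape}")
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"candidate {i} score {score} outside [0,1]")

    @property
    def best_score(self) -> float:
        return max(s for _, s in self.candidates)


@runtime_checkable
class Segmenter(Protocol):
    """Backend contract: candidate masks for an image + box prompt."""

    backend_id: str

    def segment_raw(self, image: np.ndarray, box: BoundingBox) -> SegmentationResult: ...


def segment(segmenter: Segmenter, image: np.ndarray, box: BoundingBox) -> SegmentationResult:
    """Segment one box prompt; candidates come back sorted by score.

    The box must intersect the image (a box fully outside is an error, a
    partially overlapping box is clipped by the backend).  Sorting is
    stable so the backend's candidate order breaks score ties.
    """
    image = np.asarray(image)
    if not box.intersects(image.shape[:2]):
        raise ValueError(f"box {box.to_dict()} lies fully outside image {image.shape[:2]}")
    try:
        result = segmenter.segment_raw(image, box)
    except Exception as exc:  # noqa: BLE001
        raise SegmentationBackendError(f"segmentation backend failed: {exc}") from exc
    result.candidates = sorted(result.candidates, key=lambda c: -c[1])
    return result


def segment_multi(
    segmenter: Segmenter, image: np.ndarray, boxes: list[BoundingBox]
) -> list[SegmentationResult]:
    """Segment each box in order; per-box failures carry the box index."""
    if not boxes:
        raise ValueError("segment_multi needs at least one box")
    out = []
    for i, box in enumerate(boxes):
        try:
            out.append(segment(segmenter, image, box))
        except (ValueError, SegmentationBackendError) as exc:
            raise SegmentationBackendError(f"box {i}: {exc}") from exc
    return out


def select_candidate(
    result: SegmentationResult,
    policy: Literal["best_score", "largest", "index"] = "best_score",
    index: int = 0,
) -> np.ndarray:
    """Pick one mask from a result under a deterministic policy.

    ``best_score`` takes the highest-scoring candidate, ``largest`` the
    one with the most foreground pixels, ``index`` the given position.
    Ties always break toward the earliest candidate.
    """
    if policy == "index":
        return np.asarray(result.candidates[index][0], dtype=bool)
    if policy == "best_score":
        key = [s for _, s in result.candidates]
    elif policy == "largest":
        key = [int(np.asarray(m, dtype=bool).sum()) for m, _ in result.candidates]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    best = max(range(len(key)), key=lambda i: (key[i], -i))
    return np.asarray(result.candidates[best][0], dtype=bool)
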
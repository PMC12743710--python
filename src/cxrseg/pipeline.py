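"""End-to-end orchestration: preprocess → detect → refine → segment → evaluate.

The pipeline runs the full prompt-guided segmentation chain on a batch of
radiographs (or synthetic phantoms): each text prompt is built, handed to
the detector over the raw or binarized pathway, the resulting boxes are
optionally refined by greedy search, segmented, and — when ground-truth
masks are available — scored with IoU, BPIoU, Dice loss and the stability
score.  Batch runs aggregate per-image rows into summary statistics,
fixed-edge score histograms per backend, and a calibration table, and
write every artifact under deterministic filenames recorded in a manifest
so a run is exactly reproducible from (inputs, config, seed).

Failure policy: a failing image is recorded and skipped, the batch
continues; only a batch where every image fails raises.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .calibration import calibration_table, plot_reliability, scores_to_probabilities
from .detection import BoundingBox, DetectorConfig, detect, detect_on_binary
from .metrics import bpiou, dice_loss, iou, stability_score
from .phantom import OracleDetector, OracleSegmenter, PhantomSpec, generate_phantom
from .preprocess import PreprocessConfig, save_mask
from .prompts import PromptSpec, build_prompt
from .refine import RefineConfig, RefineTrace, refine_all
from .segmentation import segment, select_candidate

logger = logging.getLogger("cxrseg")

__all__ = [
    "RunConfig",
    "ImageItem",
    "ImageReport",
    "BatchReport",
    "PipelineError",
    "phantom_batch",
    "run_single",
    "run_batch",
]

HISTOGRAM_EDGES = np.linspace(0.0, 1.0, 21)  # fixed BPIoU histogram binning


class PipelineError(RuntimeError):
    """Raised when a whole batch fails (per-image failures are recorded)."""


@dataclass
class ImageItem:
    """One unit of work: an image, its id, and optional ground truth."""

    image_id: str
    image: np.ndarray
    gt_masks: Optional[dict[str, np.ndarray]] = None


@dataclass
class RunConfig:
    """Everything a run needs; the seed fixes all stochastic components."""

    prompts: list[PromptSpec] = field(
        default_factory=lambda: [
            PromptSpec(("right lung",)),
            PromptSpec(("left lung",)),
        ]
    )
    pathway: str = "raw"  # "raw" | "binary"
    backend: str = "oracle"  # "oracle" | "oracle_eroded<k>" | plugin id
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    refine_enabled: bool = True
    candidate_policy: str = "best_score"
    detector_jitter: int = 0
    stability_n: int = 4
    stability_jitter: int = 3
    calibration_bins: int = 10
    iou_cutoff: float = 0.5
    output_dir: Optional[Path] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pathway not in ("raw", "binary"):
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if not self.prompts:
            raise ValueError("at least one prompt is required")


@dataclass
class ImageReport:
    image_id: str
    status: str  # "ok" or "failed: <reason>"
    rows: list[dict] = field(default_factory=list)
    traces: dict[str, RefineTrace] = field(default_factory=dict)
    artifacts: dict[str, Path] = field(default_factory=dict)


@dataclass
class BatchReport:
    reports: list[ImageReport]
    metrics: pd.DataFrame
    summary: pd.DataFrame
    histogram: pd.DataFrame
    calibration: Optional[object]  # CalibrationTable, None when no GT
    manifest: dict
    output_dir: Optional[Path]


def _item_seed(seed: int, image_id: str) -> int:
    """Stable per-image seed below 2**31 derived from the run seed."""
    return (seed * 1_000_003 + zlib.crc32(image_id.encode())) % (2**31)


def phantom_batch(
    n: int,
    height: int = 128,
    width: int = 128,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[ImageItem]:
    """Generate a batch of phantoms with seed-varied geometry.

    Geometry is perturbed slightly per image (center shifts and semi-axis
    scaling) to emulate patient positioning and size variation.
    """
    items = []
    rng = np.random.default_rng(seed)
    for i in range(n):
        base = PhantomSpec.default(height, width, noise_sd=noise_sd, seed=int(rng.integers(2**31)))
        jitter = rng.uniform(-0.02, 0.02, size=4)
        scale = rng.uniform(0.92, 1.0, size=2)
        lobes = {}
        for j, side in enumerate(("right", "left")):
            lobe = base.lobes[side]
            cy, cx = lobe.center
            a, b = lobe.semi_axes
            lobes[side] = type(lobe)(
                center=(cy + jitter[2 * j] * height, cx + jitter[2 * j + 1] * width),
                semi_axes=(a * scale[j], b * scale[j]),
                rotation_deg=lobe.rotation_deg,
                intensity=lobe.intensity,
            )
        spec = PhantomSpec(
            height=height,
            width=width,
            lobes=lobes,
            background_intensity=base.background_intensity,
            noise_sd=noise_sd,
            seed=base.seed,
        )
        image, masks = generate_phantom(spec)
        items.append(ImageItem(image_id=f"phantom_{i:04d}", image=image, gt_masks=masks))
    return items


def _make_backends(config: RunConfig, item: ImageItem):
    """Instantiate (detector, segmenter) for one image."""
    if config.backend.startswith("oracle"):
        if item.gt_masks is None:
            raise PipelineError(
                f"{item.image_id}: oracle backend needs ground-truth masks"
            )
        detector = OracleDetector(
            item.gt_masks,
            jitter=config.detector_jitter,
            seed=_item_seed(config.seed, item.image_id),
        )
        erosion = 0
        if config.backend.startswith("oracle_eroded"):
            erosion = int(config.backend.removeprefix("oracle_eroded") or 1)
        segmenter = OracleSegmenter(erosion=erosion)
        return detector, segmenter
    from . import backends as _backends  # optional plugin adapters

    return _backends.load_backend_pair(config.backend)


def _match_gt(mask: np.ndarray, gt_masks: dict[str, np.ndarray], prompt: str) -> tuple[str, np.ndarray]:
    """Pick the ground-truth lobe a predicted mask should be scored against.

    A side named in the prompt wins ("left"/"right" token containment);
    otherwise the lobe with the highest IoU against the prediction.
    """
    low = prompt.lower()
    for side in ("right", "left"):
        if side in low:
            return side, gt_masks[side]
    best = max(gt_masks, key=lambda s: iou(mask, gt_masks[s]))
    return best, gt_masks[best]


def _slugify(text: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in text).strip("-").lower()


def run_single(config: RunConfig, item: ImageItem) -> ImageReport:
    """Run the full chain on one image; returns rows, traces and artifacts."""
    report = ImageReport(image_id=item.image_id, status="ok")
    t0 = time.perf_counter()
    try:
        detector, segmenter = _make_backends(config, item)
        backend_id = getattr(segmenter, "backend_id", config.backend)
        for pspec in config.prompts:
            prompt = build_prompt(pspec)
            slug = _slugify(prompt)
            stem = f"{item.image_id}__{slug}__{backend_id}__{config.pathway}"
            if config.pathway == "binary":
                pre = config.preprocess
                if config.backend.startswith("oracle"):
                    # Oracle boxes live in ground-truth (native) space, so the
                    # binary rendering must stay at native resolution.
                    pre = dataclasses.replace(pre, target_size=item.image.shape[:2])
                boxes = detect_on_binary(
                    detector, item.image, prompt, pre, config.detector
                )
            else:
                boxes = detect(detector, item.image, prompt, config.detector)
            logger.info(
                "stage=detect image=%s prompt=%r pathway=%s n_boxes=%d",
                item.image_id, prompt, config.pathway, len(boxes),
            )
            if not boxes:
                report.rows.append(
                    {
                        "image_id": item.image_id,
                        "prompt": prompt,
                        "backend_id": backend_id,
                        "pathway": config.pathway,
                        "box_index": -1,
                        "n_detections": 0,
                        "refined": config.refine_enabled,
                        "status": "no_detection",
                    }
                )
                continue
            if config.refine_enabled:
                traces = refine_all(item.image, boxes, segmenter, config.refine, detector)
                final_boxes = [t.final_box for t in traces]
                for bi, t in enumerate(traces):
                    report.traces[f"{stem}__box{bi}"] = t
            else:
                final_boxes = boxes
            for bi, box in enumerate(final_boxes):
                result = segment(segmenter, item.image, box)
                mask = select_candidate(result, policy=config.candidate_policy)
                row = {
                    "image_id": item.image_id,
                    "prompt": prompt,
                    "backend_id": backend_id,
                    "pathway": config.pathway,
                    "box_index": bi,
                    "n_detections": len(boxes),
                    "confidence": boxes[min(bi, len(boxes) - 1)].confidence,
                    "quality_score": result.candidates[0][1],
                    "refined": config.refine_enabled,
                    "status": "ok",
                }
                if item.gt_masks is not None:
                    side, gt = _match_gt(mask, item.gt_masks, prompt)
                    row["gt_side"] = side
                    row["iou"] = iou(mask, gt)
                    row["bpiou"] = bpiou(mask, gt)
                    row["dice_loss"] = dice_loss(mask, gt)
                    row["stability"] = stability_score(
                        segmenter,
                        item.image,
                        box,
                        jitter=config.stability_jitter,
                        n_perturbations=config.stability_n,
                        seed=_item_seed(config.seed, f"{item.image_id}/{prompt}/{bi}"),
                        policy=config.candidate_policy,
                    )
                report.rows.append(row)
                if config.output_dir is not None:
                    out = Path(config.output_dir)
                    out.mkdir(parents=True, exist_ok=True)
                    mask_path = out / f"{stem}__box{bi}_mask.png"
                    save_mask(mask_path, mask)
                    report.artifacts[mask_path.name] = mask_path
            if config.output_dir is not None:
                out = Path(config.output_dir)
                boxes_path = out / f"{stem}_boxes.json"
                boxes_path.write_text(
                    json.dumps([b.to_dict() for b in final_boxes], indent=2)
                )
                report.artifacts[boxes_path.name] = boxes_path
                for key, t in report.traces.items():
                    if key.startswith(stem):
                        tp = out / f"{key}_trace.jsonl"
                        t.to_jsonl(tp)
                        report.artifacts[tp.name] = tp
    except Exception as exc:  # noqa: BLE001 - batch policy: record and continue
        report.status = f"failed: {exc}"
        logger.warning("stage=run_single image=%s status=failed error=%s", item.image_id, exc)
    logger.info(
        "stage=run_single image=%s status=%s duration=%.3fs",
        item.image_id, report.status, time.perf_counter() - t0,
    )
    return report


_METRIC_COLS = ["iou", "bpiou", "dice_loss", "stability", "quality_score", "confidence"]


def run_batch(config: RunConfig, items: list[ImageItem]) -> BatchReport:
    """Run every image, aggregate, and (optionally) write artifacts."""
    if not items:
        raise PipelineError("empty batch")
    reports = [run_single(config, item) for item in items]
    ok_rows = [r for rep in reports for r in rep.rows if r.get("status") == "ok"]
    failed = [rep for rep in reports if rep.status != "ok"]
    if len(failed) == len(reports):
        raise PipelineError(
            "all images failed: " + "; ".join(f"{r.image_id}: {r.status}" for r in failed)
        )
    metrics = pd.DataFrame([r for rep in reports for r in rep.rows])

    present = [c for c in _METRIC_COLS if c in metrics.columns]
    ok = metrics[metrics["status"] == "ok"] if "status" in metrics.columns else metrics
    if not ok.empty and present:
        summary = (
            ok.groupby(["prompt", "backend_id", "pathway"], sort=True)[present]
            .agg(["mean", "median", "count"])
        )
        summary.columns = ["_".join(c) for c in summary.columns]
        summary = summary.reset_index()
    else:
        summary = pd.DataFrame()

    hist_rows = []
    score_col = "bpiou" if "bpiou" in ok.columns else "quality_score"
    if not ok.empty:
        for (prompt, backend), grp in ok.groupby(["prompt", "backend_id"], sort=True):
            counts, _ = np.histogram(grp[score_col].to_numpy(dtype=float), bins=HISTOGRAM_EDGES)
            for lo, hi, c in zip(HISTOGRAM_EDGES[:-1], HISTOGRAM_EDGES[1:], counts):
                hist_rows.append(
                    {
                        "prompt": prompt,
                        "backend_id": backend,
                        "bin_low": lo,
                        "bin_high": hi,
                        "count": int(c),
                        "metric": score_col,
                    }
                )
    histogram = pd.DataFrame(hist_rows)

    calib = None
    if "stability" in ok.columns and len(ok) >= 2 and "iou" in ok.columns:
        probs = scores_to_probabilities(ok["stability"].to_numpy(dtype=float))
        outcomes = (ok["iou"].to_numpy(dtype=float) >= config.iou_cutoff).astype(int)
        calib = calibration_table(probs, outcomes, n_bins=config.calibration_bins)

    manifest = {
        "seed": config.seed,
        "backend": config.backend,
        "pathway": config.pathway,
        "prompts": [build_prompt(p) for p in config.prompts],
        "refine_enabled": config.refine_enabled,
        "detector_jitter": config.detector_jitter,
        "n_images": len(items),
        "n_failed": len(failed),
        "failed": {r.image_id: r.status for r in failed},
        "histogram_edges": [float(e) for e in HISTOGRAM_EDGES],
        "artifacts": sorted(
            name for rep in reports for name in rep.artifacts
        ),
    }

    out_dir = Path(config.output_dir) if config.output_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        histogram.to_csv(out_dir / "histogram.csv", index=False)
        if calib is not None:
            calib.to_csv(out_dir / "calibration.csv")
            plot_reliability(calib, out_dir / "calibration.png")
        with (out_dir / "manifest.yaml").open("w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    return BatchReport(
        reports=reports,
        metrics=metrics,
        summary=summary,
        histogram=histogram,
        calibration=calib,
        manifest=manifest,
        output_dir=out_dir,
    )
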
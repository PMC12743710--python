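"""Segmentation quality metrics: IoU, BPIoU, Dice loss, stability score.

All overlap metrics operate on masks of equal shape.  IoU (Jaccard index)
is |A ∩ B| / |A ∪ B|.  BPIoU ("binarized predicted IoU") first binarizes
a possibly soft prediction at a threshold (default 0.5) and then takes the
IoU against the boolean ground truth; on an already-boolean prediction it
reduces to plain IoU.  The Dice loss uses the squared-sum (soft) form

    L_dice = 1 - 2 Σ(g · p) / (Σ g² + Σ p²)

which on boolean masks coincides with the classical 1 - 2|A∩B|/(|A|+|B|)
since v² = v for v in {0, 1}.

The stability score quantifies how robust a segmenter is to small prompt
perturbations: the box prompt is jittered n times (or, in image mode, the
image is perturbed with noise), each perturbation is segmented, and the
score is the mean pairwise IoU among the selected masks — 1.0 means the
segmentation is insensitive to the perturbation.

Empty-mask conventions: two empty masks agree perfectly (IoU 1, Dice loss
0, with a warning for the Dice case), so agreement never scores worse than
disagreement.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .detection import BoundingBox
from .segmentation import SegmentationBackendError, Segmenter, segment, select_candidate

__all__ = [
    "MaskPair",
    "iou",
    "bpiou",
    "dice_coefficient",
    "dice_loss",
    "stability_score",
]


@dataclass(frozen=True)
class MaskPair:
    """A predicted mask (boolean or soft, values in [0,1]) with its ground truth."""

    predicted: np.ndarray
    ground_truth: np.ndarray

    def __post_init__(self) -> None:
        pred, gt = np.asarray(self.predicted), np.asarray(self.ground_truth)
        if pred.shape != gt.shape:
            raise ValueError(f"shape mismatch: predicted {pred.shape} vs ground truth {gt.shape}")
        if gt.dtype != bool and not np.isin(gt, (0, 1)).all():
            raise ValueError("ground truth must be strictly boolean")
        if pred.dtype != bool and (pred.min() < 0 or pred.max() > 1):
            raise ValueError("soft predictions must lie in [0,1]")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks; both-empty -> 1.0."""
    a, b = _check_pair(a, b)
    a, b = a.astype(bool), b.astype(bool)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def bpiou(predicted: np.ndarray, ground_truth: np.ndarray, threshold: float = 0.5) -> float:
    """IoU of the binarized prediction against the ground truth.

    A soft prediction is thresholded at ``threshold`` (soft value >=
    threshold -> foreground); boolean input is used unchanged and the
    threshold is ignored.
    """
    predicted, ground_truth = _check_pair(predicted, ground_truth)
    if predicted.dtype == bool:
        binarized = predicted
    else:
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold {threshold} outside [0,1]")
        binarized = predicted >= threshold
    return iou(binarized, ground_truth.astype(bool))


def dice_coefficient(predicted: np.ndarray, ground_truth: np.ndarray) -> float:
    """Soft (squared-sum) Dice coefficient; both-empty -> 1.0 with warning."""
    predicted, ground_truth = _check_pair(predicted, ground_truth)
    p = predicted.astype(float)
    g = ground_truth.astype(float)
    denom = (g * g).sum() + (p * p).sum()
    if denom == 0:
        warnings.warn("both masks empty: Dice defined as perfect agreement", stacklevel=2)
        return 1.0
    return float(2.0 * (g * p).sum() / denom)


def dice_loss(predicted: np.ndarray, ground_truth: np.ndarray) -> float:
    """1 minus the soft Dice coefficient."""
    return 1.0 - dice_coefficient(predicted, ground_truth)


def stability_score(
    segmenter: Segmenter,
    image: np.ndarray,
    box: BoundingBox,
    jitter: int = 5,
    n_perturbations: int = 8,
    seed: int = 0,
    mode: str = "box",
    noise_sd: float = 5.0,
    policy: str = "best_score",
) -> float:
    """Mean pairwise IoU among segmentations of n perturbed prompts.

    ``mode="box"`` (default) jitters the box by seeded integer offsets up
    to +/-jitter per axis; ``mode="image"`` leaves the box alone and adds
    seeded Gaussian noise (sd ``noise_sd``) to the image instead.  Needs
    n >= 2; segmentation failures report the perturbation index.
    """
    if n_perturbations < 2:
        raise ValueError("stability needs at least 2 perturbations")
    if mode not in ("box", "image"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    image = np.asarray(image)
    rng = np.random.default_rng(seed)
    masks = []
    for i in range(n_perturbations):
        if mode == "box":
            dx, dy = (
                rng.integers(-jitter, jitter + 1, size=2) if jitter > 0 else (0, 0)
            )
            pert_box = box.translate(int(dx), int(dy))
            clipped = pert_box.clip_to(image.shape[:2])
            pert_box = clipped if clipped is not None else box
            pert_image = image
        else:
            pert_box = box
            pert_image = image + rng.normal(0.0, noise_sd, image.shape)
        try:
            result = segment(segmenter, pert_image, pert_box)
        except (ValueError, SegmentationBackendError) as exc:
            raise RuntimeError(f"perturbation {i} failed: {exc}") from exc
        masks.append(select_candidate(result, policy=policy))
    pair_ious = [iou(a, b) for a, b in itertools.combinations(masks, 2)]
    return float(np.mean(pair_ious))
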
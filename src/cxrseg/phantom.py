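"""Synthetic chest phantoms with exact ground truth, and oracle backends.

A phantom emulates the geometry a frontal chest radiograph presents to a
segmentation pipeline: two roughly elliptical radiolucent (dark) lung
fields of unequal size and position on a brighter, optionally noisy
thoracic background.  Because each lung field is an analytic ellipse, the
per-lobe ground-truth masks are exact, which makes every downstream stage
(detection, box refinement, segmentation, metrics, calibration) testable
without any pre-trained model weights.

Two deterministic *oracle* backends are provided:

* :class:`OracleDetector` — stands in for a text-grounded object detector.
  It parses the anatomical side out of the prompt, returns the tight
  bounding box of the named lobe (optionally displaced by a seeded jitter,
  with a confidence that decays with displacement), and returns both lobes
  for side-less prompts, mirroring the multi-detection behaviour real
  grounded detectors show on "lung"-only prompts.
* :class:`OracleSegmenter` — stands in for a box-promptable segmenter.  It
  thresholds inside the box (Otsu) and scores the result by the fraction
  of the intersected dark connected components captured, so the score is
  maximal exactly when the box contains the whole lobe.  That property
  gives the box-refinement stage a verifiable objective landscape.

By default the phantom follows radiographic convention: the patient's
right lung appears on the image's left side.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .detection import BoundingBox
from .preprocess import PreprocessConfig, binarize, save_image, save_mask
from .segmentation import SegmentationResult

__all__ = [
    "LobeEllipse",
    "PhantomSpec",
    "generate_phantom",
    "tight_box",
    "OracleDetector",
    "OracleSegmenter",
    "save_phantom",
]


@dataclass(frozen=True)
class LobeEllipse:
    """One lung field as a rotated ellipse.

    center is (row, col); semi-axes (a, b) are along the unrotated row and
    column directions; rotation is counter-clockwise degrees; intensity is
    the interior gray level (must be darker than the background).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float = 0.0
    intensity: float = 60.0

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Boolean point-in-ellipse test (boundary inclusive)."""
        cy, cx = self.center
        a, b = self.semi_axes
        th = math.radians(self.rotation_deg)
        dr, dc = rows - cy, cols - cx
        u = dr * math.cos(th) + dc * math.sin(th)
        v = -dr * math.sin(th) + dc * math.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def bounding_extent(self) -> tuple[float, float]:
        """Half-extents (row, col) of the rotated ellipse's tight AABB."""
        a, b = self.semi_axes
        th = math.radians(self.rotation_deg)
        er = math.hypot(a * math.cos(th), b * math.sin(th))
        ec = math.hypot(a * math.sin(th), b * math.cos(th))
        return er, ec


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic chest phantom.

    ``lobes`` maps anatomical side ("right"/"left") to its ellipse.  With
    ``radiographic=True`` (default) the patient's right lobe should sit on
    the image's left half; the flag is informational and not enforced, but
    the default layout respects it.  Lung interiors must be darker than
    the background (lungs are radiolucent), both ellipses must lie fully
    inside the image, and their pixel masks must be disjoint.
    """

    height: int = 224
    width: int = 224
    lobes: dict[str, LobeEllipse] = field(default_factory=dict)
    background_intensity: float = 180.0
    noise_sd: float = 0.0
    seed: int = 0
    radiographic: bool = True

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if set(self.lobes) != {"right", "left"}:
            raise ValueError('lobes must have exactly the keys "right" and "left"')
        for side, lobe in self.lobes.items():
            if lobe.intensity >= self.background_intensity:
                raise ValueError(
                    f"{side} lobe intensity {lobe.intensity} not darker than "
                    f"background {self.background_intensity}"
                )
            cy, cx = lobe.center
            er, ec = lobe.bounding_extent()
            if cy - er < 0 or cy + er > self.height - 1 or cx - ec < 0 or cx + ec > self.width - 1:
                raise ValueError(f"{side} lobe ellipse exceeds image bounds")

    @classmethod
    def default(
        cls,
        height: int = 224,
        width: int = 224,
        noise_sd: float = 0.0,
        seed: int = 0,
        lobe_intensity: float = 60.0,
        background_intensity: float = 180.0,
        asymmetry: float = 0.85,
    ) -> "PhantomSpec":
        """A realistic two-lobe layout scaled to the requested size.

        The left lung is drawn slightly smaller than the right
        (``asymmetry`` scales its semi-axes), mimicking the cardiac
        silhouette encroaching on the left lung field.  Radiographic
        convention: the patient's right lobe occupies the image's left
        half.
        """
        h, w = height, width
        right = LobeEllipse(
            center=(0.52 * h, 0.30 * w),
            semi_axes=(0.31 * h, 0.16 * w),
            rotation_deg=-6.0,
            intensity=lobe_intensity,
        )
        left = LobeEllipse(
            center=(0.50 * h, 0.70 * w),
            semi_axes=(0.31 * h * asymmetry, 0.16 * w * asymmetry),
            rotation_deg=6.0,
            intensity=lobe_intensity,
        )
        return cls(
            height=h,
            width=w,
            lobes={"right": right, "left": left},
            background_intensity=background_intensity,
            noise_sd=noise_sd,
            seed=seed,
        )


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render a phantom image and its exact per-lobe ground-truth masks.

    Returns (image, masks) where image is float64 clipped to [0, 255] and
    masks maps "right"/"left" to boolean arrays.  Identical spec (including
    seed) gives bit-identical output.  Overlapping lobes are rejected:
    disjoint masks are what makes the left/right ground truth well defined.
    """
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    masks = {side: lobe.contains(rows, cols) for side, lobe in spec.lobes.items()}
    if (masks["right"] & masks["left"]).any():
        raise ValueError("lobe ellipses overlap: ground-truth masks must be disjoint")
    image = np.full((spec.height, spec.width), float(spec.background_intensity))
    for side, lobe in spec.lobes.items():
        image[masks[side]] = float(lobe.intensity)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    return np.clip(image, 0.0, 255.0), masks


def tight_box(mask: np.ndarray, confidence: float = 1.0, phrase: str = "") -> BoundingBox:
    """Tight half-open bounding box of a nonempty boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return BoundingBox(
        x_min=int(cols[0]),
        y_min=int(rows[0]),
        x_max=int(cols[-1]) + 1,
        y_max=int(rows[-1]) + 1,
        confidence=confidence,
        phrase=phrase,
    )


_SIDE_TOKENS = {"left", "right"}
_ANATOMY_TOKENS = {"lung", "lungs", "lobe", "lobes"}


def _tokens(prompt: str) -> list[str]:
    return [t for t in re.split(r"[^a-z]+", prompt.lower()) if t]


class OracleDetector:
    """Ground-truth-backed detector with controllable localization error.

    Parses "left"/"right" and "lung"/"lobe" tokens from the prompt.  A
    sided prompt yields the tight box of that lobe; a side-less anatomical
    prompt yields both lobes; a prompt with no anatomical token yields
    nothing.  With ``jitter > 0`` the box is translated by a seeded random
    offset up to +/-jitter pixels per axis and the confidence decays as
    ``exp(-|offset| / confidence_scale)``; jitter 0 gives the exact box at
    confidence 1.  Detection is a pure function of (masks, jitter, seed,
    prompt), so repeated calls are identical.
    """

    backend_id = "oracle"

    def __init__(
        self,
        gt_masks: dict[str, np.ndarray],
        jitter: int = 0,
        seed: int = 0,
        confidence_scale: float = 10.0,
    ) -> None:
        if jitter < 0:
            raise ValueError("jitter must be non-negative")
        if confidence_scale <= 0:
            raise ValueError("confidence_scale must be positive")
        self.gt_masks = {k: np.asarray(v, dtype=bool) for k, v in gt_masks.items()}
        self.jitter = int(jitter)
        self.seed = int(seed)
        self.confidence_scale = float(confidence_scale)

    def _box_for(self, side: str, phrase: str, shape: tuple[int, int], rng) -> BoundingBox | None:
        box = tight_box(self.gt_masks[side], phrase=phrase)
        if self.jitter > 0:
            dx, dy = rng.integers(-self.jitter, self.jitter + 1, size=2)
            conf = math.exp(-math.hypot(dx, dy) / self.confidence_scale)
            box = box.translate(int(dx), int(dy))
            box = BoundingBox(
                box.x_min, box.y_min, box.x_max, box.y_max,
                confidence=conf, phrase=phrase,
            )
            clipped = box.clip_to(shape)
            if clipped is None:
                return None
            box = clipped
        return box

    def detect_raw(
        self, image: np.ndarray, prompt: str, text_threshold: float = 0.25
    ) -> list[BoundingBox]:
        toks = set(_tokens(prompt))
        if not toks & _ANATOMY_TOKENS:
            return []
        sides = sorted(toks & _SIDE_TOKENS) or ["right", "left"]
        # Fresh generator per call keeps detection a pure function of the
        # constructor arguments and the prompt.
        rng = np.random.default_rng([self.seed, len(prompt)])
        shape = np.asarray(image).shape[:2]
        out = []
        for side in sides:
            box = self._box_for(side, prompt, shape, rng)
            if box is not None:
                out.append(box)
        return out

    def box_confidence(self, image: np.ndarray, box: BoundingBox, phrase: str) -> float:
        """Confidence this detector would assign to an arbitrary box.

        Decays with the displacement of the box's corners from the named
        (or nearest) lobe's tight box; used as the detector-confidence
        refinement objective.
        """
        toks = set(_tokens(phrase))
        sides = sorted(toks & _SIDE_TOKENS) or ["right", "left"]
        best = 0.0
        for side in sides:
            ref = tight_box(self.gt_masks[side])
            d = math.hypot(box.x_min - ref.x_min, box.y_min - ref.y_min) / 2 + math.hypot(
                box.x_max - ref.x_max, box.y_max - ref.y_max
            ) / 2
            best = max(best, math.exp(-d / self.confidence_scale))
        return best


class OracleSegmenter:
    """Box-promptable segmenter driven by local thresholding.

    Inside the (clipped) box, pixels below an Otsu threshold computed on
    the box contents are taken as foreground.  The quality score is the
    captured fraction of the dark connected components the box touches:
    score 1 exactly when every touched component lies fully inside the box.
    On a noiseless phantom with the tight lobe box this reproduces the
    ground-truth mask with score 1.0.

    ``erosion`` > 0 erodes the produced mask by that many iterations — a
    deliberately degraded variant for backend-comparison experiments.
    """

    def __init__(self, erosion: int = 0, backend_id: str = "oracle") -> None:
        if erosion < 0:
            raise ValueError("erosion must be non-negative")
        self.erosion = int(erosion)
        self.backend_id = backend_id if erosion == 0 else f"{backend_id}_eroded{erosion}"

    def segment_raw(self, image: np.ndarray, box: BoundingBox) -> SegmentationResult:
        image = np.asarray(image)
        shape = image.shape[:2]
        empty = np.zeros(shape, dtype=bool)
        clipped = box.clip_to(shape)
        if clipped is None or clipped.area == 0:
            return SegmentationResult(
                candidates=[(empty, 0.0)], box_used=box, backend_id=self.backend_id
            )
        sl = clipped.slices()
        patch = image[sl]
        # Dark pixels inside the box: below the box-local Otsu threshold.
        bright, _t = binarize(patch, PreprocessConfig(threshold_mode="otsu"))
        dark_in_box = ~bright
        mask = empty.copy()
        mask[sl] = dark_in_box
        if not mask.any():
            return SegmentationResult(
                candidates=[(mask, 0.0)], box_used=box, backend_id=self.backend_id
            )
        # Captured fraction of the touched dark connected components,
        # measured against the same threshold applied to the whole image.
        dark_global = image < _t
        labels, _n = ndimage.label(dark_global)
        touched = np.unique(labels[mask & (labels > 0)])
        if touched.size == 0:
            score = 0.0
        else:
            total = int(np.isin(labels, touched).sum())
            captured = int(mask[np.isin(labels, touched)].sum())
            score = captured / total if total else 0.0
        if self.erosion > 0 and mask.any():
            before = int(mask.sum())
            mask = ndimage.binary_erosion(mask, iterations=self.erosion)
            score *= float(mask.sum()) / before
        return SegmentationResult(
            candidates=[(mask, float(score))], box_used=box, backend_id=self.backend_id
        )


def save_phantom(
    directory: str | Path, image_id: str, image: np.ndarray, masks: dict[str, np.ndarray]
) -> dict[str, Path]:
    """Write a phantom and its masks as PNGs; return the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"image": directory / f"{image_id}.png"}
    save_image(paths["image"], np.rint(image).astype(np.uint8))
    for side, mask in masks.items():
        p = directory / f"{image_id}__gt_{side}.png"
        save_mask(p, mask)
        paths[f"gt_{side}"] = p
    return paths
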
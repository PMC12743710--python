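"""Detector contract, confidence thresholding, and coordinate mapping.

A *detector* turns an image plus a free-text anatomical prompt into scored,
phrase-labeled axis-aligned bounding boxes.  Two implementations ship with
the package: the deterministic oracle built on phantom ground truth
(:mod:`cxrseg.phantom`), and an optional Grounding DINO adapter
(:mod:`cxrseg.backends`) that loads only when its heavy dependencies are
installed.

:func:`detect` applies the confidence (box) threshold and sorts the
survivors; :func:`detect_on_binary` runs the binarized-image pathway, where
detection happens on a rendered binary image at working resolution and the
boxes are mapped back to original coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Protocol, runtime_checkable

import numpy as np

from .preprocess import PreprocessConfig, binarize, render_binary, resize, to_grayscale

__all__ = [
    "BoundingBox",
    "DetectorConfig",
    "Detector",
    "DetectionBackendError",
    "detect",
    "detect_on_binary",
    "map_box",
]


class DetectionBackendError(RuntimeError):
    """A detection backend failed (distinct from a clean empty result)."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, half-open on both axes.

    ``[x_min, x_max) x [y_min, y_max)`` in the stated image space, with the
    backend's confidence score and the text phrase that produced it.
    """

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    confidence: float = 1.0
    phrase: str = ""
    source_space: str = "original"

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0,1]")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def translate(self, dx: int, dy: int) -> "BoundingBox":
        return replace(
            self,
            x_min=self.x_min + dx,
            x_max=self.x_max + dx,
            y_min=self.y_min + dy,
            y_max=self.y_max + dy,
        )

    def clip_to(self, shape: tuple[int, int]) -> "BoundingBox | None":
        """Clip to image bounds; None if nothing remains."""
        h, w = shape
        x0, x1 = max(self.x_min, 0), min(self.x_max, w)
        y0, y1 = max(self.y_min, 0), min(self.y_max, h)
        if x0 >= x1 or y0 >= y1:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)

    def intersects(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return self.x_min < w and self.x_max > 0 and self.y_min < h and self.y_max > 0

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices for indexing an image array."""
        return slice(self.y_min, self.y_max), slice(self.x_min, self.x_max)

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "y_min": self.y_min,
            "x_max": self.x_max,
            "y_max": self.y_max,
            "confidence": self.confidence,
            "phrase": self.phrase,
            "source_space": self.source_space,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoundingBox":
        return cls(**d)

    def to_coco(self, image_id: int = 0, category_id: int = 1) -> dict:
        """COCO detection record: bbox is [x, y, width, height]."""
        return {
            "image_id": image_id,
            "category_id": category_id,
            "bbox": [self.x_min, self.y_min, self.width, self.height],
            "score": self.confidence,
        }


@dataclass(frozen=True)
class DetectorConfig:
    """Confidence thresholds applied to detector output.

    ``box_threshold`` filters detections by confidence; ``text_threshold``
    is forwarded to backends that ground phrases (the oracle ignores it).
    Both default to 0.25.
    """

    box_threshold: float = 0.25
    text_threshold: float = 0.25

    def __post_init__(self) -> None:
        for name in ("box_threshold", "text_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0,1]")


@runtime_checkable
class Detector(Protocol):
    """Backend contract: raw (unfiltered) detections for an image + prompt."""

    def detect_raw(
        self, image: np.ndarray, prompt: str, text_threshold: float = 0.25
    ) -> list[BoundingBox]: ...


def detect(
    detector: Detector,
    image: np.ndarray,
    prompt: str,
    config: DetectorConfig | None = None,
) -> list[BoundingBox]:
    """Run a detector and keep detections with confidence >= box_threshold.

    Survivors are sorted by descending confidence (stable, so the backend's
    order breaks ties).  An empty result is a valid outcome — the backend
    simply found nothing above threshold; backend exceptions are wrapped in
    :class:`DetectionBackendError`.
    """
    config = config or DetectorConfig()
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if not prompt:
        raise ValueError("empty prompt")
    try:
        raw = detector.detect_raw(image, prompt, text_threshold=config.text_threshold)
    except Exception as exc:  # noqa: BLE001 - contract: wrap backend failures
        raise DetectionBackendError(f"detection backend failed: {exc}") from exc
    kept = [b for b in raw if b.confidence >= config.box_threshold]
    return sorted(kept, key=lambda b: -b.confidence)


def detect_on_binary(
    detector: Detector,
    image: np.ndarray,
    prompt: str,
    pre_config: PreprocessConfig | None = None,
    det_config: DetectorConfig | None = None,
) -> list[BoundingBox]:
    """Binarized-image detection pathway.

    The image is converted to grayscale, resized to the working resolution,
    thresholded, and rendered as a binary image; detection runs on that
    rendering and boxes are mapped back to original coordinates, tagged
    ``source_space="binary"``.
    """
    pre_config = pre_config or PreprocessConfig()
    gray = to_grayscale(np.asarray(image))
    resized, (sy, sx) = resize(gray, pre_config)
    mask, _ = binarize(resized, pre_config)
    rendered = render_binary(mask, pre_config)
    boxes = detect(detector, rendered, prompt, det_config)
    return [map_box(b, (1.0 / sy, 1.0 / sx), "binary") for b in boxes]


def map_box(
    box: BoundingBox, scale: tuple[float, float], target_space: str
) -> BoundingBox:
    """Rescale a box between image spaces, preserving coverage.

    ``scale`` is (sy, sx) multiplying y and x coordinates respectively.
    Mins are floored and maxes ceiled so the mapped box never loses pixels
    covered by the original.
    """
    sy, sx = scale
    if sy <= 0 or sx <= 0:
        raise ValueError(f"non-positive scale {scale}")
    return replace(
        box,
        x_min=math.floor(box.x_min * sx),
        y_min=math.floor(box.y_min * sy),
        x_max=math.ceil(box.x_max * sx),
        y_max=math.ceil(box.y_max * sy),
        source_space=target_space,
    )
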
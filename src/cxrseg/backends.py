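"""Optional heavyweight detector/segmenter adapters.

The core package runs and is tested entirely with the oracle backends; the
adapters here wrap real pre-trained models behind the same
:class:`~cxrseg.detection.Detector` / :class:`~cxrseg.segmentation.Segmenter`
contracts.  They import their dependencies lazily and raise
:class:`MissingBackendError` with an actionable message when those
dependencies (torch, segment-anything, groundingdino) are not installed —
the adapters are plugins, not requirements.
"""

from __future__ import annotations

import numpy as np

from .detection import BoundingBox
from .segmentation import SegmentationResult

__all__ = [
    "MissingBackendError",
    "GroundingDinoDetector",
    "SamSegmenter",
    "load_backend_pair",
]

SAM_VARIANTS = ("vit_b", "vit_l", "vit_h")


class MissingBackendError(ImportError):
    """An optional model backend's dependencies are not installed."""


class GroundingDinoDetector:
    """Text-grounded detector adapter (requires torch + groundingdino).

    Emits phrase-labeled boxes in pixel coordinates; the text threshold is
    applied inside the model's phrase grounding, the box threshold by
    :func:`cxrseg.detection.detect` as for every backend.
    """

    backend_id = "grounding_dino"

    def __init__(self, weights_path: str, config_path: str, device: str = "cpu") -> None:
        try:
            import torch  # noqa: F401
            from groundingdino.util.inference import load_model
        except ImportError as exc:
            raise MissingBackendError(
                "GroundingDinoDetector needs the optional 'torch' and "
                "'groundingdino' packages plus model weights"
            ) from exc
        self._model = load_model(config_path, weights_path)
        self._device = device

    def detect_raw(
        self, image: np.ndarray, prompt: str, text_threshold: float = 0.25
    ) -> list[BoundingBox]:
        import torch
        from groundingdino.util.inference import predict

        rgb = np.stack([np.asarray(image)] * 3, axis=-1).astype(np.float32)
        tensor = torch.from_numpy(rgb / 255.0).permute(2, 0, 1)
        h, w = image.shape[:2]
        boxes, logits, phrases = predict(
            model=self._model,
            image=tensor,
            caption=prompt,
            box_threshold=0.0,  # filtering belongs to detect()
            text_threshold=text_threshold,
            device=self._device,
        )
        out = []
        for (cx, cy, bw, bh), conf, phrase in zip(
            boxes.tolist(), logits.tolist(), phrases
        ):
            out.append(
                BoundingBox(
                    x_min=int((cx - bw / 2) * w),
                    y_min=int((cy - bh / 2) * h),
                    x_max=int((cx + bw / 2) * w),
                    y_max=int((cy + bh / 2) * h),
                    confidence=float(min(max(conf, 0.0), 1.0)),
                    phrase=phrase,
                )
            )
        return out


class SamSegmenter:
    """Promptable-segmenter adapter for SAM checkpoints (vit_b/l/h).

    The model's predicted-IoU estimates fill the quality-score slot;
    ``multimask_output`` controls whether the single- or multi-mask head
    is used.
    """

    def __init__(
        self,
        checkpoint_path: str,
        variant: str = "vit_h",
        device: str = "cpu",
        multimask_output: bool = True,
    ) -> None:
        if variant not in SAM_VARIANTS:
            raise ValueError(f"variant must be one of {SAM_VARIANTS}")
        try:
            import torch  # noqa: F401
            from segment_anything import SamPredictor, sam_model_registry
        except ImportError as exc:
            raise MissingBackendError(
                "SamSegmenter needs the optional 'torch' and "
                "'segment-anything' packages plus a checkpoint"
            ) from exc
        sam = sam_model_registry[variant](checkpoint=checkpoint_path)
        sam.to(device)
        self._predictor = SamPredictor(sam)
        self.backend_id = variant
        self.multimask_output = multimask_output

    def segment_raw(self, image: np.ndarray, box: BoundingBox) -> SegmentationResult:
        rgb = np.stack([np.asarray(image)] * 3, axis=-1).astype(np.uint8)
        self._predictor.set_image(rgb)
        masks, scores, _ = self._predictor.predict(
            box=np.array([box.x_min, box.y_min, box.x_max, box.y_max]),
            multimask_output=self.multimask_output,
        )
        candidates = [
            (m.astype(bool), float(min(max(s, 0.0), 1.0)))
            for m, s in zip(masks, scores)
        ]
        return SegmentationResult(
            candidates=candidates, box_used=box, backend_id=self.backend_id
        )


def load_backend_pair(backend: str):
    """Resolve a plugin backend id like ``"dino+vit_h"`` to instances.

    Kept deliberately strict: weights paths must come from environment
    configuration, so the core pipeline never silently downloads models.
    """
    raise MissingBackendError(
        f"backend {backend!r} is a plugin backend; construct "
        "GroundingDinoDetector / SamSegmenter explicitly with weight paths "
        "and pass them to the pipeline, or use the 'oracle' backend"
    )
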
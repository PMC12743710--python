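"""Radiograph preprocessing: grayscale conversion, resizing, binarization.

The preprocessing chain standardizes inputs ahead of text-prompted
detection: multi-channel images are collapsed to a single luminance
channel, resized to a working resolution (224x224 by default), and
optionally binarized.  Binarization follows the thresholding rule

    B(x, y) = 1  if I(x, y) >= T,   0 otherwise

where ``T`` is either a fixed value (default 127) or chosen automatically
by Otsu's method, which maximizes the between-class intensity variance of
the two classes the threshold induces.  The boolean mask is the canonical
binary representation; :func:`render_binary` encodes it as a grayscale
image (foreground 196 by default) for detectors that consume images.

Coordinate bookkeeping: :func:`resize` returns the (sy, sx) scale factors
so that boxes found in resized space can be mapped back exactly.  Pixel
indices are 0-based; boxes are half-open ``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import resize_local_mean as _sk_resize_local_mean

__all__ = [
    "PreprocessConfig",
    "to_grayscale",
    "resize",
    "otsu_threshold",
    "binarize",
    "render_binary",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
]

# Rec.601 luma weights for RGB -> grayscale.
_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the preprocessing chain.

    Parameters
    ----------
    target_size : (height, width) of the working resolution.
    threshold_mode : ``"otsu"`` (automatic, default) or ``"fixed"``.
    fixed_threshold : intensity used in fixed mode, and the fallback when
        Otsu is requested on a constant image.
    binar_high_value : intensity assigned to foreground pixels when a
        boolean mask is rendered back to a grayscale image.
    interpolation : ``"area"`` (local-mean averaging, good for downscale),
        ``"nearest"`` or ``"linear"``.
    """

    target_size: tuple[int, int] = (224, 224)
    threshold_mode: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float = 127
    binar_high_value: int = 196
    interpolation: Literal["area", "nearest", "linear"] = "area"

    def __post_init__(self) -> None:
        th, tw = self.target_size
        if th <= 0 or tw <= 0:
            raise ValueError(f"target_size must be positive, got {self.target_size}")
        if self.fixed_threshold < 0:
            raise ValueError("fixed_threshold must be non-negative")
        if self.binar_high_value <= 0:
            raise ValueError("binar_high_value must be positive")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.interpolation not in ("area", "nearest", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a 1- or 3-channel image to a single channel.

    Already-grayscale (2-D) input is returned unchanged.  3-channel input
    is combined with the Rec.601 luma weights (0.299 R + 0.587 G + 0.114 B)
    and rounded back to the input's integer dtype when applicable.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0]
    if image.ndim == 3 and image.shape[2] == 3:
        gray = image.astype(float) @ _REC601
        if np.issubdtype(image.dtype, np.integer):
            info = np.iinfo(image.dtype)
            gray = np.clip(np.rint(gray), info.min, info.max).astype(image.dtype)
        return gray
    n = image.shape[2] if image.ndim == 3 else image.ndim
    raise ValueError(f"unsupported channel count: {n} (expected 1 or 3 channels)")


def resize(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Resize to the working resolution; return the image and (sy, sx).

    The scale factors are target/original per axis, so a coordinate in
    original space maps to resized space by multiplication, and back by
    division.
    """
    config = config or PreprocessConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("resize expects a single-channel image")
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    th, tw = config.target_size
    h, w = image.shape
    sy, sx = th / h, tw / w
    if (h, w) == (th, tw):
        return image.copy(), (1.0, 1.0)
    if config.interpolation == "area":
        out = _sk_resize_local_mean(image.astype(float), (th, tw))
    else:
        order = 0 if config.interpolation == "nearest" else 1
        out = _sk_resize(
            image.astype(float), (th, tw), order=order, anti_aliasing=False,
            preserve_range=True,
        )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out, (sy, sx)


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's automatic threshold for an integer-valued image.

    Returns the integer T maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2`` of the split ``{I < T}`` / ``{I >= T}``,
    with T ranging over the observed intensity range.  Ties are broken
    toward the smallest T.  Raises on a constant image (no split exists).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    vals = np.rint(image).astype(np.int64)
    lo, hi = int(vals.min()), int(vals.max())
    if lo == hi:
        raise ValueError("constant image has no Otsu threshold")
    counts = np.bincount((vals - lo).ravel(), minlength=hi - lo + 1).astype(float)
    levels = np.arange(lo, hi + 1, dtype=float)
    total = counts.sum()
    # For candidate T = lo+1 .. hi: class0 = levels < T, class1 = levels >= T.
    w0 = np.cumsum(counts)[:-1]  # pixels below each candidate T
    w1 = total - w0
    s0 = np.cumsum(counts * levels)[:-1]
    s1 = counts @ levels - s0
    with np.errstate(invalid="ignore", divide="ignore"):
        var_between = w0 * w1 * (s0 / w0 - s1 / w1) ** 2
    var_between = np.nan_to_num(var_between, nan=-1.0)
    return int(lo + 1 + np.argmax(var_between))


def binarize(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, float]:
    """Threshold an image to a boolean mask; return (mask, threshold used).

    Foreground is ``I >= T``.  In ``otsu`` mode T is computed from the
    image; a constant image falls back to the configured fixed threshold
    with a warning.  In ``fixed`` mode the configured value is used as is.
    """
    config = config or PreprocessConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("binarize expects a single-channel image")
    if config.threshold_mode == "otsu":
        try:
            t: float = otsu_threshold(image)
        except ValueError:
            warnings.warn(
                "constant image: Otsu undefined, falling back to fixed threshold",
                stacklevel=2,
            )
            t = config.fixed_threshold
    else:
        t = config.fixed_threshold
    return image >= t, t


def render_binary(mask: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Encode a boolean mask as a grayscale image (True -> high value, False -> 0)."""
    config = config or PreprocessConfig()
    mask = np.asarray(mask, dtype=bool)
    dtype = np.uint8 if config.binar_high_value <= 255 else np.uint16
    return (mask.astype(dtype)) * dtype(config.binar_high_value)


# ---------------------------------------------------------------------------
# Image I/O: 8/16-bit PNG and DICOM pixel arrays.

def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale radiograph from PNG or DICOM.

    DICOM MONOCHROME1 (inverted) data is flipped to MONOCHROME2 semantics
    so dark always means radiolucent.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
            arr = arr.max() - arr
        return to_grayscale(np.asarray(arr))
    import imageio.v3 as iio

    return to_grayscale(np.asarray(iio.imread(path)))


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a grayscale image as 8- or 16-bit PNG."""
    import imageio.v3 as iio

    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.integer):
        image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    elif image.dtype not in (np.uint8, np.uint16):
        image = image.astype(np.uint16 if image.max() > 255 else np.uint8)
    iio.imwrite(Path(path), image)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(mask, dtype=bool).astype(np.uint8) * 255)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask back to boolean (any nonzero pixel is True)."""
    import imageio.v3 as iio

    return np.asarray(iio.imread(Path(path))) > 0
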
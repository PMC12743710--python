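import math

import numpy as np
import pytest

from cxrseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom128():
    """Noiseless 128x128 two-lobe phantom with exact ground truth."""
    spec = PhantomSpec.default(128, 128)
    image, masks = generate_phantom(spec)
    return spec, image, masks


@pytest.fixture(scope="session")
def phantom64():
    """Small noiseless phantom for exhaustive sweeps."""
    spec = PhantomSpec.default(64, 64)
    image, masks = generate_phantom(spec)
    return spec, image, masks


def brute_force_ellipse(lobe, height, width):
    """Per-pixel point-in-ellipse rasterization (independent loop oracle)."""
    cy, cx = lobe.center
    a, b = lobe.semi_axes
    th = math.radians(lobe.rotation_deg)
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            u = (r - cy) * math.cos(th) + (c - cx) * math.sin(th)
            v = -(r - cy) * math.sin(th) + (c - cx) * math.cos(th)
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                mask[r, c] = True
    return mask


def brute_force_tight_box(mask):
    """Loop-based tight box (x_min, y_min, x_max, y_max), half-open."""
    xs, ys = [], []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                ys.append(r)
                xs.append(c)
    return min(xs), min(ys), max(xs) + 1, max(ys) + 1


def brute_force_counts(a, b):
    """(intersection, union, |a|, |b|) by explicit pixel counting."""
    inter = union = na = nb = 0
    for va, vb in zip(a.ravel().tolist(), b.ravel().tolist()):
        va, vb = bool(va), bool(vb)
        inter += va and vb
        union += va or vb
        na += va
        nb += vb
    return inter, union, na, nb


def brute_force_otsu(image):
    """Exhaustive between-class-variance argmax over thresholds 1..255.

    Class 0 is {I < T}, class 1 is {I >= T}; smallest-T tie break.
    """
    flat = image.ravel().astype(float)
    best_t, best_var = None, -1.0
    for t in range(1, 256):
        lo = flat[flat < t]
        hi = flat[flat >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t
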
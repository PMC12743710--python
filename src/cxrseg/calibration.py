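"""Reliability-diagram calibration of segmentation quality scores.

Segmentation quality scores (stability or predicted-IoU style scores) are
turned into probability proxies, each segmentation is labeled as a binary
success or failure against ground truth, and the (probability, outcome)
pairs are binned: a model is well calibrated when, within each score bin,
the observed fraction of successes matches the mean predicted probability
— i.e. the reliability curve tracks the diagonal.

The success judgment is operationalized as an IoU cutoff (default 0.5)
so the procedure is reproducible; score-to-probability conversion is
min-max scaling by default (identity scaling available for scores already
interpretable as probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .metrics import MaskPair, iou

__all__ = [
    "CalibrationTable",
    "scores_to_probabilities",
    "assign_outcomes",
    "calibration_table",
    "plot_reliability",
]


@dataclass(frozen=True)
class CalibrationTable:
    """Per-bin calibration summary over equal-width bins of [0, 1].

    For each bin: the interval, the mean predicted probability, the
    observed fraction of positive outcomes, and the sample count.  Empty
    bins keep count 0 with NaN means/fractions.
    """

    bin_edges: np.ndarray  # length n_bins + 1
    mean_probability: np.ndarray  # per bin, NaN when empty
    fraction_positive: np.ndarray  # per bin, NaN when empty
    counts: np.ndarray  # per bin

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "mean_probability": self.mean_probability,
                "fraction_positive": self.fraction_positive,
                "count": self.counts,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def scores_to_probabilities(
    scores: Sequence[float], mode: Literal["minmax", "identity"] = "minmax"
) -> np.ndarray:
    """Scale raw quality scores to the [0, 1] probability range.

    ``minmax`` maps the observed range onto [0, 1]; a constant score list
    is degenerate (zero range) and maps to all 1.0 with a warning.
    ``identity`` passes scores through after verifying they already lie in
    [0, 1].
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be nonempty")
    if mode == "identity":
        if scores.min() < 0 or scores.max() > 1:
            raise ValueError("identity scaling requires scores already in [0,1]")
        return scores
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        warnings.warn(
            "constant scores: degenerate min-max scale, mapping all to 1.0",
            stacklevel=2,
        )
        return np.ones_like(scores)
    return (scores - lo) / (hi - lo)


def assign_outcomes(pairs: Sequence[MaskPair], iou_cutoff: float = 0.5) -> np.ndarray:
    """Binary success labels: 1 iff IoU(predicted, ground truth) >= cutoff."""
    if not 0.0 < iou_cutoff < 1.0:
        raise ValueError(f"iou_cutoff {iou_cutoff} must lie in (0,1)")
    return np.array(
        [
            1 if iou(np.asarray(p.predicted) if np.asarray(p.predicted).dtype == bool
                     else np.asarray(p.predicted) >= 0.5,
                     p.ground_truth) >= iou_cutoff else 0
            for p in pairs
        ],
        dtype=int,
    )


def calibration_table(
    probabilities: Sequence[float], outcomes: Sequence[int], n_bins: int = 10
) -> CalibrationTable:
    """Bin (probability, outcome) pairs into equal-width bins on [0, 1].

    Bins are left-closed with a right-closed last bin, so probability 1.0
    falls in the top bin.  Counts conserve the sample total exactly.
    """
    probs = np.asarray(list(probabilities), dtype=float)
    outs = np.asarray(list(outcomes), dtype=float)
    if probs.shape != outs.shape:
        raise ValueError(f"length mismatch: {probs.shape} probabilities vs {outs.shape} outcomes")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0,1]")
    idx = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sum_p = np.bincount(idx, weights=probs, minlength=n_bins)
    sum_y = np.bincount(idx, weights=outs, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_p = np.where(counts > 0, sum_p / np.maximum(counts, 1), np.nan)
        frac = np.where(counts > 0, sum_y / np.maximum(counts, 1), np.nan)
    return CalibrationTable(
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        mean_probability=mean_p,
        fraction_positive=frac,
        counts=counts,
    )


def plot_reliability(table: CalibrationTable, path: str | Path, title: str = "") -> None:
    """Reliability diagram: fraction positive vs mean probability per bin,
    with the diagonal perfect-calibration reference line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], "--", color="gray", label="perfect calibration")
    occ = table.counts > 0
    ax.plot(
        table.mean_probability[occ],
        table.fraction_positive[occ],
        "o-",
        color="tab:blue",
        label="model",
    )
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("fraction of positive outcomes")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
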
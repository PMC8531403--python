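"""Bland-Altman agreement between predicted and actual scores.

Pearson correlation only measures linear association; Bland-Altman
analysis asks whether two measurements *agree*: the bias is the mean of
the pairwise differences and the 95% limits of agreement (LOA) are
bias +/- 1.96 SD of the differences. For clinical use the LOA are
compared against the minimum clinically important difference of the
score.

Conventions fixed here: differences are predicted - actual, and the
multiplier is the classical normal quantile 1.96 (no small-sample t
correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["BlandAltmanResult", "bland_altman", "bland_altman_plot"]

LOA_MULTIPLIER = 1.96


@dataclass
class BlandAltmanResult:
    """Bias, limits of agreement and the share of points inside them."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    within_loa_fraction: float
    n: int

    @property
    def loa_width(self) -> float:
        return self.loa_high - self.loa_low


def bland_altman(predicted: np.ndarray, actual: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman statistics of predicted vs actual.

    d = predicted - actual; bias = mean(d); sd uses the n-1
    denominator; LOA = bias +/- 1.96 sd; the within-LOA fraction is the
    share of differences inside the closed interval [loa_low,
    loa_high]. For Gaussian differences roughly 95% of points are
    expected within the LOA.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size != a.size:
        raise ValueError(f"length mismatch: {p.size} vs {a.size}")
    if p.size < 3:
        raise ValueError("need at least 3 paired points")
    d = p - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = bias - LOA_MULTIPLIER * sd
    hi = bias + LOA_MULTIPLIER * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanResult(
        bias=bias, sd=sd, loa_low=lo, loa_high=hi, within_loa_fraction=within, n=p.size
    )


def bland_altman_plot(
    predicted: np.ndarray, actual: np.ndarray, out_path: str | Path, title: str = ""
) -> BlandAltmanResult:
    """Scatter of difference vs mean with bias and LOA lines, saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(predicted, actual)
    p = np.asarray(predicted, float).ravel()
    a = np.asarray(actual, float).ravel()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((p + a) / 2.0, p - a, s=18, alpha=0.7)
    ax.axhline(res.bias, color="k", lw=1, label=f"bias = {res.bias:.3g}")
    for y, lab in ((res.loa_low, "LOA low"), (res.loa_high, "LOA high")):
        ax.axhline(y, color="r", ls="--", lw=1, label=f"{lab} = {y:.3g}")
    ax.set_xlabel("mean of predicted and actual")
    ax.set_ylabel("predicted - actual")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return res
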
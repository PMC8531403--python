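"""ROI time series -> Fisher-z functional-connectivity feature vectors.

The feature construction is the one used throughout whole-brain
connectome MVPA: clean each region's BOLD-like time course (detrend,
nuisance regression, 0.01-0.08 Hz band-pass), correlate every ROI pair
(Pearson), keep the strict lower triangle of the R x R matrix and apply
Fisher's z-transformation. With the 116-region AAL parcellation this
yields the 6,670-edge feature vector that feeds every downstream
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RoiTimeSeries",
    "FcMatrix",
    "FcFeatureVector",
    "edge_pairs",
    "n_edges",
    "clean_series",
    "compute_fc",
    "vectorize",
    "devectorize",
    "fisher_z",
    "feature_table",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class RoiTimeSeries:
    """T x R matrix of per-ROI signals plus acquisition metadata."""

    values: np.ndarray
    tr: float
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D T x R array")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("TR must be positive (seconds)")
        if self.roi_labels is not None and len(self.roi_labels) != self.values.shape[1]:
            raise ValueError("roi_labels length must match the number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class FcMatrix:
    """R x R Pearson correlation matrix (symmetric, unit diagonal)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValueError("FC matrix is not symmetric within 1e-10")
        if np.max(np.abs(np.diag(v) - 1.0)) > 1e-10:
            raise ValueError("FC matrix diagonal must be exactly 1")
        if np.max(np.abs(v)) > 1.0 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 1.0)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class FcFeatureVector:
    """Length R(R-1)/2 Fisher-z edge vector in the canonical edge order."""

    values: np.ndarray
    n_rois: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != n_edges(self.n_rois):
            raise ValueError(
                f"expected {n_edges(self.n_rois)} edges for {self.n_rois} ROIs, "
                f"got {len(self.values)}"
            )

    def edge_to_rois(self, k: int) -> tuple[int, int]:
        ii, jj = edge_pairs(self.n_rois)
        return int(ii[k]), int(jj[k])


def n_edges(n_rois: int) -> int:
    """Number of distinct ROI pairs: R(R-1)/2 (6,670 for R=116)."""
    return n_rois * (n_rois - 1) // 2


@lru_cache(maxsize=32)
def edge_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: (i, j), i > j, column-major over the
    strict lower triangle — edge k runs down column 0 first (1,0),
    (2,0), ..., then column 1, and so on. Fixed and identical for every
    subject so feature k always means the same ROI pair.
    """
    jj, ii = np.triu_indices(n_rois, 1)  # row-major upper == column-major lower
    return ii, jj


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transformation z = atanh(r), variance-stabilising for
    correlations. |r| is clipped to 1 - 1e-7 so degenerate r = +/-1
    (e.g. identical synthetic columns) stays finite.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -_R_CLIP, _R_CLIP))
    return out if isinstance(r, np.ndarray) else float(out)


def clean_series(
    ts: RoiTimeSeries,
    confounds: np.ndarray | None = None,
    band: tuple[float, float] | None = (0.01, 0.08),
) -> RoiTimeSeries:
    """Detrend, regress out confounds, band-pass filter each column.

    Order of operations: linear detrend, then ordinary-least-squares
    residualisation against the confound columns (plus an implicit
    intercept), then zero-phase 4th-order Butterworth band-pass.

    Parameters
    ----------
    confounds:
        T x C nuisance matrix (motion parameters, global/WM/CSF
        signals, ...). ``None`` or zero columns skips the regression.
    band:
        (low, high) in Hz; the default 0.01-0.08 Hz is the standard
        resting-state band. ``None`` skips filtering. ``high`` must be
        below the Nyquist frequency 1/(2 TR).
    """
    x = signal.detrend(ts.values, axis=0, type="linear")

    if confounds is not None and np.size(confounds) > 0:
        c = np.atleast_2d(np.asarray(confounds, dtype=float))
        if c.shape[0] != ts.n_timepoints:
            raise ValueError(
                f"confound matrix has {c.shape[0]} rows but the series has "
                f"{ts.n_timepoints} time points"
            )
        # confounds are detrended like the data so the regression acts on
        # the same (trend-free) subspace
        c = signal.detrend(c, axis=0, type="linear")
        design = np.column_stack([np.ones(ts.n_timepoints), c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn(
                "confound matrix is rank deficient; using pseudo-inverse",
                stacklevel=2,
            )
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta

    if band is not None:
        low, high = band
        nyq = 1.0 / (2.0 * ts.tr)
        if not (0.0 <= low < high):
            raise ValueError(f"invalid band {band}: need 0 <= low < high")
        if high >= nyq:
            raise ValueError(
                f"band upper edge {high} Hz is at or above Nyquist {nyq} Hz "
                f"for TR = {ts.tr} s"
            )
        if low == 0.0:
            sos = signal.butter(4, high / nyq, btype="lowpass", output="sos")
        else:
            sos = signal.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
        x = signal.sosfiltfilt(sos, x, axis=0)

    return RoiTimeSeries(values=x, tr=ts.tr, roi_labels=ts.roi_labels)


def compute_fc(ts: RoiTimeSeries) -> FcMatrix:
    """Pearson correlation of every ROI pair's time courses."""
    sd = ts.values.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        labels = (
            [ts.roi_labels[k] for k in dead]
            if ts.roi_labels is not None
            else [str(k) for k in dead]
        )
        raise ValueError(f"zero-variance ROI column(s): {', '.join(labels)}")
    corr = np.corrcoef(ts.values, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return FcMatrix(values=corr)


def vectorize(fc: FcMatrix) -> FcFeatureVector:
    """Strict lower triangle in the canonical order, then Fisher z.

    The diagonal (unit self-correlations) and the redundant upper
    triangle are discarded; 116 ROIs give exactly 6,670 edge values.
    """
    ii, jj = edge_pairs(fc.n_rois)
    return FcFeatureVector(values=fisher_z(fc.values[ii, jj]), n_rois=fc.n_rois)


def devectorize(vec: FcFeatureVector) -> FcMatrix:
    """Inverse of :func:`vectorize`: rebuild the correlation matrix."""
    r = vec.n_rois
    ii, jj = edge_pairs(r)
    mat = np.eye(r)
    vals = np.tanh(vec.values)
    mat[ii, jj] = vals
    mat[jj, ii] = vals
    return FcMatrix(values=mat)


def feature_table(
    series: Sequence[RoiTimeSeries],
    subject_ids: Sequence[str],
    confounds: Sequence[np.ndarray | None] | None = None,
    band: tuple[float, float] | None = (0.01, 0.08),
    clean: bool = True,
) -> pd.DataFrame:
    """Cohort feature matrix: one row per subject, edge_0001... columns.

    Runs clean_series -> compute_fc -> vectorize for every subject and
    assembles the CSV-ready table all downstream analyses consume.
    """
    if len(series) != len(subject_ids):
        raise ValueError("series and subject_ids length mismatch")
    rows = []
    width = None
    for k, ts in enumerate(series):
        if clean:
            conf = confounds[k] if confounds is not None else None
            ts = clean_series(ts, confounds=conf, band=band)
        vec = vectorize(compute_fc(ts))
        if width is None:
            width = len(vec.values)
        elif len(vec.values) != width:
            raise ValueError("subjects have differing ROI counts")
        rows.append(vec.values)
    ndigits = max(4, len(str(width)))
    cols = [f"edge_{k + 1:0{ndigits}d}" for k in range(width)]
    df = pd.DataFrame(np.vstack(rows), columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    return df
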
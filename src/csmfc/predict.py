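"""SVR prediction of clinical scores from FC features.

Predicts preoperative JOA, JOA recovery and JOA recovery rate from the
Fisher-z edge vector with epsilon-SVR (linear kernel, library
defaults). Feature selection is univariate and embedded: within every
training fold each edge is correlated with the training labels and
edges with Pearson p < 0.05 are kept; the SVR is trained on the kept
edges and predicts the held-out subject. Performance is the Pearson
correlation between predicted and actual scores plus the RMSE, each
against a label-permutation null (the whole filtered LOOCV rerun per
permutation). Cross-site validation trains on one full site and
predicts the other, both directions.

Two RMSE scales are supported: the native score scale, and a
normalised mode in which labels are min-max scaled to [0, 1] on the
training fold before fitting (useful when comparing errors across
targets with very different ranges).

A broken variant that filters features on *all* subjects before
cross-validation is retained (``filter_before_cv=True``) as a
negative control for selection leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVR

from .classify import PermutationNull

__all__ = [
    "RegressionRun",
    "correlation_feature_filter",
    "loocv_regress",
    "evaluate_prediction",
    "permutation_test_regression",
    "cross_site_regress",
]


def _svr() -> SVR:
    # epsilon-SVR, linear kernel, library defaults (C=1, epsilon=0.1)
    return SVR(kernel="linear", C=1.0, epsilon=0.1)


@dataclass
class RegressionRun:
    """Assembled out-of-sample predictions and their quality metrics."""

    predicted: np.ndarray
    actual: np.ndarray
    selected: list[np.ndarray]  # per fold (or single entry cross-site)
    label_scaling: str = "native"
    r: float = field(init=False)
    rmse: float = field(init=False)

    def __post_init__(self) -> None:
        self.r, self.rmse = evaluate_prediction(self.predicted, self.actual)

    @property
    def n_subjects(self) -> int:
        return len(self.actual)

    def selection_frequency(self, n_features: int) -> np.ndarray:
        """Across-fold selection frequency per feature, in [0, 1]."""
        counts = np.zeros(n_features)
        for idx in self.selected:
            counts[idx] += 1
        return counts / max(len(self.selected), 1)


def correlation_feature_filter(
    features: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Indices of features whose Pearson correlation with the labels is
    significant at p < alpha (strict), two-sided.

    p comes from the exact t transform t = r sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom. May return an empty set — permuted-label
    runs routinely do.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("features and labels disagree on the number of subjects")
    n = y.size
    if n < 4:
        raise ValueError("need >= 4 subjects for a defined correlation p-value")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise ValueError("labels are constant; correlation filter undefined")
    xc = x - x.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.nan_to_num(r)  # zero-variance features: r := 0, never selected
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.nonzero(p < alpha)[0]


def _scale_labels(y: np.ndarray, mode: str) -> tuple[np.ndarray, float, float]:
    if mode == "native":
        return y, 0.0, 1.0
    if mode == "minmax":
        lo, hi = float(y.min()), float(y.max())
        span = hi - lo
        if span == 0:
            raise ValueError("constant training labels cannot be min-max scaled")
        return (y - lo) / span, lo, span
    raise ValueError(f"unknown label scaling mode {mode!r}")


def loocv_regress(
    features: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    label_scaling: str = "native",
    filter_before_cv: bool = False,
) -> RegressionRun:
    """Leave-one-out SVR with per-fold correlation feature filtering.

    Per fold: filter features on the training subjects only, train the
    SVR on the kept edges, predict the held-out subject. A fold whose
    filter keeps nothing falls back to predicting the training-label
    mean. In ``minmax`` mode labels are scaled to [0, 1] using the
    training fold's min/max and predictions (and the reported r/rmse)
    stay on that scale; the actual vector is scaled per-fold the same
    way.

    ``filter_before_cv=True`` filters once on all subjects (the broken,
    leaking protocol) and exists only as a negative control.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    n = y.size
    if x.shape[0] != n:
        raise ValueError("features and labels disagree on the number of subjects")
    if n < 5:
        raise ValueError("need >= 5 subjects for LOOCV regression")
    if np.ptp(y) == 0:
        raise ValueError("labels are constant")

    global_idx = correlation_feature_filter(x, y, alpha) if filter_before_cv else None

    predicted = np.empty(n)
    actual = np.empty(n)
    selected: list[np.ndarray] = []
    for hold in range(n):
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        xtr, ytr_native = x[mask], y[mask]
        ytr, lo, span = _scale_labels(ytr_native, label_scaling)
        idx = global_idx if global_idx is not None else correlation_feature_filter(
            xtr, ytr_native, alpha
        )
        selected.append(idx)
        if idx.size == 0:
            pred = float(ytr.mean())
        else:
            pred = float(_svr().fit(xtr[:, idx], ytr).predict(x[hold : hold + 1, idx])[0])
        predicted[hold] = pred
        actual[hold] = (y[hold] - lo) / span
    return RegressionRun(
        predicted=predicted, actual=actual, selected=selected, label_scaling=label_scaling
    )


def evaluate_prediction(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """(Pearson r, RMSE) between predicted and actual scores.

    RMSE is on whatever scale the vectors are on; r needs a
    non-constant actual vector.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size != a.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {a.size} actuals")
    if p.size < 3:
        raise ValueError("need at least 3 points")
    rmse = float(np.sqrt(np.mean((p - a) ** 2)))
    if np.ptp(a) == 0 or np.ptp(p) == 0:
        r = 0.0  # correlation undefined for a constant vector; report 0
    else:
        r = float(stats.pearsonr(p, a).statistic)
    return r, rmse


def permutation_test_regression(
    features: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    label_scaling: str = "native",
) -> tuple[RegressionRun, PermutationNull, PermutationNull]:
    """Label-permutation nulls for the LOOCV r and RMSE.

    Each permutation shuffles the labels once and reruns the full
    filtered LOOCV. For r the extreme tail is null >= observed; for
    RMSE it is null <= observed (a *smaller* error is better). Zero
    extreme counts are reported as p < 1/n_perm via the floor flag.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(labels, dtype=float).ravel()
    observed = loocv_regress(features, y, alpha, label_scaling)
    null_r = np.empty(n_perm)
    null_rmse = np.empty(n_perm)
    for b in range(n_perm):
        run = loocv_regress(features, rng.permutation(y), alpha, label_scaling)
        null_r[b], null_rmse[b] = run.r, run.rmse
    return (
        observed,
        PermutationNull(observed=observed.r, null=np.sort(null_r), tail="ge"),
        PermutationNull(observed=observed.rmse, null=np.sort(null_rmse), tail="le"),
    )


def cross_site_regress(
    features_a: np.ndarray,
    labels_a: np.ndarray,
    features_b: np.ndarray,
    labels_b: np.ndarray,
    alpha: float = 0.05,
    label_scaling: str = "native",
) -> dict[str, RegressionRun]:
    """Train on one full site, predict the other; both directions.

    The correlation filter and the SVR fit use the training site only.
    Returns {"a_to_b": ..., "b_to_a": ...}.
    """
    xa, xb = np.asarray(features_a, float), np.asarray(features_b, float)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(
            f"edge count mismatch between sites: {xa.shape[1]} vs {xb.shape[1]}"
        )
    out: dict[str, RegressionRun] = {}
    for name, (xtr, ytr_native, xte, yte) in {
        "a_to_b": (xa, np.asarray(labels_a, float).ravel(), xb, np.asarray(labels_b, float).ravel()),
        "b_to_a": (xb, np.asarray(labels_b, float).ravel(), xa, np.asarray(labels_a, float).ravel()),
    }.items():
        ytr, lo, span = _scale_labels(ytr_native, label_scaling)
        idx = correlation_feature_filter(xtr, ytr_native, alpha)
        if idx.size == 0:
            pred = np.full(len(yte), float(ytr.mean()))
        else:
            pred = _svr().fit(xtr[:, idx], ytr).predict(xte[:, idx])
        out[name] = RegressionRun(
            predicted=np.asarray(pred, float),
            actual=(yte - lo) / span,
            selected=[idx],
            label_scaling=label_scaling,
        )
    return out
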
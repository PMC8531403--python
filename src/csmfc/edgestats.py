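"""Mass-univariate edge-wise group comparison with FDR control.

Each of the R(R-1)/2 Fisher-z edges is tested for a patient-vs-control
difference with a covariate-adjusted two-sample t-test: the edge value
is regressed on an intercept, a group indicator and the nuisance
covariates (age, sex, education, site), and the t-statistic of the
group coefficient is reported. With no covariates this reduces exactly
to the pooled-variance two-sample t-test. The resulting p-values are
corrected with the Benjamini-Hochberg step-up procedure (q < 0.05 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import edge_pairs

__all__ = ["EdgeTestResult", "edgewise_group_test", "fdr_correct"]


@dataclass
class EdgeTestResult:
    """Per-edge group-difference statistics.

    direction is +1 where the patient mean (covariate-adjusted) exceeds
    the control mean, -1 otherwise.
    """

    t: np.ndarray
    p: np.ndarray
    q_pass: np.ndarray
    direction: np.ndarray
    q: float

    @property
    def n_flagged(self) -> int:
        return int(self.q_pass.sum())

    def frame(self, n_rois: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "edge": np.arange(len(self.t)),
                "t": self.t,
                "p": self.p,
                "q_pass": self.q_pass,
                "direction": self.direction,
            }
        )
        if n_rois is not None:
            ii, jj = edge_pairs(n_rois)
            df.insert(1, "roi_i", ii)
            df.insert(2, "roi_j", jj)
        return df


def edgewise_group_test(
    features: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    q: float = 0.05,
) -> EdgeTestResult:
    """Covariate-adjusted two-sample t-test at every edge.

    Parameters
    ----------
    features:
        subjects x edges matrix of Fisher-z values.
    group:
        binary labels; 1/True = patient, 0/False = control. At least 3
        subjects per group.
    covariates:
        optional subjects x C nuisance matrix. Constant columns are
        dropped (a site indicator is constant in a single-site run); a
        covariate collinear with the group indicator raises, naming it.
    q:
        Benjamini-Hochberg FDR level.
    """
    x = np.asarray(features, dtype=float)
    g = np.asarray(group).astype(float).ravel()
    if x.ndim != 2 or x.shape[0] != g.size:
        raise ValueError("features must be subjects x edges matching the labels")
    n1, n0 = int(g.sum()), int((1 - g).sum())
    if min(n0, n1) < 3:
        raise ValueError(f"need >= 3 subjects per group, got {n1} patients / {n0} controls")

    design_cols = [np.ones(g.size), g]
    kept_names: list[str] = []
    if covariates is not None and np.size(covariates):
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != g.size:
            c = c.T
        if c.shape[0] != g.size:
            raise ValueError("covariate rows must match the number of subjects")
        names = covariate_names or [f"cov_{k}" for k in range(c.shape[1])]
        base_rank = 2
        for k in range(c.shape[1]):
            col = c[:, k]
            if np.ptp(col) == 0:
                continue  # constant (e.g. site within one dataset): drop silently
            trial = np.column_stack(design_cols + [col])
            if np.linalg.matrix_rank(trial) <= base_rank:
                raise ValueError(
                    f"covariate '{names[k]}' is collinear with the group indicator "
                    f"or the covariates already included"
                )
            design_cols.append(col)
            kept_names.append(names[k])
            base_rank += 1

    X = np.column_stack(design_cols)
    n, p_cols = X.shape
    dof = n - p_cols
    if dof < 1:
        raise ValueError("not enough subjects for the covariate-adjusted model")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ x)  # p_cols x edges
    resid = x - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    t = beta[1] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q_pass = fdr_correct(p, q)
    direction = np.where(beta[1] >= 0, 1, -1)
    return EdgeTestResult(t=t, p=p, q_pass=q_pass, direction=direction, q=q)


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: flag the edges surviving FDR level q.

    Sort the m p-values ascending, find the largest k with
    p(k) <= k q / m, and flag everything at or below p(k).
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
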
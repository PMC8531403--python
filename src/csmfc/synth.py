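"""Two-site synthetic cohort generator and clinical score arithmetic.

The real study cohorts (resting-state fMRI of cervical spondylotic
myelopathy patients and healthy controls from two scanners) are not
publicly deposited, so every analysis in this package is exercised on
synthetic cohorts that reproduce the *statistical* structure the
analyses assume:

* per-subject ROI-by-time BOLD-like series drawn from a multivariate
  normal with a shared base correlation matrix;
* a sparse set of group-discriminative edges, shifted on the Fisher-z
  scale for patients;
* JOA-like clinical scores linearly linked to a sparse set of
  score-linked edges plus Gaussian noise;
* two sites that differ in series length, repetition time and noise
  level, mimicking the two-scanner asymmetry cross-site validation has
  to survive.

No haemodynamics, head motion or volumetric imaging is simulated — the
pipeline starts from ROI time series, so that is where the generator
starts too.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import RoiTimeSeries, edge_pairs, fisher_z

JOA_MAX = 17.0

__all__ = [
    "SiteConfig",
    "SyntheticConfig",
    "SubjectRecord",
    "Cohort",
    "generate_cohort",
    "joa_recovery",
    "joa_recovery_rate",
    "random_correlation_matrix",
    "nearest_correlation_matrix",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# clinical score arithmetic


def joa_recovery(pre: float, post: float) -> float:
    """JOA recovery: postoperative minus preoperative JOA score.

    Both scores live on the 0-17 Japanese Orthopedic Association scale
    (higher = better function). The difference may be negative
    (deterioration).
    """
    _check_joa(pre, "pre")
    _check_joa(post, "post")
    return post - pre


def joa_recovery_rate(pre: float, post: float) -> float:
    """JOA recovery rate: (post - pre) / (17 - pre).

    The fraction of the maximum possible improvement that was achieved.
    Undefined when ``pre`` is already at the scale maximum of 17.
    """
    _check_joa(pre, "pre")
    _check_joa(post, "post")
    if pre == JOA_MAX:
        raise ValueError(
            "JOA recovery rate is undefined for a preoperative score of 17 "
            "(zero denominator: no room for improvement)"
        )
    return (post - pre) / (JOA_MAX - pre)


def _check_joa(value: float, name: str) -> None:
    if not np.isfinite(value) or not (0.0 <= value <= JOA_MAX):
        raise ValueError(f"JOA {name} score must lie in [0, 17], got {value!r}")


# ---------------------------------------------------------------------------
# configuration and records


@dataclass(frozen=True)
class SiteConfig:
    """Per-site acquisition emulation.

    Defaults mirror the two scanners of the study design: site 1
    acquired 180 volumes at TR 2.0 s and site 2 acquired 450 volumes at
    TR 0.8 s, with the first 10 volumes of each run discarded before
    analysis (hence 170 and 440 usable time points).
    """

    n_patients: int
    n_controls: int
    n_timepoints: int
    tr: float
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("per-site subject counts must be >= 1")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points per series")
        if self.tr <= 0:
            raise ValueError("TR must be positive (seconds)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic two-site cohort.

    Parameters
    ----------
    n_rois:
        Number of regions of interest; 116 matches the AAL atlas
        parcellation the study used.
    sites:
        Acquisition/sample-size description per site. Defaults are the
        study's cohort sizes (27+11 and 26+36) and scan lengths.
    n_disc_edges:
        Number of group-discriminative edges. May be 0 (pure null).
    disc_effect:
        Fisher-z shift applied to patients' base correlation at the
        discriminative edges.
    n_score_edges:
        Number of edges whose subject-level variation drives the
        JOA-like scores. May be 0 (scores pure noise).
    score_edge_sd:
        SD of the per-subject Fisher-z fluctuation at score-linked
        edges (the individual-differences signal the SVR has to find).
    score_gain:
        JOA points per unit of summed score-edge fluctuation.
    score_noise_sd:
        SD of the additive Gaussian noise on the preoperative JOA
        score, in JOA points.
    """

    n_rois: int = 116
    sites: tuple[SiteConfig, ...] = (
        SiteConfig(n_patients=27, n_controls=11, n_timepoints=170, tr=2.0),
        SiteConfig(n_patients=26, n_controls=36, n_timepoints=440, tr=0.8, noise_scale=1.3),
    )
    n_disc_edges: int = 10
    disc_effect: float = 0.4
    n_score_edges: int = 8
    score_edge_sd: float = 0.3
    score_gain: float = 2.0
    score_noise_sd: float = 1.0
    base_offdiag_level: float = 0.2
    joa_pre_mean: float = 11.5
    recovery_mean: float = 3.5
    recovery_sd: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_disc_edges < 0 or self.n_score_edges < 0:
            raise ValueError("edge counts must be >= 0")
        n_edges = self.n_rois * (self.n_rois - 1) // 2
        if self.n_disc_edges + self.n_score_edges > n_edges:
            raise ValueError("more ground-truth edges requested than edges exist")
        if self.score_noise_sd < 0 or self.score_edge_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not self.sites:
            raise ValueError("at least one site is required")

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites"] = [dataclasses.asdict(s) for s in self.sites]
        return d


@dataclass
class SubjectRecord:
    """One participant: identifiers, site, group, covariates, scores."""

    subject_id: str
    site: int
    group: str  # "patient" | "control"
    age: float
    sex: str  # "female" | "male"
    education: float
    joa_pre: float | None = None
    joa_post: float | None = None

    def clinical_scores(self) -> tuple[float, float | None]:
        """(recovery, recovery_rate); rate is None at the scale ceiling."""
        if self.joa_pre is None or self.joa_post is None:
            raise ValueError(f"subject {self.subject_id} has no JOA scores")
        rec = joa_recovery(self.joa_pre, self.joa_post)
        rate = None if self.joa_pre == JOA_MAX else joa_recovery_rate(self.joa_pre, self.joa_post)
        return rec, rate


@dataclass
class Cohort:
    """A generated cohort plus its ground truth."""

    config: SyntheticConfig
    subjects: list[SubjectRecord]
    series: list[RoiTimeSeries]
    disc_edges: np.ndarray  # ground-truth group-discriminative edge indices
    score_edges: np.ndarray  # ground-truth score-linked edge indices

    def phenotype_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "site": s.site,
                    "group": s.group,
                    "age": s.age,
                    "sex": s.sex,
                    "education": s.education,
                    "joa_pre": s.joa_pre,
                    "joa_post": s.joa_post,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation-matrix machinery


def random_correlation_matrix(
    n: int, rng: np.random.Generator, offdiag_level: float = 0.2, dof_factor: int = 2
) -> np.ndarray:
    """Random dense correlation matrix with a controlled mean |off-diagonal|.

    A Wishart-style draw (``G G.T`` with Gaussian G, normalised to unit
    diagonal) is shrunk toward the identity until the mean absolute
    off-diagonal correlation is close to ``offdiag_level`` — a dense,
    weak coupling pattern like whole-brain functional connectivity.
    """
    g = rng.standard_normal((n, max(n * dof_factor, n + 1)))
    w = g @ g.T
    d = np.sqrt(np.diag(w))
    corr = w / np.outer(d, d)
    off = np.abs(corr[np.triu_indices(n, 1)]).mean()
    if off > 0:
        lam = min(1.0, offdiag_level / off)
        corr = lam * corr + (1.0 - lam) * np.eye(n)
    np.fill_diagonal(corr, 1.0)
    return corr


def nearest_correlation_matrix(a: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalue clipping at ``eps`` followed by diagonal renormalisation.
    One pass is enough for the mild perturbations used here; the result
    is validated by the caller.
    """
    sym = (a + a.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def _perturb_edges(
    base: np.ndarray,
    edge_idx: np.ndarray,
    deltas: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray],
    context: str,
) -> np.ndarray:
    """Shift selected edges of ``base`` by ``deltas`` on the Fisher-z scale.

    Back-transforms to the correlation scale and repairs to a PSD
    correlation matrix by alternating projections: eigenvalue clipping
    with diagonal renormalisation, then re-pinning the targeted edges,
    iterated until the matrix is PSD with the requested edges intact.
    Raises, naming the offending effect size, if no PSD matrix realises
    the requested shifts within tolerance.
    """
    if len(edge_idx) == 0:
        return base
    ii, jj = pairs[0][edge_idx], pairs[1][edge_idx]
    z = fisher_z(base[ii, jj]) + deltas
    r_new = np.tanh(z)
    pert = base.copy()
    pert[ii, jj] = r_new
    pert[jj, ii] = r_new
    pinned = pert
    fixed = pert
    for _ in range(300):
        fixed = nearest_correlation_matrix(pinned)  # PSD, unit diagonal
        if np.max(np.abs(fixed[ii, jj] - r_new)) < 1e-7:
            break
        pinned = fixed.copy()
        pinned[ii, jj] = r_new
        pinned[jj, ii] = r_new
    min_eig = np.linalg.eigvalsh(fixed).min()
    realised_err = np.max(np.abs(fisher_z(fixed[ii, jj]) - z))
    if min_eig < -1e-8 or realised_err > 1e-3:
        raise ValueError(
            f"could not repair the perturbed correlation matrix to PSD for {context} "
            f"(min eigenvalue {min_eig:.3g}, residual Fisher-z edge error "
            f"{realised_err:.3g}); the requested shift of magnitude "
            f"{np.max(np.abs(deltas)):.3g} is too large for this base matrix"
        )
    return fixed


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a two-site synthetic cohort with known ground truth.

    Every subject's T x R series is drawn from a zero-mean multivariate
    normal. Patients share a base correlation matrix perturbed by
    ``disc_effect`` (Fisher-z scale) at ``n_disc_edges`` ground-truth
    edges; every subject additionally receives individual Fisher-z
    fluctuations at ``n_score_edges`` edges, and patients' preoperative
    JOA scores are an affine function of those fluctuations plus noise
    (clipped to [0, 17], rounded to one decimal). Site 2 series get
    extra white noise per ``noise_scale``.

    Randomness is driven by a single master seed; per-subject streams
    are split off deterministically, so equal configs give bitwise
    identical cohorts.

    Returns the subject records, the per-subject series (site order,
    patients before controls within site) and the ground-truth
    discriminative and score-linked edge index sets.
    """
    master = np.random.SeedSequence(config.seed)
    ss_structure, ss_subjects = master.spawn(2)
    rng = np.random.Generator(np.random.PCG64(ss_structure))

    r = config.n_rois
    pairs = edge_pairs(r)
    base = random_correlation_matrix(r, rng, config.base_offdiag_level)

    all_edges = rng.permutation(config.n_edges)
    disc_edges = np.sort(all_edges[: config.n_disc_edges])
    score_edges = np.sort(all_edges[config.n_disc_edges : config.n_disc_edges + config.n_score_edges])

    patient_base = _perturb_edges(
        base,
        disc_edges,
        np.full(len(disc_edges), config.disc_effect),
        pairs,
        context=f"disc_effect={config.disc_effect}",
    )

    roi_labels = [f"roi_{k + 1:03d}" for k in range(r)]
    subjects: list[SubjectRecord] = []
    series: list[RoiTimeSeries] = []
    counter = 0
    for site_no, site in enumerate(config.sites, start=1):
        groups = ["patient"] * site.n_patients + ["control"] * site.n_controls
        for group in groups:
            counter += 1
            srng = np.random.Generator(np.random.PCG64(ss_subjects.spawn(1)[0]))
            group_base = patient_base if group == "patient" else base
            # subject-level fluctuation at score-linked edges
            if config.n_score_edges:
                deltas = srng.normal(0.0, config.score_edge_sd, size=config.n_score_edges)
                subj_corr = _perturb_edges(
                    group_base, score_edges, deltas, pairs, context="score_edge_sd"
                )
            else:
                deltas = np.zeros(0)
                subj_corr = group_base

            chol = np.linalg.cholesky(subj_corr + 1e-12 * np.eye(r))
            ts = srng.standard_normal((site.n_timepoints, r)) @ chol.T
            if site.noise_scale > 1.0:
                extra = np.sqrt(site.noise_scale**2 - 1.0)
                ts = ts + extra * srng.standard_normal(ts.shape)

            sid = f"sub-{counter:04d}"
            age = float(np.round(srng.normal(55.0, 9.0), 1))
            sex = "female" if srng.random() < 0.5 else "male"
            edu = float(np.clip(np.round(srng.normal(11.0, 2.5), 1), 0, None))
            rec = SubjectRecord(sid, site_no, group, age, sex, edu)
            if group == "patient":
                pre = config.joa_pre_mean + config.score_gain * deltas.sum()
                pre += srng.normal(0.0, config.score_noise_sd)
                pre = float(np.round(np.clip(pre, 0.0, JOA_MAX), 1))
                post = pre + srng.normal(config.recovery_mean, config.recovery_sd)
                post = float(np.round(np.clip(post, 0.0, JOA_MAX), 1))
                rec.joa_pre, rec.joa_post = pre, post
            subjects.append(rec)
            series.append(RoiTimeSeries(values=ts, tr=site.tr, roi_labels=list(roi_labels)))

    return Cohort(config, subjects, series, disc_edges, score_edges)


# ---------------------------------------------------------------------------
# on-disk form


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write phenotype CSV, per-subject series, and ground-truth JSON.

    Series files are headerless whitespace-delimited text, T rows by R
    columns, one file per subject named after the subject id.
    """
    out = Path(out_dir)
    series_dir = out / "series"
    series_dir.mkdir(parents=True, exist_ok=True)

    pheno_path = out / "phenotype.csv"
    cohort.phenotype_frame().to_csv(pheno_path, index=False)

    for rec, ts in zip(cohort.subjects, cohort.series):
        np.savetxt(series_dir / f"{rec.subject_id}.txt", ts.values, fmt="%.6f")

    truth_path = out / "ground_truth.json"
    truth = {
        "disc_edges": [int(k) for k in cohort.disc_edges],
        "score_edges": [int(k) for k in cohort.score_edges],
        "config": cohort.config.to_dict(),
    }
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {"phenotype": pheno_path, "series_dir": series_dir, "ground_truth": truth_path}


def load_series_dir(
    series_dir: str | Path, subject_ids: Sequence[str], tr_by_subject: Sequence[float]
) -> list[RoiTimeSeries]:
    """Read per-subject delimited series files back into memory."""
    out = []
    for sid, tr in zip(subject_ids, tr_by_subject):
        vals = np.loadtxt(Path(series_dir) / f"{sid}.txt", ndmin=2)
        out.append(RoiTimeSeries(values=vals, tr=tr))
    return out
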
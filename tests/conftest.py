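import numpy as np
import pytest

from csmfc import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """10-ROI two-site cohort with strong discriminative signal."""
    cfg = synth.SyntheticConfig(
        n_rois=10,
        sites=(
            synth.SiteConfig(n_patients=10, n_controls=10, n_timepoints=120, tr=2.0),
            synth.SiteConfig(n_patients=10, n_controls=10, n_timepoints=200, tr=0.8, noise_scale=1.3),
        ),
        n_disc_edges=5,
        disc_effect=0.6,
        n_score_edges=4,
        score_edge_sd=0.3,
        score_noise_sd=0.5,
        seed=42,
    )
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """(X, group, site) feature matrix for the small cohort, no cleaning."""
    from csmfc.features import feature_table

    df = feature_table(
        small_cohort.series,
        [s.subject_id for s in small_cohort.subjects],
        clean=False,
    )
    X = df.drop(columns="subject_id").to_numpy()
    group = np.array([s.group == "patient" for s in small_cohort.subjects])
    site = np.array([s.site for s in small_cohort.subjects])
    return X, group, site
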
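# Methods

## Problem and scope

Cervical spondylotic myelopathy (CSM) compresses the spinal cord, and a
question of clinical interest is whether the *brain's* resting-state
functional organisation carries enough information to (a) distinguish
patients from healthy controls and (b) predict sensorimotor status and
post-surgical recovery, measured on the Japanese Orthopedic Association
(JOA) scale (0–17 points, higher is better; recovery = post − pre;
recovery rate = (post − pre)/(17 − pre), the fraction of the maximum
possible improvement achieved).

This package implements the analysis layer of that question: it starts
from per-subject ROI-by-time BOLD-like series (volumetric preprocessing
— realignment, normalisation, smoothing — is upstream and out of
scope), builds whole-brain functional-connectivity (FC) features, and
runs mass-univariate edge statistics, SVM classification, SVR score
prediction, cross-site validation and Bland–Altman agreement. Because
no patient fMRI is bundled, every analysis is exercised on synthetic
two-site cohorts with planted, recoverable ground truth.

## Feature construction

Each ROI time course is linearly detrended, residualised against
nuisance regressors by OLS (regressors are detrended the same way, so
the projection acts on the trend-free subspace), and band-pass filtered
to 0.01–0.08 Hz with a zero-phase forward–backward Butterworth filter
of order 4. The band is the conventional resting-state window; only the
band is prescribed by the protocol, so the filter realisation is our
choice — forward–backward Butterworth is standard and phase-preserving.
A band edge at or above Nyquist (1/(2·TR)) is rejected with an error
naming the TR.

FC is the Pearson correlation of every ROI pair. With R ROIs the
feature vector is the strict lower triangle, R(R−1)/2 values (6,670 for
the 116-region AAL atlas), Fisher z-transformed (z = atanh r,
approximately variance-stabilising). Two fixed conventions:

* **Edge ordering** is column-major over the strict lower triangle —
  edge k runs (1,0), (2,0), …, (R−1,0), (2,1), … Any fixed global order
  is equivalent; this one is frozen in `edge_pairs` and used
  everywhere, so edge k always denotes the same ROI pair.
* **Clipping**: |r| is clipped to 1 − 1e−7 before atanh so degenerate
  r = ±1 (possible in synthetic data) stays finite.

## Edge-wise group statistics

Each edge is regressed on intercept + group + covariates (age, sex as
a binary indicator, education, site); the group coefficient's
t-statistic and two-sided p are reported. With no covariates this is
algebraically the pooled-variance two-sample t-test. The "scan
parameters" nuisance variable is operationalised as the site indicator
— the only scan-level variable that differs between subjects in a
combined analysis — and covariates that are constant in a subset run
(site within a single dataset) are dropped automatically; a covariate
collinear with the group indicator raises an error naming it.

Multiplicity is controlled by Benjamini–Hochberg step-up FDR at
q < 0.05 (BH rather than BY: the plain FDR is the field default, and
nothing in the protocol indicates dependence correction).

## Classification

Linear SVM (LibSVM via scikit-learn), C = 1, no probability outputs,
no feature scaling by default — features are already Fisher-z values
on a common scale; an optional per-fold train-statistics
standardisation sits behind a flag.

**Embedded selection inside LOOCV.** For each held-out subject: train
on the remaining subjects with all features; rank features by the
absolute SVM weight; keep the top fraction; retrain on the kept
features; predict the held-out subject. The fraction sweeps
0.05–1.00 in steps of 0.05 (20 values); fraction 1.0 short-circuits to
the full-feature classifier, so it reproduces the no-selection
analysis bit for bit. The selected count is k = round-half-up
(fraction × n_features) — the only rounding consistent with the
selected-feature counts 1,001 / 1,668 / 2,001 at 15 / 25 / 30% of
6,670. Weight ties are broken by ascending feature index, making
selection deterministic.

**Permutation inference.** Each permutation shuffles the labels once
and reruns the *entire* embedded-selection LOOCV — selection is redone
on the permuted labels. This is the only scheme that yields a valid
null: reusing the feature sets selected on the unpermuted labels leaks
signal into the null and inflates significance; that broken reading is
retained behind `perm_fixed_features=True` purely as a negative
control. p = #(null ≥ observed)/n_perm, ties counted as extreme; a zero
count is reported as "p < 1/n_perm" with a floor flag. The 20
per-fraction p-values are Bonferroni-corrected with the strict
threshold α/20 (0.0025 at α = 0.05).

**Cross-site validation** trains on one full site (selection computed
on the training site only) and predicts every subject of the other
site, in both directions; the per-fraction mean of the two accuracies
is reported. All 20 fractions are emitted and the post-hoc best
fraction is labelled as such — choosing the maximum after the fact is
optimistic, and the output says so rather than hiding it.

**ROC/AUC** uses the signed distances to the hyperplane (held-out
decision values within site; the single trained model's decision
values cross-site). AUC is the trapezoidal area, identical to the
Mann–Whitney pair-ranking probability with ties counted ½ (asserted
against a brute-force pair-counting oracle in the tests).

## Score prediction

Epsilon-SVR, linear kernel, C = 1, ε = 0.1 (library defaults, matching
the classification choice of default parameters). Feature selection is
univariate and embedded: within each training fold, every edge is
correlated with the training labels; edges with two-sided Pearson
p < 0.05 (strict, via t = r√((n−2)/(1−r²)) with n−2 df) are kept. A
fold whose filter keeps nothing predicts the training-label mean —
permuted-label runs produce empty sets routinely, so erroring would
make the null undefined. Changing a held-out subject's label never
changes that subject's prediction (metamorphic no-leakage property,
tested); the broken filter-on-all-subjects variant is kept as a
negative control and must fail the null-centred-r property.

Performance is Pearson r between assembled out-of-sample predictions
and actual scores, plus RMSE. The r-tail of the permutation test is
null ≥ observed; the RMSE tail is null ≤ observed (smaller error is
better). RMSE is reported on the native score scale by default; an
optional `minmax` mode rescales labels to [0, 1] on the training fold
(errors across targets with very different ranges — recovery rate is
dimensionless, pre-JOA spans points — are then comparable). Both modes
exist because error magnitudes on normalised scales are not
interchangeable with native-scale ones, and the choice is made
explicit per run.

The three targets (pre-operative JOA, recovery, recovery rate) run
through the same parameterised pipeline; recovery-rate labels are
dimensionless and never rescaled implicitly.

## Agreement

Bland–Altman on predicted vs actual: differences d = predicted −
actual (direction fixed and documented), bias = mean d, SD with n−1,
LOA = bias ± 1.96·SD (classical normal quantile; no small-sample t
correction), and the share of points inside the closed LOA interval
(~95% expected for Gaussian d). For clinical reading the LOA should be
compared with the score's minimum clinically important difference;
this package reports the numbers and leaves the judgement to the user.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analyses
assume, nothing more:

* **Base connectivity**: a Wishart-style random correlation matrix
  shrunk toward the identity until mean |off-diagonal| ≈ 0.2 — dense
  weak coupling of the kind whole-brain FC shows. The real study gives
  only the dimensionality (116 ROIs), not a covariance, so this is a
  convention.
* **Group effect**: patients share the base matrix shifted by
  `disc_effect` on the Fisher-z scale at `n_disc_edges` randomly chosen
  edges, back-transformed and repaired to a PSD correlation matrix by
  alternating projections (eigenvalue clipping + diagonal
  renormalisation, re-pinning the target edges each pass). If no PSD
  matrix realises the requested shifts within tolerance the generator
  errors, naming the effect size. The repair keeps the *injected*
  effect interpretable on the analysis scale; no published effect sizes
  exist for the FC group differences, so the default (0.4) is a
  convention, with 0.6 used in the recovery tests.
* **Score linkage**: every subject receives individual Gaussian
  Fisher-z fluctuations (SD `score_edge_sd` = 0.3) at `n_score_edges`
  edges; a patient's pre-operative JOA is an affine function
  (gain 2.0 points per summed z) of those fluctuations plus Gaussian
  noise, clipped to [0, 17] and rounded to one decimal. Post-operative
  JOA adds a recovery increment drawn N(3.5, 1.8) — *independent* of
  the features, mirroring how much harder recovery prediction is than
  severity prediction. Controls carry no JOA scores.
* **Two sites**: site 1 has 170 usable volumes at TR 2.0 s, site 2 has
  440 at TR 0.8 s (180/450 acquired minus 10 discarded), with extra
  white noise on site 2 (noise_scale 1.3). Site cohort sizes default to
  27+11 and 26+36.
* **Determinism**: one integer master seed; per-subject streams are
  split off a `SeedSequence`, so equal configs give bitwise-identical
  cohorts and the full pipeline is byte-reproducible.

What the generator does **not** emulate: haemodynamics, autocorrelated
BOLD noise, head motion, physiological artefacts, atlas misalignment,
or site effects beyond length/TR/noise scale. Passing tests therefore
demonstrate the *statistical machinery* — honesty of the cross-
validation, calibration of the permutation tests, recoverability of
planted effects — not performance on real fMRI.

## Numerical and procedural choices

* LOOCV accuracy on balanced null data sits slightly *below* chance:
  leaving a subject out tilts the training majority against its class.
  This pessimistic bias is expected and conservative; the leakage tests
  bound the honest pipeline one-sidedly against optimism and use the
  single-run binomial band two-sidedly.
* The tie-inclusive permutation p is valid but discrete; with few
  LOOCV folds the accuracy support is coarse and the test is
  conservative. Calibration checks use 20-fold cohorts, where the
  nominal 5% level is exercised (measured type-I ≈ 0.03–0.07).
* The analysis drivers and the acceptance script run a 20-ROI
  (190-edge) cohort with the study's subject counts and scan lengths —
  small enough for minutes-scale single-CPU runs, while keeping
  subjects ≪ edges, the regime the methods target. The test-suite
  cohorts are smaller still (8–10 ROIs).
* Empty inputs, single-class folds, constant labels, zero-variance
  ROIs, rank-deficient confounds and band edges at Nyquist all fail
  fast with messages naming the offending quantity.

## Known limitations

* Synthetic series are temporally white; analyses whose null
  distributions depend on autocorrelation (not used here) would need a
  richer generator.
* The recovery and recovery-rate targets are unpredictable by
  construction in the default cohorts (the recovery increment is
  feature-independent); they exercise the pipeline's null behaviour,
  not its power.
* Cross-site "best fraction" is post hoc whenever it is chosen after
  seeing all 20 accuracies; the output labels it accordingly, and any
  headline use should pre-register a fraction.
* The RMSE scale question (native vs normalised labels) is left
  explicit because reported errors are meaningless without the scale;
  both modes are first-class.
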
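# Methods

## Data model and containers

Tractometry input is a workbook with one sheet per microstructural metric;
rows are subjects, columns follow `bundle_hemi_section`.  Bundle names may
contain underscores (`SLF_II`), so the convention is parsed right-to-left:
the trailing integer is the 1-based section, the preceding token is the
hemisphere iff it is `left`/`right` (case-insensitive), and everything
before is the bundle; commissural tracts carry no hemisphere token.
Within each (metric, bundle, hemisphere) the sections must form the
contiguous range 1..S — anything else is rejected at load time rather than
silently reindexed.

Subjects with missing values for a metric are dropped with a logged
warning, never imputed: imputation from the pooled sample would leak
patient information into the normative statistics.

A directory of `<metric>.csv` files is accepted as an equivalent
plain-text container.  CSV round-trips bit-exactly (floats are written in
shortest round-trip representation and parsed with the exact parser); the
xlsx writer serializes floats at 16 significant digits, so xlsx
round-trips to within one unit in the last place.

## Preprocessing

Confound removal is per-feature OLS on the user-chosen covariates (age in
years; sex encoded as a 0/1 indicator).  Coefficients are estimated on the
**training controls only** and applied unchanged everywhere else;
residuals are re-centered at the training feature mean so scaled values
remain comparable across groups.  Min–max scaling maps the residualized
training range onto [0, 1]; held-out data may fall outside [0, 1] and is
deliberately not clipped, because exceeding the normative range is exactly
the signal the detectors consume.  A `preprocessed` flag on the feature
matrix guards against accidentally scaling twice.

SMOTE augmentation (for very small control cohorts) interpolates each
synthetic row between a random control and one of its k = 5 nearest
neighbours with a uniform mixing weight; originals are retained, so factor
f yields n·(f + 1) rows.  Parent indices and mixing weights can be
returned for auditing.

## Detectors

**z-score.** Per-feature standardization against the control mean and
unbiased (n − 1) sd; the subject score averages |z| over features
(a signed-average mode is available).  σ = 0 features are rejected.

**PCA + Mahalanobis.** PCA keeps the smallest number of leading components
whose cumulative explained variance reaches the threshold (default 0.85;
a threshold of 1 keeps all components).  The control covariance C is
estimated in un-whitened component space; if its condition number exceeds
10¹⁰ a ridge of 10⁻⁶·trace(C)/d is added.  The quadratic form
(x − μ)ᵀC⁻¹(x − μ) is computed exactly and reported as its square root —
the classical Mahalanobis distance; the square root is strictly monotone,
so rankings, AUCs and outlier calls are identical either way.  On fresh
draws from the training distribution the squared distance is
approximately χ² with d degrees of freedom, which the tests exploit.

**Autoencoder.** Five fully connected layers with widths
[n, ⌈n/2⌉, ⌈n/4⌉, ⌈n/2⌉, n] (ceiling halving keeps widths ≥ 1 for odd n;
at least 4 input features required).  Hidden activations are ReLU, the
output layer tanh; the bottleneck activation carries an ℓ1 penalty of
10⁻⁵ (mean over the batch of the summed absolute activations).  Training
is full-batch-shuffled minibatch Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) on
mean squared error for exactly 25 epochs — no early stopping — at batch
size 24 and learning rate 10⁻³.  A 10 % inner split is held out purely to
monitor the loss curve.  Weights and biases are initialized uniform
fan-in (±1/√fan_in) from a seeded generator; the whole fit is
deterministic given the seed, and the backward pass is verified against
finite differences in the test suite.  The implementation is plain numpy:
the matrices involved (tens of subjects × tens-to-hundreds of features)
are far below the scale where a GPU framework pays off, and an explicit
implementation keeps the arithmetic bit-reproducible.

The anomaly score is the mean absolute reconstruction error per subject;
signed per-feature errors x − x̂ (positive where the network learned a
smaller value than presented) drive localization.

**SVM baseline.** For comparison only: a class-weight-balanced SVC
evaluated by 10 × 5 repeated stratified cross-validation, with a per-fold
grid search over kernel {RBF, linear}, C ∈ {1, 10, 100, 1000} and
γ ∈ {10⁻³..10³} (32 parameter combinations), scored by ROC AUC.

## Bootstrapped evaluation

Patient cohorts are small and heavily imbalanced, so a single train/test
split would be dominated by which controls happen to be held out.  Each
bootstrap iteration draws, without replacement, as many controls as there
are patients; these plus all patients form the validation set, and the
remaining controls (minimum 8) are the training set.  Preprocessing and
detector are refit per iteration; the iteration ROC AUC (patients
positive) uses that iteration's scores.  Per-subject final scores average
over the iterations in which the subject was scored: every iteration for
patients, held-out iterations only for controls.  Group separation of the
final scores is tested with an equal-variance two-tailed t-test when the
groups are balanced and a two-sample Kolmogorov–Smirnov test otherwise,
plus Cohen's d with pooled sd.  Clinical association uses Spearman's ρ
with tie-aware ranks, pairwise exclusion of missing values, and a minimum
of 5 pairs.  Per-iteration seeds descend from the master seed through a
`SeedSequence` spawn, so the entire protocol is reproducible
bit-for-bit.

The precision-recall AUC is average precision; its random-classifier
baseline equals the positive prevalence (0.08 for 8 patients among 98
subjects), which the report carries alongside the value.

## Along-tract localization

One patient versus N ≥ 10 controls, N + 1 model fits: the patient is
scored by a network trained on all N controls; each control is scored by a
network trained on the other N − 1 controls *plus the patient* (the
patient is shuffled back into the population).  Every subject is therefore
scored against the N others, making the errors exchangeable under the
null: the probability that the patient's error at a feature exceeds all N
null errors is 1/(N + 1).  A feature is flagged when the patient's error
is positive and exceeds the entire null; a two-sided variant (|error|
ranks) is available behind a flag.  All folds train from the same seed, so
initialization variance is common to patient and null fits and cancels
from the comparison rather than inflating the null.  Preprocessing is
refit inside every fold.  Within each (bundle, hemisphere, metric),
maximal runs of at least two consecutive flagged sections are reported;
single-section hits are suppressed, and runs cannot span tract boundaries
by construction.

On smooth profiles, neighbouring sections' errors are correlated, so
null-patient exceedances cluster: the per-feature flag rate is calibrated
at 1/(N + 1), but consecutive co-exceedances (hence spurious short runs)
occur more often than an independence calculation suggests.  Interpreting
run counts therefore requires a null reference at the run level, which the
synthetic generator can provide.

## Repeatability

ICC uses the two-way mean-square decomposition with rows = subjects (n)
and columns = sessions (k): consistency of single measurements
C,1 = (MS_R − MS_E)/(MS_R + (k − 1)MS_E), and absolute agreement of
session averages A,k = (MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n).  Confidence
intervals follow the standard F-based construction (exact for C,1;
Satterthwaite degrees of freedom and a Spearman–Brown step-up for A,k);
both forms agree with an independent reference implementation to 10
decimals in the tests.  Degenerate data with zero between-subject variance
returns 0 with a warning rather than raising.  The coefficient of
variation is the within-subject sd divided by the subject mean, averaged
over subjects (undefined for non-positive subject means).

Reliability transfer between cohorts assumes the measurement-error
variance carries over: σ²_e = (1 − ICC_src)·sd²_src·inflation, projected
ICC = 1 − σ²_e/sd²_target, clipped to [0, 1].  This is the minimal model
consistent with "similar measurement-related variance" and is interpretive
rather than exact.

## Synthetic cohorts

One feature value is mean curve + covariate effects + subject offset +
correlated noise (+ session noise) (+ lesion).  Mean curves are low-order
cosine expansions (c₀ ~ U(0.45, 0.65), three higher coefficients
~ N(0, 0.03)), giving smooth FA/RISH-like profiles.  Defaults: 60
controls, 8 patients; three tracts (AF left/right, CC4) × 20 sections;
tract-level subject offsets N(0, 0.04); along-tract noise N(0, 0.04) with
squared-exponential correlation of length scale 3 sections (real tract
profiles are strongly smooth because neighbouring sections share
streamline support); age U(8, 18) years with slope 0.002 per year on every
feature and a 0.01 sex offset — magnitudes chosen so that individual
covariate effects are visible but smaller than the biological
between-subject spread.  Amplitudes of injected lesions are expressed in
units of the total per-feature sd σ = √(0.04² + 0.04²) ≈ 0.057 and applied
as half-cosine bumps (unit peak at the centre section for odd widths), so
localization tolerance of ±1 section is meaningful.  Test-retest designs
share the subject-level components across sessions and add iid session
noise.  The clinical score is 50 + slope · (total injected amplitude) +
N(0, 5).  Generation is a pure, seeded function of the spec.

What the generator does *not* emulate: scanner/site effects and
harmonization residuals, metric-specific value ranges and floor/ceiling
effects, non-Gaussian pathology distributions, partial or failed tract
reconstructions, and correlations *between* tracts beyond what covariates
induce.  Passing tests on this generator demonstrate the statistical
machinery (calibration, leakage safety, recovery of injected effects), not
performance on any particular scanner or disorder.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the bootstrap at 20
iterations on 60 + 8 cohorts with 60 features, localization with N = 20
controls, and ICC recovery over 200 replicates of a 6 × 5 design — sizes
at which every result is stable yet the whole suite completes in well
under a minute of numpy time.  Detection AUC under these conditions
plateaus around 0.7–0.9 for all three detectors: the injected half-cosine
lesion has a mean amplitude of ~1.9 σ over its width, and tract-level
offsets plus smooth noise leave few effectively independent features, so
this is the information ceiling of the cohort rather than a property of
any one detector (the univariate z-score, nearly optimal for a pure mean
shift, sits in the same range).

Ties in ranks are handled by scipy's tie-aware ranking; ROC AUC counts
ties as half.  All sds use the unbiased (n − 1) denominator.  Degenerate
inputs (constant features, rank-deficient covariates, single-class labels,
incomplete session tables) raise typed errors early rather than
propagating NaNs.
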
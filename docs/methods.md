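# Methods

## Signal preparation

The pipeline consumes spatially normalized 4D images (or precomputed
region-by-time matrices); registration, segmentation and slice-timing
belong to upstream tools and are out of scope.  Given a label atlas, each
region's signal is the plain voxel mean at every time point, regions
ordered by ascending label id.  Nuisance regression comes first (design:
intercept, linear trend, supplied confound columns — e.g. the 24-parameter
motion expansion `[m, Δm, m², (Δm)²]`, global, white-matter and CSF
signals), followed by band-pass filtering.  Rank-deficient confound
designs are resolved by the minimum-norm least-squares solution, so
duplicated columns change nothing.

The band-pass is an ideal rectangular mask in the discrete Fourier domain:
bins whose center frequency lies in `[low, high]` (inclusive, default
0.01–0.1 Hz) are kept, all others — including DC — are zeroed.  This is
the convention of the common fMRI preprocessing toolchains, it is exactly
idempotent, and it makes the test oracles trivial (a bin-aligned sinusoid
passes with ratio 1).  A Butterworth filter would be a one-line swap but
would blur the pass/stop contract the tests rely on.  Since region
averaging and linear filtering commute, extracting means before filtering
is equivalent to filtering voxelwise first.

## Directed connectivity

For each ordered region pair the influence of *i* on *j* is the Geweke log
variance ratio `ln(RSS_restricted / RSS_full)` of two regressions of
region *j*'s signal on delay-embedded lags, floored at zero.  Estimation is
**pairwise**, not conditional on the remaining regions: a conditional
kernel regression in ~190×p dimensions would be statistically vacuous at
140 time points.

The non-parametric back-end is Nadaraya–Watson regression with a
multiplicative kernel — the product of univariate Gaussians over the lag
columns — and **leave-one-out** residuals.  LOO scoring is essential: the
full model has strictly more kernel dimensions and would otherwise always
reduce in-sample RSS, making the statistic positive by construction.  With
LOO, an irrelevant extra dimension typically *hurts* prediction, so null
values floor at zero.

Numerical choices, all fixed and deterministic:

* lag order `p = 1` (default; configurable).  At TR = 3 s the hemodynamic
  signal decorrelates quickly and longer lags are weakly identified.
* bandwidth: per-column median absolute pairwise difference; a
  zero-spread column gets bandwidth 1.  No data-dependent optimization.
* ridge `1e-6` added to the kernel-weight normalization so rows with
  vanishing total weight do not divide by zero.
* ties (`RSS_r = RSS_f`) give exactly 0; there is no randomness anywhere
  in estimation.
* with `kernel="linear"` the back-end is OLS (exact hat-matrix LOO
  residuals in leave-one-out mode); in in-sample mode this is the
  textbook linear Granger causality, used as the closed-form oracle.

Whole-matrix estimation reuses one lag-kernel per region, so an N-region
subject costs N kernel builds plus one elementwise product per directed
pair; a 12-region, 140-volume subject fits in ~10 ms, and the full
192-region configuration is supported.

## Preferred flow measures

`P(i, j) = G(i, j) / (G(i, j) + G(j, i))`, with 0/0 defined as 0.5 ("no
information either way"); the per-region index is the mean of `P(i, ·)`
over the other regions (self-flow is undefined and excluded).  The matrix
is exactly antisymmetric (`P + Pᵀ = 1` off-diagonal), scale-invariant in
G, and the indices sum to N/2 identically.  Only the strict upper triangle
is carried into statistics and machine learning; the lower triangle is
redundant.

Because the floored GCA can be exactly zero, a null pair's preferred
direction is a mixture: exactly 0.5 when both directions floor (roughly
half of null replicates at T = 2000), and 0 or 1 — symmetrically — when
exactly one direction is positive.  The replicate *mean* is therefore an
unbiased estimate of 0.5 with a standard error of ~0.025 at 200
replicates; single-pair values should never be over-interpreted.

## Group inference

Edge-wise and node-wise two-sample t-tests (Student's pooled variant by
default, Welch available) with Benjamini–Hochberg FDR control: edges are
corrected jointly over all upper-triangle edges, nodes separately over the
N nodes.  Degenerate features (zero variance in both groups) give p = 1
when the means agree.  For summary-table statistics the package also
provides t-tests from printed means/SDs/ns, Pearson chi-squared without
continuity correction, a fitted-normal Kolmogorov–Smirnov normality check
(Lilliefors situation — the returned p is conservative, which only makes
the normality gate lenient), and the Mann–Whitney U test (exact for small
tie-free samples).

## Classification and prediction

FDR-significant features feed a linear-kernel SVC (C = 1) under
leave-one-out cross-validation, with standardization refit on every
training fold.  The default protocol selects features on the **full**
sample, mirroring the common (and optimistic) practice in the literature;
a nested mode that redoes selection inside every training fold is provided
and recommended when an unbiased accuracy estimate matters.  The positive
class for sensitivity/PPV is the control group by default (configurable).

Lasso prediction standardizes features, picks the penalty by internal
cross-validation on a log grid, and reports Pearson's r between predicted
and actual outcomes.  Two scoring modes exist because published reports
often do not say which was used: `in_sample` (single full-data fit) and
`loocv`.  A caveat the tests document explicitly: under the null, a fully
shrunk training fold predicts the training mean, which is exactly
anti-correlated with the held-out value, so cross-validated r is biased
*negative* — the meaningful null check is the absence of spuriously
positive r, not |r| ≈ 0.

## Synthetic cohorts

The generator emulates the study conditions: two groups (default 40
controls vs 49 patients), 140 volumes at TR = 3 s, with full-scale
192-region networks supported and a 12-region default for routine runs.
Subjects are realizations of a stationary VAR(1),
`x_t = Aᵀ x_{t−1} + ε_t` with iid Gaussian innovations (unit SD), a
≥200-step burn-in, and optional centered-quadratic edge terms for
nonlinear coupling; stationarity is enforced via the linearized spectral
radius (< 0.95).  No hemodynamic convolution is applied by default — the
analysis operates on band-limited signals and the ground-truth direction
must stay unambiguous; a moving-average flag crudely emulates BOLD
sluggishness when wanted.  Gaussian innovations are an assumption of
convenience; the empirical signal distribution of real cohorts is not
modeled, nor are physiological noise or head motion, so passing tests
certify estimator and pipeline behavior under the generative model, not
performance on real scanners.

Group effects multiply selected couplings in the patient group.  Effect
edges are planted on **reciprocally coupled pairs** (base weight 0.25 both
ways, one direction tripled): with a one-way edge the reverse GCA floors
at zero and the preferred direction saturates at 1 in *both* groups,
erasing the contrast the pipeline measures; a reciprocal pair moves the
population preferred direction from 0.5 to ~0.8.  Outcome variables
(memory-, executive-, and CSF-biomarker-like) are linear functions of the
group's *population* flow features plus Gaussian noise, where population
features come from a large-T (6000-sample) linear-GCA plug-in — so
prediction experiments measure estimator and outcome model jointly, and
the noiseless limit is exactly linear.

## Validation problem sizes

The acceptance suite runs at desk scale, chosen once: 200 null pairs at
T = 2000 for the definitional null; 20 pairs for the linear-kernel oracle
equivalence; 100 seeds for direction recovery (linear weight 0.7 at
T = 500; quadratic weight 0.9 at T = 1000); 100 null cohorts (8 regions,
10/10 subjects, T = 140) and 20 effect cohorts (20/20, T = 500) for FDR
calibration and power; 10 effect cohorts (8 regions, 25/25, T = 500) for
end-to-end classification.  The node-level power check uses a 5-region
star network (25/25, T = 500) because the flow index dilutes a hub's
effect across all its partners.

## Known limitations

Pairwise GCA can report indirect influence (i → k → j) as direct; the
preferred-direction ratio is unstable when both raw causalities are near
zero (by design it then lands on {0, 0.5, 1}); full-sample feature
selection inflates LOOCV accuracy (use the nested mode for honest
estimates); and at 192 regions with 140 volumes the per-edge estimates are
individually noisy — the group-level statistics, not single edges, are the
interpretable output.
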
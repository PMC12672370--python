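# Methods

`cyclebrain` implements a dense-sampling analysis of whole-brain structural
dynamics across the menstrual cycle: a small number of individuals are
imaged near-daily for a month, serum estradiol (E, pmol/l) and progesterone
(P, nmol/l) are assayed at each session, and the per-session gray-matter
volume maps (or cortical-thickness vectors) are decomposed into shared
spatial patterns with individual temporal trajectories that are then related
to the hormone time series.  This note documents the models, the synthetic
generators, the numerical choices, and what the tests do and do not
establish.

## Spatiotemporal decomposition

Sessions from all individuals are stacked into one matrix `X` (N sessions x
V in-mask locations) and column-centered.  The default is **per-individual
centering**: each individual's own voxel means are removed, so the static
anatomy drops out and the shared right singular vectors describe
within-cycle change.  (Global centering is available via configuration; with
several anatomically distinct individuals it lets between-person differences
dominate the leading components, which is not the scientific target here.)

The thin SVD `X = U diag(sigma) V'` yields spatiotemporal patterns: the
unit-norm spatial weights `v_k`, the session-wise temporal scores `u_k`, and
the variance fraction `f_k = sigma_k^2 / sum_j sigma_j^2` (the standard
variance-explained convention — squared singular values, not singular
values).  SVD signs are arbitrary, so each component is oriented to make its
largest-magnitude spatial weight positive.  Components with `f_k >= 0.095`
are retained: the retention rule is "at least 10% of variance after rounding
to integer percent", so a 9.7% component counts.  For reporting, spatial
weights are display-thresholded to the +/-[0.01, 0.1] band (sub-threshold
weights zeroed, larger magnitudes clipped to the color-bar limit); statistics
always use the raw unit-norm vectors.  Temporal scores used downstream are
z-scored within each individual's session block, which makes the later
regressions invariant to the arbitrary SVD scaling.

## Temporal model (penalized-spline GAM)

Each retained component's standardized scores are modeled as
`score = beta0 + f(test day)` with `f` a cubic regression spline of basis
dimension k = 10 (knots at quantiles of the observed days) and the exact
integrated-squared-second-derivative penalty `S = D' B^{-1} D` built from the
knot spacings.  The penalty null space is exactly {constant, linear}, so the
infinite-smoothing limit of the fit is the least-squares straight line — a
property the tests check directly.  The smoothing parameter is selected by
GCV over a fixed grid of 61 log-spaced values in [1e-4, 1e6]; the penalized
system is solved through an augmented QR factorization, which stays accurate
at both grid extremes.  Effective degrees of freedom are the trace of the
smoother matrix.  No autoregressive terms are included: with ~25 sessions
they overfit, and the simpler GAM is the deliberate choice.

**Significance of the smooth.**  The fluctuation test is the exact F test of
the full (unpenalized) k-dimensional spline family against the intercept-only
model, with (k-1, n-k) degrees of freedom.  We do not report an approximate
F test conditioned on the GCV-chosen penalty: selecting the smoothing
parameter from the data invalidates that reference distribution, and in our
simulations the conditioned test rejected white noise at ~15% instead of the
nominal 5% at n = 25 (undersmoothing-penalized GCV variants still gave
7-10%).  The unpenalized family test has an exact null distribution
(measured type-I error 4.9-5.0% over 2000 white-noise series) at a modest
power cost.  The penalized fit still provides the reported curve, lambda and
EDF.  Constant score series are degenerate by definition: EDF 1, p = 1.

Multiple GAMs are corrected with Benjamini-Hochberg FDR across the retained
components x individuals of a measure type.

## Hormone transforms and associations

Hormone levels are square-root transformed before entering any brain model
(variance stabilization).  The progesterone-to-estradiol ratio is computed
with both hormones on the pmol/l scale, `R = 1000 P / E`; this convention is
fixed by the male control's summary statistics (mean ratio ~6.9 with mean P
0.863 nmol/l and mean E 128.7 pmol/l is only consistent with pmol/pmol).
A naive nmol-over-pmol ratio is available behind a configuration switch.

For every individual x retained component x predictor (sqrt E, sqrt P, R),
two statistics are computed: an OLS time-series regression of the
standardized scores on the contemporaneous sqrt-hormone level (two-sided t
test on the slope, n-2 df; predictors deliberately not z-scored) and a
Spearman rank correlation (mid-ranks for ties; the two-sided p-value is
exact by full n! enumeration for n <= 7 and a t approximation otherwise).
BH-FDR is applied within each individual's family of tests, separately per
statistic route.

**Headline flag.**  An association is reported as significant only when both
routes are FDR-significant at 5% ("concordant" flagging).  The two routes
answer the same question with different robustness profiles; requiring
concordance protects against flags driven by non-normality and by the serial
dependence that contemporaneous OLS ignores (both score and hormone series
are strongly autocorrelated across days, which inflates naive OLS
significance — measured at roughly twice the nominal rate for smooth null
loadings).  Each route's adjusted p-values remain available individually.

## Endocrine group comparison

The four female hormone profiles are compared treating sessions as
independent observations: a one-way MANOVA on (E, P, R) reporting Pillai's
trace `V = sum lambda_i/(1+lambda_i)` with the standard F approximation and
Roy's largest root `theta = max lambda_i` with the upper-bound approximation
`F = theta (N-d-1)/d`, `d = max(p, g-1)`; partial eta squared is `V/s` and
`theta/(1+theta)`.  With p = 3 variables, g = 4 individuals and N = 104
sessions the approximations give F(9,300) and F(3,100).  Post hoc one-way
ANOVAs per variable and Bonferroni-corrected pairwise two-tailed t-tests
follow; the t denominator uses the pooled within-group mean square with
N - g df (the convention of mainstream social-science packages), with
independent-variance pairwise tests available as an option.  Hormone values
enter untransformed (the sqrt transform belongs to the brain associations).
Treating repeated sessions as independent is a deliberate replication of the
field's practice for this design, not an endorsement.

A cycle is classified ovulatory when peak progesterone strictly exceeds
15.9 nmol/l.

## Mass-univariate GLM and TFCE

Voxel- or vertex-wise inference regresses each location's map value on the
sqrt-hormone level — per individual, or pooled with one intercept per
individual and a common slope.  For a single covariate the t statistic is
symmetric in predictor and response, so this is equivalent to the
hormone-as-dependent formulation.  Volumetric analyses first drop voxels
whose mean gray-matter value across sessions is below 0.1 (boundary value
retained).

The slope t map is enhanced with TFCE, `TFCE(x) = integral of
e(h,x)^E h^H dh` up to `t(x)`, with E = 0.5, H = 2, 26-connectivity on voxel
grids and edge-list adjacency on vertex graphs.  The integral is computed
cellwise over `n_steps` threshold cells (default 100): within each cell the
`h^H` factor is integrated in closed form up to each location's own
statistic, and the extent factor is the trapezoidal average of the
connected-component extents at the two cell edges (one labeling per edge,
shared between neighboring cells).  Cells in which the extent factor jumps
by more than 10% for a surviving location — cluster merges — are bisected
adaptively to depth 4.  This makes a flat, isolated plateau exact to machine
precision against the closed form `e^E h0^(H+1)/(H+1)` and keeps random
smooth maps within ~0.7% of a 10,000-step reference.  Positive and negative
associations are enhanced separately from `t` and `-t`.

**Permutation FWE.**  The null distribution of the map-wide maximum TFCE
statistic is built by permuting hormone values across sessions within each
individual (n_perm = 1000 by default; temporal autocorrelation is ignored by
the permutation scheme, a known limitation shared with the standard
toolboxes).  `fwe_p(x) = (1 + #{perm max >= TFCE(x)}) / (n_perm + 1)`,
separately per direction, each direction being its own FWE family at
alpha = 0.01.  Inside the permutation loop the enhancement uses the fixed
threshold grid without adaptive bisection: the test only requires that
observed and null maps receive the identical transformation, and validity
(measured family-wise false-positive rate ~1% at alpha 1%) is independent of
the integration fineness.

## Synthetic generators

The generators define the study conditions under which the pipeline is
exercised and verified.

**Hormones.**  Each female template is a deterministic Gaussian-bump
trajectory — baseline, pre-ovulatory estradiol surge peaking the day before
ovulation, mid-luteal progesterone bump, smaller mid-luteal estradiol bump —
multiplied by lognormal noise with a given coefficient of variation (0.12
for natural cycles).  Template parameters encode the studied cycles: a
27-day typical cycle (25 weekday sessions, 14-day luteal phase, luteal P
peak 35 nmol/l), a 30-day daily-sampled typical cycle (30 sessions, 16-day
luteal phase), a 24-day endometriosis cycle (sessions exclude test day 8,
8-day luteal phase, elevated estradiol with luteal E dominance, luteal P
peak 20 nmol/l — ovulatory but estradiol-dominant), an OC cycle
(progesterone flat at ~1 nmol/l, estradiol at natural-cycle levels with a
slow modulation, last 7 days labeled inactive-pill), and a male control
calibrated to the observed summaries (E mean 128.7, sd 17.3, clipped to the
observed 98.0-161.0 pmol/l range; P lognormal around 0.863 nmol/l with CV
0.62 clipped to 0.329-3.420; phases carry a neutral label).  Peak heights
and bump widths reproduce the qualitative phenomenology (two estradiol
peaks, luteal P > 15.9 in natural cycles, luteal ratio ordering typical >
endometriosis > OC); they are fixed choices, not fitted quantities.

**Image stacks.**  A session map is a static smooth anatomical baseline
(~0.45 gray-matter fraction) plus K = 3 planted orthonormal smooth spatial
patterns weighted by session loadings, plus iid voxel noise.  The default
grid is 24^3 voxels at 2 mm with an ellipsoidal mask (~5,300 in-mask
voxels); the vertex-wise stand-in is a 32x32 lattice graph with 4-neighbor
adjacency and a 2.5 mm thickness baseline.  Component 1's loadings equal the
standardized sqrt level of the individual's dominant hormone (progesterone
in the two typical cycles, estradiol in the endometriosis and OC cycles);
components 2-3 are standardized AR(1) series (rho = 0.5) orthogonalized
against the earlier loadings, modeling non-hormonal day-to-day structure.
Loading norms are scaled so the three planted components hold exactly
50/20/10% of the expected total centered sum of squares and noise holds the
remaining 20% — component 3 sits deliberately near the 10% retention
boundary.  Because Gaussian smoothing is linear, the planted patterns are
generated directly as smoothed orthonormalized random fields and no second
smoothing pass is applied in the default design; `simulate_stack` does
implement masked, edge-renormalized FWHM smoothing (sigma = FWHM/2.3548)
for stacks built with explicit smoothing, and the generator preserves the
mask-mean intensity within 1%.

**What the phantom does not emulate:** registration and segmentation error,
scanner drift, motion, spatially structured (non-iid) noise, true anatomy.
Passing recovery and dissociation tests therefore demonstrates correctness
of the pipeline's mathematics under its stated model, not robustness to real
preprocessing artifacts.

## Problem sizes used in the checks

Recovery and dissociation run the full four-individual study (104 sessions,
24^3 grid) over 20 and 50 seeds respectively; GAM calibration uses 2000
white-noise series of length 25; FWE calibration uses 500 replications of a
10^3-voxel null study with 200 permutations each and a 10-cell TFCE grid;
the TFCE oracle comparisons run on a 16^3 phantom.  These sizes give the
Monte-Carlo intervals quoted in the tests while keeping the default suite
quick on a single CPU.

## Known limitations

- Contemporaneous OLS and Spearman tests ignore serial dependence; the
  concordance requirement mitigates but does not remove this.
- The MANOVA treats within-person sessions as independent observations.
- The permutation scheme exchanges days freely within an individual,
  ignoring cyclical autocorrelation.
- Roy's largest-root F is an upper bound (liberal by construction).
- The spline fluctuation test trades some power for exact calibration.
- Variance fractions depend on the centering convention; per-individual
  centering is the default and the one under which the retention thresholds
  were chosen.
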
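# Methods

## The calibration problem

Five UV-absorbing components — two actives (naphazoline HCl, NZ;
pheniramine maleate, PN) and three official impurities (NZ impurity B, PN
impurities A and B) — are quantified simultaneously from one absorbance
scan. All five absorb between 250 and 300 nm with heavily overlapping
envelopes, so the calibration must be multivariate: a matrix **X**
(mixtures × wavelengths) of absorbances is regressed onto a matrix **Y**
(mixtures × 5) of concentrations in µg mL⁻¹. Below 250 nm the instrument
signal is noisy and above 300 nm the components barely absorb, so all
calculation uses the 250.0–300.0 nm window of the 200–400 nm @ 0.2 nm scan
— 251 grid points, which is also the input dimension of the network model.

## Calibration design

The 25-run five-level design assigns each factor the coded levels
−2…+2, five times each, such that every ordered pair of factors covers all
25 level combinations exactly once. Construction: run *i* is indexed by its
base-5 digits (a, b); factor *j* takes level (αⱼ·a + βⱼ·b) mod 5 with the
direction vectors (αⱼ, βⱼ) pairwise linearly independent over GF(5). Any
two such columns form a bijection onto the 5×5 grid, which *is* the
orthogonality contract; the contract is validated directly by
`DesignTable.validate` rather than against any published run listing. The
six available directions support up to six factors; the assay uses five.
Coded levels map affinely onto the component ranges (5–13, 10–60, 1–5,
2–14, 2–14 µg mL⁻¹), exact at both endpoints.

The 15/10 calibration/validation split is seeded-random under two
constraints: (a) every level of every factor appears in the calibration
subset, so validation never extrapolates; (b) the calibration runs still
span the full 5-dimensional factor space after deleting any single run.
Constraint (b) exists because leave-one-out cross-validation refits on 14
runs: without it, a fold can turn into an extrapolation whose error
dominates the pooled RMSECV curve and corrupts model selection (this
happens in practice for some 15-run subsets of the design). Feasible
splits are found within a handful of redraws for all tested seeds.

## Synthetic spectra

Pure-component spectra are sums of Gaussian bands
ε(λ) = Σ peak·exp(−(λ−center)²/2σ²), per unit concentration with the 1 cm
path folded into the peak absorptivity. Gaussian envelopes are a standard
smooth surrogate for UV absorption bands and make the degree of overlap
controllable. The default five-component library places every principal
band inside 250–300 nm (pairwise cosine similarity up to ≈0.97 in the
window — severe overlap — while keeping the pure-spectra matrix
conditioned around 10², i.e. overlapping but identifiable), decays to
<5 % of peak above 300 nm, and scales peaks so design-range mixtures span
roughly 0.1–1.3 AU. A seed jitters band centers (±1.5 nm), widths and
peaks (±8 %), giving structurally equivalent but distinct systems.

Mixtures follow Beer–Lambert superposition exactly; instrument noise is
i.i.d. Gaussian per wavelength with σ = 2 mAU at ≥250 nm and 10 mAU below
250 nm (emulating the noisy short-wavelength region), plus an optional
smooth quadratic baseline drift of ~1 mAU amplitude. These defaults are
typical of a benchtop double-beam spectrophotometer. What the generator
does **not** emulate: stray light, detector nonlinearity at high AU,
wavelength-registration error, solvent/pH band shifts, and inter-day
drift. Passing tests therefore demonstrate correctness of the calibration
mathematics under linear additive spectroscopy, not robustness to
real-instrument artifacts.

## Preprocessing

Window selection slices existing grid points only (inclusive endpoints,
matching tolerance 1e−9 nm); it never interpolates. Both **X** and **Y** are
mean-centered on the calibration set, and the stored training means are
reused for any later data (no leakage). Centering Y and adding the mean
back after prediction is the long-standing convention of multivariate
calibration toolboxes; it is harmless and makes the coefficient matrix
intercept-free.

## PLS

PLS2 via NIPALS: for each latent variable, the Y-score is initialized from
the Y column of maximal residual variance (deterministic), the inner loop
alternates weight/score updates to a relative tolerance of 1e−12 (max 500
iterations), each weight vector's largest-magnitude element is forced
positive (sign indeterminacy removed for reproducible serialization), and
both blocks are deflated by the rank-one score/loading product. The
regression matrix is B = W(PᵀW)⁻¹Qᵀ on centered data. If the X block is
exhausted before the requested number of latent variables, fitting fails
with the achievable maximum named.

Leave-one-out cross-validation refits on each 14-run subset and predicts
the held-out run; RMSECV is pooled over samples and components in original
concentration units (per-component curves are also reported), alongside
the calibration-set RMSEC curve. When a fold is rank-exhausted below the
requested depth (noiseless low-rank data), the deepest feasible model's
prediction is reused for the larger depths — the standard treatment, which
keeps the curve defined without extrapolating the rank. The number of
latent variables is the smallest whose RMSECV is within 2 % (default
`threshold_ratio=0.02`) of the curve minimum — a fixed, testable stand-in
for the usual visual "least noise, satisfactory recovery" judgement of the
error-versus-complexity plot.

## Linear network

The network is input → hidden → output with identity transfer throughout,
i.e. an affine map of effective rank ≤ hidden width, trained by full-batch
gradient descent on MSE. Inputs are centered and divided by the pooled
standard deviation of the calibration absorbances; targets are scaled per
component to [−1, 1] from calibration min/max (inverted at prediction).
Without this scaling, a 0.1 learning rate on raw AU × µg mL⁻¹ magnitudes
diverges immediately.

Two presets:

- `legacy` — 4 hidden units, learning rate 0.1, 50 epochs: the historical
  configuration, kept verbatim. Note that 50 full-batch epochs are far
  from convergence on these problems, and a width-4 linear network cannot
  represent the full rank-5 concentration map: with per-component [−1, 1]
  target scaling all five concentration directions carry equal weight, so
  the best rank-4 affine map must discard an entire direction. This
  preset is therefore a faithful historical reference, not an accuracy
  recommendation.
- `accuracy` — 5 hidden units (one per analyte, so the affine map can
  reach full rank), learning rate 0.05, up to 30 000 epochs with an early
  stop at loss ≤ 1e−14. On noiseless linear data it recovers validation
  concentrations to better than 1 %, and on noisy data it converges toward
  the least-squares affine fit.

A `hidden_size_scan` utility reports calibration RMSEC across widths 1–8,
mirroring the usual hidden-size search.

## Figures of merit

Per component on the validation set: recoveries 100·ŷ/y, their mean and
sample SD (n−1); RMSEP = √(Σe²/n); SEP = √(Σe²/(n−2)) so that SEP/RMSEP =
√(n/(n−2)) on the same residuals (the closeness of the two is the usual
overfitting check). The n−2, no-bias-subtraction SEP convention is the
only one consistent with the published (SEP, RMSEP) benchmark pairs at
n = 10; the bias-corrected n−1 alternative is available via
`convention="biased-n1"` but is not the default. Predicted-vs-actual is
ordinary least squares of predictions on true concentrations; LOD and LOQ
follow the 3.3σ/S and 10σ/S pattern with σ taken as the regression
residual SD (df = n−2) and S the slope — the 10/3.3 LOQ/LOD ratio holds
identically by construction. Absolute LOD values depend on the residuals
of the particular dataset; only their internal ratios are reproducible
from published summaries.

Method comparison from summary statistics uses the pooled-variance
two-sample t (two-sided, df n₁+n₂−2) and the variance-ratio F with the
larger variance in the numerator and the one-tailed upper critical value
at α = 0.05. For df (9, 4) that critical value is 6.00 (8.90 two-tailed);
the value of 5.60 tabulated alongside the published benchmark summaries is
inconsistent with every standard convention for those degrees of freedom,
and `compare_methods` reports the standard value.

Display rounding is half-up at report precision; all internal arithmetic
is full precision.

## Problem sizes and determinism

The test suite and the reproduction script run the study at its native
size: 25 design runs, 1001-point scans, 251-point window, 15/10 split.
Stochastic property checks use 20 fixed-seed noise replicates per level at
σ ∈ {1, 5, 10} mAU. Every random quantity (library jitter, noise, split,
network initialization) flows from an explicit seed, and all fits are
deterministic given their inputs, so every reported number is exactly
reproducible.

## Known limitations

- The synthetic band library is a plausible surrogate, not a fit to
  measured spectra of these five compounds; absolute figures of merit from
  synthetic runs are therefore indicative, not comparable instrument-for-
  instrument with published values.
- The `legacy` network preset reproduces a configuration, not its reported
  performance; see the rank argument above.
- Recovery percentages are ratio statistics: at high noise they are biased
  upward for components whose smallest calibrated concentration is near
  the noise-induced error (visible above ~5 mAU in the noise sweep).
- No derivative/smoothing preprocessing, variable selection beyond the
  single window, or nonlinear calibration models.
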
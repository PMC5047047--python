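# Methods

This document states the mathematical model behind each stage of the
analysis, the parameters with their units, defaults and rationale, the
scope of the synthetic phantom generator, and the numerical choices and
limitations of the implementation.

## 1. Signal model

A transflectance FTIR image is a cube `A[r, c, v]` of absorbance versus
wavenumber `v` (cm⁻¹, stored high→low). Under the Beer–Lambert model each
pixel spectrum is, to first order, a non-negative mixture of constituent
spectra plus a smooth baseline and noise:

```
A(r,c,·) = Σ_j  C[r,c,j] · s_j(·)  +  baseline(·)  +  ε
```

Differentiation is linear, so the same bilinear structure holds for the
second derivative with the baseline (up to quadratic order, see §2)
removed:

```
D ≈ C · Sᵀ        D: pixels × wavenumbers,  C ≥ 0 (softly),  S: profiles
```

The package works throughout in the **negated** second derivative, so that
absorbance peaks appear as positive lobes; this makes the non-negativity
convention on `C` and the "positive dominant lobe" sign convention on `S`
natural.

Assumptions: linear mixing (no strong scattering or anomalous-dispersion
residuals after differentiation), spatially constant constituent spectra,
and a number of constituents `k` small compared to both pixel count and
channel count.

## 2. Preprocessing

**Savitzky–Golay second derivative** — `second_derivative(data,
window_length=15, poly_order=3)`. Each trace is fit locally by a cubic
over a 15-channel window (30 cm⁻¹ at 2 cm⁻¹ spacing) and the analytic
second derivative of the fit is taken at the window centre. Output is in
per-channel-index² units (no division by the physical spacing); edge
channels use a one-sided polynomial fit so the axis length is preserved.

Properties relied on (and tested): the filter is *exact* on polynomials up
to the fit order at interior points, so constant and linear baselines are
annihilated to round-off; a quadratic baseline is not annihilated but
contributes only a constant offset to the derivative spectrum, which the
bilinear model absorbs far better than a sloped baseline. Window 15 /
order 3 balances band sharpening against noise amplification at 2 cm⁻¹
point spacing; both are configurable.

**Tissue masking** — `compute_mask(image, marker_wavenumber=1554.0,
threshold=0.0)`. Protein amide II produces a strong negative
second-derivative lobe at 1554 cm⁻¹; paraffin and bare substrate are flat
there. A pixel is tissue iff its second derivative at the channel nearest
the marker is strictly below the threshold. The default threshold 0
accepts any negative lobe; raising it (more negative) tightens the mask.

## 3. MCR-ALS unmixing

`resolve(image, mask, k, region=(950, 1300), ...)` restricts to the fingerprint
region (950–1300 cm⁻¹, where the carbohydrate and C–O–S bands that
discriminate the constituents live, and where paraffin interference from
the 1460 cm⁻¹ band is avoided), negates the masked second-derivative
matrix and factorizes it.

**Initial estimates.** NIPALS power iteration with deflation computes the
first `k` principal factors (equivalent to a truncated SVD; agreement of
the k-term reconstruction error with the SVD is an acceptance check).
Principal factors are abstract rotations, not spectra, so they are rotated
onto *purest-pixel* estimates: a greedy vertex search that repeatedly
picks the observed pixel spectrum with the largest residual norm after
projection onto the span of the already-chosen ones (QR-projection
deflation). Observed near-pure pixels are excellent, physically plausible
starting profiles and largely remove the rotational ambiguity of the
bilinear model.

**Alternating least squares.** With `S` fixed, `C = D S (SᵀS)⁻¹` solved by
least squares, then softly constrained; symmetrically for `S`. The soft
non-negativity map is `X ← (1−α)·X + α·max(X, 0)` with `α_C = 0.5`,
`α_S = 0` by default: second-derivative profiles legitimately have
negative side-lobes, so `S` is unconstrained, while concentrations are
pulled halfway toward non-negativity each sweep — strong enough to
suppress sign-flipped degeneracies, weak enough not to bias overlapping
components. After each sweep the columns of `S` are normalized to unit
Euclidean norm and the norm is absorbed into `C` (fixing the bilinear
scale indeterminacy).

**Quality and stopping.** Lack of fit is
`LOF = 100 · sqrt(Σ(D − C Sᵀ)² / ΣD²)` (percent). The optimizer keeps the
best iterate seen, so the reported `lof_history` is non-increasing by
construction. Iteration stops when the relative LOF change falls below
`tol` (default 1e-6) — with an absolute floor of `tol²` so that a fit
already at machine-level LOF is recognized as converged — or after 50
sweeps without improvement, or at `max_iter` (default 500).

**Sign convention.** For each factor, if the column sum of its
concentrations is negative the factor pair is negated; ties fall back to
the sign of the dominant profile lobe. This makes concentrations
predominantly positive and profiles peak-positive in the working
orientation.

## 4. Mapping and factor assignment

**Assignment** — `assign_factors(model, library, region)` computes Pearson
correlations between each resolved profile and each reference
second-derivative profile over the model region and solves the linear
assignment (Hungarian) problem maximizing total correlation. Unmatched
factors are labelled `extra`. Hungarian matching is used instead of
greedy best-match because collagen I/II and PG1/PG2 are highly correlated
pairs where greedy assignment can double-book a reference. When a known
subset of constituents is modelled, assign against that restricted
library; with a large library, weak factors can match spectrally similar
confounders.

**Tissue map** — `tissue_map(image, mask, 1186, 1297)` integrates the
positive part of the negated second derivative over the amide III window
(1186–1297 cm⁻¹) by the trapezoid rule. Amide III is proportional to
protein content and nearly constituent-independent, so it serves as a
section-thickness reference. The positive-part clip makes the integral a
proper non-negative measure of band area in the derivative domain.

**Ratio maps** — component map divided by tissue map, pixelwise, masked
pixels `NaN`. Ratios cancel thickness and compaction variation.

**C–O–S peak** — `cos_peak_position(profile, window=(1100, 1140))` finds
the strict local maximum of a factor profile in the C–O–S stretching
window and refines it by a three-point parabolic fit, reported to
0.1 cm⁻¹. The ≈2 cm⁻¹ displacement between the two proteoglycan forms
(≈1126 vs ≈1124 cm⁻¹) is the sulfation-pattern handle; sub-channel
refinement is required because the displacement is comparable to the
2 cm⁻¹ channel spacing.

## 5. Width-normalized regional gradients

A horizontal 10-row area of interest through the tissue centroid
(`default_aoi`) crosses the disc anterior→posterior. For each ratio map,
`width_normalized_profile` detects the tissue extent per the mask, maps
the extent onto a fixed 0–100 % axis (101 points), and averages within
percent bins — so discs of different physical width become comparable.
Regional parameters are trapezoid integrals of the profile over the
standard windows: anterior AF 10–20 %, NP 51–61 %, posterior AF 85–95 %
(window means are the integral divided by the 10 % width). The
normalization is tested to be invariant (≤2 % RMS) under column
duplication, i.e. under resampling of the disc width.

## 6. Statistics

**Theil–Sen / Kendall** — `nonparametric_regression` reports the median of
pairwise slopes (intercept = median of `y − slope·x`) with two-sided
significance from the Kendall S statistic. For `n ≤ 10` without ties the
exact permutation null is used, computed from the Mahonian
inversion-count distribution. Otherwise a Gaussian tail approximation
with the tau-b tie-corrected variance and a continuity correction of 1 is
used; in the no-tie case a one-term Edgeworth (kurtosis) correction is
applied using the exact closed-form fourth cumulant
`κ₄(S) = −n(n−1)(6n³+21n²+31n+31)/225`, which brings the worst-case
disagreement with the exact null at n = 10 below 1e-3. Rank-based
testing makes ordinal covariates (histological grade) valid inputs.

**Cohort correlation** — `correlate_cohort` inner-joins the regional
parameter table with the covariate table per requested
(component, covariate, region) triple, and optionally applies
Benjamini–Hochberg adjustment across the requested set.

**T2\* relaxometry** — `t2star_fit` recovers T2\* from multi-echo
gradient-echo trains by ordinary least squares of log intensity on echo
time (`T2* = −1/slope`), exact on noiseless mono-exponentials.

## 7. Phantom generator: scope

`generate_phantom(PhantomConfig(...))` produces a 60 × 208 pixel section
on a 950–1800 cm⁻¹ axis at 2 cm⁻¹ spacing with full ground truth
(concentration grids, reference spectra, regional abundances). Reference
spectra are sums of Gaussian bands, max-normalized; PG1 and PG2 differ by
a configurable C–O–S band displacement (`pg_shift`, default 2 cm⁻¹).
Zonation: collagen I in the outer AF, collagen II in the NP, PG1 in
inner-AF lobes with a NP tail, PG2 in an elliptical NP core, paraffin
everywhere (stronger in the embedding border). The degeneration level
`d ∈ [0, 1]` trades PG1 for PG2: PG1 scales by `1 − 0.8d`, PG2 by
`0.2 + 0.8d`. Distortions: additive Gaussian noise (`noise_sigma`,
default 0.005 absorbance units against unit band height), random
polynomial baselines (order 2, scale 0.1), optional multiplicative gain.

`generate_cohort(n, seed)` draws per-sample degeneration levels and
derives linked covariates (grade 0–6, GAG, hydroxyproline, T2*) with
controlled noise, returning per-sample configs, a covariate table and a
ground-truth regional table. All child seeds are drawn below 2³¹.

The generator is a *validation instrument*, not a tissue model: bands are
Gaussian, mixing is exactly bilinear, zonation is geometric, and
scattering/dispersion artefacts are not simulated. Conclusions about the
chain's behaviour on real transflectance data are limited accordingly.

## 8. Numerical choices and limitations

- **Keep-best ALS** guarantees a monotone quality history but means the
  returned iterate need not be the last one computed.
- **Soft (not hard) non-negativity** preserves least-squares optimality
  direction each half-step; hard clipping can stall on overlapping
  components. The price is that small negative concentrations survive.
- **Rotational ambiguity** is reduced, not eliminated, by purest-pixel
  initialization; with strongly overlapping concentration patterns the
  recovered pair of factors can be rotated within their span even when the
  subspace is recovered to under a degree. Factor-wise comparisons to
  references should be read with this in mind.
- **Savitzky–Golay second derivatives** are exact on cubics only to
  float64 round-off relative to the data magnitude; "exact to 1e-10" is
  meaningful only for well-scaled data (values ≲10³).
- **ENVI I/O** is implemented directly (header + raw binary, bsq/bil/bip,
  numeric band names required for cubes); masks are written as single-band
  8-bit grids with a descriptive band name and are not meant to be read
  back through the cube reader.
- **Timing-sensitive checks** warm the allocator first: on a cold
  container, first-touch page faults on ~100 MB buffers dominate wall
  time and are not a property of the algorithms.
- The exact Kendall null is only used for `n ≤ 10` without ties; tied
  small samples fall back to the tie-corrected Gaussian approximation
  without the Edgeworth term.
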
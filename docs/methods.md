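# Methods

This note documents the models, numerical choices, and the synthetic
data-generating process behind `localuse`, and what the test suite does
and does not establish about behavior on real data.

## Exposure surface

Local use is a deterministic aggregation, not a fate-and-transport
simulation: q_i = Σ_u q_u · 0.37^(d_iu/CTD), with the weight overridden
to 1 for sections whose centroid is covered by the unit polygon
(boundary points count as inside; the inclusive convention is chosen
for determinism). Distances are Euclidean, centroid-to-centroid, on
planar km coordinates. No cutoff radius is applied — every section
contributes, so the cost is O(units × sections) per CTD; weights below
1e-300 underflow to exactly 0. Wind, hydrology, and chemistry are
deliberately absent: q_i is *potential* exposure, a proxy, and all
downstream effect estimates inherit that interpretation.

Section totals default to the all-study-period sum (`period_total`);
`annual_mean` divides by the number of study years. Units with q_i = 0
for a given CTD have no defined log₁₀ outcome and are dropped from that
cell's regression, with the count logged. Section-centroid geocoding
makes the 1 km CTD intrinsically noisy (source locations are only known
to the 1.6 km section); the package reproduces, rather than corrects,
that limitation.

## Spatial weights

Row-standardized k-nearest-neighbor weights (default k = 3) built from
population-weighted centroids. kNN rather than contiguity because
place-type geographies are spatially isolated and contiguity leaves
most of them neighborless. Distance ties break by ascending unit
identifier, so duplicate coordinates are legal and results are
reproducible. kNN weights are asymmetric and are used as-is — nothing
in the estimator assumes symmetry. Moran's I uses the standard
row-standardized form I = (n/S₀)·(z̃ᵀWz̃)/(z̃ᵀz̃).

## Spatial Durbin estimation

The likelihood is concentrated twice: (β, θ) by least squares of
y − ρWy on [1, X, WX] (making RSS(ρ) an exact quadratic, so each
profile evaluation is O(np)), and σ² analytically. The log-determinant
ln|I − ρW| is evaluated from the eigenvalues of W, computed once per
weights object and cached; complex conjugate pairs contribute log
moduli. The feasible ρ interval is (1/λ_min, 1) using the smallest real
eigenvalue, or (−1, 1) when none is negative; the scalar optimizer is
bounded Brent with xatol 1e-10, and a solution within 1e-5 of the
boundary is an error rather than a result. An estimate at the boundary
almost always means a misspecified model, not a useful fit.

The parameter covariance over (β, θ, ρ) is the inverted negative
central-difference Hessian of the σ²-concentrated log-likelihood
(relative step 1e-5, ρ steps kept inside the feasible interval). This
matches common spatial-econometrics software closely enough for
interval estimation without closed-form information matrices.

One identification caveat, found and frozen into a test: in the
noiseless non-spatial limit (σ → 0, θ = 0) ρ is unidentified — the
likelihood has an exact ridge along which the intercept and θ
reparameterize ρ. Slope coefficients and total impacts are
ridge-invariant; tests assert those rather than ρ itself in that limit.

## Impacts

The dense oracle computes S_k = (I − ρW)⁻¹(Iβ_k + Wθ_k) exactly and is
the reference for n ≤ ~2000. The production estimator draws (β, θ, ρ)
from N(estimates, vcov) — ρ draws outside the feasible interval are
rejected and redrawn, at most 1000 attempts — and evaluates the direct
impact by the truncated power series with precomputed traces tr(Wʲ),
j ≤ q = 30, and the total impact by the closed form (β_k + θ_k)/(1 − ρ)
valid for row-standardized W. For |ρ| ≤ 0.8 the truncation error of the
direct-impact series is below 1e-3 relative (the tail is damped both by
ρʲ and by tr(Wʲ)/n → O(1/n) once j exceeds the graph diameter); a
non-PSD covariance (possible numerically) is projected to the nearest
PSD matrix with a warning.

## Survey preparation

Derived proportions use the survey-handbook propagation
MOE_p = (1/den)·√(MOE_num² − p²·MOE_den²), falling back to the ratio
formula (plus sign) when the radicand is negative, which guarantees a
real nonnegative MOE. Density enters as log₁₀ residents/km² (base 10
throughout, matching the outcome scale). County controls are count
aggregates over retained member units — log₁₀(Σpop/Σarea) and
Σag/Σemployment — broadcast to members; this is what a county-level
survey pull would give, as opposed to area-weighted means of unit
values. Units with zero estimated population or employment are excluded
up front (the filter is idempotent and logs each exclusion); reported
subgroup counts exceeding their denominator are clamped with a logged
count. Tracts and places run in parallel and are never pooled.

## Measurement-error bootstrap

Resampling is "at" fixed locations: W, y, centroids, and county
controls never change; each IV value is redrawn from
Normal(estimate, moe_to_sd × MOE) and the spatial lags WX are rebuilt
from the resampled values (forced by the model definition). The default
moe_to_sd = 1.0 uses the MOE directly as the sd; since ACS MOEs are 90%
half-widths, sd = MOE/1.645 is the other defensible convention and is a
config knob. Resampled proportions are clamped to [0, 1] by default
(logged). IVs with no published MOE — log density and the county
controls — are not resampled unless MOEs are supplied. Defaults are 500
resamples × 100 impact draws = 50,000 pooled draws per IV and cell,
summarized by the median and 5th/95th percentiles, raw and transformed
(ζ_trans = 10^(ζ/10)). Individual resample-fit failures are skipped and
counted; more than 10% aborts the cell.

**What the bootstrap does and does not fix.** It propagates
measurement-error *uncertainty* into wider intervals; it does not
remove attenuation *bias*. Refitting on estimate+noise doubles the
effective error variance, so the pooled distribution centers on a
slightly more attenuated value than the naive fit. The bias scales as
~2ζ(σ_e/σ_x)²: second-order when the MOE is small relative to the IV's
spatial spread, but large enough to drive interval undercoverage when
σ_e/σ_x grows past ~0.1–0.15. `attenuation_demo` quantifies the
mechanism in the non-spatial limit (naive slope → β·σ_x²/(σ_x²+σ_e²);
at σ_e = σ_x the slope halves). The bootstrap interval width also
stops growing with σ_e once attenuation collapses the slope itself —
the width is monotone in σ_e only in the small-noise regime.

## Synthetic data-generating process

The generator emulates the four pipeline inputs on an abstract planar
grid: rectangular units tiling the extent (n_units rounded up to the
nearest rows×cols grid), ≥1 positive-population block point per unit,
a 1.6 km section lattice, and per-section use records drawn log-uniform
in [1e-2, 1e4] lbs (the observed annualized range) scaled by a
nonnegative intensity surface. Latent IV proportions are Beta draws
with means/spreads loosely matching tract-level descriptive statistics
(e.g. Hispanic 0.42 ± 0.24); reported values add Normal(0, moe_scale)
error — the exact inverse of the bootstrap's resampling assumption —
and are clamped to [0, 1] with the clamped fraction recorded. Outcomes
come from the dense solve y = (I − ρW)⁻¹(Xβ + WXθ + ε). A single
run-level seed derives all substream seeds via `SeedSequence`, so every
stage is independently reproducible.

What it does *not* emulate: real geography (irregular polygons,
coastlines), spatially correlated covariates beyond what the grid
induces, crop-specific or seasonal use patterns, heteroscedastic or
spatially structured MOEs, and count-level survey error (noise is
applied to proportions directly). Passing tests therefore establish
that the estimators are correct under their own assumptions — not that
those assumptions hold for any particular real landscape, where
heteroscedasticity and residual spatial autocorrelation (both reported
per fit via residual Moran's I) are to be expected.

## Problem sizes and verification design

Simulation-based checks use sizes chosen to make Monte Carlo error
small relative to the tolerances while keeping the suite fast:
parameter recovery runs 100 replicates at n = 400 (90% Wald coverage
for every parameter required within [0.83, 0.97]); bootstrap interval
calibration runs 50 replicates at n = 200 with 100 resamples each. The
calibration experiment fixes moe = 0.02 against sd(X) = 0.2 — ME
variance 1% of IV variance — because interval coverage is a
well-posed expectation only in that second-order regime (see the bias
discussion above); the large-ME regime is covered by the attenuation
tests instead. Oracle agreement for impacts is asserted at n = 200
across ρ ∈ [−0.8, 0.8]. Full-design smoke runs use 36–64 units with
reduced bootstrap sizes; all sizes are configuration, not limits of the
method.

## Known limitations

- The exposure model is a proxy; impact estimates quantify disparity in
  *potential* exposure only.
- ρ inference near the feasible-interval boundary is unreliable by
  construction (the fit refuses boundary solutions).
- The ME bootstrap's intervals undercover when MOEs are large relative
  to IV spread (attenuation bias is not corrected).
- The trace-series direct impact assumes q = 30 suffices; for |ρ| > 0.9
  increase `trace_order`.
- County-stratified submodels, alternative weight families, and
  spatial-error/SARAR specifications are out of scope.
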
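# Methods

This note documents the models behind `phenosel`, the design of the
synthetic-data generators, the numerical choices, and what the test suite
does and does not demonstrate about real data.

## Platform trait extraction

**Shoot dry weight calibration.** Non-destructive SDW is an affine
function of leaf area and plant age, `SDW = c0 + c1·LA + c2·LA·age`
(defaults 0.1 g, 0.00184 g cm⁻², 0.0000926 g cm⁻² d⁻¹). The coefficients
are a platform-specific calibration and are overridable in the
configuration; the intercept represents seed-reserve biomass present at
zero measured leaf area.

**Growth analysis.** RER is the slope of ln(leaf area) over an
observation interval. NAR uses the classical growth-analysis form
`(ΔSDW/Δt)·(Δln LA/ΔLA)`, whose second factor is the reciprocal
logarithmic mean of leaf area; when the two areas are equal the analytic
limit `1/LA` is taken, which makes NAR exactly `(ΔSDW/Δt)/LA` there. A
quotient variant (`formula="as_printed"`) is retained for audits of
sources that typeset the expression as a division; it is dimensionally
inconsistent with g cm⁻² d⁻¹ and is never the default. Leaflet
width×length→area conversion requires an explicit calibration factor `k`;
no default is asserted because the factor is cultivar- and
protocol-dependent.

**Pot water balance.** Pot weight is soil water plus plant fresh mass.
Daily transpiration is
`T = (previous weight + irrigation − today's weight) − evaporation + gain`:
soil evaporation is the daily mean of plantless control pots (days without
controls reuse the last estimate, flagged), and `gain` — the day's plant
fresh-mass increase, obtained by linear interpolation of weekly
fresh-weight calibration harvests per treatment — is *added back* because
the plant's own growth masks water loss on the balance. Negative balances
(weighing noise) clamp to zero by default with a diagnostic; raw values
are kept in an audit column, and cumulative series use the clamped values
(hence are nondecreasing). The convention assumes pots are weighed after
irrigation; a pre-irrigation convention only relabels which day's
irrigation enters the difference.

**Transpiration efficiency.** `TE = 1000·SDW/cumulative T` (g kg⁻¹),
cumulated from emergence. TE is evaluated wherever leaf area was measured,
with SDW from the calibration above. Note a structural feature: because
the calibration has a seed-reserve intercept that costs no transpired
water, early-season TE computed this way runs roughly twice the marginal
dry-mass-per-water ratio and declines with age; this matches how such
platform TE values behave and is reproduced by the generator.

**Trait moments.** Trait observations enter the selection battery at the
experiment's scheduled measurement moments — the days leaf area was
recorded — one observation per plant per moment. The full daily
transpiration series remains available through
`water_use.transpiration_series` for water-budget work; scoring daily
fluxes at all ~57 weighing days as separate candidates would hand the
earliness criterion dozens of noise-dominated early-day candidates whose
5% false-positive rate dominates the selection, which is a property of
multiple testing, not of the biology.

## Two-segment TR–VPD response

Transpiration rate vs vapor pressure deficit is modelled as two
independent straight lines split at a breakpoint (BP); both intercepts are
free parameters (no continuity constraint), matching protocols that report
I₁ and I₂ separately. The BP is estimated by scanning a uniform candidate
grid (default 0.01 kPa) inside the observed VPD range, fitting each side by
OLS and minimizing pooled SSE; candidates must leave at least two distinct
VPD values per side, and SSE ties break toward the smaller BP. A
continuity-constrained variant (`continuity=True`) is available for
sensitivity checks. The workflow is: free-BP fit per genotype → common BP
as the unweighted mean (± sd) of genotype BPs → per-plant refits with the
BP fixed at the common value → derived parameters S₂:S₁, TR at BP and TR
at the maximum observed VPD.

Two precision facts shape the tests. With noise-free data the BP is
identified only up to the gap between adjacent VPD observations (any
candidate in the gap has zero SSE; the tie rule picks its lower edge), so
"exact" recovery means within one data-grid spacing. With 5% signal noise
and 30 points, the BP's statistical precision is ≈ 0.15–0.2 kPa for both
the unconstrained and the constrained estimator; recovery bounds tied to
the scan step are therefore only informative at a commensurate resolution,
and the recovery test scans at 0.15 kPa. Real fits should use the fine
default grid — the scan step is not the accuracy.

## DSI, variance components and repeatability

DSI follows the ratio-of-relative-reductions formula with population
means X defined as unweighted means of genotype means, which makes the
mean DSI exactly 1 by construction and is robust to unequal replication.
Genotypes missing a treatment are excluded from both the table and the X
means, with a diagnostic. The same implementation serves platform traits
and field yields (dry environments standing in for water deficit).

Variance components for balanced layouts use ANOVA expected-mean-squares
estimators (one-way: σ̂²e = MSE, σ̂²g = (MSG−MSE)/r; two-way random:
σ̂²ge = (MSGE−MSE)/r, σ̂²g = (MSG−MSGE)/(rt)); these coincide with REML
whenever nonnegative, which the suite verifies against an independent
mixed-model REML fit. Unbalanced layouts go directly to REML
(statsmodels `MixedLM`, genotype intercepts plus a genotype×environment
variance component). Negative estimates truncate to zero and are flagged.
Repeatability uses the single-environment formula before treatment onset
(all plants share one regime, every plant a replicate) and the
multi-environment formula — treatments as environments, with the G×E
component — from onset on; `r` is the mean cell replication.

## Four-criterion selection

The target is the DSI of *harvested* final shoot dry weight (leaf + stem
dry mass), computed at the final day; its phenotyping cost counts the
replicates of both water regimes times days-to-harvest (a DSI needs both
regimes; configurable). Each trait×moment×treatment candidate is scored
by OLS of genotype trait means on the target (R², two-sided slope p),
plant·day cost, efficiency ratio R²/relative-cost, and w². Filters:
p ≤ α (default 0.05, no multiple-testing correction — each candidate is
screened on its own, as a per-trait decision; a Benjamini–Hochberg
variant can be applied downstream on the audit table), ratio ≥ 2,
w² ≥ 0.5. Earliness is an ordering, not a cutoff, unless a hard DAE
ceiling is configured (`earliness_strict_dae`); the final ranking is
lexicographic (earliest DAE, then highest w², then highest ratio). The
audit table always retains every candidate with per-criterion flags.

## Field trial network

Water input is total rainfall from 60 days before sowing through
physiological maturity; the critical period is the window from 3 months
to 1 month before maturity (maturity stands in for harvest — the only
harvest-adjacent date in the schema; an explicit harvest date column can
be supplied where available). Monthly records are pro-rated by day count
assuming uniform within-month distribution; a missing month inside a
required window is an error naming the gap.

The envelope `yield = a(1 − e^{b(w−c)})` is fitted with b < 0 enforced via
an internal positive decay parameter (reported on the printed convention,
where `a` is attainable yield, `c` the minimum water input for any yield).
The "95% below" rule is realized as asymmetric least squares: residuals of
points above the curve carry a weight λ, blended by a narrow sigmoid
(0.2% of the yield scale) so a single smooth bounded least-squares solve
(scipy `least_squares`, trust-region reflective) suffices per λ; λ is
doubled from 1 and then bisected, warm-starting each solve from the
previous solution, until the on-or-below fraction is the smallest
achievable value ≥ 0.95. Points within 0.1% of the yield scale count as
exactly on the curve, hence below — the asymmetric loss leaves touching
points a hair above the curve, and this tolerance is the operational
meaning of "on". The decay rate is bounded below (0.3/range) so the
envelope cannot degenerate into an unbounded straight line at high λ. The
(λ, fraction) trace is kept on the fit object; the fraction is weakly
increasing in λ, which the suite asserts.

Classification: water-limited ⇔ mean yield within the closed ±20% band
around the envelope prediction; among water-limited, dry ⇔ critical
rainfall < 175 mm, wet ⇔ ≥ 350 mm (double the dry threshold), else
intermediate; non-water-limited environments are excluded from tolerance
estimation. Yield DSI uses genotype mean yields over dry vs wet
environments; the ΔY slope regresses yield-minus-environment-mean on water
input over all water-limited environments (≥ 3 required). With ~10
environments per genotype the ΔY slope is the more stable estimate; both
are reported and their rankings agree on data with built-in sensitivity.

## Synthetic data

The platform generator emulates a 7-genotype, two-regime (well-watered /
water-deficit from 33 DAE), 8-replicate screening, harvested at 57 DAE
with leaf area recorded at 13/20/27/33/38/44/57 DAE. Growth is
exponential over the vegetative window (leaf area ≈ 20 cm² at emergence,
RER ≈ 0.08 d⁻¹, reaching ≈ 1900 cm² and ≈ 14 g SDW at 57 DAE); water
deficit multiplies the daily expansion increment by
`1 − intensity·sensitivity_g` after onset (intensity 0.25), giving final
SDW reductions of roughly 30–45% and SDW-DSI spreads of about 0.7–1.3
across the panel. Daily transpiration is the dry-mass increment divided by
the plant's marginal TE (mean 1.8 g kg⁻¹, genotype sd 0.24, plant sd
0.08), so extracted cumulative TE at 13 DAE centers near 3.7 g kg⁻¹ with a
genotype range of several tenths. Pot weights evolve by the exact balance
(irrigation restores toward a 5 kg set point) using the same control-pot
evaporation means and interpolated fresh-weight gains the recovery
pipeline reconstructs, so the water balance closes exactly by
construction; observation error enters only as weighing noise on the
recorded weights (sd 1.5 g — load-cell scale) and relative leaf-area
measurement error (6% — manual/image error). Weighing errors telescope in
cumulative sums, which is why daily fluxes are far noisier than cumulative
TE — a deliberate, physically grounded feature. Stomatal conductance and
leaf temperatures carry genotype and treatment effects unrelated to
drought sensitivity.

The TE↔sensitivity coupling (default −0.9) is imposed as the *realized*
sample correlation of the generated panel (empirical standardization plus
Gram–Schmidt), not as a population parameter of a random draw: screening
and validation panels are deliberately chosen to span the tolerance range,
so the panel correlation is a design quantity. With 7 genotypes a random
draw at population ρ = −0.9 would scatter its sample correlation roughly
between −0.65 and −0.98, making any fixed end-to-end selection rate
meaningless.

The field generator draws 80 environments with water inputs uniform on
300–1200 mm; mean yields are the envelope truth (a = 5500 kg ha⁻¹,
b = −0.004 mm⁻¹, c = 150 mm) minus nonnegative shortfalls (≤ 18% of the
prediction for water-limited environments, ~5% exactly on the curve; 10
environments get 28–45% shortfalls and are thereby non-water-limited).
Monthly rainfall is built at uniform within-month rates chosen so that
window pro-rating recovers the constructed water input and
critical-period totals exactly; the driest water-limited environments are
constructed dry (critical rainfall ≈ 80–140 mm), the wettest wet
(≈ 380–480 mm), in roughly 2:2:1 dry:intermediate:wet proportions.
Genotype yields deviate from the environment mean by
`slope_g·(water − mean water)` plus centered noise; genotype TE values are
anti-correlated with the slopes (spread ≈ 0.5 g kg⁻¹, noise sd 0.1).

What the generators do **not** emulate: ontogenetic decline of RER,
weather-driven day-to-day transpiration forcing (VPD enters the TR
battery, not the daily balance), spatial/block effects on the platform,
soil-type and maturity-group covariates in the network, and non-water
yield limitations that correlate with rainfall. Passing tests therefore
demonstrate that the pipeline recovers what its own model class generates
at realistic noise levels — not that the biological coupling holds in any
particular dataset.

## Numerical conventions and degenerate inputs

Ratios with zero denominators (zero shoot mass, zero cumulative
transpiration, zero Slope1, zero trait variance, fewer than 3 genotypes)
propagate as missing values with diagnostics, never as exceptions, so
downstream stages drop them explicitly. Validation of input tables is
total: every row is either accepted or yields exactly one diagnostic.
Dates are ISO-8601; days after emergence is the canonical platform time
axis. All randomness flows from a single integer seed through numpy
Generators; identical seeds reproduce byte-identical data outputs (run
metadata carries the only timestamp). Stomatal-conductance units are
carried opaquely (porometer-dependent) and never converted.
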
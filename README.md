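# phenosel

Phenotyping-efficiency trait selection for soybean drought tolerance.

Breeding for drought tolerance is slow because the target — yield stability
under water deficit in the field — is expensive and late to measure.
Automated greenhouse platforms can phenotype dozens of candidate traits on
young plants, but that only helps if one knows *which* early trait actually
predicts field performance, and whether measuring it is worth its cost.
`phenosel` implements, as a tested reusable pipeline, a framework for
answering that question: it computes a battery of growth and water-use
traits from pot-level longitudinal platform data, scores every
trait × measurement-moment × water-treatment combination against a target
drought-tolerance index with four explicit criteria, and validates the
selected trait against a multi-environment field trial network. It is aimed
at plant phenomics groups and breeding programs that run (or plan) indoor
drought screenings.

## The statistics at the core

**Drought susceptibility index (DSI).** For any trait measured under
well-watered (ww) and water-deficit (wd) regimes,

    DSI = (1 − Y_wd / Y_ww) / (1 − X_wd / X_ww)

where *Y* are a genotype's treatment means and *X* the unweighted means of
genotype means. DSI = 1 is average susceptibility, 0 an unaffected
genotype, negative a trait that increases under deficit. The DSI of final
shoot dry weight is the pipeline's default target (the inverse of drought
tolerance).

**Trait battery.** From daily pot weighings and leaf-area measurements the
pipeline derives shoot dry weight `SDW = 0.1 + 0.00184·LA + 0.0000926·LA·age`
(a platform calibration, overridable), relative expansion rate
`RER = Δln LA / Δt`, net assimilation rate
`NAR = (ΔSDW/Δt)·(Δln LA/ΔLA)`, allometric ratios (LAR, SLA, LMR, SMR and
branch variants), leaf−air temperature difference, daily transpiration from
the pot water balance (corrected for soil evaporation via plantless control
pots and for plant fresh-weight gain via weekly calibration harvests), and
transpiration efficiency `TE = 1000·SDW / cumulative transpiration`
(g kg⁻¹). A two-segment linear regression of transpiration rate on vapor
pressure deficit yields slopes, intercepts, a per-genotype breakpoint and
the derived TR parameters.

**Four selection criteria.** Each candidate combination is scored by
(1) significance of its regression on the target across genotypes
(p ≤ 0.05); (2) the ratio of R² to relative phenotyping cost — cost being
replicates × days-to-measurement (plant·day) — with ratio ≥ 2 required;
(3) earliness (ascending days after emergence); (4) repeatability
`w² = σ²g / (σ²g + σ²e/r)` before treatment onset, or
`σ²g / (σ²g + σ²e/(rt) + σ²ge/t)` across t soil-water treatments, with
w² ≥ 0.5. Variance components come from ANOVA expected-mean-squares
estimators on balanced layouts and REML otherwise.

**Field validation.** Environment mean yields are related to water input
(rainfall from 60 days before sowing to maturity) through a boundary
(envelope) function `yield = a(1 − e^{b(w−c)})`, b < 0, fitted so that at
least 95% of environments lie on or below the curve. Environments within
±20% of the envelope are water-limited; critical-period rainfall (3 to 1
months before maturity) splits them into dry (< 175 mm), wet (≥ 350 mm)
and intermediate. Genotype tolerance is estimated as the yield DSI between
dry and wet environments and as the slope of yield deviation from the
environment mean against water input (ΔY slope; negative = tolerant), and
the platform trait is regressed on both.

Because the original experiments and the trial-network database are not
public, the package ships first-class synthetic-data generators
(`phenosel.synthetic_data`) that emulate both data sources with known
ground truth — including a configurable correlation between genotype TE
and drought sensitivity — so every stage is testable end to end.

## Worked example

```bash
phenosel simulate platform --out demo/sim --seed 7
phenosel select --platform demo/sim/platform.csv \
    --harvest demo/sim/harvest.csv --evaporation demo/sim/evaporation.csv \
    --fresh-weights demo/sim/fresh_weights.csv --onset 33 --out demo/sel
```

prints

```
selected: TE at 13 DAE (WD), ratio=6.59
```

i.e. among 122 trait × moment × treatment combinations, transpiration
efficiency measured at 13 days after emergence — three weeks *before* the
water-deficit treatment is imposed — passed all four criteria and ranked
first: its regression against the DSI of final shoot dry weight was
significant, its R²-to-relative-cost ratio was 6.6 (a 13-day single-regime
measurement is ~9× cheaper than the 57-day two-regime target), and its
repeatability was high. `demo/sel/efficiency.csv` holds the full audit
table (one row per combination with per-criterion flags),
`demo/sel/target_dsi.csv` the per-genotype DSI values. The field stage is
exercised the same way (`phenosel simulate field`, `phenosel
field-classify`, `phenosel validate`), or everything at once with
`phenosel run --out demo/full --seed 7`.

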
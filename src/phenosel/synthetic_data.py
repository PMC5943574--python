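"""Synthetic platform experiments and field trial networks with known truth.

The generators emulate the two data sources the framework consumes:

* a multi-genotype greenhouse platform experiment — exponential-phase leaf
  area growth with genotype, treatment, genotype-x-treatment and residual
  effects; pot-weight series whose daily water balance closes exactly by
  construction; per-genotype transpiration efficiency (TE) whose coupling
  with drought sensitivity is a configurable correlation; harvest records
  and soil-evaporation control pots;
* an 80-environment trial network whose mean yields lie on or below a
  saturating envelope of water input, with a configurable fraction of
  environments limited by non-water factors, per-genotype sensitivity
  slopes, and monthly rainfall series built at uniform within-month rates
  so that window pro-rating recovers the constructed water inputs and
  critical-period totals exactly.

Every simulation returns the generated dataset together with a truth record
holding the sampled effects, so parameter-recovery tests can compute every
downstream quantity in closed form. All randomness flows from a single
seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import FieldDataset, PlatformDataset
from .growth_traits import estimate_sdw
from .vpd_response import SegmentedFit
from .water_use import plant_weight_correction

__all__ = [
    "FieldSimConfig",
    "PlatformSimConfig",
    "simulate_field_network",
    "simulate_platform_experiment",
    "simulate_vpd_series",
]


@dataclass
class PlatformSimConfig:
    """Design and effect sizes of a simulated platform experiment.

    Defaults mirror a 7-genotype, two-regime screening: water deficit
    imposed at 33 days after emergence (DAE), harvest at 57 DAE, leaf area
    measured at seven moments. Growth is exponential over the vegetative
    window; drought acts multiplicatively on the expansion rate after
    onset. ``te_coupling`` is the correlation between a genotype's TE and
    its drought-sensitivity multiplier (negative: efficient genotypes are
    tolerant).
    """

    n_genotypes: int = 7
    n_replicates: int = 8
    treatments: dict[str, float] = dc_field(
        default_factory=lambda: {"WW": 0.0, "WD": 0.25})
    onset_dae: int = 33
    final_dae: int = 57
    measurement_daes: tuple[int, ...] = (13, 20, 27, 33, 38, 44, 57)
    gs_daes: tuple[int, ...] = (17, 24, 37, 46)
    thermal_daes: tuple[int, ...] = (17, 24, 37, 46)

    la0_mean: float = 20.0         # cm^2 at emergence (cotyledons + unifoliates)
    la0_genotype_sd: float = 0.04  # log scale
    rer_mean: float = 0.08         # d^-1
    rer_genotype_sd: float = 0.002
    rer_ge_sd: float = 0.0003      # genotype x treatment, log-RER scale
    rer_residual_sd: float = 0.004 # per plant-day
    la_measurement_cv: float = 0.06  # leaf-area observation error (fraction)

    #: marginal TE: g dry-mass increment per kg transpired after emergence;
    #: the extracted cumulative TE at 13 DAE is roughly twice this because
    #: the dry-weight calibration's seed-reserve intercept does not cost water
    te_mean: float = 1.8
    te_genotype_sd: float = 0.24
    te_residual_sd: float = 0.08
    te_coupling: float = -0.9
    sens_mean: float = 1.0
    sens_sd: float = 0.25

    lmr_mean: float = 0.55
    lmr_genotype_sd: float = 0.02
    branch_fraction: float = 0.15
    harvest_mass_cv: float = 0.02  # drying/weighing error on harvest masses

    pot_weight_start: float = 5000.0  # g
    pot_weight_noise_sd: float = 1.5  # weighing error, g (observation only)
    fresh_to_dry_ratio: float = 6.0
    evaporation_base: float = 10.0    # g d^-1
    evaporation_amplitude: float = 3.0
    evaporation_control_sd: float = 0.5
    n_evaporation_controls: int = 3

    gs_mean: float = 300.0
    gs_genotype_sd: float = 25.0
    gs_residual_sd: float = 20.0
    gs_wd_drop: float = 60.0
    air_temp_mean: float = 26.0
    leaf_dt_mean: float = -1.5
    leaf_dt_wd_shift: float = 1.5
    leaf_dt_residual_sd: float = 0.4

    vpd_day_mean: float = 1.8
    vpd_day_amplitude: float = 0.6

    seed: int = 0

    def validate(self) -> None:
        if not -1.0 <= self.te_coupling <= 1.0:
            raise ValueError("te_coupling must be in [-1, 1]")
        if not 0 < self.onset_dae < self.final_dae:
            raise ValueError("onset_dae must lie inside the simulated span")
        for name in ("la0_genotype_sd", "rer_genotype_sd", "rer_ge_sd",
                     "rer_residual_sd", "te_genotype_sd", "te_residual_sd",
                     "sens_sd", "la_measurement_cv", "pot_weight_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PlatformTruth:
    """Sampled effects behind one simulated platform experiment."""

    genotypes: pd.DataFrame   # genotype, la0, rer, te, sensitivity, lmr
    plants: pd.DataFrame      # plant_id, genotype, treatment, replicate, te_plant
    fresh_weights: pd.DataFrame  # treatment, dae, fresh_weight
    daily: pd.DataFrame       # plant_id, dae, la_true, sdw_true, transpiration,
                              # cumulative_transpiration (noise-free truth)
    config: PlatformSimConfig


def _coupled_effects(
    rng: np.random.Generator, n: int, coupling: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance vectors whose *sample* correlation equals ``coupling``.

    The panel is constructed, not sampled: screening panels are chosen to
    span the tolerance range, so the realized correlation in a panel is
    treated as a design quantity rather than a random draw. Empirical
    standardization plus Gram-Schmidt makes the realized correlation exact
    for any panel size >= 3.
    """
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    if n < 3 or abs(coupling) >= 1.0:
        w = coupling * z1 + np.sqrt(max(0.0, 1.0 - coupling**2)) * z2
        return z1, w
    u = (z1 - z1.mean()) / z1.std(ddof=0)
    resid = z2 - z2.mean() - (np.dot(z2 - z2.mean(), u) / n) * u
    v = resid / resid.std(ddof=0)
    w = coupling * u + np.sqrt(1.0 - coupling**2) * v
    return u, w


def simulate_platform_experiment(
    config: PlatformSimConfig | None = None,
    seed: int | None = None,
) -> tuple[PlatformDataset, PlatformTruth]:
    """Generate one platform experiment plus its ground-truth record.

    The pot-weight series is built so the daily water balance closes
    exactly: the balance uses the mean of the generated control pots as
    evaporation and the treatment-level interpolated fresh-weight gain as
    the plant-weight term — the same quantities the recovery pipeline
    reconstructs. Per-plant cumulative transpiration is tied to estimated
    shoot dry weight through the plant's TE, so TE extracted downstream
    equals the sampled plant-level TE.
    """
    config = config or PlatformSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    G, R = config.n_genotypes, config.n_replicates
    treatments = list(config.treatments)
    days = np.arange(0, config.final_dae + 1)
    n_days = len(days)

    # genotype-level effects; TE and sensitivity share the coupled draw
    z_te, z_sens = _coupled_effects(rng, G, config.te_coupling)
    genotypes = pd.DataFrame({
        "genotype": [f"G{i + 1:02d}" for i in range(G)],
        "la0": config.la0_mean * np.exp(config.la0_genotype_sd * rng.standard_normal(G)),
        "rer": config.rer_mean + config.rer_genotype_sd * rng.standard_normal(G),
        "te": config.te_mean + config.te_genotype_sd * z_te,
        "sensitivity": np.clip(config.sens_mean + config.sens_sd * z_sens, 0.05, None),
        "lmr": config.lmr_mean + config.lmr_genotype_sd * rng.standard_normal(G),
    })

    # plant grid
    grid = [
        (f"{geno}_{trt}_R{r + 1:02d}", geno, trt, r + 1)
        for geno in genotypes["genotype"] for trt in treatments for r in range(R)
    ]
    plants = pd.DataFrame(grid, columns=["plant_id", "genotype", "treatment", "replicate"])
    plants = plants.merge(genotypes, on="genotype")
    n_plants = len(plants)
    plants["te_plant"] = np.clip(
        plants["te"] + config.te_residual_sd * rng.standard_normal(n_plants), 0.2, None)
    ge = {
        (geno, trt): config.rer_ge_sd * rng.standard_normal()
        for geno in genotypes["genotype"] for trt in treatments
    }
    plants["rer_ge"] = [ge[(g, t)] for g, t in zip(plants["genotype"], plants["treatment"])]

    # daily log-growth increments (plants x days); day 0 holds ln(la0)
    intensity = plants["treatment"].map(config.treatments).to_numpy(float)
    stress = np.ones((n_plants, n_days))
    after_onset = days[None, :] > config.onset_dae
    stress = np.where(after_onset,
                      1.0 - (intensity * plants["sensitivity"].to_numpy(float))[:, None],
                      1.0)
    base = (plants["rer"].to_numpy(float) + plants["rer_ge"].to_numpy(float))[:, None]
    incr = (base + config.rer_residual_sd * rng.standard_normal((n_plants, n_days))) * stress
    incr[:, 0] = 0.0
    ln_la = np.log(plants["la0"].to_numpy(float))[:, None] + np.cumsum(incr, axis=1)
    la = np.exp(ln_la)
    sdw = estimate_sdw(la, np.broadcast_to(days, la.shape).astype(float))

    # transpiration tied to marginal TE: each day's water use is the dry-mass
    # increment over te_plant, so the cumulative from emergence equals
    # 1000*(SDW(d) - SDW(0))/te_plant (seed reserves cost no water)
    cum_target = (1000.0 * (sdw - sdw[:, [0]])
                  / plants["te_plant"].to_numpy(float)[:, None])
    transp = np.zeros_like(cum_target)
    transp[:, 1:] = np.diff(cum_target, axis=1)
    transp = np.maximum(transp, 0.0)

    # evaporation controls; the balance uses the per-day control mean
    evap_true = (config.evaporation_base
                 + config.evaporation_amplitude * np.sin(days / 5.0))
    controls = np.clip(
        evap_true[None, :]
        + config.evaporation_control_sd * rng.standard_normal(
            (config.n_evaporation_controls, n_days)),
        0.0, None)
    evap_mean = controls.mean(axis=0)

    # treatment-level fresh-weight calibration (weekly) and its interpolated
    # daily gain — the same correction the recovery pipeline applies
    weekly = np.arange(0, config.final_dae + 1, 7)
    if weekly[-1] != config.final_dae:
        weekly = np.append(weekly, config.final_dae)
    fresh_rows = []
    gain = np.zeros((n_plants, n_days))
    for trt in treatments:
        mask = (plants["treatment"] == trt).to_numpy()
        fw = config.fresh_to_dry_ratio * sdw[mask].mean(axis=0)
        for d in weekly:
            fresh_rows.append((trt, int(d), float(fw[d])))
        cal = pd.DataFrame({"dae": weekly, "fresh_weight": fw[weekly]})
        g, _ = plant_weight_correction(cal, days)
        gain[mask] = g.to_numpy(float)[None, :]
    fresh_weights = pd.DataFrame(fresh_rows, columns=["treatment", "dae", "fresh_weight"])

    # pot weights: exact balance with irrigation restoring toward setpoint
    weight = np.zeros((n_plants, n_days))
    irrigation = np.zeros((n_plants, n_days))
    weight[:, 0] = config.pot_weight_start
    for d in range(1, n_days):
        deficit = config.pot_weight_start - weight[:, d - 1]
        irrigation[:, d] = np.round(
            np.clip(transp[:, d] + evap_mean[d] + 0.5 * deficit, 0.0, None), 1)
        weight[:, d] = (weight[:, d - 1] + irrigation[:, d]
                        - transp[:, d] - evap_mean[d] + gain[:, d])

    # optional physiology traits
    vpd_series = config.vpd_day_mean + config.vpd_day_amplitude * np.sin(days / 3.0)
    gs_geno = config.gs_genotype_sd * rng.standard_normal(G)
    gs_map = dict(zip(genotypes["genotype"], gs_geno))

    # observation errors: weighing noise on the pot-weight column (errors
    # telescope in cumulative sums, so they blur daily transpiration far
    # more than cumulative TE) and relative leaf-area measurement error
    weight_obs = weight + config.pot_weight_noise_sd * rng.standard_normal(weight.shape)
    la_obs = la * (1.0 + config.la_measurement_cv * rng.standard_normal(la.shape))

    long = pd.DataFrame({
        "plant_id": np.repeat(plants["plant_id"].to_numpy(), n_days),
        "genotype": np.repeat(plants["genotype"].to_numpy(), n_days),
        "treatment": np.repeat(plants["treatment"].to_numpy(), n_days),
        "replicate": np.repeat(plants["replicate"].to_numpy(), n_days),
        "dae": np.tile(days, n_plants),
        "pot_weight": weight_obs.ravel(),
        "irrigation_added": irrigation.ravel(),
        "vpd": np.tile(vpd_series, n_plants),
    })
    measured = np.isin(long["dae"].to_numpy(), config.measurement_daes)
    long["leaf_area"] = np.where(measured, la_obs.ravel(), np.nan)

    on_gs = np.isin(long["dae"].to_numpy(), config.gs_daes)
    wd_now = ((long["treatment"] != "WW").to_numpy()
              & (long["dae"].to_numpy() > config.onset_dae))
    gs_vals = (config.gs_mean
               + long["genotype"].map(gs_map).to_numpy(float)
               - config.gs_wd_drop * wd_now
               + config.gs_residual_sd * rng.standard_normal(len(long)))
    long["gs"] = np.where(on_gs, gs_vals, np.nan)

    on_thermal = np.isin(long["dae"].to_numpy(), config.thermal_daes)
    air = config.air_temp_mean + 0.5 * np.sin(long["dae"].to_numpy() / 4.0)
    dt_vals = (config.leaf_dt_mean + config.leaf_dt_wd_shift * wd_now
               + config.leaf_dt_residual_sd * rng.standard_normal(len(long)))
    long["air_temp"] = np.where(on_thermal, air, np.nan)
    long["leaf_temp"] = np.where(on_thermal, air + dt_vals, np.nan)
    long["leaf_temp2"] = np.where(
        on_thermal,
        air + dt_vals + 0.2 * rng.standard_normal(len(long)),
        np.nan)

    # harvest at the final day (dry masses carry a small weighing error)
    final_sdw = sdw[:, -1]
    lmr = plants["lmr"].to_numpy(float)
    leaf_dw = lmr * final_sdw * (1.0 + config.harvest_mass_cv
                                 * rng.standard_normal(n_plants))
    stem_dw = (1.0 - lmr) * final_sdw * (1.0 + config.harvest_mass_cv
                                         * rng.standard_normal(n_plants))
    harvests = pd.DataFrame({
        "plant_id": plants["plant_id"],
        "dae": config.final_dae,
        "leaf_dw": leaf_dw,
        "stem_dw": stem_dw,
        "leaf_dw_branches": config.branch_fraction * leaf_dw,
        "stem_dw_branches": config.branch_fraction * stem_dw,
        "n_nodes": rng.integers(10, 16, n_plants),
        "n_branches": rng.integers(2, 6, n_plants),
    })

    evap_df = pd.DataFrame({
        "dae": np.tile(days, config.n_evaporation_controls),
        "pot_id": np.repeat(
            [f"CTRL{i + 1}" for i in range(config.n_evaporation_controls)], n_days),
        "evaporation": controls.ravel(),
    })

    dataset = PlatformDataset(
        plants=long,
        harvests=harvests,
        evaporation=evap_df,
        treatment_onset_dae=config.onset_dae,
        experiment_id="synthetic-platform",
    )
    daily_truth = pd.DataFrame({
        "plant_id": np.repeat(plants["plant_id"].to_numpy(), n_days),
        "dae": np.tile(days, n_plants),
        "la_true": la.ravel(),
        "sdw_true": sdw.ravel(),
        "transpiration": transp.ravel(),
        "cumulative_transpiration": cum_target.ravel(),
    })
    truth = PlatformTruth(
        genotypes=genotypes,
        plants=plants[["plant_id", "genotype", "treatment", "replicate",
                       "te_plant", "rer_ge"]].copy(),
        fresh_weights=fresh_weights,
        daily=daily_truth,
        config=config,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# TR-VPD series


def simulate_vpd_series(
    fit_truth: SegmentedFit,
    n: int = 30,
    noise_sd: float = 0.05,
    vpd_range: tuple[float, float] = (1.2, 2.98),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """(vpd, tr) pairs from a two-segment truth plus proportional noise.

    ``noise_sd`` is a fraction of the local signal magnitude (Gaussian).
    """
    if n < 8:
        raise ValueError("need n >= 8 points")
    rng = rng if rng is not None else np.random.default_rng(seed)
    vpd = rng.uniform(vpd_range[0], vpd_range[1], n)
    low = vpd < fit_truth.bp
    tr = np.where(low,
                  fit_truth.i1 + fit_truth.s1 * vpd,
                  fit_truth.i2 + fit_truth.s2 * vpd)
    tr = tr + noise_sd * np.abs(tr) * rng.standard_normal(n)
    return pd.DataFrame({"vpd": vpd, "tr": tr})


# ---------------------------------------------------------------------------
# field trial network


@dataclass
class FieldSimConfig:
    """Design of a simulated multi-environment trial network.

    Mean environment yields are the envelope truth minus nonnegative
    shortfalls; ``n_non_water_limited`` environments get shortfalls beyond
    the +/-20% band (limited by factors other than water). Genotype yields
    deviate from the environment mean by ``slope_g x (water - mean water)``
    so each genotype carries a built-in sensitivity; genotype TE values are
    anti-correlated with those slopes through ``te_coupling_scale``.
    """

    n_environments: int = 80
    genotypes: tuple[str, ...] = tuple(f"V{i + 1:02d}" for i in range(7))
    envelope_a: float = 5500.0   # kg ha^-1
    envelope_b: float = -0.004   # mm^-1 (saturating convention, negative)
    envelope_c: float = 150.0    # mm
    water_range: tuple[float, float] = (300.0, 1200.0)
    deviation_max_frac: float = 0.18
    on_curve_frac: float = 0.05
    n_non_water_limited: int = 10
    excluded_deviation_frac: tuple[float, float] = (0.28, 0.45)
    dry_frac: float = 0.40
    wet_frac: float = 0.20
    slope_sd: float = 1.5        # kg ha^-1 mm^-1
    yield_noise_sd: float = 80.0
    te_mean: float = 3.7
    te_coupling_scale: float = 0.17  # g kg^-1 per unit slope sd
    te_noise_sd: float = 0.10
    first_year: int = 2012
    seed: int = 0

    def validate(self) -> None:
        if self.n_environments < 10:
            raise ValueError("need >= 10 environments")
        if self.n_non_water_limited >= self.n_environments:
            raise ValueError("too many non-water-limited environments")
        if self.envelope_b >= 0:
            raise ValueError("envelope_b must be negative (saturating convention)")


@dataclass
class FieldTruth:
    """Constructed effects behind one simulated trial network."""

    environments: pd.DataFrame  # env, water_input, crit target, deviation, class
    genotypes: pd.DataFrame     # genotype, slope, te
    config: FieldSimConfig


def _monthly_rainfall(
    water_total: float,
    crit_total: float,
    sowing: dt.date,
    maturity: dt.date,
) -> dict[str, float]:
    """Month totals with uniform within-month rates chosen so that window
    pro-rating recovers ``water_total`` over [sowing-60 d, maturity] and
    ``crit_total`` over [maturity-3 months, maturity-1 month) exactly."""
    from .field_network import _month_bounds

    start = sowing - dt.timedelta(days=60)
    end = maturity + dt.timedelta(days=1)
    mat = pd.Timestamp(maturity)
    c_start = (mat - pd.DateOffset(months=3)).date()
    c_end = (mat - pd.DateOffset(months=1)).date()

    months: dict[str, tuple[dt.date, dt.date]] = {}
    cursor = dt.date(start.year, start.month, 1)
    while cursor < end:
        label = f"{cursor.year:04d}-{cursor.month:02d}"
        months[label] = _month_bounds(label)
        cursor = months[label][1]

    crit_months = {m for m, (ms, me) in months.items()
                   if min(me, c_end) > max(ms, c_start)}
    crit_days = (c_end - c_start).days
    rate_crit = crit_total / crit_days

    totals: dict[str, float] = {}
    crit_window_contribution = 0.0
    other_days = 0
    for label, (ms, me) in months.items():
        if label in crit_months:
            totals[label] = rate_crit * (me - ms).days
            crit_window_contribution += rate_crit * (min(me, end) - max(ms, start)).days
        else:
            other_days += (min(me, end) - max(ms, start)).days
    remaining = water_total - crit_window_contribution
    if remaining < 0:
        raise ValueError(
            "critical-period rainfall target incompatible with total water input")
    rate_other = remaining / other_days if other_days else 0.0
    for label, (ms, me) in months.items():
        if label not in crit_months:
            totals[label] = rate_other * (me - ms).days
    return totals


def simulate_field_network(
    config: FieldSimConfig | None = None,
    seed: int | None = None,
) -> tuple[FieldDataset, FieldTruth]:
    """Generate a trial network plus truth record.

    Water inputs span ``water_range``; the driest water-limited
    environments are constructed dry (critical rainfall ~100 mm), the
    wettest wet (~430 mm), the rest intermediate, with class counts set by
    ``dry_frac``/``wet_frac``.
    """
    config = config or FieldSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_environments
    genos = list(config.genotypes)

    water = np.sort(rng.uniform(*config.water_range, n))
    pred = config.envelope_a * (1.0 - np.exp(config.envelope_b * (water - config.envelope_c)))

    dev_frac = rng.uniform(0.0, config.deviation_max_frac, n)
    on_curve = rng.random(n) < config.on_curve_frac
    dev_frac[on_curve] = 0.0
    excluded_idx = rng.choice(n, size=config.n_non_water_limited, replace=False)
    dev_frac[excluded_idx] = rng.uniform(*config.excluded_deviation_frac,
                                         config.n_non_water_limited)
    mean_yield = pred * (1.0 - dev_frac)
    water_limited = np.ones(n, dtype=bool)
    water_limited[excluded_idx] = False

    # class targets among water-limited environments, ordered by water input
    classes = np.array(["intermediate"] * n, dtype=object)
    wl_order = np.flatnonzero(water_limited)  # water already sorted ascending
    n_wl = len(wl_order)
    n_dry = int(round(config.dry_frac * n_wl))
    n_wet = int(round(config.wet_frac * n_wl))
    classes[wl_order[:n_dry]] = "dry"
    classes[wl_order[n_wl - n_wet:]] = "wet"
    crit_target = np.empty(n)
    for i in range(n):
        if classes[i] == "dry":
            crit_target[i] = rng.uniform(80.0, 140.0)
        elif classes[i] == "wet":
            crit_target[i] = rng.uniform(380.0, 480.0)
        else:
            crit_target[i] = rng.uniform(210.0, 320.0)
        # a critical-window month set spans ~90 days at the critical rate;
        # keep its share of the total window below the water input
        crit_target[i] = min(crit_target[i], 0.60 * water[i])
    classes[~water_limited] = "excluded"

    slopes = config.slope_sd * rng.standard_normal(len(genos))
    slopes -= slopes.mean()
    te = (config.te_mean
          - (config.te_coupling_scale / config.slope_sd) * slopes
          + config.te_noise_sd * rng.standard_normal(len(genos)))
    geno_truth = pd.DataFrame({"genotype": genos, "slope": slopes, "te": te})

    w_center = water.mean()
    trial_rows = []
    rain_rows = []
    env_rows = []
    for i in range(n):
        env_id = f"E{i + 1:03d}"
        year = config.first_year + int(rng.integers(0, 5))
        sowing = dt.date(year, 11, 1) + dt.timedelta(days=int(rng.integers(0, 25)))
        emergence = sowing + dt.timedelta(days=int(rng.integers(6, 12)))
        maturity = sowing + dt.timedelta(days=int(rng.integers(110, 130)))
        totals = _monthly_rainfall(water[i], crit_target[i], sowing, maturity)
        for month, mm in totals.items():
            rain_rows.append((env_id, month, mm))
        noise = config.yield_noise_sd * rng.standard_normal(len(genos))
        noise -= noise.mean()
        for j, geno in enumerate(genos):
            y = mean_yield[i] + slopes[j] * (water[i] - w_center) + noise[j]
            trial_rows.append((env_id, geno, max(y, 0.0),
                               sowing.isoformat(), emergence.isoformat(),
                               maturity.isoformat()))
        env_rows.append((env_id, water[i], crit_target[i], dev_frac[i],
                         bool(water_limited[i]), classes[i], mean_yield[i]))

    trials = pd.DataFrame(trial_rows, columns=[
        "environment_id", "genotype", "yield_kg_ha",
        "sowing_date", "emergence_date", "maturity_date"])
    rainfall = pd.DataFrame(rain_rows, columns=["environment_id", "month", "rainfall_mm"])
    dataset = FieldDataset(trials=trials, rainfall=rainfall)
    truth = FieldTruth(
        environments=pd.DataFrame(env_rows, columns=[
            "environment_id", "water_input", "critical_rainfall_target",
            "deviation_frac", "water_limited", "moisture_class", "mean_yield"]),
        genotypes=geno_truth,
        config=config,
    )
    return dataset, truth


def truth_to_tables(truth: PlatformTruth | FieldTruth) -> dict[str, pd.DataFrame]:
    """Flatten a truth record into named tables (for truth.csv outputs)."""
    cfg = pd.DataFrame(
        [(k, repr(v)) for k, v in dataclasses.asdict(truth.config).items()],
        columns=["parameter", "value"])
    if isinstance(truth, PlatformTruth):
        return {"truth_genotypes": truth.genotypes, "truth_plants": truth.plants,
                "truth_fresh_weights": truth.fresh_weights, "truth_config": cfg}
    return {"truth_environments": truth.environments,
            "truth_genotypes": truth.genotypes, "truth_config": cfg}
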
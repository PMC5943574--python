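"""Trial-network analysis: envelope of yield vs water input, environment
classification, and per-genotype field drought-tolerance estimates.

Water input of an environment is the total rainfall from 60 days before
sowing through physiological maturity (monthly records pro-rated by day
count). Attainable yield follows the saturating boundary (envelope)
function

    yield = a * (1 - exp(b * (water_input - c)))       (b < 0)

fitted so that at least 95% of environments lie on or below the curve —
here by asymmetric-loss least squares whose above-curve weight is raised by
bisection until the on-or-below fraction reaches the smallest achievable
value >= the target. Environments whose mean yield is within +/-20% of the
curve are "water-limited"; among them, critical-period rainfall (the two
months from 3 to 1 month before maturity) splits dry (< 175 mm), wet
(>= 350 mm) and intermediate years. Genotype tolerance is then quantified
two ways: the yield drought susceptibility index between dry and wet
environments, and the slope of yield deviation from the environment mean
(Delta-Y) against water input (negative slope = relatively better in dry
environments = tolerant).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy import stats

from .core_data import Diagnostic, FieldDataset, diagnostics_frame
from .tolerance_stats import dsi

ON_CURVE_RTOL = 1e-3

__all__ = [
    "EnvelopeFit",
    "ON_CURVE_RTOL",
    "classify_environments",
    "critical_period_rainfall",
    "delta_y_slope",
    "environment_summaries",
    "fit_envelope",
    "validate_trait",
    "water_input",
    "window_rainfall",
    "yield_dsi",
]


def _month_bounds(label: str) -> tuple[dt.date, dt.date]:
    """(first day, first day of next month) for a YYYY-MM label."""
    y, m = int(label[:4]), int(label[5:7])
    start = dt.date(y, m, 1)
    end = dt.date(y + 1, 1, 1) if m == 12 else dt.date(y, m + 1, 1)
    return start, end


def window_rainfall(
    rainfall: pd.DataFrame, start: dt.date, end_exclusive: dt.date
) -> float:
    """Rainfall (mm) over [start, end), pro-rating partial months by days.

    ``rainfall`` has columns ``month (YYYY-MM), rainfall_mm``; a month
    inside the window but absent from the table raises, naming the gap.
    Uniform within-month distribution is assumed.
    """
    available = dict(zip(rainfall["month"], rainfall["rainfall_mm"]))
    total = 0.0
    missing = []
    cursor = dt.date(start.year, start.month, 1)
    while cursor < end_exclusive:
        label = f"{cursor.year:04d}-{cursor.month:02d}"
        m_start, m_end = _month_bounds(label)
        overlap = (min(m_end, end_exclusive) - max(m_start, start)).days
        if overlap > 0:
            if label not in available or pd.isna(available[label]):
                missing.append(label)
            else:
                total += available[label] * overlap / (m_end - m_start).days
        cursor = m_end
    if missing:
        raise ValueError(f"rainfall coverage gap for month(s): {', '.join(missing)}")
    return total


def water_input(
    rainfall: pd.DataFrame, sowing_date: dt.date, maturity_date: dt.date
) -> float:
    """Total rainfall (mm) from 60 days before sowing through maturity."""
    return window_rainfall(
        rainfall,
        sowing_date - dt.timedelta(days=60),
        maturity_date + dt.timedelta(days=1),
    )


def critical_period_rainfall(rainfall: pd.DataFrame, maturity_date: dt.date) -> float:
    """Rainfall (mm) in the window from 3 months to 1 month before maturity."""
    mat = pd.Timestamp(maturity_date)
    start = (mat - pd.DateOffset(months=3)).date()
    end = (mat - pd.DateOffset(months=1)).date()
    return window_rainfall(rainfall, start, end)


def environment_summaries(dataset: FieldDataset) -> pd.DataFrame:
    """Per-environment water input, critical rainfall and mean yield."""
    rows = []
    for env, grp in dataset.trials.groupby("environment_id"):
        rain = dataset.environment_rainfall(env)
        sowing = dt.date.fromisoformat(str(grp["sowing_date"].iloc[0]))
        maturity = dt.date.fromisoformat(str(grp["maturity_date"].iloc[0]))
        rows.append((
            env,
            water_input(rain, sowing, maturity),
            critical_period_rainfall(rain, maturity),
            float(grp["yield_kg_ha"].mean()),
            grp["genotype"].nunique(),
        ))
    return pd.DataFrame(rows, columns=[
        "environment_id", "water_input", "critical_rainfall", "mean_yield", "n_genotypes",
    ])


# ---------------------------------------------------------------------------
# envelope fit


@dataclass
class EnvelopeFit:
    """Fitted boundary function yield = a(1 - exp(b(w - c))), b < 0.

    ``a`` is the attainable yield (kg ha^-1), ``b`` the (negative) initial
    factor-use efficiency parameter (mm^-1), ``c`` the minimum water input
    (mm) for any yield. ``trace`` records (asymmetry weight, on-or-below
    fraction) pairs from the bisection.
    """

    a: float
    b: float
    c: float
    fraction_below: float
    n: int
    trace: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, w: np.ndarray | float) -> np.ndarray | float:
        return self.a * (1.0 - np.exp(self.b * (np.asarray(w, dtype=float) - self.c)))


def _asymmetric_envelope_fit(
    w: np.ndarray, y: np.ndarray, lam: float, x0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Least squares with asymmetric weight ``lam`` on points above the curve.

    The above/below weight switch is blended with a narrow sigmoid (0.2% of
    the yield scale) so the objective stays smooth and a single bounded
    least-squares solve suffices.
    """
    scale = max(1.0, float(np.abs(y).max()))
    eps = 2e-3 * scale

    def resid(p: np.ndarray) -> np.ndarray:
        pred = p[0] * (1.0 - np.exp(-p[1] * (w - p[2])))
        r = y - pred
        above = 1.0 / (1.0 + np.exp(np.clip(-r / eps, -50.0, 50.0)))
        return np.sqrt(1.0 + (lam - 1.0) * above) * r

    sol = least_squares(resid, x0, bounds=bounds, method="trf")
    return sol.x


def fit_envelope(
    env_points: pd.DataFrame,
    target_fraction: float = 0.95,
    max_doublings: int = 30,
    bisection_steps: int = 40,
) -> EnvelopeFit:
    """Fit the yield-vs-water-input envelope with the below-curve rule.

    ``env_points`` needs columns ``water_input, mean_yield``. The
    above-curve loss weight starts at 1 (symmetric fit) and is doubled,
    then bisected, until the fraction of points on or below the curve is
    the smallest achievable fraction >= ``target_fraction``; points exactly
    on the curve count as below.
    """
    w = env_points["water_input"].to_numpy(float)
    y = env_points["mean_yield"].to_numpy(float)
    if len(w) < 10:
        raise ValueError("envelope fit needs >= 10 environments")
    if np.ptp(w) <= 0:
        raise ValueError("degenerate water-input range")

    span = np.ptp(w)
    # a point within 0.1% of the yield scale counts as exactly on the curve,
    # hence below (the asymmetric loss leaves touching points a hair above)
    tol = ON_CURVE_RTOL * max(1.0, np.abs(y).max())
    x0 = np.array([1.05 * y.max(), 2.0 / span, w.min() - 0.2 * span])
    # the exponent must decay appreciably over the observed range, otherwise
    # the "envelope" degenerates to an unbounded straight line
    lower = np.array([0.5 * y.max(), 0.3 / span, w.min() - 2.0 * span])
    upper = np.array([20.0 * y.max(), 100.0 / span, w.min() - 1e-9])
    bounds = (lower, upper)

    def fraction(params: np.ndarray) -> float:
        pred = params[0] * (1.0 - np.exp(-params[1] * (w - params[2])))
        return float(np.mean(y <= pred + tol))

    trace: list[tuple[float, float]] = []
    warm = {"x0": x0}

    def fit_at(lam: float) -> tuple[np.ndarray, float]:
        # continuation: each weight level starts from the previous solution
        params = _asymmetric_envelope_fit(w, y, lam, warm["x0"], bounds)
        warm["x0"] = params
        frac = fraction(params)
        trace.append((lam, frac))
        return params, frac

    lam_lo, (params, frac) = 1.0, fit_at(1.0)
    if frac >= target_fraction:
        a, bprime, c = params
        return EnvelopeFit(float(a), float(-bprime), float(c), frac, len(w), trace)

    lam_hi = 1.0
    params_hi, frac_hi = params, frac
    for _ in range(max_doublings):
        lam_hi *= 2.0
        params_hi, frac_hi = fit_at(lam_hi)
        if frac_hi >= target_fraction:
            break
        lam_lo = lam_hi
    else:
        raise RuntimeError(
            f"envelope fit did not reach the {target_fraction:.0%} below-curve "
            f"fraction after {max_doublings} weight doublings; trace: {trace}"
        )

    best_params, best_frac = params_hi, frac_hi
    for _ in range(bisection_steps):
        if lam_hi / lam_lo < 1.05:
            break
        lam_mid = 0.5 * (lam_lo + lam_hi)
        params_mid, frac_mid = fit_at(lam_mid)
        if frac_mid >= target_fraction:
            lam_hi, best_params, best_frac = lam_mid, params_mid, frac_mid
        else:
            lam_lo = lam_mid
    a, bprime, c = best_params
    return EnvelopeFit(float(a), float(-bprime), float(c), best_frac, len(w), trace)


def classify_environments(
    summaries: pd.DataFrame,
    fit: EnvelopeFit,
    band: float = 0.20,
    dry_mm: float = 175.0,
) -> pd.DataFrame:
    """Water-limited flag and dry/intermediate/wet class per environment.

    An environment is water-limited when its mean yield lies within the
    closed band [(1-band), (1+band)] x the envelope prediction. Among
    water-limited environments, critical-period rainfall below ``dry_mm``
    is dry and at least double ``dry_mm`` is wet; the rest are
    intermediate. Non-water-limited environments are excluded.
    """
    out = summaries.copy()
    pred = np.asarray(fit.predict(out["water_input"].to_numpy(float)), dtype=float)
    out["predicted_envelope_yield"] = pred
    my = out["mean_yield"].to_numpy(float)
    out["water_limited"] = (my >= (1.0 - band) * pred) & (my <= (1.0 + band) * pred)
    crit = out["critical_rainfall"].to_numpy(float)
    moisture = np.where(crit < dry_mm, "dry",
                        np.where(crit >= 2.0 * dry_mm, "wet", "intermediate"))
    out["moisture_class"] = np.where(out["water_limited"], moisture, "excluded")
    return out


# ---------------------------------------------------------------------------
# genotype tolerance


def yield_dsi(
    trials: pd.DataFrame, classes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype yield DSI between dry and wet water-limited environments.

    Dry environments stand in for the water-deficit treatment and wet ones
    for well-watered; genotype means over each set feed the shared DSI
    formula, with population means the unweighted means of genotype means.
    Genotypes lacking either class are excluded with a diagnostic.
    """
    class_map = classes.set_index("environment_id")["moisture_class"]
    df = trials.copy()
    df["moisture_class"] = df["environment_id"].map(class_map)
    diags: list[Diagnostic] = []
    rows = []
    for geno, grp in df.groupby("genotype"):
        dry = grp[grp["moisture_class"] == "dry"]["yield_kg_ha"]
        wet = grp[grp["moisture_class"] == "wet"]["yield_kg_ha"]
        if not len(dry) or not len(wet):
            diags.append(Diagnostic(None, "genotype",
                                    f"{geno!r} missing dry or wet environments; DSI absent"))
            continue
        rows.append((geno, float(dry.mean()), float(wet.mean()), len(dry), len(wet)))
    per_geno = pd.DataFrame(rows, columns=["genotype", "mean_yield_dry",
                                           "mean_yield_wet", "n_dry", "n_wet"])
    if len(per_geno):
        x_wd = float(per_geno["mean_yield_dry"].mean())
        x_ww = float(per_geno["mean_yield_wet"].mean())
        per_geno["dsi_yield"] = [
            dsi(r.mean_yield_wet, r.mean_yield_dry, x_ww, x_wd)
            for r in per_geno.itertuples(index=False)
        ]
    else:
        per_geno["dsi_yield"] = pd.Series(dtype=float)
    return per_geno, diagnostics_frame(diags)


def delta_y_slope(
    trials: pd.DataFrame, summaries: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS slope of yield deviation from the environment mean vs water input.

    Delta-Y = genotype yield - environment mean yield; the slope over
    environments (kg ha^-1 mm^-1) estimates sensitivity: positive =
    sensitive, negative = tolerant. Genotypes in fewer than 3 environments
    are reported absent with a diagnostic.
    """
    env = summaries.set_index("environment_id")
    df = trials.copy()
    df["env_mean"] = df["environment_id"].map(env["mean_yield"])
    df["w"] = df["environment_id"].map(env["water_input"])
    df["delta_y"] = df["yield_kg_ha"] - df["env_mean"]
    diags: list[Diagnostic] = []
    rows = []
    for geno, grp in df.dropna(subset=["w", "delta_y"]).groupby("genotype"):
        if len(grp) < 3 or grp["w"].nunique() < 2:
            diags.append(Diagnostic(None, "genotype",
                                    f"{geno!r} has < 3 usable environments; slope absent"))
            continue
        res = stats.linregress(grp["w"].to_numpy(float), grp["delta_y"].to_numpy(float))
        rows.append((geno, float(res.slope), float(res.pvalue), len(grp)))
    table = pd.DataFrame(rows, columns=["genotype", "delta_y_slope", "p_value", "n_environments"])
    return table, diagnostics_frame(diags)


def validate_trait(
    trait_values: pd.Series, tolerance: pd.Series
) -> tuple[float, float, float]:
    """Regress a field tolerance estimate on a platform trait across genotypes.

    Both series are indexed by genotype. Returns (r2, p, slope); a negative
    slope means higher trait values go with field drought tolerance.
    """
    joined = pd.concat({"trait": trait_values, "tol": tolerance},
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        return float("nan"), float("nan"), float("nan")
    x = joined["trait"].to_numpy(float)
    if np.ptp(x) == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(x, joined["tol"].to_numpy(float))
    return float(res.rvalue**2), float(res.pvalue), float(res.slope)
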
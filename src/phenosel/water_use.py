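"""Transpiration from daily pot weighings, and transpiration efficiency.

The platform weighs every pot daily (after irrigation by default). Pot
weight is soil water plus plant fresh mass, so the water balance reads

    T = (previous weight + irrigation - today's weight)
        - soil evaporation + plant fresh-weight gain

(the plant-weight correction adds back the weight the growing plant itself
contributed), with soil evaporation taken as the daily mean of plantless
control pots and the plant-weight term interpolated from weekly
fresh-weight calibration harvests. Negative balances (weighing noise)
clamp to zero by default; raw values are kept in an audit column.

Transpiration efficiency (TE, g kg^-1) is shoot dry mass per kilogram of
water transpired cumulatively from emergence — the framework's headline
early-screening trait.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import Diagnostic, PlatformDataset, diagnostics_frame
from .growth_traits import SDW_COEFFICIENTS, estimate_sdw

__all__ = [
    "daily_transpiration",
    "evaporation_estimate",
    "plant_weight_correction",
    "transpiration_efficiency",
    "transpiration_rate_per_area",
    "transpiration_series",
    "water_use_traits",
]


def daily_transpiration(
    prev_weight: float,
    today_weight: float,
    irrigation_added: float,
    evaporation: float,
    plant_weight_gain: float,
    clamp: bool = True,
) -> tuple[float, float]:
    """One day's transpiration (g) from the pot water balance.

    ``plant_weight_gain`` is the plant's fresh-mass increase over the day;
    it is added back because the pot's weight change includes it. Returns
    ``(transpiration, raw_balance)``; with ``clamp`` the first is floored
    at zero while the raw balance is preserved for audit.
    """
    if prev_weight <= 0 or today_weight <= 0:
        raise ValueError("pot weights must be > 0")
    if evaporation < 0:
        raise ValueError("evaporation must be >= 0")
    raw = (prev_weight + irrigation_added - today_weight) - evaporation + plant_weight_gain
    value = max(raw, 0.0) if clamp else raw
    return value, raw


def evaporation_estimate(
    controls: pd.DataFrame, days: Iterable[int]
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-day soil evaporation (g d^-1): mean over plantless control pots.

    ``controls`` has columns ``dae, evaporation`` (one row per pot per day).
    Days without any control carry the last available estimate forward and
    are flagged.
    """
    days = sorted(set(int(d) for d in days))
    per_day = controls.groupby("dae")["evaporation"].mean()
    diags: list[Diagnostic] = []
    values: dict[int, float] = {}
    last = None
    for d in days:
        if d in per_day.index:
            last = float(per_day.loc[d])
        elif last is not None:
            diags.append(Diagnostic(None, "evaporation",
                                    f"no control pots on dae {d}; reusing previous estimate"))
        else:
            diags.append(Diagnostic(None, "evaporation",
                                    f"no control pots on or before dae {d}; evaporation set to 0"))
            last = 0.0
        values[d] = last
    return pd.Series(values, name="evaporation"), diagnostics_frame(diags)


def plant_weight_correction(
    weekly_fresh_weights: pd.DataFrame, days: Iterable[int]
) -> tuple[pd.Series, pd.DataFrame]:
    """Daily plant fresh-weight gain (g d^-1) from weekly calibration harvests.

    ``weekly_fresh_weights`` has columns ``dae, fresh_weight``. Fresh weight
    is interpolated linearly between calibration days; the daily gain is the
    successive difference (zero outside the calibrated range). With fewer
    than two calibration points the correction is zero and flagged.
    """
    days = sorted(set(int(d) for d in days))
    cal = weekly_fresh_weights.dropna().sort_values("dae")
    if len(cal) < 2:
        diag = diagnostics_frame([
            Diagnostic(None, "fresh_weight",
                       "fewer than 2 fresh-weight calibration points; plant-weight correction is 0")
        ])
        return pd.Series(0.0, index=pd.Index(days, name="dae"), name="gain"), diag
    xs = cal["dae"].to_numpy(float)
    ys = cal["fresh_weight"].to_numpy(float)
    grid = np.array(days, dtype=float)
    w_today = np.interp(grid, xs, ys)
    w_prev = np.interp(grid - 1.0, xs, ys)
    gain = pd.Series(w_today - w_prev, index=pd.Index(days, name="dae"), name="gain")
    return gain, diagnostics_frame([])


def transpiration_efficiency(sdw: float, cumulative_transpiration: float) -> float:
    """TE (g kg^-1) = 1000 * shoot dry weight / cumulative transpired water."""
    if cumulative_transpiration <= 0:
        return float("nan")
    return 1000.0 * sdw / cumulative_transpiration


def transpiration_rate_per_area(
    transpiration: float, leaf_area: float, interval: float
) -> float:
    """Transpiration rate (mg m^-2 s^-1) from mass over a timed interval.

    ``transpiration`` in g over ``interval`` seconds, ``leaf_area`` in cm^2.
    """
    if interval <= 0:
        raise ValueError("interval must be > 0")
    if leaf_area <= 0:
        return float("nan")
    return transpiration * 1.0e7 / (leaf_area * interval)


def transpiration_series(
    dataset: PlatformDataset,
    *,
    fresh_weights: pd.DataFrame | None = None,
    clamp: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily and cumulative transpiration per plant from pot weighings.

    ``fresh_weights``, when given, carries the weekly calibration harvests
    as columns ``treatment, dae, fresh_weight`` (one correction series per
    treatment). Returns a tidy frame with columns ``plant_id, genotype,
    treatment, replicate, dae, transpiration, transpiration_raw,
    cumulative_transpiration`` plus a diagnostics frame (clamped days,
    evaporation fallbacks). The first observed day of each plant has no
    previous weight and therefore no daily value; it contributes zero to
    the cumulative sum.
    """
    plants = dataset.plants.dropna(subset=["pot_weight"]).copy()
    if not len(plants):
        empty = pd.DataFrame(columns=[
            "plant_id", "genotype", "treatment", "replicate", "dae",
            "transpiration", "transpiration_raw", "cumulative_transpiration",
        ])
        return empty, diagnostics_frame([])

    days = plants["dae"].unique()
    evap, diags_frames = evaporation_estimate(dataset.evaporation, days)
    all_diags = [diags_frames]

    gains: dict[str, pd.Series] = {}
    if fresh_weights is not None and len(fresh_weights):
        for trt, grp in fresh_weights.groupby("treatment"):
            g, d = plant_weight_correction(grp[["dae", "fresh_weight"]], days)
            gains[trt] = g
            all_diags.append(d)

    clamp_diags: list[Diagnostic] = []
    out_rows: list[pd.DataFrame] = []
    for pid, grp in plants.groupby("plant_id", sort=False):
        grp = grp.sort_values("dae")
        dae = grp["dae"].to_numpy(int)
        weight = grp["pot_weight"].to_numpy(float)
        irrigation = grp["irrigation_added"].fillna(0.0).to_numpy(float)
        trt = grp["treatment"].iloc[0]
        gain_series = gains.get(trt)

        raw = np.full(len(grp), np.nan)
        consecutive = np.diff(dae) == 1
        ev = evap.reindex(dae[1:]).to_numpy(float)
        gn = (gain_series.reindex(dae[1:]).fillna(0.0).to_numpy(float)
              if gain_series is not None else np.zeros(len(dae) - 1))
        raw[1:] = np.where(
            consecutive,
            (weight[:-1] + irrigation[1:] - weight[1:]) - ev + gn,
            np.nan,
        )
        value = np.where(np.isnan(raw), np.nan, np.maximum(raw, 0.0)) if clamp else raw
        n_clamped = int(np.nansum((raw < 0)))
        if clamp and n_clamped:
            clamp_diags.append(Diagnostic(
                None, "transpiration",
                f"plant {pid!r}: {n_clamped} negative daily balance(s) clamped to 0"))
        res = grp[["plant_id", "genotype", "treatment", "replicate", "dae"]].copy()
        res["transpiration"] = value
        res["transpiration_raw"] = raw
        res["cumulative_transpiration"] = np.nancumsum(np.nan_to_num(value))
        out_rows.append(res)

    all_diags.append(diagnostics_frame(clamp_diags))
    out = pd.concat(out_rows, ignore_index=True)
    return out, pd.concat(all_diags, ignore_index=True)


def window_sum(series: pd.DataFrame, plant_id: str, dae_from: int, dae_to: int) -> float:
    """Total transpiration (g) of one plant over [dae_from, dae_to]."""
    sub = series[(series["plant_id"] == plant_id)
                 & (series["dae"] >= dae_from) & (series["dae"] <= dae_to)]
    return float(sub["transpiration"].sum(skipna=True))


def water_use_traits(
    dataset: PlatformDataset,
    *,
    te_days: Sequence[int] | None = None,
    t_days: Sequence[int] | None = None,
    fresh_weights: pd.DataFrame | None = None,
    coefficients: Sequence[float] = SDW_COEFFICIENTS,
    clamp: bool = True,
) -> pd.DataFrame:
    """Water-use trait battery as tidy (trait, dae, treatment, genotype,
    replicate, value) observations.

    Emits daily "Transpiration (T)" (restricted to ``t_days`` when given —
    e.g. the experiment's scheduled observation moments), final-day "Total
    transpired water", "Transpired water during WS" (treatment onset to
    final day) and "TE" at ``te_days`` (default: every day with a leaf-area
    measurement), with shoot dry weight for TE taken from the leaf-area
    calibration.
    """
    series, _ = transpiration_series(dataset, fresh_weights=fresh_weights, clamp=clamp)
    if not len(series):
        return pd.DataFrame(columns=["trait", "dae", "treatment", "genotype", "replicate", "value"])
    obs: list[pd.DataFrame] = []

    daily = series.dropna(subset=["transpiration"])
    if t_days is not None:
        daily = daily[daily["dae"].isin(list(t_days))]
    daily = daily[["dae", "treatment", "genotype", "replicate", "transpiration"]].rename(
        columns={"transpiration": "value"})
    daily.insert(0, "trait", "Transpiration (T)")
    obs.append(daily)

    final = series.sort_values("dae").groupby("plant_id").tail(1)
    total = final[["dae", "treatment", "genotype", "replicate", "cumulative_transpiration"]]
    total = total.rename(columns={"cumulative_transpiration": "value"})
    total.insert(0, "trait", "Total transpired water")
    obs.append(total)

    onset = dataset.treatment_onset_dae
    if onset is not None:
        ws = (series[series["dae"] >= onset]
              .groupby(["plant_id", "treatment", "genotype", "replicate"], as_index=False)
              .agg(value=("transpiration", "sum"), dae=("dae", "max")))
        ws = ws[["dae", "treatment", "genotype", "replicate", "value"]]
        ws.insert(0, "trait", "Transpired water during WS")
        obs.append(ws)

    la = dataset.plants.dropna(subset=["leaf_area"])
    if te_days is not None:
        la = la[la["dae"].isin(list(te_days))]
    if len(la):
        te = la.merge(
            series[["plant_id", "dae", "cumulative_transpiration"]],
            on=["plant_id", "dae"], how="inner",
        )
        sdw = estimate_sdw(te["leaf_area"].to_numpy(float), te["dae"].to_numpy(float),
                           coefficients)
        cum = te["cumulative_transpiration"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(cum > 0, 1000.0 * sdw / cum, np.nan)
        t = te[["dae", "treatment", "genotype", "replicate"]].copy()
        t.insert(0, "trait", "TE")
        t["value"] = values
        obs.append(t)

    out = pd.concat(obs, ignore_index=True)
    out["dae"] = out["dae"].astype(int)
    out["replicate"] = out["replicate"].astype(int)
    return out.dropna(subset=["value"]).reset_index(drop=True)
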
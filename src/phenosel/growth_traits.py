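"""Classical growth-analysis and morphology traits from platform records.

Covers the non-destructive shoot-dry-weight calibration (an affine function
of leaf area and plant age), relative leaf-area expansion rate (RER), net
assimilation rate (NAR), leaf area ratio (LAR), specific leaf area (SLA),
mass-partitioning ratios at harvest and the leaf-to-air temperature
difference. Ratios with zero denominators propagate as missing values
(NaN), never as exceptions, so downstream regressions drop them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .core_data import HarvestRecord, PlatformDataset

__all__ = [
    "GrowthIndices",
    "estimate_sdw",
    "growth_indices_at_harvest",
    "leaf_air_temperature_difference",
    "leaf_area_from_leaflets",
    "net_assimilation_rate",
    "platform_growth_traits",
    "relative_expansion_rate",
]

#: default shoot-dry-weight calibration: SDW = c0 + c1*LA + c2*LA*age
SDW_COEFFICIENTS = (0.1, 0.00184, 0.0000926)


@dataclass(frozen=True)
class GrowthIndices:
    """Morphology and partitioning indices for one plant at harvest."""

    lmr: float
    smr: float
    lmr_b: float
    smr_b: float
    sla: float
    lar: float


def estimate_sdw(
    leaf_area: float | np.ndarray,
    plant_age: float | np.ndarray,
    coefficients: Sequence[float] = SDW_COEFFICIENTS,
) -> float | np.ndarray:
    """Shoot dry weight (g) from leaf area (cm^2) and plant age (days).

    The calibration is platform-specific; coefficients are overridable.
    Affine in leaf area at fixed age and nondecreasing in both arguments
    for nonnegative coefficients.
    """
    la = np.asarray(leaf_area, dtype=float)
    age = np.asarray(plant_age, dtype=float)
    if np.any(la < 0) or np.any(age < 0):
        raise ValueError("leaf_area and plant_age must be >= 0")
    c0, c1, c2 = coefficients
    out = c0 + c1 * la + c2 * la * age
    return float(out) if out.ndim == 0 else out


def leaf_area_from_leaflets(
    leaflets: Iterable[tuple[float, float]], k: float | None
) -> float:
    """Leaf area (cm^2) from terminal-leaflet (width, length) pairs.

    ``k`` is the width*length-to-area calibration factor; it has no
    universal value and must be supplied explicitly.
    """
    if k is None:
        raise ValueError(
            "leaflet area factor k is a required calibration input; "
            "set leaflet_k in the configuration"
        )
    if k <= 0:
        raise ValueError("k must be > 0")
    total = 0.0
    for width, length in leaflets:
        if width < 0 or length < 0:
            raise ValueError("leaflet dimensions must be >= 0")
        total += k * width * length
    return total


def relative_expansion_rate(la1: float, la2: float, t1: float, t2: float) -> float:
    """RER (d^-1): slope of ln(leaf area) over the interval [t1, t2]."""
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if la1 <= 0 or la2 <= 0:
        raise ValueError("leaf areas must be > 0")
    return (math.log(la2) - math.log(la1)) / (t2 - t1)


def net_assimilation_rate(
    sdw1: float,
    sdw2: float,
    la1: float,
    la2: float,
    t1: float,
    t2: float,
    formula: Literal["classical", "as_printed"] = "classical",
) -> float:
    """NAR (g cm^-2 d^-1): dry-mass gain per unit leaf area per day.

    The classical growth-analysis form multiplies the mass increment rate by
    the logarithmic-mean reciprocal of leaf area,
    ``(dSDW/dt) * (ln LA2 - ln LA1)/(LA2 - LA1)``, degenerating to
    ``(dSDW/dt)/LA`` when the areas are equal. The ``as_printed`` variant
    divides instead of multiplying; it is retained only for audits of
    sources that typeset the expression as a quotient (it is dimensionally
    inconsistent with g cm^-2 d^-1).
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if la1 <= 0 or la2 <= 0:
        raise ValueError("leaf areas must be > 0")
    rate = (sdw2 - sdw1) / (t2 - t1)
    if la2 == la1:
        log_mean_reciprocal = 1.0 / la1
    else:
        log_mean_reciprocal = (math.log(la2) - math.log(la1)) / (la2 - la1)
    if formula == "classical":
        return rate * log_mean_reciprocal
    if formula == "as_printed":
        return rate / log_mean_reciprocal
    raise ValueError(f"unknown NAR formula {formula!r}")


def growth_indices_at_harvest(harvest: HarvestRecord, leaf_area: float) -> GrowthIndices:
    """Partitioning ratios and leaf-area indices at destructive harvest.

    Shoot mass is the dataset convention leaf_dw + stem_dw (branch masses
    are subsets). Zero denominators yield NaN.
    """
    shoot = harvest.leaf_dw + harvest.stem_dw
    if shoot <= 0:
        nan = float("nan")
        return GrowthIndices(nan, nan, nan, nan, nan, nan)
    sla = leaf_area / harvest.leaf_dw if harvest.leaf_dw > 0 else float("nan")
    return GrowthIndices(
        lmr=harvest.leaf_dw / shoot,
        smr=harvest.stem_dw / shoot,
        lmr_b=harvest.leaf_dw_branches / shoot,
        smr_b=harvest.stem_dw_branches / shoot,
        sla=sla,
        lar=leaf_area / shoot,
    )


def leaf_air_temperature_difference(
    leaf_temps: Sequence[float], air_temp: float
) -> float:
    """Mean leaf temperature minus air temperature (degC); NaN if no leaves."""
    temps = [t for t in leaf_temps if t is not None and not math.isnan(t)]
    if not temps:
        return float("nan")
    return float(np.mean(temps)) - air_temp


# ---------------------------------------------------------------------------
# dataset-level trait extraction


def _interval_traits(group: pd.DataFrame, coefficients: Sequence[float]) -> pd.DataFrame:
    """Per-plant RER and NAR over consecutive leaf-area observations."""
    grp = group.dropna(subset=["leaf_area"]).sort_values("dae")
    rows = []
    for (d1, a1), (d2, a2) in zip(
        grp[["dae", "leaf_area"]].itertuples(index=False),
        grp[["dae", "leaf_area"]].iloc[1:].itertuples(index=False),
    ):
        if a1 <= 0 or a2 <= 0 or d2 <= d1:
            continue
        s1 = estimate_sdw(a1, d1, coefficients)
        s2 = estimate_sdw(a2, d2, coefficients)
        rows.append(("RER", d2, relative_expansion_rate(a1, a2, d1, d2)))
        rows.append(("NAR", d2, net_assimilation_rate(s1, s2, a1, a2, d1, d2)))
    return pd.DataFrame(rows, columns=["trait", "dae", "value"])


def platform_growth_traits(
    dataset: PlatformDataset,
    coefficients: Sequence[float] = SDW_COEFFICIENTS,
) -> pd.DataFrame:
    """Extract the morphology/growth trait battery as tidy observations.

    Returns one row per (trait, dae, treatment, genotype, replicate):
    leaf area and estimated shoot dry weight at every measured day, interval
    RER/NAR labelled by the interval's end day, leaf-to-air temperature
    difference where thermal data exist, and harvest-day LAR/SLA/LMR/SMR
    (with branch variants) where harvest records exist.
    """
    plants = dataset.plants
    obs: list[pd.DataFrame] = []

    la = plants.dropna(subset=["leaf_area"]).copy()
    if len(la):
        base = la[["dae", "treatment", "genotype", "replicate"]].copy()
        for trait, values in (
            ("Leaf area", la["leaf_area"].to_numpy(float)),
            ("Shoot dry weight",
             estimate_sdw(la["leaf_area"].to_numpy(float), la["dae"].to_numpy(float),
                          coefficients)),
        ):
            t = base.copy()
            t.insert(0, "trait", trait)
            t["value"] = values
            obs.append(t)

    thermal = plants.dropna(subset=["air_temp"]).copy()
    if len(thermal):
        leaf_mean = thermal[["leaf_temp", "leaf_temp2"]].mean(axis=1)
        ok = leaf_mean.notna()
        t = thermal.loc[ok, ["dae", "treatment", "genotype", "replicate"]].copy()
        t.insert(0, "trait", "Leaf-to-Air temperature difference")
        t["value"] = (leaf_mean[ok] - thermal.loc[ok, "air_temp"]).to_numpy(float)
        obs.append(t)
        t2 = thermal.loc[ok, ["dae", "treatment", "genotype", "replicate"]].copy()
        t2.insert(0, "trait", "Leaf temperature")
        t2["value"] = leaf_mean[ok].to_numpy(float)
        obs.append(t2)

    gs = plants.dropna(subset=["gs"]).copy()
    if len(gs):
        t = gs[["dae", "treatment", "genotype", "replicate"]].copy()
        t.insert(0, "trait", "Stomatal conductance (gs)")
        t["value"] = gs["gs"].to_numpy(float)
        obs.append(t)

    meta = plants[["plant_id", "treatment", "genotype", "replicate"]].drop_duplicates("plant_id")
    interval_rows = []
    for pid, grp in plants.groupby("plant_id", sort=False):
        it = _interval_traits(grp, coefficients)
        if len(it):
            it["plant_id"] = pid
            interval_rows.append(it)
    if interval_rows:
        intervals = pd.concat(interval_rows).merge(meta, on="plant_id")
        obs.append(intervals[["trait", "dae", "treatment", "genotype", "replicate", "value"]])

    if len(dataset.harvests):
        final_la = (
            plants.dropna(subset=["leaf_area"])
            .sort_values("dae")
            .groupby("plant_id")
            .tail(1)[["plant_id", "leaf_area"]]
        )
        hv = dataset.harvests.merge(final_la, on="plant_id", how="left").merge(meta, on="plant_id")
        harvest_rows = []
        for row in hv.itertuples(index=False):
            rec = HarvestRecord(
                plant_id=row.plant_id, dae=int(row.dae),
                leaf_dw=row.leaf_dw, stem_dw=row.stem_dw,
                leaf_dw_branches=row.leaf_dw_branches,
                stem_dw_branches=row.stem_dw_branches,
            )
            gi = growth_indices_at_harvest(rec, row.leaf_area if pd.notna(row.leaf_area) else 0.0)
            for trait, value in (
                ("Final shoot dry weight", rec.leaf_dw + rec.stem_dw),
                ("LMR", gi.lmr), ("SMR", gi.smr), ("LMR_b", gi.lmr_b),
                ("SMR_b", gi.smr_b), ("SLA", gi.sla), ("LAR", gi.lar),
            ):
                harvest_rows.append(
                    (trait, int(row.dae), row.treatment, row.genotype, row.replicate, value)
                )
        obs.append(pd.DataFrame(
            harvest_rows,
            columns=["trait", "dae", "treatment", "genotype", "replicate", "value"],
        ))

    if not obs:
        return pd.DataFrame(columns=["trait", "dae", "treatment", "genotype", "replicate", "value"])
    out = pd.concat(obs, ignore_index=True)
    out["dae"] = out["dae"].astype(int)
    out["replicate"] = out["replicate"].astype(int)
    return out
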
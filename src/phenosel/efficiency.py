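"""Four-criterion phenotyping-efficiency scoring and trait selection.

Every candidate is one trait x measurement moment (days after emergence,
DAE) x water treatment. Against a target trait (typically the drought
susceptibility index of final shoot dry weight) each candidate is scored
by:

1. **Significance** — the OLS regression of genotype trait means on the
   target across genotypes must have p <= alpha (default 0.05).
2. **Efficiency ratio** — R^2 divided by the relative phenotyping cost
   (candidate cost / target cost, in plant.day = replicates x DAE) must
   reach ``ratio_min`` (default 2): an indirect trait has to be markedly
   cheaper per unit of predictive power.
3. **Earliness** — survivors are ordered by ascending DAE (earlier is
   better for platform throughput); optionally a hard DAE ceiling.
4. **Repeatability** — w^2 >= ``w2_min`` (default 0.5) so genotype
   differences are actually detectable.

The final ranking of survivors is lexicographic: earliest DAE, then
highest w^2, then highest efficiency ratio. The full audit table keeps
every candidate with per-criterion flags (no silent drops).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AnalysisConfig

__all__ = [
    "build_efficiency_table",
    "efficiency_ratio",
    "phenotyping_cost",
    "select_traits",
    "trait_vs_target_regression",
]


def trait_vs_target_regression(
    trait_values: pd.Series, target_values: pd.Series
) -> tuple[float, float, float]:
    """OLS of genotype trait means on the target; returns (r2, p, slope).

    Both inputs are indexed by genotype; only genotypes present in both are
    used. Returns NaNs when fewer than 3 genotypes overlap or the trait has
    zero variance.
    """
    joined = pd.concat({"trait": trait_values, "target": target_values},
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        return float("nan"), float("nan"), float("nan")
    x = joined["target"].to_numpy(float)
    y = joined["trait"].to_numpy(float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue), float(res.slope)


def phenotyping_cost(n_replicates: float, dae: float) -> float:
    """Phenotyping cost proxy (plant.day): replicates x days to measurement."""
    if n_replicates < 1 or dae <= 0:
        raise ValueError("need n_replicates >= 1 and dae > 0")
    return n_replicates * dae


def efficiency_ratio(r2: float, cost_trait: float, cost_target: float) -> float:
    """R^2 over relative phenotyping cost (candidate cost / target cost)."""
    if cost_trait <= 0 or cost_target <= 0:
        raise ValueError("costs must be > 0")
    return r2 / (cost_trait / cost_target)


def build_efficiency_table(
    observations: pd.DataFrame,
    target_values: pd.Series,
    target_cost: float,
    w2_table: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Score every trait x DAE x treatment candidate against the target.

    ``observations`` is the tidy trait table; ``target_values`` the
    per-genotype target (e.g. DSI of final shoot dry weight);
    ``target_cost`` its plant.day cost. ``w2_table`` (from
    :func:`phenosel.tolerance_stats.repeatability_table`) supplies w^2 per
    (trait, dae). Candidates whose regression is infeasible (fewer than 3
    genotypes, zero variance) stay in the table with NaN statistics.
    """
    config = config or AnalysisConfig()
    w2_lookup = {}
    if w2_table is not None and len(w2_table):
        w2_lookup = {(r.trait, r.dae): r.w2 for r in w2_table.itertuples(index=False)}

    rows = []
    for (trait, dae, trt), grp in observations.groupby(["trait", "dae", "treatment"]):
        grp = grp.dropna(subset=["value"])
        means = grp.groupby("genotype")["value"].mean()
        n_reps = float(grp.groupby("genotype").size().mean()) if len(grp) else 0.0
        r2, p, slope = trait_vs_target_regression(means, target_values)
        cost = phenotyping_cost(max(n_reps, 1.0), dae)
        rel_cost = cost / target_cost
        ratio = r2 / rel_cost if np.isfinite(r2) else float("nan")
        rows.append((trait, int(dae), trt, len(means), n_reps,
                     r2, p, slope, cost, rel_cost, ratio,
                     w2_lookup.get((trait, dae), float("nan"))))
    return pd.DataFrame(rows, columns=[
        "trait", "dae", "treatment", "n_genotypes", "n_replicates",
        "r2", "p_value", "slope", "cost", "relative_cost", "ratio", "w2",
    ])


def select_traits(
    table: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Apply the four criteria and rank survivors.

    Returns the audit table (every input candidate exactly once) with
    boolean flags ``pass_significance, pass_ratio, pass_earliness,
    pass_repeatability``, a ``selected`` flag for candidates passing all
    four, and ``rank`` (1 = best) over the selected set ordered by
    (ascending DAE, descending w^2, descending ratio).
    """
    config = config or AnalysisConfig()
    config.validate()
    out = table.copy()
    out["pass_significance"] = (out["p_value"] <= config.alpha).fillna(False)
    out["pass_ratio"] = (out["ratio"] >= config.ratio_min).fillna(False)
    if config.earliness_strict_dae is not None:
        out["pass_earliness"] = out["dae"] <= config.earliness_strict_dae
    else:
        out["pass_earliness"] = True
    out["pass_repeatability"] = (out["w2"] >= config.w2_min).fillna(False)

    out["selected"] = (out["pass_significance"] & out["pass_ratio"]
                       & out["pass_earliness"] & out["pass_repeatability"])
    out["rank"] = pd.NA
    chosen = out[out["selected"]].sort_values(
        ["dae", "w2", "ratio"], ascending=[True, False, False]
    )
    out.loc[chosen.index, "rank"] = np.arange(1, len(chosen) + 1)
    return out.sort_values(["dae", "trait", "treatment"]).reset_index(drop=True)
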
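"""Drought susceptibility index and repeatability from variance components.

The drought susceptibility index (DSI) of a genotype for a trait is its
relative reduction under water deficit scaled by the population-average
relative reduction:

    DSI = (1 - Y_wd / Y_ww) / (1 - X_wd / X_ww)

where Y are the genotype's treatment means and X the unweighted means of
genotype means. DSI = 1 is average susceptibility, 0 an unaffected
genotype, negative a trait that increases under deficit.

Repeatability (w^2), the broad-sense fraction of variance among genotype
means that is genotypic, is computed from variance components:

    single environment:   w^2 = s2_g / (s2_g + s2_e / r)
    multi-environment:    w^2 = s2_g / (s2_g + s2_e/(r t) + s2_ge / t)

with r replicates per cell and t environments (here: soil-water
treatments). Balanced layouts use the closed-form expected-mean-squares
(EMS) estimators, which coincide with REML when nonnegative; unbalanced
layouts fall back to iterative REML (linear mixed model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core_data import Diagnostic, diagnostics_frame

__all__ = [
    "DsiRecord",
    "RepeatabilityResult",
    "VarianceComponents",
    "dsi",
    "dsi_table",
    "repeatability",
    "repeatability_table",
    "variance_components",
]


@dataclass(frozen=True)
class DsiRecord:
    genotype: str
    trait: str
    dae: int
    dsi: float
    y_ww: float
    y_wd: float
    x_ww: float
    x_wd: float


@dataclass(frozen=True)
class VarianceComponents:
    """Genotypic, residual and (optionally) G x E variance components."""

    sigma2_g: float
    sigma2_e: float
    sigma2_ge: float | None
    r: float
    t: int | None
    truncated: bool = False


@dataclass(frozen=True)
class RepeatabilityResult:
    w2: float
    components: VarianceComponents
    scope: str


def dsi(y_ww: float, y_wd: float, x_ww: float, x_wd: float) -> float:
    """Drought susceptibility index from genotype and population means."""
    if y_ww <= 0 or x_ww <= 0:
        raise ValueError("well-watered means must be > 0")
    denom = 1.0 - x_wd / x_ww
    if denom == 0:
        raise ValueError(
            "population unaffected by the deficit (X_wd == X_ww); DSI undefined"
        )
    return (1.0 - y_wd / y_ww) / denom


def dsi_table(
    observations: pd.DataFrame,
    trait: str,
    dae: int,
    ww_label: str = "WW",
    wd_label: str = "WD",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype DSI for one trait x moment.

    Genotype means are computed per treatment; the population means X are
    unweighted means of the genotype means (robust to unequal replication).
    Genotypes missing either treatment are excluded from the table and from
    the X means, with a diagnostic.
    """
    sub = observations[
        (observations["trait"] == trait)
        & (observations["dae"] == dae)
        & (observations["treatment"].isin([ww_label, wd_label]))
    ].dropna(subset=["value"])
    means = sub.groupby(["genotype", "treatment"])["value"].mean().unstack("treatment")

    diags: list[Diagnostic] = []
    for geno in means.index:
        if ww_label not in means.columns or pd.isna(means.loc[geno].get(ww_label)) \
                or wd_label not in means.columns or pd.isna(means.loc[geno].get(wd_label)):
            diags.append(Diagnostic(None, "genotype",
                                    f"{geno!r} lacks one treatment for {trait!r} at dae {dae}"))
    complete = means.dropna(subset=[c for c in (ww_label, wd_label) if c in means.columns]) \
        if {ww_label, wd_label} <= set(means.columns) else means.iloc[0:0]

    if not len(complete):
        empty = pd.DataFrame(columns=["genotype", "trait", "dae", "dsi",
                                      "y_ww", "y_wd", "x_ww", "x_wd"])
        return empty, diagnostics_frame(diags)

    x_ww = float(complete[ww_label].mean())
    x_wd = float(complete[wd_label].mean())
    rows = []
    for geno, row in complete.iterrows():
        try:
            value = dsi(row[ww_label], row[wd_label], x_ww, x_wd)
        except ValueError as exc:
            diags.append(Diagnostic(None, "dsi", f"{geno!r}: {exc}"))
            value = float("nan")
        rows.append((geno, trait, dae, value, row[ww_label], row[wd_label], x_ww, x_wd))
    table = pd.DataFrame(rows, columns=["genotype", "trait", "dae", "dsi",
                                        "y_ww", "y_wd", "x_ww", "x_wd"])
    return table, diagnostics_frame(diags)


# ---------------------------------------------------------------------------
# variance components


def _is_balanced(counts: pd.Series) -> bool:
    return counts.nunique() == 1


def _ems_one_way(df: pd.DataFrame) -> VarianceComponents:
    g = df["genotype"].nunique()
    r = int(df.groupby("genotype").size().iloc[0])
    grand = df["value"].mean()
    gmeans = df.groupby("genotype")["value"].mean()
    msg = r * ((gmeans - grand) ** 2).sum() / (g - 1)
    sse = ((df["value"] - df["genotype"].map(gmeans)) ** 2).sum()
    mse = sse / (g * (r - 1)) if r > 1 else 0.0
    sigma2_g = (msg - mse) / r
    truncated = sigma2_g < 0
    return VarianceComponents(max(sigma2_g, 0.0), float(mse), None, r, None, truncated)


def _ems_two_way(df: pd.DataFrame) -> VarianceComponents:
    g = df["genotype"].nunique()
    t = df["environment"].nunique()
    r = int(df.groupby(["genotype", "environment"]).size().iloc[0])
    grand = df["value"].mean()
    gmeans = df.groupby("genotype")["value"].mean()
    emeans = df.groupby("environment")["value"].mean()
    cmeans = df.groupby(["genotype", "environment"])["value"].mean()

    msg = r * t * ((gmeans - grand) ** 2).sum() / (g - 1)
    inter = cmeans.reset_index()
    inter["dev"] = (inter["value"] - inter["genotype"].map(gmeans)
                    - inter["environment"].map(emeans) + grand)
    msge = r * (inter["dev"] ** 2).sum() / ((g - 1) * (t - 1))
    cell = df.merge(cmeans.rename("cell_mean"), on=["genotype", "environment"])
    sse = ((cell["value"] - cell["cell_mean"]) ** 2).sum()
    mse = sse / (g * t * (r - 1)) if r > 1 else 0.0

    sigma2_ge = (msge - mse) / r
    sigma2_g = (msg - msge) / (r * t)
    truncated = sigma2_g < 0 or sigma2_ge < 0
    return VarianceComponents(max(sigma2_g, 0.0), float(mse),
                              max(sigma2_ge, 0.0), r, t, truncated)


def _reml_mixedlm(df: pd.DataFrame, model: str) -> VarianceComponents:
    import statsmodels.formula.api as smf

    r = float(df.groupby(
        ["genotype", "environment"] if model == "two_way" else "genotype"
    ).size().mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if model == "one_way":
            md = smf.mixedlm("value ~ 1", df, groups=df["genotype"])
            fit = md.fit(reml=True)
            sigma2_g = float(fit.cov_re.iloc[0, 0])
            return VarianceComponents(max(sigma2_g, 0.0), float(fit.scale),
                                      None, r, None, sigma2_g < 0)
        md = smf.mixedlm(
            "value ~ C(environment)", df, groups=df["genotype"],
            re_formula="1", vc_formula={"ge": "0 + C(environment)"},
        )
        fit = md.fit(reml=True)
        sigma2_g = float(fit.cov_re.iloc[0, 0])
        sigma2_ge = float(fit.vcomp[0])
        t = df["environment"].nunique()
        return VarianceComponents(max(sigma2_g, 0.0), float(fit.scale),
                                  max(sigma2_ge, 0.0), r, t,
                                  sigma2_g < 0 or sigma2_ge < 0)


def variance_components(
    observations: pd.DataFrame,
    model: Literal["one_way", "two_way"] = "one_way",
) -> VarianceComponents:
    """Estimate genotypic / residual (/ G x E) variance components.

    ``observations`` needs columns ``genotype, value`` and, for the two-way
    model, ``environment``. Balanced layouts use the ANOVA
    expected-mean-squares estimators (equal to REML whenever nonnegative);
    unbalanced layouts use restricted maximum likelihood. Negative
    estimates truncate to zero and are flagged.
    """
    df = observations.dropna(subset=["value"]).copy()
    if df["genotype"].nunique() < 2:
        raise ValueError("variance components need >= 2 genotypes")
    if model == "one_way":
        counts = df.groupby("genotype").size()
        if counts.min() < 2:
            raise ValueError("variance components need >= 2 replicates per genotype")
        return _ems_one_way(df) if _is_balanced(counts) else _reml_mixedlm(df, model)
    if model == "two_way":
        if "environment" not in df.columns or df["environment"].nunique() < 2:
            raise ValueError("two-way model needs >= 2 environments")
        counts = df.groupby(["genotype", "environment"]).size()
        full = df["genotype"].nunique() * df["environment"].nunique()
        if len(counts) < full:
            return _reml_mixedlm(df, model)
        return _ems_two_way(df) if _is_balanced(counts) else _reml_mixedlm(df, model)
    raise ValueError(f"unknown model {model!r}")


def repeatability(
    components: VarianceComponents,
    scope: Literal["single_env", "multi_env"] = "single_env",
) -> RepeatabilityResult:
    """w^2 of genotype means from variance components (NaN if all zero)."""
    c = components
    if scope == "single_env":
        denom = c.sigma2_g + c.sigma2_e / c.r
    elif scope == "multi_env":
        if c.sigma2_ge is None or c.t is None:
            raise ValueError("multi_env repeatability needs sigma2_ge and t")
        denom = c.sigma2_g + c.sigma2_e / (c.r * c.t) + c.sigma2_ge / c.t
    else:
        raise ValueError(f"unknown scope {scope!r}")
    w2 = c.sigma2_g / denom if denom > 0 else float("nan")
    return RepeatabilityResult(w2=w2, components=c, scope=scope)


def repeatability_table(
    observations: pd.DataFrame,
    treatment_onset_dae: int,
) -> pd.DataFrame:
    """Per (trait, dae) repeatability over the whole trait battery.

    Before treatment onset all plants share one environment, so the
    single-environment formula applies with every plant a replicate. From
    onset on, soil-water treatments are distinct environments and the
    multi-environment formula (with G x E) applies.
    """
    rows = []
    for (trait, dae), grp in observations.groupby(["trait", "dae"]):
        grp = grp.dropna(subset=["value"])
        try:
            if dae < treatment_onset_dae or grp["treatment"].nunique() < 2:
                comp = variance_components(grp, "one_way")
                res = repeatability(comp, "single_env")
            else:
                two = grp.rename(columns={"treatment": "environment"})
                comp = variance_components(two, "two_way")
                res = repeatability(comp, "multi_env")
        except ValueError:
            continue
        rows.append((trait, int(dae), res.scope, res.w2,
                     comp.sigma2_g, comp.sigma2_e,
                     comp.sigma2_ge if comp.sigma2_ge is not None else np.nan,
                     comp.r, comp.t if comp.t is not None else np.nan))
    return pd.DataFrame(rows, columns=[
        "trait", "dae", "scope", "w2",
        "sigma2_g", "sigma2_e", "sigma2_ge", "r", "t",
    ])
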
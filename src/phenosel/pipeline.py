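"""Stage orchestration: chaining platform traits, DSI, selection and the
field validation into reproducible runs."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .core_data import AnalysisConfig, PlatformDataset, FieldDataset, write_report
from .efficiency import build_efficiency_table, phenotyping_cost, select_traits
from .field_network import (
    classify_environments,
    delta_y_slope,
    environment_summaries,
    fit_envelope,
    validate_trait,
    yield_dsi,
)
from .growth_traits import platform_growth_traits
from .tolerance_stats import dsi_table, repeatability_table
from .water_use import water_use_traits

__all__ = [
    "RunManifest",
    "extract_traits",
    "run_field_analysis",
    "run_platform_analysis",
    "run_pipeline",
]

#: default selection target: drought susceptibility index of the
#: destructively harvested final shoot biomass
TARGET_TRAIT = "Final shoot dry weight"


@dataclass
class RunManifest:
    stages: list[str]
    outputs: list[str]
    config_hash: str
    seed: int
    version: str

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


def extract_traits(
    dataset: PlatformDataset,
    config: AnalysisConfig | None = None,
    fresh_weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full tidy trait battery (growth + water use) for one experiment."""
    config = config or AnalysisConfig()
    growth = platform_growth_traits(dataset, config.sdw_coefficients)
    # traits enter the selection battery at the experiment's scheduled
    # observation moments (the days leaf area was recorded); the full daily
    # transpiration series stays available via water_use.transpiration_series
    schedule = sorted(
        dataset.plants.dropna(subset=["leaf_area"])["dae"].astype(int).unique())
    water = water_use_traits(
        dataset,
        t_days=schedule or None,
        fresh_weights=fresh_weights,
        coefficients=config.sdw_coefficients,
        clamp=config.clamp_negative_transpiration,
    )
    return pd.concat([growth, water], ignore_index=True)


def run_platform_analysis(
    dataset: PlatformDataset,
    config: AnalysisConfig | None = None,
    fresh_weights: pd.DataFrame | None = None,
    target_trait: str = TARGET_TRAIT,
    target_dae: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Traits -> target DSI -> repeatability -> four-criterion selection.

    The target trait defaults to the drought susceptibility index of final
    shoot dry weight; its phenotyping cost counts the replicates of both
    water regimes (configurable) times the days to the final measurement.
    """
    config = config or AnalysisConfig()
    traits = extract_traits(dataset, config, fresh_weights)
    if target_trait == TARGET_TRAIT and target_trait not in set(traits["trait"]):
        target_trait = "Shoot dry weight"  # no harvest records: use the estimate
    if target_dae is None:
        target_dae = int(traits.loc[traits["trait"] == target_trait, "dae"].max())

    target, target_diags = dsi_table(traits, target_trait, target_dae)
    target_values = target.set_index("genotype")["dsi"]

    sub = traits[(traits["trait"] == target_trait) & (traits["dae"] == target_dae)]
    reps = float(sub.groupby(["genotype", "treatment"]).size().mean()) if len(sub) else 1.0
    n_treat = 2 if config.target_cost_both_treatments else 1
    target_cost = phenotyping_cost(max(reps, 1.0) * n_treat, target_dae)

    w2 = repeatability_table(traits, dataset.treatment_onset_dae or 10**6)
    audit = build_efficiency_table(traits, target_values, target_cost, w2, config)
    ranked = select_traits(audit, config)
    return {
        "traits": traits,
        "target_dsi": target,
        "target_diagnostics": target_diags,
        "repeatability": w2,
        "efficiency": ranked,
        "selection": ranked[ranked["selected"]].sort_values("rank"),
    }


def run_field_analysis(
    dataset: FieldDataset,
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Envelope fit -> environment classes -> genotype tolerance tables."""
    config = config or AnalysisConfig()
    summaries = environment_summaries(dataset)
    fit = fit_envelope(summaries.rename(columns={"mean_yield": "mean_yield"}))
    classes = classify_environments(summaries, fit, config.water_limited_band, config.dry_mm)
    dsi_tab, dsi_diags = yield_dsi(dataset.trials, classes)
    slope_tab, slope_diags = delta_y_slope(
        dataset.trials, classes[classes["water_limited"]])
    tolerance = dsi_tab.merge(slope_tab, on="genotype", how="outer")
    envelope = pd.DataFrame([{
        "a": fit.a, "b": fit.b, "c": fit.c,
        "fraction_below": fit.fraction_below, "n": fit.n,
    }])
    return {
        "environments": classes,
        "envelope": envelope,
        "tolerance": tolerance,
        "tolerance_diagnostics": pd.concat([dsi_diags, slope_diags], ignore_index=True),
    }


def run_validation(
    trait_values: pd.Series, tolerance: pd.DataFrame
) -> pd.DataFrame:
    """Regress both field tolerance estimates on a platform trait."""
    rows = []
    for col in ("dsi_yield", "delta_y_slope"):
        if col in tolerance.columns:
            r2, p, slope = validate_trait(
                trait_values, tolerance.set_index("genotype")[col])
            rows.append((col, r2, p, slope))
    return pd.DataFrame(rows, columns=["tolerance_estimate", "r2", "p_value", "slope"])


def run_pipeline(
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Full synthetic end-to-end chain, writing every stage's tables.

    Simulates a platform experiment and a field network from ``seed``, runs
    the platform selection and the field classification/validation, and
    writes a manifest whose re-run reproduces byte-identical data outputs.
    """
    from . import __version__
    from .synthetic_data import (
        FieldSimConfig, PlatformSimConfig,
        simulate_field_network, simulate_platform_experiment, truth_to_tables,
    )

    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed
    platform_cfg = PlatformSimConfig(seed=seed)
    field_cfg = FieldSimConfig(seed=seed + 1)

    dataset, truth = simulate_platform_experiment(platform_cfg)
    results = run_platform_analysis(dataset, config, truth.fresh_weights)

    field_ds, field_truth = simulate_field_network(field_cfg)
    field_results = run_field_analysis(field_ds, config)

    te13 = results["traits"]
    te13 = te13[(te13["trait"] == "TE") & (te13["dae"] == 13)]
    te_by_geno = te13.groupby("genotype")["value"].mean()
    # platform and field genotype panels are distinct breeding materials; the
    # validation uses the field panel's TE truth stand-ins
    field_te = field_truth.genotypes.set_index("genotype")["te"]
    validation = run_validation(field_te, field_results["tolerance"])

    tables = {
        **{k: v for k, v in results.items()},
        **{f"field_{k}": v for k, v in field_results.items()},
        "validation": validation,
        "platform_te13_by_genotype": te_by_geno.reset_index(),
        **truth_to_tables(truth),
        **{f"field_{k}": v for k, v in truth_to_tables(field_truth).items()},
    }
    paths = write_report(tables, out_dir, config=config.to_dict(), seed=seed)
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
    manifest = RunManifest(
        stages=["simulate", "traits", "dsi", "efficiency", "field-classify", "validate"],
        outputs=[str(p) for p in paths],
        config_hash=cfg_hash,
        seed=seed,
        version=__version__,
    )
    manifest.to_yaml(Path(out_dir) / "manifest.yaml")
    return manifest
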
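"""Shared data model, tidy-CSV I/O and configuration.

All pipeline stages exchange two kinds of tables:

* **Platform data** — longitudinal pot-level records from a greenhouse
  phenotyping platform (one row per plant per day after emergence), plus
  harvest records and daily soil-evaporation controls from plantless pots.
* **Field data** — a multi-environment trial network (one row per
  environment x genotype) with sowing/emergence/maturity dates and wide
  monthly-rainfall columns (``rain_YYYY-MM``).

Validation is total: every input row is either accepted or produces exactly
one diagnostic row, so ``accepted + rejected == input``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AnalysisConfig",
    "Diagnostic",
    "FieldDataset",
    "HarvestRecord",
    "PlatformDataset",
    "SchemaError",
    "IntegrityError",
    "diagnostics_frame",
    "read_field_csv",
    "read_platform_csv",
    "write_field_csv",
    "write_platform_csv",
    "write_report",
]

RAIN_PREFIX = "rain_"

#: canonical column order for the per-plant longitudinal table
PLANT_COLUMNS = [
    "plant_id", "genotype", "treatment", "replicate", "dae",
    "leaf_area", "pot_weight", "irrigation_added",
    "leaf_temp", "leaf_temp2", "air_temp", "gs", "vpd",
]
PLANT_MANDATORY = ["plant_id", "genotype", "treatment", "replicate", "dae"]

HARVEST_COLUMNS = [
    "plant_id", "dae", "leaf_dw", "stem_dw",
    "leaf_dw_branches", "stem_dw_branches", "n_nodes", "n_branches",
]

EVAPORATION_COLUMNS = ["dae", "pot_id", "evaporation"]

TRIAL_COLUMNS = [
    "environment_id", "genotype", "yield_kg_ha",
    "sowing_date", "emergence_date", "maturity_date",
]


class SchemaError(ValueError):
    """A mandatory column is absent (the message names it)."""


class IntegrityError(ValueError):
    """Conflicting duplicate records or broken cross-table references."""


@dataclass(frozen=True)
class Diagnostic:
    """One row-level validation message."""

    row: int | None
    field: str
    message: str


def diagnostics_frame(diags: Iterable[Diagnostic]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.row, d.field, d.message) for d in diags],
        columns=["row", "field", "message"],
    )


@dataclass(frozen=True)
class HarvestRecord:
    """Destructive-harvest masses and counts for one plant.

    Branch masses are subsets of the whole-plant leaf/stem masses.
    """

    plant_id: str
    dae: int
    leaf_dw: float
    stem_dw: float
    leaf_dw_branches: float = 0.0
    stem_dw_branches: float = 0.0
    n_nodes: int = 0
    n_branches: int = 0

    def __post_init__(self) -> None:
        for name in ("leaf_dw", "stem_dw", "leaf_dw_branches", "stem_dw_branches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.leaf_dw_branches > self.leaf_dw + 1e-12:
            raise ValueError("leaf_dw_branches exceeds leaf_dw")
        if self.stem_dw_branches > self.stem_dw + 1e-12:
            raise ValueError("stem_dw_branches exceeds stem_dw")


@dataclass
class PlatformDataset:
    """One platform experiment: longitudinal plant records, harvests and
    soil-evaporation controls.

    ``plants`` is a tidy frame with :data:`PLANT_COLUMNS` (optional
    measurements NaN when absent), ``harvests`` with
    :data:`HARVEST_COLUMNS` and ``evaporation`` with
    :data:`EVAPORATION_COLUMNS` (one row per control pot per day).
    """

    plants: pd.DataFrame
    harvests: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=HARVEST_COLUMNS))
    evaporation: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVAPORATION_COLUMNS))
    treatment_onset_dae: int | None = None
    experiment_id: str = "exp"

    def __post_init__(self) -> None:
        for col in PLANT_COLUMNS:
            if col not in self.plants.columns:
                self.plants[col] = np.nan
        self.plants = self.plants[PLANT_COLUMNS].reset_index(drop=True)
        harvested = set(self.harvests["plant_id"]) if len(self.harvests) else set()
        known = set(self.plants["plant_id"])
        orphans = harvested - known
        if orphans:
            raise IntegrityError(
                f"harvested plants absent from the longitudinal table: {sorted(orphans)}"
            )

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.plants["genotype"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.plants["treatment"].unique())

    def equals(self, other: "PlatformDataset") -> bool:
        def _eq(a: pd.DataFrame, b: pd.DataFrame) -> bool:
            a = a.reset_index(drop=True)
            b = b.reset_index(drop=True)
            if list(a.columns) != list(b.columns) or len(a) != len(b):
                return False
            for c in a.columns:
                x, y = a[c], b[c]
                if x.dtype.kind in "fc" or y.dtype.kind in "fc":
                    if not np.allclose(x.astype(float), y.astype(float),
                                       rtol=1e-12, atol=1e-12, equal_nan=True):
                        return False
                elif not (x.astype(str) == y.astype(str)).all():
                    return False
            return True

        return (
            _eq(self.plants, other.plants)
            and _eq(self.harvests, other.harvests)
            and _eq(self.evaporation, other.evaporation)
            and self.treatment_onset_dae == other.treatment_onset_dae
            and self.experiment_id == other.experiment_id
        )


@dataclass
class FieldDataset:
    """Trial-network yields plus monthly rainfall.

    ``trials`` has :data:`TRIAL_COLUMNS` (dates as ISO-8601 strings);
    ``rainfall`` is long, one row per environment per month with columns
    ``environment_id, month (YYYY-MM), rainfall_mm``.
    """

    trials: pd.DataFrame
    rainfall: pd.DataFrame
    flags: pd.DataFrame = field(default_factory=lambda: diagnostics_frame([]))

    def environments(self) -> list[str]:
        return sorted(self.trials["environment_id"].unique())

    def environment_rainfall(self, environment_id: str) -> pd.DataFrame:
        sub = self.rainfall[self.rainfall["environment_id"] == environment_id]
        return sub.sort_values("month").reset_index(drop=True)


# ---------------------------------------------------------------------------
# platform I/O


def _validate_plant_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[Diagnostic]]:
    diags: list[Diagnostic] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        if pd.isna(row["dae"]) or row["dae"] < 0:
            diags.append(Diagnostic(i, "dae", f"dae must be >= 0, got {row['dae']}"))
            keep[i] = False
        elif pd.notna(row.get("leaf_area")) and row["leaf_area"] < 0:
            diags.append(Diagnostic(i, "leaf_area", f"negative leaf area {row['leaf_area']}"))
            keep[i] = False
        elif pd.notna(row.get("pot_weight")) and row["pot_weight"] <= 0:
            diags.append(Diagnostic(i, "pot_weight", f"non-positive pot weight {row['pot_weight']}"))
            keep[i] = False
        elif pd.isna(row["replicate"]) or row["replicate"] < 1:
            diags.append(Diagnostic(i, "replicate", f"replicate must be >= 1, got {row['replicate']}"))
            keep[i] = False
    return df[keep].reset_index(drop=True), diags


def _check_duplicates(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["plant_id", "dae"], keep=False)
    if not dup.any():
        return
    value_cols = [c for c in PLANT_COLUMNS
                  if c not in ("plant_id", "dae") and c in df.columns]
    for (pid, dae), grp in df[dup].groupby(["plant_id", "dae"]):
        if grp[value_cols].round(12).astype(str).nunique().max() > 1:
            raise IntegrityError(
                f"conflicting duplicate records for plant {pid!r} at dae {dae}"
            )


def read_platform_csv(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    *,
    harvest_path: str | Path | None = None,
    evaporation_path: str | Path | None = None,
    treatment_onset_dae: int | None = None,
    experiment_id: str = "exp",
) -> tuple[PlatformDataset, pd.DataFrame]:
    """Read a tidy platform CSV into a validated :class:`PlatformDataset`.

    ``schema_config`` maps file column names to canonical names, so files
    produced elsewhere can be ingested without renaming. Returns the dataset
    together with a diagnostics frame listing every rejected row.
    """
    df = pd.read_csv(path)
    if schema_config:
        df = df.rename(columns=dict(schema_config))
    missing = [c for c in PLANT_MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory platform column(s) missing: {', '.join(missing)}")
    df, diags = _validate_plant_rows(df)
    _check_duplicates(df)

    harvests = (
        pd.read_csv(harvest_path) if harvest_path is not None
        else pd.DataFrame(columns=HARVEST_COLUMNS)
    )
    evaporation = (
        pd.read_csv(evaporation_path) if evaporation_path is not None
        else pd.DataFrame(columns=EVAPORATION_COLUMNS)
    )
    ds = PlatformDataset(
        plants=df,
        harvests=harvests,
        evaporation=evaporation,
        treatment_onset_dae=treatment_onset_dae,
        experiment_id=experiment_id,
    )
    return ds, diagnostics_frame(diags)


def write_platform_csv(
    dataset: PlatformDataset,
    path: str | Path,
    *,
    harvest_path: str | Path | None = None,
    evaporation_path: str | Path | None = None,
) -> list[Path]:
    paths = [Path(path)]
    dataset.plants.to_csv(path, index=False)
    if harvest_path is not None:
        dataset.harvests.to_csv(harvest_path, index=False)
        paths.append(Path(harvest_path))
    if evaporation_path is not None:
        dataset.evaporation.to_csv(evaporation_path, index=False)
        paths.append(Path(evaporation_path))
    return paths


# ---------------------------------------------------------------------------
# field I/O


def _parse_date(value: Any, row: int, col: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"row {row}: unparseable {col} {value!r}") from exc


def _month_range(start: dt.date, end: dt.date) -> list[str]:
    """Inclusive YYYY-MM labels for the months intersecting [start, end]."""
    months = []
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        months.append(f"{y:04d}-{m:02d}")
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return months


def read_field_csv(path: str | Path) -> tuple[FieldDataset, pd.DataFrame]:
    """Read a trial-network CSV (wide ``rain_YYYY-MM`` columns) and validate.

    Every environment's rainfall columns must cover the window from 60 days
    before sowing through physiological maturity; a gap raises naming the
    missing month. Environments carrying a single genotype are kept but
    flagged, since their environment mean is then a single cultivar's yield.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory field column(s) missing: {', '.join(missing)}")
    rain_cols = sorted(c for c in df.columns if c.startswith(RAIN_PREFIX))

    diags: list[Diagnostic] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        sowing = _parse_date(row["sowing_date"], i, "sowing_date")
        maturity = _parse_date(row["maturity_date"], i, "maturity_date")
        _parse_date(row["emergence_date"], i, "emergence_date")
        if row["yield_kg_ha"] < 0:
            diags.append(Diagnostic(i, "yield_kg_ha", f"negative yield {row['yield_kg_ha']}"))
            keep[i] = False
            continue
        if maturity <= sowing:
            diags.append(Diagnostic(i, "maturity_date", "maturity not after sowing"))
            keep[i] = False
            continue
        window = _month_range(sowing - dt.timedelta(days=60), maturity)
        for month in window:
            col = RAIN_PREFIX + month
            if col not in df.columns or pd.isna(row[col]):
                raise ValueError(
                    f"row {i} (environment {row['environment_id']!r}): rainfall "
                    f"missing for month {month} inside the 60 d-before-sowing"
                    "-to-maturity window"
                )
            if row[col] < 0:
                diags.append(Diagnostic(i, col, f"negative rainfall {row[col]}"))
                keep[i] = False
                break

    trials = df.loc[keep, TRIAL_COLUMNS].reset_index(drop=True)
    rain_long = (
        df.loc[keep, ["environment_id"] + rain_cols]
        .drop_duplicates(subset="environment_id")
        .melt(id_vars="environment_id", var_name="month", value_name="rainfall_mm")
        .dropna(subset=["rainfall_mm"])
    )
    rain_long["month"] = rain_long["month"].str.removeprefix(RAIN_PREFIX)
    rain_long = rain_long.sort_values(["environment_id", "month"]).reset_index(drop=True)

    flags = []
    for env, grp in trials.groupby("environment_id"):
        if grp["genotype"].nunique() == 1:
            flags.append(Diagnostic(None, "environment_id",
                                    f"environment {env!r} has a single genotype"))
    ds = FieldDataset(trials=trials, rainfall=rain_long, flags=diagnostics_frame(flags))
    return ds, diagnostics_frame(diags)


def write_field_csv(dataset: FieldDataset, path: str | Path) -> Path:
    wide_rain = dataset.rainfall.pivot(
        index="environment_id", columns="month", values="rainfall_mm"
    )
    wide_rain.columns = [RAIN_PREFIX + m for m in wide_rain.columns]
    out = dataset.trials.merge(wide_rain, left_on="environment_id", right_index=True, how="left")
    out.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# reporting


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write one CSV per named table plus a run-metadata YAML.

    Data CSVs are byte-deterministic for identical inputs; only the metadata
    file carries the timestamp.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    paths = []
    for name, table in tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
    meta = {
        "version": __version__,
        "seed": seed,
        "config": dict(config) if config else {},
        "written_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
        "tables": sorted(tables),
    }
    meta_path = out / "run_metadata.yaml"
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    paths.append(meta_path)
    return paths


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AnalysisConfig:
    """Thresholds and calibration constants for the whole pipeline.

    Defaults follow the framework's published operating points: per-trait
    significance screen at ``alpha``, efficiency-ratio floor ``ratio_min``,
    repeatability floor ``w2_min``, the 175 mm critical-period rainfall cut
    between dry and intermediate water-limited environments, and the +/-20%
    yield band around the envelope that defines "water-limited".
    """

    alpha: float = 0.05
    ratio_min: float = 2.0
    w2_min: float = 0.5
    dry_mm: float = 175.0
    water_limited_band: float = 0.20
    #: shoot-dry-weight calibration (intercept g, per-cm2, per-cm2-per-day)
    sdw_coefficients: tuple[float, float, float] = (0.1, 0.00184, 0.0000926)
    #: terminal-leaflet width*length to area factor; platform calibration,
    #: deliberately without a default
    leaflet_k: float | None = None
    bp_grid: float = 0.01
    clamp_negative_transpiration: bool = True
    weighing_after_irrigation: bool = True
    earliness_strict_dae: int | None = None
    target_cost_both_treatments: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.ratio_min <= 0:
            raise ValueError("ratio_min must be > 0")
        if not 0 <= self.w2_min <= 1:
            raise ValueError("w2_min must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "sdw_coefficients" in raw:
            raw["sdw_coefficients"] = tuple(raw["sdw_coefficients"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sdw_coefficients"] = list(self.sdw_coefficients)
        return d
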
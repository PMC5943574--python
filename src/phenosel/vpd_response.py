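"""Two-segment linear response of transpiration rate to vapor pressure deficit.

Above a breakpoint (BP) in evaporative demand, stomatal limitation bends the
TR-VPD relationship: the model is two independent straight lines,

    TR = I1 + S1 * VPD   for VPD < BP
    TR = I2 + S2 * VPD   for VPD >= BP

with no continuity constraint (both intercepts are free parameters). The BP
is found by grid search minimizing the pooled residual sum of squares of the
two per-side ordinary least-squares fits; the analysis workflow fits a free
BP per genotype, averages those into a common BP, then refits every plant
with the BP fixed at the common value and extracts the derived parameters
(slope ratio, TR at BP, TR at the maximum observed VPD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DerivedVpdParams",
    "SegmentedFit",
    "SegmentedFitError",
    "common_breakpoint",
    "derived_params",
    "fit_two_segment",
    "vpd_trait_battery",
]


class SegmentedFitError(ValueError):
    """Raised when a two-segment fit is infeasible (too few or collinear points)."""


@dataclass(frozen=True)
class SegmentedFit:
    """Parameters of a two-segment TR-VPD regression.

    Units: intercepts mg m^-2 s^-1, slopes mg m^-2 s^-1 kPa^-1, bp kPa.
    """

    i1: float
    s1: float
    i2: float
    s2: float
    bp: float
    sse: float
    n: int


@dataclass(frozen=True)
class DerivedVpdParams:
    """Slope ratio and TR evaluated at the breakpoint and at maximum VPD."""

    s2_s1_ratio: float
    tr_bp: float
    tr_maxvpd: float


def _side_ols(x: np.ndarray, y: np.ndarray, side: str) -> tuple[float, float, float]:
    """Least-squares line for one side; returns (intercept, slope, sse)."""
    if len(x) < 2 or np.unique(x).size < 2:
        raise SegmentedFitError(
            f"{side} side of the breakpoint needs >= 2 distinct VPD values"
        )
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return float(intercept), float(slope), float(resid @ resid)


def _fit_at_bp(vpd: np.ndarray, tr: np.ndarray, bp: float,
               continuity: bool = False) -> SegmentedFit:
    left = vpd < bp
    if not left.any() or left.all():
        raise SegmentedFitError("breakpoint outside the observed VPD range")
    if continuity:
        # TR = i1 + s1*vpd + (s2 - s1)*(vpd - bp)_+ : segments meet at bp
        if len(vpd) < 4 or np.unique(vpd[left]).size < 2 or np.unique(vpd[~left]).size < 2:
            raise SegmentedFitError("need >= 2 distinct VPD values per side")
        design = np.column_stack([np.ones_like(vpd), vpd, np.maximum(vpd - bp, 0.0)])
        beta, *_ = np.linalg.lstsq(design, tr, rcond=None)
        i1, s1, dslope = (float(b) for b in beta)
        resid = tr - design @ beta
        s2 = s1 + dslope
        return SegmentedFit(i1=i1, s1=s1, i2=i1 - dslope * bp, s2=s2,
                            bp=float(bp), sse=float(resid @ resid), n=len(vpd))
    i1, s1, sse1 = _side_ols(vpd[left], tr[left], "low-VPD")
    i2, s2, sse2 = _side_ols(vpd[~left], tr[~left], "high-VPD")
    return SegmentedFit(i1=i1, s1=s1, i2=i2, s2=s2, bp=float(bp),
                        sse=sse1 + sse2, n=len(vpd))


def fit_two_segment(
    tr: Sequence[float],
    vpd: Sequence[float],
    bp_fixed: float | None = None,
    bp_grid: float = 0.01,
    continuity: bool = False,
) -> SegmentedFit:
    """Fit the two-segment model, estimating the breakpoint unless fixed.

    With ``bp_fixed`` the two sides are fit independently by OLS at that
    breakpoint (both intercepts free — the default, matching a protocol
    that reports I1 and I2 as separate parameters). Otherwise candidate
    breakpoints on a ``bp_grid``-spaced grid inside the observed VPD range
    are scanned; only candidates leaving at least two distinct VPD values
    on each side are feasible, and ties in residual sum of squares break
    toward the smaller breakpoint. ``continuity`` switches to a variant
    constrained to meet at the breakpoint (for sensitivity audits).
    """
    vpd = np.asarray(vpd, dtype=float)
    tr = np.asarray(tr, dtype=float)
    ok = np.isfinite(vpd) & np.isfinite(tr)
    vpd, tr = vpd[ok], tr[ok]
    if len(vpd) < 4:
        raise SegmentedFitError("need >= 4 (vpd, tr) points for a two-segment fit")

    if bp_fixed is not None:
        return _fit_at_bp(vpd, tr, bp_fixed, continuity)

    uniq = np.unique(vpd)
    if uniq.size < 4:
        raise SegmentedFitError("need >= 4 distinct VPD values to estimate a breakpoint")
    # candidate must leave >= 2 distinct values strictly below and >= 2 at-or-above
    lo, hi = uniq[2], uniq[-2]
    if hi <= lo:
        raise SegmentedFitError("VPD range too narrow for the grid at this resolution")
    start = np.ceil(lo / bp_grid) * bp_grid
    candidates = np.arange(start, hi + 0.5 * bp_grid, bp_grid)
    candidates = candidates[(candidates > uniq[1]) & (candidates <= hi)]
    if candidates.size == 0:
        raise SegmentedFitError("no feasible breakpoint candidates on the grid")

    best: SegmentedFit | None = None
    for bp in candidates:
        try:
            fit = _fit_at_bp(vpd, tr, float(bp), continuity)
        except SegmentedFitError:
            continue
        if best is None or fit.sse < best.sse - 1e-12:
            best = fit
    if best is None:
        raise SegmentedFitError("no candidate breakpoint admitted >= 2 points per side")
    return best


def common_breakpoint(fits: Sequence[SegmentedFit]) -> tuple[float, float]:
    """Unweighted mean and sample standard deviation of per-genotype BPs.

    A single fit returns its BP with sd 0 (n=1).
    """
    if not fits:
        raise ValueError("need at least one fit")
    bps = np.array([f.bp for f in fits], dtype=float)
    if bps.size == 1:
        return float(bps[0]), 0.0
    return float(bps.mean()), float(bps.std(ddof=1))


def derived_params(fit: SegmentedFit, vpd_max: float) -> DerivedVpdParams:
    """Slope ratio and TR at the breakpoint / at the maximum observed VPD."""
    if vpd_max < fit.bp:
        raise ValueError("vpd_max must be >= the breakpoint")
    ratio = fit.s2 / fit.s1 if fit.s1 != 0 else float("nan")
    return DerivedVpdParams(
        s2_s1_ratio=ratio,
        tr_bp=fit.i1 + fit.s1 * fit.bp,
        tr_maxvpd=fit.i2 + fit.s2 * vpd_max,
    )


def vpd_trait_battery(
    observations: pd.DataFrame,
    dae: int,
    bp_grid: float = 0.01,
) -> tuple[pd.DataFrame, float, float]:
    """Per-plant segmented-fit traits with a common genotype-average breakpoint.

    ``observations`` needs columns ``genotype, replicate, treatment, vpd,
    tr``. Per-genotype free-breakpoint fits establish the common BP (mean
    over genotypes); every plant is then refit with the BP fixed there.
    Returns tidy trait rows labelled "Slope1", "Slope2", "Slope2:Slope1",
    "Intercept 1", "Intercept 2", "Transpiration rate at break Point" and
    "Transpiration rate at max VPD", plus the common BP mean and sd.
    """
    genotype_fits = [
        fit_two_segment(grp["tr"], grp["vpd"], bp_grid=bp_grid)
        for _, grp in observations.groupby("genotype")
    ]
    bp_mean, bp_sd = common_breakpoint(genotype_fits)
    vpd_max = float(observations["vpd"].max())

    rows = []
    for (geno, rep, trt), grp in observations.groupby(["genotype", "replicate", "treatment"]):
        try:
            fit = fit_two_segment(grp["tr"], grp["vpd"], bp_fixed=bp_mean)
        except SegmentedFitError:
            continue
        dv = derived_params(fit, vpd_max)
        for trait, value in (
            ("Slope1", fit.s1), ("Slope2", fit.s2), ("Slope2:Slope1", dv.s2_s1_ratio),
            ("Intercept 1", fit.i1), ("Intercept 2", fit.i2),
            ("Transpiration rate at break Point", dv.tr_bp),
            ("Transpiration rate at max VPD", dv.tr_maxvpd),
        ):
            rows.append((trait, dae, trt, geno, rep, value))
    table = pd.DataFrame(
        rows, columns=["trait", "dae", "treatment", "genotype", "replicate", "value"]
    )
    return table, bp_mean, bp_sd
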
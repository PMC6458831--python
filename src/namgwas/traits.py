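"""Derivation of growth and harvest traits from plant-level records.

The fourteen traits per cart are: SAsm (spline-smoothed shoot area at the
last imaging day, kPix), absolute growth rates AGR32/AGR42/AGR52 (kPix/d)
and relative growth rates RGR32/RGR42/RGR52 (1/d) over the intervals
32-40, 42-50 and 52-59 days after planting, the image-derived integrals
CHA and CL (consumed as precomputed columns), fresh and dry weight (g),
plant height (cm), tiller number, and water-use efficiency (g dry mass
per g irrigation water).

Smoothing is a penalised natural cubic smoothing spline with the penalty
chosen by generalised cross-validation by default; a fixed
effective-degrees-of-freedom target is available for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import pearsonr

from .phenosim import AGR_INTERVALS, RGR_INTERVALS

TRAIT_NAMES = [
    "SAsm", "AGR32", "AGR42", "AGR52", "RGR32", "RGR42", "RGR52",
    "CHA", "CL", "FW", "DW", "HEI", "TN", "WUE",
]


def _effective_df(days: np.ndarray, lam: float) -> float:
    """Trace of the smoother matrix at penalty ``lam`` (small n only)."""
    n = len(days)
    tr = 0.0
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        tr += float(make_smoothing_spline(days, e, lam=lam)(days[i]))
    return tr


def smooth_series(days, psa, lam: float | None = None, df: float | None = None):
    """Fit a penalised natural cubic smoothing spline to one PSA series.

    Parameters
    ----------
    days, psa
        Strictly increasing imaging days and the matching areas (>= 4
        finite points required).
    lam
        Fixed penalty; ``None`` selects it by generalised cross-validation.
    df
        Alternatively, a target effective degrees of freedom (2 < df <= n);
        the penalty is found by bisection on the smoother trace.

    Returns a callable (scipy BSpline) evaluable at any day in range.
    """
    days = np.asarray(days, dtype=float)
    psa = np.asarray(psa, dtype=float)
    if len(days) < 4:
        raise ValueError("need at least 4 observations to smooth")
    if not (np.all(np.diff(days) > 0)):
        raise ValueError("days must be strictly increasing")
    if not (np.isfinite(days).all() and np.isfinite(psa).all()):
        raise ValueError("non-finite input")
    if df is not None:
        if not 2 < df <= len(days):
            raise ValueError("df must be in (2, n]")
        lo, hi = 1e-8, 1e8
        for _ in range(80):
            mid = np.sqrt(lo * hi)
            if _effective_df(days, mid) > df:
                lo = mid
            else:
                hi = mid
        lam = np.sqrt(lo * hi)
    return make_smoothing_spline(days, psa, lam=lam)


def absolute_growth_rate(smoothed, d1: float, d2: float,
                         day_range=(32.0, 59.0)) -> float:
    """(S(d2) - S(d1)) / (d2 - d1), kPix per day."""
    if not (day_range[0] <= d1 < d2 <= day_range[1]):
        raise ValueError(f"interval ({d1}, {d2}) outside imaging range")
    return float(smoothed(d2) - smoothed(d1)) / (d2 - d1)


def relative_growth_rate(smoothed, d1: float, d2: float,
                         day_range=(32.0, 59.0)) -> float:
    """(ln S(d2) - ln S(d1)) / (d2 - d1); NaN where the area is not positive."""
    if not (day_range[0] <= d1 < d2 <= day_range[1]):
        raise ValueError(f"interval ({d1}, {d2}) outside imaging range")
    s1, s2 = float(smoothed(d1)), float(smoothed(d2))
    if s1 <= 0 or s2 <= 0:
        return float("nan")
    return (np.log(s2) - np.log(s1)) / (d2 - d1)


def water_use_efficiency(dw: float, total_water: float) -> float:
    """Dry biomass per gram of irrigation water (g/g)."""
    if total_water <= 0:
        raise ValueError("total water must be positive")
    return dw / total_water


def derive_trait_table(
    psa_long: pd.DataFrame,
    harvest: pd.DataFrame,
    lam: float | None = None,
    df: float | None = None,
    final_day: int = 59,
    year_scale: float = 1.0,
) -> pd.DataFrame:
    """Build the per-cart trait table from PSA series and harvest records.

    ``year_scale`` rescales the PSA pixel counts before smoothing (to
    reconcile camera resolutions across years). SAsm is the spline value
    at ``final_day``; when a series stops earlier, the last evaluable day
    is used and flagged in the ``sasm_day`` column.
    """
    harvest = harvest.set_index("cart_id")
    rows = []
    for cart, grp in psa_long.groupby("cart_id"):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=float)
        psa = grp["psa"].to_numpy(dtype=float) * year_scale
        spline = smooth_series(days, psa, lam=lam, df=df)
        eval_day = min(final_day, days.max())
        rng = (days.min(), days.max())
        rec = {"cart_id": cart, "SAsm": float(spline(eval_day)),
               "sasm_day": int(eval_day)}
        for name, (d1, d2) in AGR_INTERVALS.items():
            try:
                rec[name] = absolute_growth_rate(spline, d1, d2, rng)
            except ValueError:
                rec[name] = float("nan")
        for name, (d1, d2) in RGR_INTERVALS.items():
            try:
                rec[name] = relative_growth_rate(spline, d1, d2, rng)
            except ValueError:
                rec[name] = float("nan")
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("cart_id")

    carry = [c for c in ("genotype", "family", "treatment", "smarthouse", "zone",
                         "lane", "position", "column", "main_plot_id", "is_check",
                         "is_recurrent", "cMainPosn", "cLane", "zadoks", "year")
             if c in harvest.columns]
    out = harvest[carry].join(table, how="inner")
    for trait in ("FW", "DW", "HEI", "TN", "CHA", "CL"):
        if trait in harvest.columns:
            out[trait] = harvest[trait]
    if "DW" in harvest.columns and "water_g" in harvest.columns:
        out["water_g"] = harvest["water_g"]
        out["WUE"] = harvest["DW"] / harvest["water_g"]
    return out.reset_index()


def drought_response_ratios(blues: pd.DataFrame,
                            value_col: str = "blue") -> tuple[pd.Series, float]:
    """Per-genotype drought/control ratios and their correlation with control.

    ``blues`` needs columns ``genotype``, ``treatment`` and the value
    column. Genotypes with a zero or missing control value get a missing
    ratio. The correlation is Pearson's r of ratio against the control
    value; it is NaN (flagged) when either side has zero variance.
    """
    wide = blues.pivot_table(index="genotype", columns="treatment",
                             values=value_col, aggfunc="mean")
    if not {"control", "drought"} <= set(wide.columns):
        raise ValueError("need both control and drought values")
    control = wide["control"]
    ratio = wide["drought"] / control.where(control != 0)
    ok = ratio.notna() & control.notna()
    if ok.sum() < 3 or np.isclose(ratio[ok].std(), 0) or np.isclose(control[ok].std(), 0):
        return ratio, float("nan")
    r, _ = pearsonr(ratio[ok], control[ok])
    return ratio, float(r)
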
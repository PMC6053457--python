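"""Purification-table arithmetic, Michaelis-Menten estimation, relative activity.

A purification table tracks total protein (mg) and total activity (U) across
steps; specific activity is U/mg, yield the percent of the starting
activity retained, and purification fold the ratio of a step's specific
activity to the starting material's.  Km and Vmax come either from the
classical Lineweaver-Burk double-reciprocal line (1/v against 1/[S]:
Vmax = 1/intercept, Km = slope * Vmax) or from a direct nonlinear
least-squares fit of v = Vmax*S/(Km+S), which is less biased under noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PurificationStep",
    "KineticsFit",
    "purification_table",
    "fit_kinetics",
    "michaelis_menten",
    "relative_activity",
]


@dataclass(frozen=True)
class PurificationStep:
    name: str
    protein_mg: float
    activity_u: float
    specific_activity: float
    yield_pct: float
    fold: float


@dataclass
class KineticsFit:
    km: float  # mM
    vmax: float  # umol/min/mg
    method: str  # "lineweaver-burk" | "direct-nonlinear"
    slope: float | None = None  # LB line: slope = Km/Vmax
    intercept: float | None = None  # LB line: intercept = 1/Vmax
    valid: bool = True


def michaelis_menten(s, vmax: float, km: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def purification_table(steps, printed_mode: bool = False) -> pd.DataFrame:
    """Derive specific activity, yield and fold for a sequence of steps.

    ``steps`` is a list of (name, protein mg, total activity U) tuples or a
    DataFrame with columns step/protein_mg/activity_u; the first row is the
    reference (yield 100, fold 1).  With ``printed_mode`` the fold is
    computed from specific activities pre-truncated to 2 decimals — the
    display convention of hand-built published tables, whose folds are
    ratios of the printed (truncated) specific activities; the default keeps
    full precision throughout.
    """
    if isinstance(steps, pd.DataFrame):
        rows = list(steps[["step", "protein_mg", "activity_u"]].itertuples(index=False, name=None))
    else:
        rows = [tuple(r) for r in steps]
    if not rows:
        raise ValueError("no purification steps supplied")
    for name, protein, activity in rows:
        if protein <= 0 or activity <= 0:
            raise ValueError(f"step {name!r}: protein and activity must be positive")

    names = [r[0] for r in rows]
    protein = np.array([r[1] for r in rows], dtype=float)
    activity = np.array([r[2] for r in rows], dtype=float)
    specific = activity / protein
    yield_pct = 100.0 * activity / activity[0]
    if printed_mode:
        trunc = np.trunc(specific * 100.0) / 100.0
        fold = trunc / trunc[0]
    else:
        fold = specific / specific[0]
    return pd.DataFrame(
        {
            "step": names,
            "protein_mg": protein,
            "activity_u": activity,
            "specific_activity": specific,
            "yield_pct": yield_pct,
            "fold": fold,
        }
    )


def fit_kinetics(s, v, method: str = "lb") -> KineticsFit:
    """Estimate Km and Vmax from ([S], v0) pairs.

    method "lb": unweighted least-squares line on the double-reciprocal plot.
    method "direct": nonlinear least squares on v = Vmax*S/(Km+S),
    initialized from the LB estimate when available.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if s.shape != v.shape or s.ndim != 1:
        raise ValueError("substrate and velocity arrays must be 1-D and equal length")
    if len(s) < 3:
        raise ValueError("at least 3 points are required")
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")

    if method in ("lb", "lineweaver-burk"):
        if np.any(v <= 0):
            raise ValueError(
                "non-positive velocity cannot be reciprocal-transformed; use the direct method"
            )
        line = stats.linregress(1.0 / s, 1.0 / v)
        slope, intercept = float(line.slope), float(line.intercept)
        if intercept == 0:
            return KineticsFit(km=np.nan, vmax=np.nan, method="lineweaver-burk",
                               slope=slope, intercept=intercept, valid=False)
        vmax = 1.0 / intercept
        km = slope * vmax
        return KineticsFit(
            km=km, vmax=vmax, method="lineweaver-burk",
            slope=slope, intercept=intercept, valid=bool(km > 0 and vmax > 0),
        )

    if method in ("direct", "direct-nonlinear"):
        try:
            lb = fit_kinetics(s, v, method="lb")
            p0 = (lb.vmax, lb.km) if lb.valid else (float(np.max(v)), float(np.median(s)))
        except ValueError:
            p0 = (float(np.max(np.abs(v))), float(np.median(s)))
        popt, _ = optimize.curve_fit(michaelis_menten, s, v, p0=p0, maxfev=10_000)
        vmax, km = float(popt[0]), float(popt[1])
        return KineticsFit(
            km=km, vmax=vmax, method="direct-nonlinear", valid=bool(km > 0 and vmax > 0)
        )

    raise ValueError(f"unknown method {method!r}; expected 'lb' or 'direct'")


def relative_activity(measurements, control: str = "Control") -> pd.Series:
    """Percent activity of each condition relative to the control condition.

    ``measurements`` is a mapping or a list of (condition, activity) pairs;
    the control must be present with positive activity.
    """
    if isinstance(measurements, dict):
        items = list(measurements.items())
    else:
        items = [tuple(m) for m in measurements]
    values = dict(items)
    if control not in values:
        raise ValueError(f"control condition {control!r} not found")
    ref = float(values[control])
    if ref <= 0:
        raise ValueError("control activity must be positive")
    return pd.Series(
        {cond: 100.0 * float(act) / ref for cond, act in items}, name="relative_activity_pct"
    )
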
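"""Plackett-Burman screening statistics.

For a balanced two-level design the concentration effect of a factor is the
difference between the mean response at its high and low levels,

    E = (sum of responses at +1  -  sum of responses at -1) / (N/2),

the experimental-error variance is estimated from the effects of the dummy
(unassigned) columns, V_eff = mean(E_d^2), its square root is the standard
error of an effect, and each factor is tested with t = E / S.E. against a
Student t distribution.  The study this package reproduces reports one-tailed
p-values whose degrees of freedom correspond to n_runs - 2; both the tail
convention and the degrees of freedom are configurable, including the
textbook choice df = number of dummy columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignMatrix

__all__ = [
    "BalanceError",
    "ScreeningResult",
    "concentration_effect",
    "dummy_variance",
    "t_and_p",
    "pbd_report",
]


class BalanceError(ValueError):
    """A screening column does not have equal counts of high and low runs."""


@dataclass
class ScreeningResult:
    """Ranked per-factor screening statistics plus the shared error estimate.

    ``table`` is indexed by factor name with columns effect, t, p,
    significant and rank (1 = largest |t|).
    """

    table: pd.DataFrame
    v_eff: float
    se: float
    df: int
    tails: str
    alpha: float
    n_runs: int
    n_dummies: int
    dummy_effects: np.ndarray

    @property
    def significant_factors(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def ranked_factors(self) -> list[str]:
        return list(self.table.index)


def _check_design(design: DesignMatrix) -> np.ndarray:
    if design.response is None:
        raise ValueError("design has no response vector attached")
    return design.response


def _effect_from_column(col: np.ndarray, y: np.ndarray, name: str) -> float:
    hi = col > 0
    lo = col < 0
    if hi.sum() != lo.sum() or hi.sum() + lo.sum() != len(col):
        raise BalanceError(f"column {name!r} is not a balanced two-level column")
    n = len(col)
    return float((y[hi].sum() - y[lo].sum()) / (n / 2))


def concentration_effect(design: DesignMatrix, factor: str) -> float:
    """Difference of mean response between a factor's high and low levels."""
    y = _check_design(design)
    return _effect_from_column(design.column(factor), y, factor)


def dummy_variance(
    design: DesignMatrix, veff_override: float | None = None
) -> tuple[float, float, np.ndarray]:
    """Error variance of an effect from the dummy columns (or an override).

    Returns (V_eff, S.E., dummy effects).  With an override the printed
    variance is used verbatim and the dummy effects are still reported when
    dummy columns exist.
    """
    dummies = design.dummy_names
    if veff_override is None and not dummies:
        raise ValueError("design has no dummy columns; supply veff_override")
    y = design.response
    e_d = np.array(
        [_effect_from_column(design.column(d), y, d) for d in dummies]
        if (dummies and y is not None)
        else []
    )
    if veff_override is not None:
        v_eff = float(veff_override)
    else:
        if y is None:
            raise ValueError("design has no response vector attached")
        v_eff = float(np.mean(e_d**2))
    return v_eff, float(np.sqrt(v_eff)), e_d


def t_and_p(
    effects: np.ndarray, se: float, df: int, tails: str = "one"
) -> tuple[np.ndarray, np.ndarray]:
    """Student t statistics and p-values for effects with a common S.E."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    effects = np.asarray(effects, dtype=float)
    if se == 0:
        warnings.warn("standard error is zero; t statistics are infinite", stacklevel=2)
        with np.errstate(invalid="ignore"):
            t = np.sign(effects) * np.inf
        t[effects == 0] = 0.0
        p = np.where(effects == 0, 0.5 if tails == "one" else 1.0, 0.0)
        return t, p
    if se < 0:
        raise ValueError("standard error must be non-negative")
    t = effects / se
    p = stats.t.sf(np.abs(t), df)
    if tails == "two":
        p = 2 * p
    return t, np.minimum(p, 1.0)


def pbd_report(
    design: DesignMatrix,
    veff_override: float | None = None,
    tails: str = "one",
    df: int | str | None = None,
    alpha: float = 0.10,
) -> ScreeningResult:
    """Full screening analysis: effects, error estimate, t/p, ranking.

    df defaults to n_runs - 2 (the convention that reproduces the study's
    printed p-values); pass an int, or "dummy" for df = number of dummy
    columns.  alpha is the significance threshold on the p-value (default
    0.10, i.e. a 90% confidence rule).
    """
    y = _check_design(design)
    names = [f.name for f in design.assigned]
    effects = np.array([_effect_from_column(design.column(n), y, n) for n in names])
    v_eff, se, e_d = dummy_variance(design, veff_override)

    if df is None:
        df_val = design.n_runs - 2
    elif df == "dummy":
        if not design.dummy_names:
            raise ValueError("df='dummy' requires dummy columns in the design")
        df_val = len(design.dummy_names)
    else:
        df_val = int(df)

    t, p = t_and_p(effects, se, df_val, tails)
    table = pd.DataFrame(
        {"effect": effects, "t": t, "p": p, "significant": p < alpha},
        index=pd.Index(names, name="factor"),
    )
    # rank by |t|, ties broken by input factor order (stable sort)
    order = np.argsort(-np.abs(t), kind="stable")
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return ScreeningResult(
        table=table,
        v_eff=v_eff,
        se=se,
        df=df_val,
        tails=tails,
        alpha=alpha,
        n_runs=design.n_runs,
        n_dummies=len(design.dummy_names),
        dummy_effects=e_d,
    )
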
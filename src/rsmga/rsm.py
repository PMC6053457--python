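"""Second-order response-surface model: fit, ANOVA, prediction, slices.

The response y over k factors is modelled by the full quadratic polynomial

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j

fit by ordinary least squares (statsmodels behind the scenes).  The model
carries a unit-system tag: the study's published coefficients are in natural
concentration units (g/100 ml); refitting the same data in coded units
changes the coefficients but not the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .designs import DesignMatrix

__all__ = [
    "SingularDesignError",
    "QuadraticModel",
    "AnovaTable",
    "QuadraticFit",
    "expand_quadratic",
    "quadratic_column_names",
    "fit_quadratic",
    "predict",
    "surface_slice",
]

RANK_TOL = 1e-10  # smallest-to-largest singular value ratio


class SingularDesignError(ValueError):
    """The quadratic model matrix is rank deficient."""


def quadratic_column_names(names: list[str]) -> list[str]:
    """Column labels in expansion order: 1, linear, squares, pairs (i<j)."""
    k = len(names)
    cols = ["Intercept"]
    cols += list(names)
    cols += [f"{n}^2" for n in names]
    cols += [f"{names[i]}*{names[j]}" for i in range(k) for j in range(i + 1, k)]
    return cols


def expand_quadratic(points: np.ndarray, names: list[str] | None = None):
    """Quadratic model matrix for points (n, k).

    Columns are ordered [1, x1..xk, x1^2..xk^2, xi*xj for i<j (row-major)].
    Returns (matrix, column names).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, k = pts.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(k)]
    cols = [np.ones(n)]
    cols += [pts[:, i] for i in range(k)]
    cols += [pts[:, i] ** 2 for i in range(k)]
    cols += [pts[:, i] * pts[:, j] for i in range(k) for j in range(i + 1, k)]
    return np.column_stack(cols), quadratic_column_names(list(names))


@dataclass
class QuadraticModel:
    """Coefficients of a full second-order polynomial in k factors.

    ``coef`` is in expansion order (1 + 2k + k(k-1)/2 entries).  ``se``,
    ``tvalues`` and ``pvalues`` are per-coefficient statistics when the model
    comes from a fit; they are None for externally supplied coefficients.
    """

    names: tuple[str, ...]
    coef: np.ndarray
    units: str = "natural"
    se: np.ndarray | None = None
    tvalues: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    cov: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        k = len(self.names)
        expected = 1 + 2 * k + k * (k - 1) // 2
        if self.coef.shape != (expected,):
            raise ValueError(f"expected {expected} coefficients for {k} factors, got {self.coef.shape}")

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def linear(self) -> np.ndarray:
        return self.coef[1 : 1 + self.k]

    @property
    def quadratic(self) -> np.ndarray:
        return self.coef[1 + self.k : 1 + 2 * self.k]

    @property
    def interactions(self) -> dict[tuple[int, int], float]:
        k = self.k
        out = {}
        idx = 1 + 2 * k
        for i in range(k):
            for j in range(i + 1, k):
                out[(i, j)] = float(self.coef[idx])
                idx += 1
        return out

    def hessian(self) -> np.ndarray:
        """Symmetric Hessian of the polynomial: H_ii = 2 b_ii, H_ij = b_ij."""
        k = self.k
        h = np.diag(2.0 * self.quadratic)
        for (i, j), b in self.interactions.items():
            h[i, j] = h[j, i] = b
        return h

    def predict(self, points) -> np.ndarray | float:
        pts = np.asarray(points, dtype=float)
        scalar = pts.ndim == 1
        x, _ = expand_quadratic(np.atleast_2d(pts), list(self.names))
        y = x @ self.coef
        return float(y[0]) if scalar else y

    @classmethod
    def from_parts(
        cls,
        names: list[str],
        intercept: float,
        linear,
        quadratic,
        interactions: dict,
        units: str = "natural",
        **kw,
    ) -> "QuadraticModel":
        """Assemble from separate pieces; interaction keys may be index pairs
        or name pairs."""
        k = len(names)
        coef = [intercept] + list(linear) + list(quadratic)
        pairs = {}
        for key, v in interactions.items():
            a, b = key
            if isinstance(a, str):
                a, b = names.index(a), names.index(b)
            pairs[tuple(sorted((a, b)))] = float(v)
        for i in range(k):
            for j in range(i + 1, k):
                coef.append(pairs.get((i, j), 0.0))
        return cls(names=tuple(names), coef=np.array(coef, dtype=float), units=units, **kw)

    def to_dict(self) -> dict:
        d = {
            "names": list(self.names),
            "coef": self.coef.tolist(),
            "units": self.units,
            "columns": quadratic_column_names(list(self.names)),
        }
        if self.se is not None:
            d["se"] = np.asarray(self.se).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        return cls(
            names=tuple(d["names"]),
            coef=np.array(d["coef"], dtype=float),
            units=d.get("units", "natural"),
            se=np.array(d["se"], dtype=float) if "se" in d else None,
        )


@dataclass
class AnovaTable:
    """Regression / residual / total decomposition with F test and R^2."""

    ss_regression: float
    ss_residual: float
    ss_total: float
    df_regression: int
    df_residual: int
    ms_regression: float
    ms_residual: float
    f_statistic: float
    p_value: float
    r_squared: float
    r: float

    @classmethod
    def from_sums_of_squares(
        cls, ss_regression: float, df_regression: int, ss_residual: float, df_residual: int
    ) -> "AnovaTable":
        """Recompute MS, F, p, R^2 from given sums of squares and df.

        This is the arithmetic mode used to reproduce a published ANOVA table
        from its printed SS/df entries, whatever model they came from.
        """
        ss_total = ss_regression + ss_residual
        ms_reg = ss_regression / df_regression
        ms_res = ss_residual / df_residual
        if ms_res > 0:
            f = ms_reg / ms_res
            p = float(stats.f.sf(f, df_regression, df_residual))
        else:
            f, p = np.inf, 0.0
        r2 = 1.0 - ss_residual / ss_total if ss_total > 0 else 0.0
        return cls(
            ss_regression=ss_regression,
            ss_residual=ss_residual,
            ss_total=ss_total,
            df_regression=df_regression,
            df_residual=df_residual,
            ms_regression=ms_reg,
            ms_residual=ms_res,
            f_statistic=float(f),
            p_value=float(p),
            r_squared=float(r2),
            r=float(np.sqrt(max(r2, 0.0))),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sum_sq": [self.ss_regression, self.ss_residual, self.ss_total],
                "df": [self.df_regression, self.df_residual, self.df_regression + self.df_residual],
                "mean_sq": [self.ms_regression, self.ms_residual, np.nan],
                "F": [self.f_statistic, np.nan, np.nan],
                "p": [self.p_value, np.nan, np.nan],
            },
            index=["regression", "residual", "total"],
        )


class QuadraticFit(NamedTuple):
    model: QuadraticModel
    anova: AnovaTable
    predictions: pd.DataFrame


def _points_and_names(design, units: str):
    if isinstance(design, DesignMatrix):
        names = [f.name for f in design.factors]
        pts = design.natural if units == "natural" else design.coded
        return np.asarray(pts, dtype=float), names
    pts = np.atleast_2d(np.asarray(design, dtype=float))
    return pts, [f"x{i + 1}" for i in range(pts.shape[1])]


def fit_quadratic(design, response=None, units: str = "natural", names=None) -> QuadraticFit:
    """Ordinary least-squares fit of the full quadratic model.

    ``design`` is a DesignMatrix (response taken from it unless given) or a
    plain (n, k) point array.  Raises SingularDesignError, naming the
    offending columns, when the model matrix is rank deficient.
    """
    pts, auto_names = _points_and_names(design, units)
    if names is None:
        names = auto_names
    if response is None and isinstance(design, DesignMatrix):
        response = design.response
    if response is None:
        raise ValueError("no response vector supplied")
    y = np.asarray(response, dtype=float)

    x, cols = expand_quadratic(pts, names)
    n, p = x.shape
    if n < p:
        raise SingularDesignError(f"{n} runs cannot identify {p} coefficients")
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[-1] / sv[0] < RANK_TOL:
        _, _, vt = np.linalg.svd(x)
        null = np.abs(vt[-1])
        bad = [cols[i] for i in np.argsort(-null)[:3]]
        raise SingularDesignError(f"model matrix is rank deficient; collinear columns include {bad}")

    res = sm.OLS(y, x).fit()
    coef = np.asarray(res.params, dtype=float)

    yhat = x @ coef
    resid = y - yhat
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_reg = ss_tot - ss_res
    df_reg, df_res = p - 1, n - p
    if ss_tot <= 1e-14 * max(1.0, float(y @ y)):
        # constant response: decomposition degenerates, R^2 = 0 by convention
        anova = AnovaTable(0.0, 0.0, 0.0, df_reg, df_res, 0.0, 0.0, np.nan, np.nan, 0.0, 0.0)
    else:
        anova = AnovaTable.from_sums_of_squares(max(ss_reg, 0.0), df_reg, ss_res, df_res)

    model = QuadraticModel(
        names=tuple(names),
        coef=coef,
        units=units,
        se=np.asarray(res.bse, dtype=float),
        tvalues=np.asarray(res.tvalues, dtype=float),
        pvalues=np.asarray(res.pvalues, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
    )
    predictions = pd.DataFrame(pts, columns=list(names))
    predictions["observed"] = y
    predictions["predicted"] = yhat
    predictions["residual"] = y - yhat
    return QuadraticFit(model=model, anova=anova, predictions=predictions)


def predict(model: QuadraticModel, point, units: str | None = None):
    """Evaluate the polynomial at one or more points.

    ``units`` is an optional guard: when given it must match the model's
    unit system, preventing a coded point from being pushed through a
    natural-unit model.
    """
    if units is not None and units != model.units:
        raise ValueError(f"point is in {units!r} units but model is in {model.units!r} units")
    return model.predict(point)


def surface_slice(
    model: QuadraticModel,
    factor_pair: tuple,
    grid: tuple,
    fixed: dict | None = None,
    n: int = 50,
) -> pd.DataFrame:
    """Predicted response over a 2-factor rectangular grid, other factors held
    at fixed values.

    factor_pair gives two distinct factor names or indices; grid is
    ((lo_i, hi_i), (lo_j, hi_j)); fixed maps the remaining factors to the
    values they are held at (required unless k == 2).  Returns a long-format
    frame with columns (xi, xj, predicted), suitable for contour plotting.
    """
    names = list(model.names)
    i, j = (names.index(f) if isinstance(f, str) else int(f) for f in factor_pair)
    if i == j:
        raise ValueError("factor pair must name two distinct factors")
    fixed = dict(fixed or {})
    others = [m for m in range(model.k) if m not in (i, j)]
    base = np.zeros(model.k)
    for m in others:
        key = names[m]
        if key in fixed:
            base[m] = fixed[key]
        elif m in fixed:
            base[m] = fixed[m]
        else:
            raise ValueError(f"no fixed value supplied for factor {key!r}")

    (lo_i, hi_i), (lo_j, hi_j) = grid
    gi = np.linspace(lo_i, hi_i, n)
    gj = np.linspace(lo_j, hi_j, n)
    xi, xj = np.meshgrid(gi, gj, indexing="ij")
    pts = np.tile(base, (xi.size, 1))
    pts[:, i] = xi.ravel()
    pts[:, j] = xj.ravel()
    return pd.DataFrame(
        {names[i]: pts[:, i], names[j]: pts[:, j], "predicted": model.predict(pts)}
    )
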
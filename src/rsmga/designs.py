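"""Two-level Plackett-Burman and five-level central composite designs.

Factors are fermentation-medium components measured in g/100 ml; responses
are enzyme activities in U/ml.  A design carries both a *coded* matrix
(levels on a symmetric scale: ±1 for two-level screening, −α…+α for a CCD)
and the *natural* concentration matrix, related per factor by the affine map

    natural = center + coded * step

where for a screening factor center = (low + high)/2 and step = (high − low)/2,
so that coded −1/+1 map onto the low/high concentrations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "DesignError",
    "PB12_GENERATOR",
    "TABLE1_COLUMN_ASSIGNMENT",
    "build_pbd_design",
    "build_ccd_design",
    "code_point",
    "decode_point",
    "classify_point_types",
]


class DesignError(ValueError):
    """Invalid or unsupported experimental design."""


#: First row of the standard cyclic 12-run Plackett-Burman construction.
#: Rows 1..11 are cyclic rotations of this generator; row 12 is all −1.
PB12_GENERATOR = (+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1)

#: Assignment of the seven screened medium components (in their conventional
#: order: yeast extract, malt extract, dextrose, calcium carbonate, starch,
#: ammonium carbonate, sodium carbonate) to columns of the cyclic 12-run
#: construction that reproduces the published screening design as a row set.
#: Found by exhaustive backtracking over column injections; the four
#: remaining columns act as dummy (error-estimating) columns.
TABLE1_COLUMN_ASSIGNMENT = (0, 1, 2, 7, 4, 10, 3)


@dataclass(frozen=True)
class FactorSpec:
    """A named medium component with its level definition.

    role is "screening" (two-level, low/high), "ccd" (center/step per coded
    unit) or "dummy" (an unassigned ±1 screening column used for error
    estimation).
    """

    name: str
    role: str
    low: float | None = None
    high: float | None = None
    center: float | None = None
    step: float | None = None
    units: str = "g/100 ml"

    def __post_init__(self) -> None:
        if self.role not in ("screening", "ccd", "dummy"):
            raise DesignError(f"unknown factor role {self.role!r}")
        if self.role in ("screening", "dummy"):
            if self.low is None or self.high is None:
                raise DesignError(f"factor {self.name!r}: screening factors need low and high")
            if not self.high > self.low:
                raise DesignError(f"factor {self.name!r}: high must exceed low")
        else:
            if self.center is None or self.step is None:
                raise DesignError(f"factor {self.name!r}: ccd factors need center and step")
            if not self.step > 0:
                raise DesignError(f"factor {self.name!r}: step must be positive")

    @classmethod
    def screening(cls, name: str, low: float, high: float, units: str = "g/100 ml") -> "FactorSpec":
        return cls(name=name, role="screening", low=low, high=high, units=units)

    @classmethod
    def ccd(cls, name: str, center: float, step: float, units: str = "g/100 ml") -> "FactorSpec":
        return cls(name=name, role="ccd", center=center, step=step, units=units)

    @classmethod
    def dummy(cls, name: str) -> "FactorSpec":
        return cls(name=name, role="dummy", low=-1.0, high=1.0, units="coded")

    @property
    def center_value(self) -> float:
        if self.role == "ccd":
            return float(self.center)
        return (float(self.low) + float(self.high)) / 2.0

    @property
    def step_value(self) -> float:
        if self.role == "ccd":
            return float(self.step)
        return (float(self.high) - float(self.low)) / 2.0


def _centers_steps(factors: list[FactorSpec]) -> tuple[np.ndarray, np.ndarray]:
    c = np.array([f.center_value for f in factors], dtype=float)
    s = np.array([f.step_value for f in factors], dtype=float)
    return c, s


def code_point(natural, factors: list[FactorSpec]) -> np.ndarray:
    """Map natural concentrations to coded units: (x − center) / step."""
    x = np.asarray(natural, dtype=float)
    if x.shape[-1] != len(factors):
        raise DesignError(f"point has {x.shape[-1]} coordinates for {len(factors)} factors")
    c, s = _centers_steps(factors)
    if np.any(s == 0):
        raise ZeroDivisionError("factor with zero step cannot be coded")
    return (x - c) / s


def decode_point(coded, factors: list[FactorSpec]) -> np.ndarray:
    """Map coded levels back to natural concentrations: center + z * step."""
    z = np.asarray(coded, dtype=float)
    if z.shape[-1] != len(factors):
        raise DesignError(f"point has {z.shape[-1]} coordinates for {len(factors)} factors")
    c, s = _centers_steps(factors)
    return c + z * s


@dataclass
class DesignMatrix:
    """Runs × factors design in coded and natural units, plus responses.

    ``coded`` and ``natural`` always have identical shape; dummy columns of a
    screening design use the ±1 coded values as their "natural" levels.
    """

    factors: list[FactorSpec]
    coded: np.ndarray
    natural: np.ndarray
    point_type: list[str]
    response: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        self.natural = np.asarray(self.natural, dtype=float)
        if self.coded.shape != self.natural.shape:
            raise DesignError("coded and natural matrices must have identical shape")
        if self.coded.shape[1] != len(self.factors):
            raise DesignError("column count does not match factor count")
        if len(self.point_type) != self.coded.shape[0]:
            raise DesignError("point_type length does not match run count")
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=float)
            if self.response.shape != (self.coded.shape[0],):
                raise DesignError("response length does not match run count")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def assigned(self) -> list[FactorSpec]:
        """Factors bound to real medium components (excludes dummy columns)."""
        return [f for f in self.factors if f.role != "dummy"]

    @property
    def dummy_names(self) -> list[str]:
        return [f.name for f in self.factors if f.role == "dummy"]

    def column(self, name: str, coded: bool = True) -> np.ndarray:
        j = self.factor_names.index(name)
        return (self.coded if coded else self.natural)[:, j]

    def with_response(self, response) -> "DesignMatrix":
        return replace(self, response=np.asarray(response, dtype=float))

    def to_frame(self, coded: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.coded if coded else self.natural, columns=self.factor_names)
        df["point_type"] = self.point_type
        if self.response is not None:
            df["response"] = self.response
        return df


def build_pbd_design(
    factors: list[FactorSpec],
    n_runs: int = 12,
    assignment: tuple[int, ...] | None = None,
) -> DesignMatrix:
    """Construct the 12-run Plackett-Burman screening design.

    The coded matrix is the standard cyclic construction: eleven rotations of
    :data:`PB12_GENERATOR` followed by an all-minus row.  The given factors
    are bound to construction columns (``assignment``, default the first
    ``len(factors)`` columns); unassigned columns become dummy columns, whose
    effects estimate the experimental error.  Returned column order is the
    factor order followed by the dummies.
    """
    if n_runs != 12:
        raise DesignError("only the 12-run Plackett-Burman construction is supported")
    if len(factors) > 11:
        raise DesignError(f"a 12-run design screens at most 11 factors, got {len(factors)}")
    for f in factors:
        if f.role != "screening":
            raise DesignError(f"factor {f.name!r} is not a two-level screening factor")

    base = np.array([np.roll(PB12_GENERATOR, i) for i in range(11)] + [[-1] * 11], dtype=float)
    if assignment is None:
        assignment = tuple(range(len(factors)))
    if len(assignment) != len(factors) or len(set(assignment)) != len(assignment):
        raise DesignError("assignment must give one distinct construction column per factor")
    if any(j < 0 or j > 10 for j in assignment):
        raise DesignError("assignment columns must be in 0..10")

    dummy_cols = [j for j in range(11) if j not in assignment]
    order = list(assignment) + dummy_cols
    coded = base[:, order]
    all_factors = list(factors) + [FactorSpec.dummy(f"dummy{i + 1}") for i in range(len(dummy_cols))]
    natural = decode_point(coded, all_factors)
    return DesignMatrix(
        factors=all_factors,
        coded=coded,
        natural=natural,
        point_type=["pbd"] * 12,
        metadata={"assignment": tuple(assignment), "dummy_construction_columns": tuple(dummy_cols)},
    )


def _half_fraction(k: int) -> np.ndarray:
    """Regular 2^(k−1) fraction: last column is the product of the others."""
    full = np.array(list(itertools.product((-1.0, 1.0), repeat=k - 1)))
    last = np.prod(full, axis=1, keepdims=True)
    return np.hstack([full, last])


def build_ccd_design(
    factors: list[FactorSpec],
    alpha: float = 2.0,
    factorial: np.ndarray | None = None,
    n_center: int = 6,
) -> DesignMatrix:
    """Construct a central composite design: factorial ±1 points, 2k axial
    (star) points at ±alpha, and replicated center points.

    ``factorial`` may be an explicit runs × k coded point set (entries ±1);
    the default is a regular half fraction for k ≥ 3 (full factorial for
    smaller k).  Axial runs place one factor at ±alpha with the others at
    their centers.  Concentrations that would go negative at −alpha are
    warned about, since a medium component cannot have a negative level.
    """
    if alpha <= 0:
        raise DesignError("alpha must be positive")
    k = len(factors)
    for f in factors:
        if f.role != "ccd":
            raise DesignError(f"factor {f.name!r} is not a ccd factor")
        if f.center_value - alpha * f.step_value < 0:
            warnings.warn(
                f"factor {f.name!r}: level at -alpha is negative "
                f"({f.center_value - alpha * f.step_value:g} {f.units}); "
                "concentrations cannot be negative",
                stacklevel=2,
            )

    if factorial is None:
        factorial = _half_fraction(k) if k >= 3 else np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    factorial = np.asarray(factorial, dtype=float)
    if factorial.ndim != 2 or factorial.shape[1] != k:
        raise DesignError("factorial point set must be runs x k")
    if not np.allclose(np.abs(factorial), 1.0, atol=1e-9):
        raise DesignError("factorial points must have coded entries in {-1, +1}")
    factorial = np.sign(factorial)  # snap float noise to exact +/-1

    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -alpha
        axial[2 * j + 1, j] = alpha
    center = np.zeros((n_center, k))

    coded = np.vstack([factorial, axial, center])
    point_type = (
        ["factorial"] * factorial.shape[0] + ["axial"] * (2 * k) + ["center"] * n_center
    )

    non_center = coded[np.array(point_type) != "center"]
    if len(np.unique(non_center, axis=0)) != non_center.shape[0]:
        warnings.warn("duplicate non-center runs in the design", stacklevel=2)

    natural = decode_point(coded, factors)
    return DesignMatrix(factors=list(factors), coded=coded, natural=natural, point_type=point_type)


def classify_point_types(coded: np.ndarray, alpha: float = 2.0, atol: float = 1e-12) -> list[str]:
    """Label CCD runs as factorial / axial / center from their coded rows."""
    labels = []
    for row in np.asarray(coded, dtype=float):
        nz = np.abs(row) > atol
        if not nz.any():
            labels.append("center")
        elif nz.sum() == 1 and np.isclose(np.abs(row[nz][0]), alpha):
            labels.append("axial")
        elif np.allclose(np.abs(row), 1.0):
            labels.append("factorial")
        else:
            labels.append("other")
    return labels
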
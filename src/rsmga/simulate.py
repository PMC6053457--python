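"""Seeded synthetic data with the structure each pipeline stage assumes.

Three generators: two-level screening responses driven by planted main
effects, CCD responses driven by a known quadratic polynomial, and
Michaelis-Menten velocity curves — each with optional Gaussian noise and a
seed fixing the full output stream.  Zero-noise output followed by the
corresponding estimator recovers the planted parameters exactly, which is
the round-trip contract the test suite leans on.

Effects use the design-of-experiments convention effect = (mean response at
+1) − (mean response at −1), so a planted effect e contributes (e/2)·coded
per run and the screening estimator returns e without noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designs import DesignMatrix
from .enzymology import michaelis_menten
from .rsm import QuadraticModel

__all__ = [
    "SimulationSpec",
    "simulate_pbd_response",
    "simulate_ccd_response",
    "simulate_mm_kinetics",
]

#: Default demo noise level (U/ml), the scale of center-point scatter in the
#: study's CCD table.
DEFAULT_NOISE_SD = 0.05


@dataclass
class SimulationSpec:
    """Declarative description of one synthetic dataset.

    kind is "pbd-linear", "ccd-quadratic" or "mm-kinetics"; params carries
    the generator's true parameters (effects mapping / model coefficients /
    km+vmax and substrate grid); noise_sd is an additive Gaussian standard
    deviation, noise_cv a multiplicative coefficient of variation (use one).
    """

    kind: str
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    noise_cv: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("pbd-linear", "ccd-quadratic", "mm-kinetics"):
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.noise_sd < 0 or self.noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        return cls(**d)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_pbd_response(
    design: DesignMatrix,
    effects: dict[str, float],
    noise_sd: float = 0.0,
    seed=0,
    baseline: float = 2.0,
) -> np.ndarray:
    """Responses on a two-level design from planted main effects plus noise.

    y_run = baseline + sum_f (effect_f / 2) * coded_f + eps.  Factors absent
    from ``effects`` (including dummy columns) contribute no signal.
    """
    rng = _rng(seed)
    y = np.full(design.n_runs, float(baseline))
    for name, effect in effects.items():
        y += (float(effect) / 2.0) * design.column(name)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, design.n_runs)
    return y


def simulate_ccd_response(
    design: DesignMatrix,
    model: QuadraticModel,
    noise_sd: float = 0.0,
    seed=0,
) -> np.ndarray:
    """Responses on a CCD from a known quadratic polynomial plus noise.

    The model is evaluated in its own unit system (natural coordinates for
    the bundled study model)."""
    rng = _rng(seed)
    pts = design.natural if model.units == "natural" else design.coded
    y = np.asarray(model.predict(pts), dtype=float)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, len(y))
    return y


def simulate_mm_kinetics(
    km: float,
    vmax: float,
    s_grid,
    noise: str = "none",
    noise_level: float = 0.0,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Michaelis-Menten velocities on a substrate grid.

    noise "none" | "additive" (sd = noise_level, velocity units) |
    "multiplicative" (cv = noise_level).  Returns (S, v) arrays.
    """
    rng = _rng(seed)
    s = np.asarray(s_grid, dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")
    v = michaelis_menten(s, vmax, km)
    if noise == "additive" and noise_level > 0:
        v = v + rng.normal(0.0, noise_level, len(s))
    elif noise == "multiplicative" and noise_level > 0:
        v = v * (1.0 + rng.normal(0.0, noise_level, len(s)))
    elif noise not in ("none", "additive", "multiplicative"):
        raise ValueError(f"unknown noise model {noise!r}")
    return s, v
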
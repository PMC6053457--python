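"""Real-coded genetic algorithm for box-constrained maximization.

Mirrors the optimizer configuration used in the study: a single population
of real vectors, rank-based fitness scaling (expectation proportional to
1/sqrt(rank)), stochastic universal sampling of parents, scattered (uniform
mask) crossover, elitism, and termination on a stall-generation limit or a
generation cap.  With crossover fraction 1.0 — the study's setting — no
mutation children are produced, so the search recombines the gene values
present in the initial population; lower the fraction to keep uniform
per-gene mutation active.

Also provides an analytic oracle, :func:`quadratic_stationary_point`, which
locates and classifies the stationary point of a fitted quadratic and falls
back to a dense grid plus local polish when the box optimum is on the
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .rsm import QuadraticModel

__all__ = [
    "GAConfig",
    "GAResult",
    "StationaryAnalysis",
    "ga_maximize",
    "evolve_generation",
    "quadratic_stationary_point",
]


@dataclass
class GAConfig:
    """Evolutionary-search settings.

    Defaults follow the study's printed optimizer block: population 200,
    elite count 2, crossover fraction 1.0, generation cap 100, stall limit
    50 generations.  Mutation (uniform per-gene resampling within bounds at
    ``mutation_rate``, or Gaussian-with-shrink) only acts on the
    1 - crossover_fraction share of non-elite children, hence is inactive at
    the default crossover fraction.
    """

    bounds: tuple = ()
    population_size: int = 200
    elite_count: int = 2
    crossover_fraction: float = 1.0
    generations: int = 100
    stall_generations: int = 50
    stall_tol: float = 1e-6
    mutation_rate: float = 0.01
    mutation_scheme: str = "uniform"  # "uniform" | "gaussian-shrink"
    mutation_sigma: float = 0.1  # fraction of the bound range (gaussian-shrink)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ValueError("crossover fraction must be in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite count must be smaller than the population")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lower < upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds], dtype=float)


@dataclass
class GAResult:
    best_point: np.ndarray
    best_value: float
    generations: int
    best_trace: np.ndarray
    mean_trace: np.ndarray
    termination: str  # "stall" | "generation-cap"
    seed: int
    config: GAConfig = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "best_point": np.asarray(self.best_point).tolist(),
            "best_value": float(self.best_value),
            "generations": int(self.generations),
            "termination": self.termination,
            "seed": int(self.seed),
            "best_trace": np.asarray(self.best_trace).tolist(),
            "mean_trace": np.asarray(self.mean_trace).tolist(),
        }


def _evaluate(objective, population: np.ndarray) -> np.ndarray:
    vals = np.empty(population.shape[0])
    bad = False
    for i, ind in enumerate(population):
        v = objective(ind)
        if not np.isfinite(v):
            bad = True
            v = -np.inf
        vals[i] = v
    if bad:
        warnings.warn(
            "objective returned a non-finite value at a feasible point; penalized with -inf",
            stacklevel=3,
        )
    return vals


def _rank_expectations(fitness: np.ndarray, n_parents: int) -> np.ndarray:
    """Rank scaling: expectation of individual with rank r is ~ 1/sqrt(r),
    normalized so expectations sum to n_parents.  Rank 1 = fittest; ties
    keep input order (stable sort)."""
    order = np.argsort(-fitness, kind="stable")
    raw = np.empty(len(fitness))
    raw[order] = 1.0 / np.sqrt(np.arange(1, len(fitness) + 1))
    return raw * (n_parents / raw.sum())


def _sus_select(expectations: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling: n equally spaced pointers over the
    cumulative expectation line, single random offset."""
    cum = np.cumsum(expectations)
    total = cum[-1]
    step = total / n
    points = rng.uniform(0.0, step) + step * np.arange(n)
    idx = np.searchsorted(cum, points, side="right")
    return np.minimum(idx, len(expectations) - 1)


def _scattered_crossover(p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(p1.shape[0]) < 0.5
    return np.where(mask, p1, p2)


def _mutate(x: np.ndarray, config: GAConfig, gen_frac: float, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.lower, config.upper
    child = x.copy()
    if config.mutation_scheme == "uniform":
        mask = rng.random(len(x)) < config.mutation_rate
        child[mask] = rng.uniform(lo[mask], hi[mask])
    elif config.mutation_scheme == "gaussian-shrink":
        scale = config.mutation_sigma * (hi - lo) * (1.0 - gen_frac)
        child = child + rng.normal(0.0, 1.0, len(x)) * scale
    else:
        raise ValueError(f"unknown mutation scheme {config.mutation_scheme!r}")
    return np.clip(child, lo, hi)


def evolve_generation(
    population: np.ndarray,
    fitness: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
    gen_frac: float = 0.0,
) -> np.ndarray:
    """One generation step: elites + crossover children + mutation children.

    The crossover fraction splits the non-elite slots; parents are drawn by
    stochastic universal sampling on rank-scaled fitness and shuffled before
    pairing.  All children are clipped into the bounds.  Deterministic given
    the generator state.
    """
    pop_n, k = population.shape
    order = np.argsort(-fitness, kind="stable")
    elites = population[order[: config.elite_count]].copy()

    n_rest = pop_n - config.elite_count
    n_xover = int(round(config.crossover_fraction * n_rest))
    n_mut = n_rest - n_xover

    n_parents = 2 * n_xover + n_mut
    children = []
    if n_parents > 0:
        expectations = _rank_expectations(fitness, n_parents)
        parents = _sus_select(expectations, n_parents, rng)
        parents = rng.permutation(parents)
        pi = 0
        for _ in range(n_xover):
            p1, p2 = population[parents[pi]], population[parents[pi + 1]]
            pi += 2
            children.append(_scattered_crossover(p1, p2, rng))
        for _ in range(n_mut):
            children.append(_mutate(population[parents[pi]], config, gen_frac, rng))
            pi += 1
    new = np.vstack([elites] + children) if children else elites
    return np.clip(new, config.lower, config.upper)


def ga_maximize(objective, bounds=None, config: GAConfig | None = None) -> GAResult:
    """Maximize a scalar objective over a box with the configured GA.

    Seeded runs are reproducible; elitism makes the per-generation best trace
    non-decreasing.  Terminates when the best fitness has improved by no more
    than ``stall_tol`` over ``stall_generations`` generations, or at the
    generation cap.
    """
    if config is None:
        config = GAConfig(bounds=tuple(bounds))
    elif bounds is not None and not config.bounds:
        config = GAConfig(**{**config.__dict__, "bounds": tuple(bounds)})
    if not config.bounds:
        raise ValueError("bounds are required")

    rng = np.random.default_rng(config.seed)
    lo, hi = config.lower, config.upper
    k = len(lo)
    population = rng.uniform(lo, hi, size=(config.population_size, k))

    best_trace, mean_trace = [], []
    best_point, best_value = None, -np.inf
    termination = "generation-cap"
    gen = 0
    for gen in range(1, config.generations + 1):
        fitness = _evaluate(objective, population)
        i_best = int(np.argmax(fitness))
        if fitness[i_best] > best_value:
            best_value = float(fitness[i_best])
            best_point = population[i_best].copy()
        best_trace.append(best_value)
        finite = fitness[np.isfinite(fitness)]
        mean_trace.append(float(finite.mean()) if finite.size else -np.inf)

        if (
            gen > config.stall_generations
            and best_trace[-1] - best_trace[-1 - config.stall_generations] <= config.stall_tol
        ):
            termination = "stall"
            break
        if gen == config.generations:
            break
        population = evolve_generation(
            population, fitness, config, rng, gen_frac=gen / config.generations
        )

    return GAResult(
        best_point=best_point,
        best_value=best_value,
        generations=gen,
        best_trace=np.array(best_trace),
        mean_trace=np.array(mean_trace),
        termination=termination,
        seed=config.seed,
        config=config,
    )


@dataclass
class StationaryAnalysis:
    """Box-constrained maximum of a quadratic plus the nature of its
    stationary point."""

    point: np.ndarray  # argmax within the box
    value: float
    nature: str  # "max" | "min" | "saddle" | "degenerate"
    stationary_point: np.ndarray | None
    boundary_constrained: bool


def _grid_polish_max(model: QuadraticModel, bounds, total_points: int = 2_000_000):
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    k = len(lo)
    n = max(3, int(total_points ** (1.0 / k)))
    n = min(n, 41)
    axes = [np.linspace(lo[i], hi[i], n) for i in range(k)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = model.predict(pts)
    x0 = pts[int(np.argmax(vals))]
    res = optimize.minimize(
        lambda x: -model.predict(x), x0, method="L-BFGS-B", bounds=list(bounds)
    )
    return res.x, float(-res.fun)


def quadratic_stationary_point(model: QuadraticModel, bounds) -> StationaryAnalysis:
    """Analytic box-constrained maximizer of a quadratic response surface.

    Solves the stationarity system H x = -g (H the Hessian, g the linear
    gradient term), classifies the stationary point by the Hessian's
    eigenvalue signs, and — whenever that point is not an interior maximum
    of the box — falls back to a dense grid search refined by L-BFGS-B,
    flagging the result as boundary-constrained.
    """
    h = model.hessian()
    g = np.asarray(model.linear, dtype=float)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)

    eig = np.linalg.eigvalsh(h)
    scale = np.max(np.abs(eig)) if np.max(np.abs(eig)) > 0 else 1.0
    if np.min(np.abs(eig)) < 1e-12 * scale:
        nature, x_star = "degenerate", None
    else:
        x_star = np.linalg.solve(h, -g)
        if np.all(eig < 0):
            nature = "max"
        elif np.all(eig > 0):
            nature = "min"
        else:
            nature = "saddle"

    if (
        nature == "max"
        and x_star is not None
        and np.all(x_star >= lo - 1e-12)
        and np.all(x_star <= hi + 1e-12)
    ):
        point = np.clip(x_star, lo, hi)
        return StationaryAnalysis(
            point=point,
            value=float(model.predict(point)),
            nature=nature,
            stationary_point=x_star,
            boundary_constrained=False,
        )

    point, value = _grid_polish_max(model, bounds)
    return StationaryAnalysis(
        point=point,
        value=value,
        nature=nature,
        stationary_point=x_star,
        boundary_constrained=True,
    )
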
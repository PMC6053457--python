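"""Genetic algorithm: operators, contracts, and oracle agreement."""

import numpy as np
import pytest

import rsmga as r
from conftest import grid_search_max, random_concave_quadratic

UNIT_BOX_4 = ((0.0, 1.0),) * 4

# Search settings used for the oracle-agreement checks: mutation stays active
# (the study's crossover fraction of 1.0 confines the search to the initial
# population's gene values, which is faithful to its printed configuration
# but not an accuracy benchmark).
SEARCH = dict(
    population_size=120,
    crossover_fraction=0.85,
    mutation_scheme="gaussian-shrink",
    generations=100,
    stall_generations=40,
)


def test_one_dimensional_parabola():
    cfg = r.GAConfig(
        bounds=((0.0, 1.0),),
        population_size=50,
        crossover_fraction=0.7,
        mutation_scheme="gaussian-shrink",
        generations=100,
        stall_generations=100,
        seed=3,
    )
    res = r.ga_maximize(lambda x: -((x[0] - 0.3) ** 2), config=cfg)
    assert abs(res.best_point[0] - 0.3) < 1e-3


def test_elites_survive_unchanged(rng):
    cfg = r.GAConfig(bounds=UNIT_BOX_4, population_size=20, elite_count=2, seed=0)
    pop = rng.uniform(0, 1, size=(20, 4))
    fitness = -np.sum((pop - 0.5) ** 2, axis=1)
    new = r.evolve_generation(pop, fitness, cfg, np.random.default_rng(1))
    order = np.argsort(-fitness)
    assert np.array_equal(new[0], pop[order[0]])
    assert np.array_equal(new[1], pop[order[1]])


def test_full_crossover_fraction_creates_no_new_gene_values(rng):
    """With crossover fraction 1.0 every non-elite child is a scattered
    crossover of two parents, so no gene value outside the current
    population's per-gene values can appear."""
    cfg = r.GAConfig(bounds=UNIT_BOX_4, population_size=30, crossover_fraction=1.0, seed=0)
    pop = rng.uniform(0, 1, size=(30, 4))
    fitness = rng.normal(size=30)
    new = r.evolve_generation(pop, fitness, cfg, np.random.default_rng(2))
    for j in range(4):
        assert set(np.round(new[:, j], 12)).issubset(set(np.round(pop[:, j], 12)))


def test_crossover_of_identical_parents_is_identity():
    point = np.array([0.2, 0.4, 0.6, 0.8])
    pop = np.tile(point, (10, 1))
    cfg = r.GAConfig(bounds=UNIT_BOX_4, population_size=10, crossover_fraction=1.0, seed=0)
    new = r.evolve_generation(pop, np.zeros(10), cfg, np.random.default_rng(3))
    assert np.allclose(new, point)


def test_seeded_runs_are_bit_reproducible(published_model):
    cfg = r.GAConfig(bounds=r.ga_bounds("ccd-box"), seed=42)
    a = r.ga_maximize(published_model.predict, config=cfg)
    b = r.ga_maximize(published_model.predict, config=cfg)
    assert np.array_equal(a.best_point, b.best_point)
    assert a.best_value == b.best_value
    assert np.array_equal(a.best_trace, b.best_trace)
    assert np.array_equal(a.mean_trace, b.mean_trace)
    assert a.generations == b.generations and a.termination == b.termination


def test_best_trace_is_monotone_under_elitism(published_model):
    res = r.ga_maximize(
        published_model.predict, config=r.GAConfig(bounds=r.ga_bounds("ccd-box"), seed=7)
    )
    assert np.all(np.diff(res.best_trace) >= 0)


def test_all_evaluated_points_stay_in_bounds():
    bounds = ((0.2, 0.6), (-1.0, 2.0), (0.0, 0.05))
    seen = []

    def objective(x):
        seen.append(x.copy())
        return -np.sum(x**2)

    cfg = r.GAConfig(bounds=bounds, population_size=40, generations=30,
                     crossover_fraction=0.8, seed=5)
    r.ga_maximize(objective, config=cfg)
    pts = np.array(seen)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    assert np.all(pts >= lo - 1e-12) and np.all(pts <= hi + 1e-12)


def test_non_finite_objective_is_penalized():
    def objective(x):
        return np.nan if x[0] > 0.5 else x[0]

    cfg = r.GAConfig(bounds=((0.0, 1.0),), population_size=30, generations=5, seed=1)
    with pytest.warns(UserWarning, match="non-finite"):
        res = r.ga_maximize(objective, config=cfg)
    assert res.best_point[0] <= 0.5
    assert np.isfinite(res.best_value)


def test_ga_agrees_with_analytic_and_grid_oracles():
    """On random concave quadratics the GA, the analytic box-constrained
    optimum and a dense grid search coincide (spot check; the full 20-seed
    sweep runs in the acceptance suite)."""
    for seed in range(5):
        model = random_concave_quadratic(seed)
        sp = r.quadratic_stationary_point(model, UNIT_BOX_4)
        cfg = r.GAConfig(bounds=UNIT_BOX_4, seed=100 + seed, **SEARCH)
        res = r.ga_maximize(model.predict, config=cfg)
        assert abs(res.best_value - sp.value) <= 1e-2
        assert abs(res.best_value - grid_search_max(model, UNIT_BOX_4, n=30)) <= 1e-2


def test_stationary_point_interior_maximum():
    model = r.QuadraticModel.from_parts(
        ["a", "b"], 0.0, [2 * 0.3, 2 * 0.7], [-1.0, -1.0], {}
    )  # -(x-0.3)^2 - (y-0.7)^2 up to a constant
    sp = r.quadratic_stationary_point(model, ((0.0, 1.0), (0.0, 1.0)))
    assert sp.nature == "max" and not sp.boundary_constrained
    np.testing.assert_allclose(sp.point, [0.3, 0.7], atol=1e-10)


def test_stationary_point_saddle_classification():
    model = r.QuadraticModel.from_parts(["a", "b"], 0.0, [0.0, 0.0], [1.0, -1.0], {})
    sp = r.quadratic_stationary_point(model, ((-1.0, 1.0), (-1.0, 1.0)))
    assert sp.nature == "saddle"
    assert sp.boundary_constrained
    assert sp.value == pytest.approx(1.0)  # corners of the box


def test_degenerate_hessian_flagged():
    model = r.QuadraticModel.from_parts(["a", "b"], 0.0, [1.0, 0.0], [-1.0, 0.0], {})
    sp = r.quadratic_stationary_point(model, ((0.0, 1.0), (0.0, 1.0)))
    assert sp.nature == "degenerate"
    assert sp.value == pytest.approx(0.25, abs=1e-8)  # max of x - x^2


def test_published_model_optimum_is_boundary_constrained(published_model):
    """The fitted surface has a saddle stationary point, so its maximum over
    the design's star-point box sits on the boundary."""
    bounds = r.ga_bounds("ccd-box")
    sp = r.quadratic_stationary_point(published_model, bounds)
    assert sp.boundary_constrained
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    assert np.any(np.isclose(sp.point, lo, atol=1e-6) | np.isclose(sp.point, hi, atol=1e-6))
    assert sp.value == pytest.approx(grid_search_max(published_model, bounds, n=41), abs=1e-3)


def test_ga_beats_best_observed_run_on_ccd_box(published_model, table2):
    """Maximizing the fitted surface with the study's optimizer settings
    reaches at least the best observed activity (2.788 U/ml)."""
    cfg = r.GAConfig(bounds=r.ga_bounds("ccd-box"), seed=1)
    res = r.ga_maximize(published_model.predict, config=cfg)
    assert res.best_value >= float(np.max(table2.response))


def test_config_validation():
    with pytest.raises(ValueError, match="crossover"):
        r.GAConfig(bounds=((0, 1),), crossover_fraction=1.5)
    with pytest.raises(ValueError, match="elite"):
        r.GAConfig(bounds=((0, 1),), elite_count=200, population_size=100)
    with pytest.raises(ValueError, match="bounds"):
        r.GAConfig(bounds=((1.0, 0.0),))
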
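"""Screening statistics: effects, error variance, t-tests, ranking."""

import numpy as np
import pytest

import rsmga as r
from rsmga.fixtures import table1_factors


def test_effects_match_published_values(table1, printed_stats):
    """Effects recomputed from the 3-decimal printed activities agree with
    the published effect row to 1e-3 (the published analysis used unrounded
    activities)."""
    for name, printed in printed_stats["effect"].items():
        assert r.concentration_effect(table1, name) == pytest.approx(printed, abs=1e-3)


def test_constant_response_gives_zero_effects(table1_full):
    design = table1_full.with_response(np.full(12, 1.8))
    for f in design.factors:
        assert r.concentration_effect(design, f.name) == pytest.approx(0.0, abs=1e-12)


def test_override_variance_reproduces_published_standard_error(printed_stats):
    design = r.table1_full_design()
    v_eff, se, _ = r.dummy_variance(design, veff_override=printed_stats["v_eff"])
    assert v_eff == printed_stats["v_eff"]
    assert se == np.sqrt(printed_stats["v_eff"])
    assert round(se, 6) == printed_stats["se"]


def test_dummy_effects_vanish_without_noise(table1_full):
    effects = {f.name: e for f, e in zip(table1_full.assigned, [0.6, 0.1, -0.2, 0.05, 0.3, -0.1, 0.02])}
    y = r.simulate_pbd_response(table1_full, effects, noise_sd=0.0)
    design = table1_full.with_response(y)
    v_eff, se, e_d = r.dummy_variance(design)
    assert np.max(np.abs(e_d)) <= 1e-12
    assert v_eff <= 1e-24 and se <= 1e-12


def test_dummy_variance_matches_closed_form_monte_carlo(table1_full):
    """Mean dummy-column V_eff over noise replicates approaches the analytic
    effect variance 4 sigma^2 / N of a balanced orthogonal design."""
    sigma, n_rep = 0.05, 2000
    gen = np.random.default_rng(2024)
    noise = gen.normal(0.0, sigma, size=(n_rep, 12))
    dummy_cols = np.column_stack([table1_full.column(d) for d in table1_full.dummy_names])
    effects = noise @ dummy_cols / 6.0  # planted effects are zero on dummies
    v_eff = (effects**2).mean(axis=1)
    expected = 4 * sigma**2 / 12
    assert np.mean(v_eff) == pytest.approx(expected, rel=0.10)


def test_published_p_values_reproduced_one_tailed(printed_stats):
    """The published p-values correspond to a one-tailed t test with
    df = n_runs - 2 = 10."""
    t = np.array(list(printed_stats["t"].values()))
    _, p = r.t_and_p(t * 0.038652, 0.038652, df=10, tails="one")
    for computed, printed in zip(p, printed_stats["p"].values()):
        if printed <= 1e-5:  # floored in print
            assert computed < 1e-5
        else:
            assert computed == pytest.approx(printed, rel=5e-3)


def test_t_zero_gives_half_probability_one_tailed():
    t, p = r.t_and_p(np.array([0.0]), se=1.0, df=11, tails="one")
    assert t[0] == 0.0 and p[0] == 0.5


def test_two_tailed_doubles_one_tailed():
    t1, p1 = r.t_and_p(np.array([1.5]), se=1.0, df=10, tails="one")
    _, p2 = r.t_and_p(np.array([1.5]), se=1.0, df=10, tails="two")
    assert p2[0] == pytest.approx(2 * p1[0])


def test_zero_standard_error_sentinel():
    with pytest.warns(UserWarning, match="zero"):
        t, p = r.t_and_p(np.array([0.5, 0.0]), se=0.0, df=10)
    assert np.isinf(t[0]) and p[0] == 0.0
    assert t[1] == 0.0


def test_effect_equals_twice_regression_slope(table1_full, rng):
    """On a balanced orthogonal two-level design every effect is exactly twice
    the least-squares slope of the response on that coded column (checked
    against an explicit normal-equations solve)."""
    y = rng.normal(2.0, 0.3, 12)
    design = table1_full.with_response(y)
    for name in design.factor_names:
        col = design.column(name)
        x = np.column_stack([np.ones(12), col])
        slope = np.linalg.solve(x.T @ x, x.T @ y)[1]
        assert r.concentration_effect(design, name) == pytest.approx(2 * slope, abs=1e-12)


def test_effects_invariant_to_run_order_and_response_shift(table1_full, rng):
    y = table1_full.response
    base = {n: r.concentration_effect(table1_full, n) for n in table1_full.factor_names}
    perm = rng.permutation(12)
    shuffled = r.DesignMatrix(
        factors=table1_full.factors,
        coded=table1_full.coded[perm],
        natural=table1_full.natural[perm],
        point_type=["pbd"] * 12,
        response=y[perm] + 5.0,
    )
    for name, e in base.items():
        assert r.concentration_effect(shuffled, name) == pytest.approx(e, abs=1e-12)


def test_t_ranking_invariant_to_positive_rescaling(table1_full):
    a = r.pbd_report(table1_full)
    b = r.pbd_report(table1_full.with_response(table1_full.response * 3.7))
    assert a.ranked_factors == b.ranked_factors


def test_report_selects_published_factors(table1_full, printed_stats):
    """With the published error variance, the 90% confidence rule keeps the
    four components that the follow-up CCD varied, led by yeast extract."""
    report = r.pbd_report(table1_full, veff_override=printed_stats["v_eff"])
    assert report.ranked_factors[0] == "yeast_extract"
    assert set(report.significant_factors) == {
        "yeast_extract",
        "dextrose",
        "starch",
        "ammonium_carbonate",
    }


def test_constant_response_nothing_significant(table1_full):
    report = r.pbd_report(table1_full.with_response(np.full(12, 2.0)), veff_override=0.001)
    assert report.significant_factors == []


def test_planted_effect_dominates_ranking(table1_full):
    """A factor with a 10-sigma planted effect is ranked first in at least
    99% of seeded noise replicates."""
    sigma = 0.05
    wins = 0
    n_rep = 500
    for seed in range(n_rep):
        y = r.simulate_pbd_response(table1_full, {"starch": 10 * sigma}, noise_sd=sigma, seed=seed)
        report = r.pbd_report(table1_full.with_response(y))
        wins += report.ranked_factors[0] == "starch"
    assert wins / n_rep >= 0.99


def test_unbalanced_column_raises(table1_full):
    coded = table1_full.coded.copy()
    coded[0, 0] = 1.0 if coded[0, 0] < 0 else -1.0  # break balance of column 1
    broken = r.DesignMatrix(
        factors=table1_full.factors,
        coded=coded,
        natural=table1_full.natural,
        point_type=["pbd"] * 12,
        response=table1_full.response,
    )
    with pytest.raises(r.BalanceError):
        r.concentration_effect(broken, broken.factor_names[0])


def test_missing_response_raises(table1_full):
    bare = r.build_pbd_design(table1_factors())
    with pytest.raises(ValueError, match="response"):
        r.concentration_effect(bare, "yeast_extract")


def test_no_dummies_requires_override(table1):
    with pytest.raises(ValueError, match="override"):
        r.dummy_variance(table1)
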
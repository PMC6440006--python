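"""Random-intercept likelihood against independent oracles; fits; suite."""

import math

import numpy as np
import pytest

from citebias.errors import FitError, NotEstimableError, SeparationError
from citebias.inference import (
    GroupedDesign,
    fit_plain_logistic,
    fit_random_intercept_logistic,
    marginal_loglik,
    odds_ratio_table,
    run_analysis_suite,
    sensitivity_exclude_highly_cited,
)


def grouped(X, y, codes):
    codes = np.asarray(codes)
    order = np.argsort(codes, kind="stable")
    X, y, codes = np.asarray(X, float)[order], np.asarray(y, float)[order], codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    names = ["(intercept)"] + [f"x{k}" for k in range(1, X.shape[1])]
    return GroupedDesign(X=X, y=y, group_codes=codes, starts=starts,
                         colnames=names, group_labels=sorted(set(codes.tolist())))


@pytest.fixture(scope="module")
def small_fixture():
    rng = np.random.default_rng(0)
    n = 12
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = (rng.random(n) < 0.4).astype(float)
    return grouped(X, y, np.repeat(np.arange(3), 4))


def _dense_oracle(beta, sigma, data, n_grid=20001, span=10.0):
    """Brute-force trapezoid integration over the random effect."""
    u = np.linspace(-span, span, n_grid)
    phi = np.exp(-(u**2) / 2) / math.sqrt(2 * math.pi)
    total = 0.0
    for s, e in zip(data.starts, list(data.starts[1:]) + [len(data.y)]):
        eta = (data.X[s:e] @ beta)[:, None] + sigma * u[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        lik = np.prod(np.where(data.y[s:e, None] == 1, p, 1 - p), axis=0)
        total += math.log(np.trapezoid(phi * lik, u))
    return total


def test_loglik_matches_dense_quadrature_oracle(small_fixture):
    beta, sigma = np.array([-0.3, 0.7]), 0.9
    oracle = _dense_oracle(beta, sigma, small_fixture)
    assert marginal_loglik(beta, sigma, small_fixture, K=25) == \
        pytest.approx(oracle, abs=1e-6)
    assert marginal_loglik(beta, sigma, small_fixture, K=15, adaptive=True) == \
        pytest.approx(oracle, abs=1e-6)


def test_loglik_converges_in_quadrature_order(small_fixture):
    beta, sigma = np.array([0.2, -0.5]), 1.3
    # adaptive centering (the fitting default) is already converged at K=15
    l15 = marginal_loglik(beta, sigma, small_fixture, K=15, adaptive=True)
    l50 = marginal_loglik(beta, sigma, small_fixture, K=50, adaptive=True)
    assert abs(l15 - l50) < 1e-6
    # fixed nodes converge monotonically toward the same limit
    errs = [abs(marginal_loglik(beta, sigma, small_fixture, K=k) - l50)
            for k in (5, 15, 25, 45)]
    assert errs[0] > errs[1] > errs[2] > errs[3]
    assert errs[3] < 1e-6


def test_sigma_zero_reduces_to_bernoulli(small_fixture):
    beta = np.array([0.4, -1.1])
    eta = small_fixture.X @ beta
    bernoulli = float(np.sum(small_fixture.y * eta - np.logaddexp(0, eta)))
    assert marginal_loglik(beta, 0.0, small_fixture, K=9) == \
        pytest.approx(bernoulli, abs=1e-12)
    n = len(small_fixture.y)
    assert marginal_loglik([0, 0], 0.0, small_fixture, K=5) == \
        pytest.approx(n * math.log(0.5), abs=1e-12)


def _two_by_two():
    # exposed: 20 events / 100; unexposed: 10 events / 100 -> OR 2.25
    X = np.column_stack([np.ones(200), np.r_[np.ones(100), np.zeros(100)]])
    y = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
    return grouped(X, y, np.repeat(np.arange(10), 20))


def test_two_by_two_mle_equals_cross_product_or():
    data = _two_by_two()
    model = fit_random_intercept_logistic(data, fix_sigma=0.0)
    assert math.exp(model.beta[1]) == pytest.approx((20 * 90) / (80 * 10),
                                                    rel=1e-6)
    assert model.converged


def test_sigma_zero_fit_equals_plain_logistic():
    data = _two_by_two()
    ri = fit_random_intercept_logistic(data, fix_sigma=0.0)
    plain = fit_plain_logistic(data)
    assert np.max(np.abs(ri.beta - plain.beta)) < 1e-6


def test_intercept_only_plain_fit_recovers_sample_mean():
    rng = np.random.default_rng(2)
    y = (rng.random(300) < 0.22).astype(float)
    data = grouped(np.ones((300, 1)), y, np.zeros(300, int))
    model = fit_plain_logistic(data)
    assert 1 / (1 + math.exp(-model.beta[0])) == pytest.approx(y.mean(),
                                                               abs=1e-9)


def test_constant_outcome_raises_separation_error():
    X = np.column_stack([np.ones(20), np.r_[np.ones(10), np.zeros(10)]])
    data = grouped(X, np.ones(20), np.repeat([0, 1], 10))
    with pytest.raises(SeparationError):
        fit_random_intercept_logistic(data)


def test_zero_event_level_raises_and_names_term():
    X = np.column_stack([np.ones(40), np.r_[np.ones(20), np.zeros(20)]])
    y = np.r_[np.zeros(20), np.ones(5), np.zeros(15)]
    data = grouped(X, y, np.repeat(np.arange(4), 10))
    with pytest.raises(SeparationError, match="x1"):
        fit_random_intercept_logistic(data)


def test_rank_deficiency_names_collinear_column():
    X = np.column_stack([np.ones(30), np.r_[np.ones(15), np.zeros(15)],
                         np.r_[np.ones(15), np.zeros(15)]])
    y = np.r_[np.ones(5), np.zeros(10), np.ones(5), np.zeros(10)]
    data = grouped(X, y, np.repeat(np.arange(3), 10))
    with pytest.raises(FitError, match="x2"):
        fit_random_intercept_logistic(data)


def test_odds_ratio_table_recomputes_from_vcov():
    data = _two_by_two()
    model = fit_random_intercept_logistic(data, fix_sigma=0.0)
    [row] = odds_ratio_table(model)
    se = math.sqrt(model.vcov[1, 1])
    assert row.or_ == pytest.approx(math.exp(model.beta[1]), abs=1e-12)
    assert row.ci_low == pytest.approx(math.exp(model.beta[1] - 1.96 * se),
                                       abs=1e-10)
    assert row.ci_high == pytest.approx(math.exp(model.beta[1] + 1.96 * se),
                                        abs=1e-10)
    assert row.ci_low <= row.or_ <= row.ci_high


def test_random_intercept_parameter_recovery_simulated_directly():
    """beta recovered within 3 Monte-Carlo SEs on data simulated from the
    model itself (100 groups x 40 rows, sigma = 1, beta1 = 0.451)."""
    truth, sigma = 0.451, 1.0
    rng = np.random.default_rng(42)
    estimates = []
    for _ in range(12):
        G, m = 100, 40
        x = (rng.random(G * m) < 0.4).astype(float)
        u = sigma * rng.standard_normal(G)
        codes = np.repeat(np.arange(G), m)
        eta = -2.5 + truth * x + u[codes]
        y = (rng.random(G * m) < 1 / (1 + np.exp(-eta))).astype(float)
        data = grouped(np.column_stack([np.ones(G * m), x]), y, codes)
        model = fit_random_intercept_logistic(data)
        estimates.append(model.beta[1])
    mc_se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
    assert abs(np.mean(estimates) - truth) < 3 * mc_se + 1e-9


def test_suite_flags_empty_category_and_continues(small_synth):
    import dataclasses
    from citebias.synthetic import generate
    cfg, _, _ = small_synth
    cfg2 = dataclasses.replace(cfg, seed=13,
                               funding_probs={"not_for_profit": 1.0,
                                              "for_profit": 0.0, "both": 0.0,
                                              "not_reported": 0.0,
                                              "not_applicable": 0.0})
    corpus, _ = generate(cfg2)
    suite = run_analysis_suite(corpus, rule=cfg2.rule,
                               determinants=("significance", "funding"))
    assert not suite.results["funding"].estimable
    assert "empty category" in suite.results["funding"].crude_error
    assert suite.results["significance"].estimable


def test_adjusted_model_adds_four_design_indicators(small_synth):
    cfg, corpus, _ = small_synth
    suite = run_analysis_suite(corpus, rule=cfg.rule,
                               determinants=("significance",))
    model = suite.results["significance"].adjusted_model
    if model is None:  # small corpus: adjustment can be inestimable
        pytest.skip("adjusted fit not estimable on this 50-publication draw")
    design_cols = [c for c in model.colnames if c.startswith("design[")]
    assert len(design_cols) == 4


def test_sensitivity_with_infinite_threshold_is_noop(small_synth):
    cfg, corpus, _ = small_synth
    dets = ("significance", "self_citation")
    suite = run_analysis_suite(corpus, rule=cfg.rule, determinants=dets)
    sens = sensitivity_exclude_highly_cited(corpus, float("inf"),
                                            rule=cfg.rule, determinants=dets)
    assert sens.excluded_ids == []
    left, right = suite.to_frame(), sens.suite.to_frame()
    assert np.allclose(left["crude_or"].to_numpy(dtype=float),
                       right["crude_or"].to_numpy(dtype=float),
                       equal_nan=True)


def test_sensitivity_removes_hub_paths(small_synth):
    from citebias.paths import enumerate_potential_paths, mark_realized, \
        summarize_citations
    cfg, corpus, _ = small_synth
    ps = mark_realized(enumerate_potential_paths(corpus, cfg.rule), corpus)
    received = summarize_citations(ps).received
    threshold = received.max() - 1  # removes at least the top publication
    sens = sensitivity_exclude_highly_cited(
        corpus, threshold, rule=cfg.rule, determinants=("self_citation",))
    assert set(received[received > threshold].index) == set(sens.excluded_ids)
    reduced_ids = set(sens.suite.pathset.corpus_ids)
    assert reduced_ids.isdisjoint(sens.excluded_ids)
    # re-enumeration oracle: path count equals direct enumeration on subset
    reduced = corpus.subset([i for i in corpus.ids
                             if i not in sens.excluded_ids])
    assert len(sens.suite.pathset) == len(
        enumerate_potential_paths(reduced, cfg.rule))
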
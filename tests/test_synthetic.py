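"""Generator determinism, shape, calibration and ground-truth consistency."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import expit, logit

from citebias.corpus import Funding, validate_corpus
from citebias.errors import ConfigError
from citebias.paths import enumerate_potential_paths, mark_realized, \
    summarize_citations
from citebias.synthetic import (
    SyntheticConfig,
    bpa_preset,
    generate,
    generate_corpus,
    recovery_experiment,
    simulate_citations,
    _generation_category,
    _PRIVATE,
)

from conftest import make_pub


def test_same_seed_gives_bit_identical_output():
    cfg = dataclasses.replace(bpa_preset(seed=5), n_publications=40)
    c1, t1 = generate(cfg)
    c2, t2 = generate(cfg)
    assert [p.to_record() for p in c1] == [p.to_record() for p in c2]
    assert t1.frame.equals(t2.frame)
    assert t1.intercept == t2.intercept


def test_single_publication_corpus():
    corpus, truth = generate(dataclasses.replace(SyntheticConfig(),
                                                 n_publications=1))
    assert len(corpus) == 1
    assert corpus.publications[0].references == []
    assert len(truth.frame) == 0


def test_infeasible_config_rejected():
    with pytest.raises(ConfigError):
        SyntheticConfig(author_pool=5, authors_max=10).validate()
    with pytest.raises(ConfigError):
        SyntheticConfig(n_publications=0).validate()
    with pytest.raises(ConfigError):
        SyntheticConfig(target_rate=1.5).validate()


def test_design_marginals_within_sampling_error():
    """Pooled over 4 seeds, each design share is within 5 SE of target."""
    target = {"cross_sectional": 63, "cohort": 34, "case_control": 29,
              "narrative_review": 35, "systematic_review": 8}
    n_total, counts = 0, {k: 0 for k in target}
    for seed in range(4):
        corpus = generate_corpus(bpa_preset(seed=seed))
        n_total += len(corpus)
        for p in corpus:
            counts[p.study_design.value] += 1
    for k, expected in target.items():
        p = expected / 169
        se = math.sqrt(n_total * p * (1 - p))
        assert abs(counts[k] - n_total * p) < 5 * se


def test_explicit_intercept_null_model_hits_target_rate():
    """With all effects zero, sigma = 0 and b0 = logit(0.065), the realized
    fraction lands within 3 binomial SEs of 6.5%."""
    cfg = SyntheticConfig(sigma=0.0, intercept=float(logit(0.065)), seed=3)
    _, truth = generate(cfg)
    n = len(truth.frame)
    se = math.sqrt(0.065 * 0.935 / n)
    assert abs(truth.realized_fraction - 0.065) < 3 * se


def test_realized_rate_monotone_in_intercept():
    base = SyntheticConfig(seed=9)
    totals = []
    for b0 in (-5.0, -3.5, -2.0):
        _, truth = generate(dataclasses.replace(base, intercept=b0))
        totals.append(truth.n_realized)
    assert totals[0] < totals[1] < totals[2]


def test_large_negative_intercept_realizes_nothing():
    _, truth = generate(dataclasses.replace(SyntheticConfig(seed=2),
                                            intercept=-30.0))
    assert truth.n_realized == 0


def test_calibrated_rate_near_target(bpa_synth):
    cfg, corpus, truth = bpa_synth
    assert truth.realized_fraction == pytest.approx(cfg.target_rate, abs=0.01)
    assert 10_000 < len(truth.frame) < 14_000  # reference-network path scale


def test_citation_distribution_right_skewed():
    """Under default settings a substantial share of publications stays
    uncited (many-zeros, few-hubs shape of real citation networks)."""
    zero_fracs = []
    for seed in range(1, 7):
        cfg = bpa_preset(seed=seed)
        corpus, _ = generate(cfg)
        ps = mark_realized(enumerate_potential_paths(corpus, cfg.rule), corpus)
        s = summarize_citations(ps)
        zero_fracs.append(s.n_zero_cited / len(corpus))
        assert s.received.max() > 3 * s.median  # long right tail
    assert np.mean(zero_fracs) >= 0.25


def test_marked_pathset_agrees_with_truth_ledger(bpa_synth):
    cfg, corpus, truth = bpa_synth
    ps = mark_realized(enumerate_potential_paths(corpus, cfg.rule), corpus)
    assert ps.n_realized == truth.n_realized
    assert len(ps) == len(truth.frame)
    assert validate_corpus(corpus).errors == []


def test_linear_predictors_recomputable_from_truth(bpa_synth):
    """lp must equal intercept + u + static effects + relational effects,
    re-derived from raw attributes and the stored effect sizes."""
    cfg, corpus, truth = bpa_synth
    pubs = {p.id: p for p in corpus}
    f = truth.frame
    for k in range(0, len(f), 211):
        row = f.iloc[k]
        cited = pubs[row["cited_id"]]
        e = cfg.effect("significance", cited.significance.value)
        e += cfg.effect("conclusion", cited.conclusion.value)
        e += cfg.effect("design", cited.study_design.value)
        if cited.title_suggestive:
            e += cfg.effect("title", "suggestive")
        if cited.funding is Funding.NOT_REPORTED:
            e += cfg.effect("funding", "not_reported")
        if cited.corr_affiliation in _PRIVATE:
            e += cfg.effect("corr_affiliation", "private")
        if cited.sample_size is not None:
            e += cfg.effect("sample_size", _generation_category(
                cited.sample_size, cfg.generation_cutoffs["sample_size"]))
        e += cfg.effect("jif", _generation_category(
            cited.jif, cfg.generation_cutoffs["jif"]))
        e += cfg.effect("n_affiliations", _generation_category(
            cited.n_affiliations, cfg.generation_cutoffs["n_affiliations"]))
        e += cfg.effect("n_references", _generation_category(
            cited.n_references, cfg.generation_cutoffs["n_references"]))
        e += cfg.effect("authority", _generation_category(
            row["authority"], cfg.generation_cutoffs["authority"]))
        if row["self_citation"]:
            e += cfg.effect("self_citation", "yes")
        expected = truth.intercept + row["u"] + e
        assert row["lp"] == pytest.approx(expected, abs=1e-10)


def test_authority_is_endogenous_recount_of_earlier_citations(bpa_synth):
    """Each path's authority value equals a brute recount of realized
    citations, to the cited publication's authors, by citing publications
    of strictly earlier years; before the first realized citation it is 0."""
    cfg, corpus, truth = bpa_synth
    f = truth.frame
    years = {p.id: p.online_date.year for p in corpus}
    authors = {p.id: p.author_set for p in corpus}
    realized = f[f["y"] == 1]
    for k in range(0, len(f), 307):
        row = f.iloc[k]
        lookup_year = years[row["citing_id"]] - 1
        coauthors = authors[row["cited_id"]]
        per_author = {a: 0 for a in coauthors}
        for r in realized.itertuples():
            if years[r.citing_id] <= lookup_year:
                for a in authors[r.cited_id] & coauthors:
                    per_author[a] += 1
        assert row["authority"] == max(per_author.values(), default=0)
    first_year = realized["citing_id"].map(years).min()
    early = f[f["citing_id"].map(years) <= first_year]
    assert (early["authority"] == 0).all()


def test_recovery_smoke_emits_per_term_bias():
    cfg = dataclasses.replace(bpa_preset(seed=17), n_publications=60)
    report = recovery_experiment(cfg, n_replicates=3,
                                 terms=("self_citation",), seed=17)
    summary = report.summary()
    assert set(summary["term"]) == {"self_citation"}
    assert np.isfinite(summary["bias_log_or"]).all()
    assert report.n_failed == 0


def test_simulate_refuses_prefilled_references(toy_corpus):
    with pytest.raises(ConfigError):
        simulate_citations(toy_corpus, SyntheticConfig())
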
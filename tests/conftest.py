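"""Shared fixtures: hand-built miniature corpora and small synthetic ones."""

from __future__ import annotations

import dataclasses

import pytest

from citebias.corpus import Corpus, OnlineDate, Publication
from citebias.synthetic import SyntheticConfig, bpa_preset, generate


def make_pub(pub_id: str, year: int, *, month: int | None = None,
             authors=("smith, a",), design: str = "cohort",
             significance: str = "no", conclusion: str = "not_in_line",
             health: str = "other", sample_size: int | None = 100,
             title_suggestive: bool = False, n_affiliations: int = 2,
             jif: float = 2.0, funding: str = "not_for_profit",
             n_references: int = 30, gender: str = "male",
             affiliation: str = "university", continent: str = "europe",
             references=()) -> Publication:
    """A publication with sensible defaults; reviews are made consistent
    (no sample size, significance not reported) automatically."""
    if design in ("narrative_review", "systematic_review"):
        sample_size = None
        significance = "not_reported"
    return Publication(
        id=pub_id, title=f"Study {pub_id}", authors=list(authors), year=year,
        online_date=OnlineDate(year, month), study_design=design,
        significance=significance, conclusion=conclusion, health_outcome=health,
        sample_size=sample_size, title_suggestive=title_suggestive,
        n_affiliations=n_affiliations, jif=jif, funding=funding,
        n_references=n_references, corr_gender=gender,
        corr_affiliation=affiliation, corr_continent=continent,
        references=list(references),
    )


@pytest.fixture
def toy_corpus() -> Corpus:
    """Six publications over 2002-2010 with two same-year pairs, a few
    realized citations and one author shared between p1 and p5."""
    pubs = [
        make_pub("p1", 2002, authors=["alpha, a", "beta, b"]),
        make_pub("p2", 2004, authors=["gamma, c"], design="cross_sectional",
                 significance="yes", conclusion="in_line"),
        make_pub("p3", 2004, authors=["delta, d"], design="narrative_review"),
        make_pub("p4", 2007, authors=["epsilon, e"], references=["p1"],
                 conclusion="in_line"),
        make_pub("p5", 2010, authors=["alpha, a", "zeta, f"],
                 references=["p1", "p2"], significance="mixed",
                 conclusion="mixed"),
        make_pub("p6", 2010, authors=["eta, g"], references=["p5"],
                 design="case_control", conclusion="in_line"),
    ]
    return Corpus(pubs, {"source": "handmade fixture"})


@pytest.fixture(scope="session")
def small_synth():
    """One 50-publication synthetic corpus under the bpa preset."""
    cfg = dataclasses.replace(bpa_preset(seed=7), n_publications=50)
    corpus, truth = generate(cfg)
    return cfg, corpus, truth


@pytest.fixture(scope="session")
def bpa_synth():
    """One full-size (169 publications) synthetic corpus, bpa preset."""
    cfg = bpa_preset(seed=11)
    corpus, truth = generate(cfg)
    return cfg, corpus, truth


@pytest.fixture(scope="session")
def null_config() -> SyntheticConfig:
    """Generator with every true effect set to zero."""
    return SyntheticConfig()
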
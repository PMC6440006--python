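"""Synthetic BPA-like citation corpora with known ground truth.

The generator emulates the shape of the coded bisphenol-A human-health
network -- 169 publications spread over 2002-2017 with strong growth
after 2010, roughly 12,000 potential citation paths, a ~6.5% realized
citation rate, and a right-skewed citation-count distribution -- while
every determinant's effect on the citation odds is set by configuration
on the logit scale.  Because the generative model *is* the fitted
random-intercept logistic model, parameter-recovery experiments can
validate the whole pipeline end to end:

    y_ij ~ Bernoulli( expit( b0 + u_j + x_ij' beta_true ) ),
    u_j ~ N(0, sigma^2)  per citing publication j,

simulated forward in time so that the authority covariate accumulates
endogenously: the citations a publication's authors receive in earlier
simulated years feed back into its authority category for later paths.

The ``bpa`` preset encodes the printed descriptive marginals and crude
odds ratios of the reference network; a :class:`TruthLedger` stored
next to every generated corpus records enough (per-path linear
predictors, random intercepts, effects) to recompute every outcome
probability exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .corpus import (
    Conclusion,
    Corpus,
    CorrAffiliation,
    Funding,
    OnlineDate,
    Publication,
    REVIEW_DESIGNS,
    Significance,
    StudyDesign,
)
from .determinants import build_authority_ledger, build_design_rows
from .errors import ConfigError, FitError, NotEstimableError, SeparationError
from .inference import GroupedDesign, fit_random_intercept_logistic
from .paths import TemporalRule, enumerate_potential_paths, mark_realized

__all__ = [
    "BPA_NETWORK",
    "SyntheticConfig",
    "TruthLedger",
    "bpa_preset",
    "generate_corpus",
    "simulate_citations",
    "generate",
    "recovery_experiment",
    "RecoveryReport",
]


#: Printed descriptives of the reference bisphenol-A network: per-category
#: publication counts, per-category potential-path counts where printed,
#: the tertile cutoffs used for categorized continuous determinants, and
#: the crude odds ratios of the published analysis.  These constants
#: parameterize the ``bpa`` preset and the corpus-shape identity checks.
BPA_NETWORK: dict = {
    "n_publications": 169,
    "n_paths": 12432,
    "n_citations": 808,
    "n_zero_cited": 60,
    "median_citations": 1,
    "year_range": (2002, 2017),
    "design_counts": {
        "cross_sectional": 63, "cohort": 34, "case_control": 29,
        "narrative_review": 35, "systematic_review": 8,
    },
    "significance_counts": {"yes": 40, "no": 36, "mixed": 47, "not_reported": 46},
    # Path counts per significance category as printed; they sum to 12,232,
    # not the stated 12,432 total (a known inconsistency of the source table).
    "significance_path_counts": {"yes": 2800, "no": 2813, "mixed": 3819,
                                 "not_reported": 2800},
    "conclusion_counts": {"in_line": 92, "not_in_line": 28, "mixed": 32,
                          "unclear": 17},
    "conclusion_path_counts": {"in_line": 6826, "not_in_line": 2114,
                               "mixed": 2658, "unclear": 834},
    "health_outcome_counts": {
        "reproductive_outcomes": 49, "metabolic_diseases": 45,
        "intermediate_health_factors": 24, "hormone_production": 18,
        "birth_outcomes": 11, "behavioral_outcomes": 7, "cancer": 4, "other": 11,
    },
    "funding_counts": {"not_for_profit": 135, "for_profit": 0, "both": 4,
                       "not_reported": 20, "not_applicable": 10},
    "gender_counts": {"male": 86, "female": 74, "unknown": 9},
    "corr_affiliation_counts": {"university": 136, "government": 14,
                                "industry": 1, "other": 18},
    "continent_counts": {"america": 73, "asia": 47, "europe": 42,
                         "australia": 1, "africa": 2, "middle_east": 4},
    "title_suggestive_count": 33,
    # Category bounds, reading "<a / a-b / >b".
    "cutoffs": {
        "sample_size": (168, 430), "jif": (2.85, 4.6), "n_affiliations": (3, 5),
        "n_references": (46, 58), "authority": (3, 26),
    },
    "crude_or": {
        "significance": {"yes": 1.57},
        "conclusion": {"in_line": 1.57},
        "design": {"cohort": 1.61, "cross_sectional": 2.00,
                   "case_control": 1.08, "systematic_review": 1.36},
        "sample_size": {"mid": 1.04, "high": 1.62},
        "title": {"suggestive": 1.25},
        "n_affiliations": {"mid": 1.46, "high": 1.50},
        "jif": {"mid": 1.21, "high": 1.41},
        "funding": {"not_reported": 0.41},
        "n_references": {"mid": 1.24, "high": 0.75},
        "gender": {"male": 1.00},
        "corr_affiliation": {"private": 0.94},
        "authority": {"mid": 2.21, "high": 3.20},
        "self_citation": {"yes": 5.14},
    },
}


def _norm_probs(counts: dict[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


@dataclass
class SyntheticConfig:
    """Everything that defines a synthetic corpus and its ground truth.

    Marginal category probabilities default to the reference-network
    proportions; ``effects`` are *true* log odds ratios per determinant
    level (reference levels are implicitly 0).  The baseline intercept
    is either given explicitly or calibrated so that the marginal
    realized-citation rate hits ``target_rate``.  ``sigma`` is the SD of
    the citing-publication random intercept on the logit scale.
    """

    n_publications: int = 169
    year_start: int = 2002
    year_end: int = 2017
    growth: float = 1.5            # per-year publication intensity multiplier
    final_year_fraction: float = 0.15  # the last year is only partly observed
    author_pool: int = 300
    authors_mean_extra: float = 3.0    # authors per publication = 2 + Poisson
    authors_max: int = 12

    design_probs: dict[str, float] = field(
        default_factory=lambda: _norm_probs(BPA_NETWORK["design_counts"]))
    significance_nonreview_probs: dict[str, float] = field(
        default_factory=lambda: _norm_probs(
            {"yes": 40, "no": 36, "mixed": 47, "not_reported": 3}))
    conclusion_probs: dict[str, float] = field(
        default_factory=lambda: _norm_probs(BPA_NETWORK["conclusion_counts"]))
    health_outcome_probs: dict[str, float] = field(
        default_factory=lambda: _norm_probs(BPA_NETWORK["health_outcome_counts"]))
    funding_probs: dict[str, float] = field(
        default_factory=lambda: _norm_probs(BPA_NETWORK["funding_counts"]))
    gender_probs: dict[str, float] = field(
        default_factory=lambda: _norm_probs(BPA_NETWORK["gender_counts"]))
    corr_affiliation_probs: dict[str, float] = field(
        default_factory=lambda: _norm_probs(BPA_NETWORK["corr_affiliation_counts"]))
    continent_probs: dict[str, float] = field(
        default_factory=lambda: _norm_probs(BPA_NETWORK["continent_counts"]))
    title_suggestive_prob: float = 33 / 169

    # Continuous determinants: lognormal (mu, sigma) chosen so the
    # published tertile cutoffs sit near the 1/3 and 2/3 quantiles.
    sample_size_lognorm: tuple[float, float] = (5.59, 1.09)
    jif_lognorm: tuple[float, float] = (1.286, 0.557)
    n_affiliations_lognorm: tuple[float, float] = (1.31, 0.92)
    n_references_lognorm: tuple[float, float] = (3.94, 0.27)

    #: True log odds ratios: effects[term][level]; missing entries are 0.
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: Category bounds used generatively ("<a / a-b / >b" convention).
    generation_cutoffs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BPA_NETWORK["cutoffs"]))

    sigma: float = 1.0
    intercept: float | None = None
    target_rate: float = 0.065
    rule: TemporalRule = field(
        default_factory=lambda: TemporalRule(resolution="finest", lag_months=6))
    seed: int = 0

    def validate(self) -> None:
        if self.n_publications < 1:
            raise ConfigError("n_publications must be >= 1")
        if self.year_end < self.year_start:
            raise ConfigError("year_end before year_start")
        if self.author_pool < min(2, self.authors_max):
            raise ConfigError("author pool smaller than authors per publication")
        if self.authors_max > self.author_pool:
            raise ConfigError("authors_max exceeds the author pool")
        if self.sigma < 0:
            raise ConfigError("sigma must be nonnegative")
        if self.intercept is None and not 0.0 < self.target_rate < 1.0:
            raise ConfigError("target_rate must lie in (0, 1)")
        for name, probs in [
            ("design_probs", self.design_probs),
            ("significance_nonreview_probs", self.significance_nonreview_probs),
            ("conclusion_probs", self.conclusion_probs),
            ("health_outcome_probs", self.health_outcome_probs),
            ("funding_probs", self.funding_probs),
            ("gender_probs", self.gender_probs),
            ("corr_affiliation_probs", self.corr_affiliation_probs),
            ("continent_probs", self.continent_probs),
        ]:
            if any(p < 0 for p in probs.values()) or not math.isclose(
                    sum(probs.values()), 1.0, abs_tol=1e-9):
                raise ConfigError(f"{name} must be a probability distribution")
        for term, levels in self.effects.items():
            for lvl, val in levels.items():
                if not math.isfinite(val):
                    raise ConfigError(f"non-finite effect for {term}[{lvl}]")

    def effect(self, term: str, level: str) -> float:
        return float(self.effects.get(term, {}).get(level, 0.0))

    def without_effects(self) -> "SyntheticConfig":
        """A copy with every true effect set to zero (null generator)."""
        return replace(self, effects={})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rule"] = asdict(self.rule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "rule" in d and isinstance(d["rule"], dict):
            d["rule"] = TemporalRule(**d["rule"])
        for key in ("sample_size_lognorm", "jif_lognorm",
                    "n_affiliations_lognorm", "n_references_lognorm"):
            if key in d:
                d[key] = tuple(d[key])
        if "generation_cutoffs" in d:
            d["generation_cutoffs"] = {k: tuple(v)
                                       for k, v in d["generation_cutoffs"].items()}
        return cls(**d)


def bpa_preset(seed: int = 0, **overrides) -> SyntheticConfig:
    """The study-conditions preset: reference-network marginals and the
    published crude odds ratios as generative truth.

    Nuisance levels the published table does not report (significance
    mixed / not reported, conclusion mixed / unclear) carry modest
    positive log odds chosen once from the descriptive realized
    fractions; they enter fitted models as extra indicator levels and
    are never themselves recovery targets.
    """
    effects = {term: {lvl: math.log(or_) for lvl, or_ in levels.items()}
               for term, levels in BPA_NETWORK["crude_or"].items()}
    effects["significance"].update({"mixed": math.log(1.57),
                                    "not_reported": math.log(1.3)})
    effects["conclusion"].update({"mixed": math.log(1.25),
                                  "unclear": math.log(1.5)})
    return SyntheticConfig(seed=seed, effects=effects, **overrides)


# ---------------------------------------------------------------------------
# Corpus generation


def _year_allocation(cfg: SyntheticConfig) -> np.ndarray:
    """Deterministic per-year publication counts (largest remainder),
    growth-shaped so most of the literature appears late."""
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    w = cfg.growth ** np.arange(len(years), dtype=float)
    w[-1] *= cfg.final_year_fraction
    w = w / w.sum() * cfg.n_publications
    counts = np.floor(w).astype(int)
    short = cfg.n_publications - counts.sum()
    order = np.argsort(-(w - np.floor(w)), kind="stable")
    counts[order[:short]] += 1
    return counts


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _author_key(idx: int) -> str:
    return f"author{idx:04d}, {_LETTERS[idx % 26]}"


def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]


def generate_corpus(config: SyntheticConfig) -> Corpus:
    """Draw publications (attributes and author lists, no references yet).

    Publications are returned in chronological order with ids
    ``p0001...``; fully deterministic given ``config.seed``.  Reviews
    get no sample size and significance = not reported by construction.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 101])
    rng_year, rng_auth, rng_attr = [np.random.default_rng(s) for s in ss.spawn(3)]

    counts = _year_allocation(config)
    dates: list[OnlineDate] = []
    for year, c in zip(range(config.year_start, config.year_end + 1), counts):
        months = rng_year.integers(1, 13, size=c)
        if year == config.year_end:
            months = rng_year.integers(1, 4, size=c)  # partial final year
        dates.extend(OnlineDate(year, int(m)) for m in sorted(months))

    pubs: list[Publication] = []
    for i, date in enumerate(dates):
        n_auth = int(np.clip(2 + rng_auth.poisson(config.authors_mean_extra),
                             1, min(config.authors_max, config.author_pool)))
        authors = [_author_key(a) for a in
                   rng_auth.choice(config.author_pool, size=n_auth, replace=False)]
        design = StudyDesign(_choice(rng_attr, config.design_probs))
        is_review = design in REVIEW_DESIGNS
        if is_review:
            significance = Significance.NOT_REPORTED
            sample_size = None
        else:
            significance = Significance(
                _choice(rng_attr, config.significance_nonreview_probs))
            mu, sd = config.sample_size_lognorm
            sample_size = max(10, int(round(rng_attr.lognormal(mu, sd))))
        mu, sd = config.jif_lognorm
        jif = round(float(rng_attr.lognormal(mu, sd)), 2)
        mu, sd = config.n_affiliations_lognorm
        n_affil = int(np.clip(round(rng_attr.lognormal(mu, sd)), 1, 40))
        mu, sd = config.n_references_lognorm
        n_refs = int(np.clip(round(rng_attr.lognormal(mu, sd)), 5, 400))
        pubs.append(Publication(
            id=f"p{i + 1:04d}",
            title=f"Synthetic publication {i + 1} on BPA and human health",
            authors=authors,
            year=date.year,
            online_date=date,
            study_design=design,
            significance=significance,
            conclusion=Conclusion(_choice(rng_attr, config.conclusion_probs)),
            health_outcome=_choice(rng_attr, config.health_outcome_probs),
            sample_size=sample_size,
            title_suggestive=bool(rng_attr.random() < config.title_suggestive_prob),
            n_affiliations=n_affil,
            jif=jif,
            funding=Funding(_choice(rng_attr, config.funding_probs)),
            n_references=n_refs,
            corr_gender=_choice(rng_attr, config.gender_probs),
            corr_affiliation=_choice(rng_attr, config.corr_affiliation_probs),
            corr_continent=_choice(rng_attr, config.continent_probs),
        ))
    meta = {"source": "citebias.synthetic", "seed": config.seed,
            "rule": asdict(config.rule)}
    return Corpus(pubs, meta)


# ---------------------------------------------------------------------------
# Citation simulation


def _generation_category(value: float, cutoffs: tuple[float, float]) -> str:
    """'<a / a-b / >b' assignment used generatively."""
    a, b = cutoffs
    if value < a:
        return "low"
    if value <= b:
        return "mid"
    return "high"


_PRIVATE = {CorrAffiliation.INDUSTRY, CorrAffiliation.OTHER}
_DEFINITE = {Conclusion.IN_LINE, Conclusion.NOT_IN_LINE}


def _static_effects(corpus: Corpus, cfg: SyntheticConfig) -> np.ndarray:
    """Per-publication sum of the time-invariant cited-side effects."""
    out = np.zeros(len(corpus))
    for i, p in enumerate(corpus.publications):
        e = cfg.effect("significance", p.significance.value)
        e += cfg.effect("conclusion", p.conclusion.value)
        e += cfg.effect("design", p.study_design.value)
        e += cfg.effect("health_outcome", p.health_outcome.value)
        if p.title_suggestive:
            e += cfg.effect("title", "suggestive")
        if p.funding is Funding.NOT_REPORTED:
            e += cfg.effect("funding", "not_reported")
        e += cfg.effect("gender", p.corr_gender.value)
        if p.corr_affiliation in _PRIVATE:
            e += cfg.effect("corr_affiliation", "private")
        if p.sample_size is not None:
            cat = _generation_category(p.sample_size,
                                       cfg.generation_cutoffs["sample_size"])
            e += cfg.effect("sample_size", cat)
        e += cfg.effect("jif", _generation_category(
            p.jif, cfg.generation_cutoffs["jif"]))
        e += cfg.effect("n_affiliations", _generation_category(
            p.n_affiliations, cfg.generation_cutoffs["n_affiliations"]))
        e += cfg.effect("n_references", _generation_category(
            p.n_references, cfg.generation_cutoffs["n_references"]))
        out[i] = e
    return out


@dataclass
class TruthLedger:
    """Ground truth stored beside a generated corpus.

    ``frame`` has one row per admissible path with the realized outcome,
    the full linear predictor, the citing publication's random intercept
    and the relational covariates as simulated -- enough to recompute
    every outcome probability as ``expit(lp)``.
    """

    effects: dict[str, dict[str, float]]
    intercept: float
    sigma: float
    seed: int
    frame: pd.DataFrame
    group_intercepts: pd.Series  # u_j indexed by citing publication id

    @property
    def n_realized(self) -> int:
        return int(self.frame["y"].sum())

    @property
    def realized_fraction(self) -> float:
        return float(self.frame["y"].mean()) if len(self.frame) else 0.0

    def to_json(self, path: str | Path) -> None:
        doc = {
            "effects": self.effects,
            "intercept": self.intercept,
            "sigma": self.sigma,
            "seed": self.seed,
            "n_realized": self.n_realized,
            "group_intercepts": {k: float(v)
                                 for k, v in self.group_intercepts.items()},
            "paths": self.frame.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")


def _run_simulation(corpus: Corpus, cfg: SyntheticConfig, intercept: float,
                    u: np.ndarray, uniforms: np.ndarray) -> dict:
    """One forward pass of the year-by-year citation process."""
    n = len(corpus)
    adm = cfg.rule.admissibility_matrix(corpus)
    static = _static_effects(corpus, cfg)

    author_index: dict[str, int] = {}
    pub_author_idx: list[np.ndarray] = []
    for p in corpus:
        for a in p.authors:
            author_index.setdefault(a, len(author_index))
        pub_author_idx.append(np.array([author_index[a] for a in p.authors],
                                       dtype=np.int64))
    n_authors = len(author_index)

    # Author overlap (self-citation opportunity) via the incidence matrix.
    B = np.zeros((n, n_authors), dtype=bool)
    for i, idx in enumerate(pub_author_idx):
        B[i, idx] = True
    overlap = (B @ B.T.astype(np.int64)).astype(bool) if n_authors else np.zeros((n, n), bool)

    conclusions = [p.conclusion for p in corpus]
    definite = np.array([c in _DEFINITE for c in conclusions])
    sc_eff = cfg.effect("self_citation", "yes")
    conc_eff = cfg.effect("concordance", "concordant")
    auth_cut = cfg.generation_cutoffs["authority"]
    auth_mid, auth_high = (cfg.effect("authority", "mid"),
                           cfg.effect("authority", "high"))

    author_counts = np.zeros(n_authors, dtype=np.int64)  # through last closed year
    pending = np.zeros(n_authors, dtype=np.int64)        # current-year citations
    pub_authority = np.zeros(n, dtype=np.int64)
    current_year = None

    order = np.arange(n)  # corpus is chronological by construction
    rows: dict[str, list] = {k: [] for k in
                             ("citing", "cited", "y", "lp", "u", "self_citation",
                              "authority", "concordant")}
    references: list[list[str]] = [[] for _ in range(n)]
    ids = corpus.ids

    for j in order:
        year_j = corpus.publications[j].online_date.year
        if current_year is None:
            current_year = year_j
        elif year_j != current_year:
            author_counts += pending
            pending[:] = 0
            if n_authors:
                pub_authority = np.array(
                    [author_counts[idx].max() if len(idx) else 0
                     for idx in pub_author_idx])
            current_year = year_j
        cands = np.flatnonzero(adm[j])
        if len(cands) == 0:
            continue
        auth_vals = pub_authority[cands]
        auth_effect = np.where(auth_vals < auth_cut[0], 0.0,
                               np.where(auth_vals <= auth_cut[1],
                                        auth_mid, auth_high))
        sc = overlap[j, cands]
        conc = definite[j] & definite[cands] & np.array(
            [conclusions[i] == conclusions[j] for i in cands])
        lp = (intercept + u[j] + static[cands] + auth_effect
              + sc_eff * sc + conc_eff * conc)
        y = (uniforms[j, cands] < expit(lp)).astype(np.int8)
        for i, yi, lpi, sci, av, ci in zip(cands, y, lp, sc, auth_vals, conc):
            rows["citing"].append(ids[j])
            rows["cited"].append(ids[i])
            rows["y"].append(int(yi))
            rows["lp"].append(float(lpi))
            rows["u"].append(float(u[j]))
            rows["self_citation"].append(bool(sci))
            rows["authority"].append(int(av))
            rows["concordant"].append(bool(ci))
            if yi:
                references[j].append(ids[i])
                pending[pub_author_idx[i]] += 1
    return {"rows": rows, "references": references}


def simulate_citations(corpus: Corpus,
                       config: SyntheticConfig) -> tuple[Corpus, TruthLedger]:
    """Fill reference lists by the forward Bernoulli citation process.

    Proceeds year by year in publication order: each new citing
    publication draws its random intercept, then realizes each
    admissible earlier publication as a citation with probability
    ``expit(b0 + u_j + x' beta_true)``, where the authority component is
    computed from citations realized in *earlier* simulated years
    (endogenous feedback) and self-citation from actual author overlap.

    If ``config.intercept`` is None, the baseline ``b0`` is calibrated
    by a pilot pass and a root-find so the marginal realized rate
    matches ``config.target_rate``; the same underlying uniforms are
    reused, keeping the output deterministic in the seed.
    """
    config.validate()
    if any(p.references for p in corpus):
        raise ConfigError("corpus already has reference lists")
    n = len(corpus)
    ss = np.random.SeedSequence([config.seed, 202])
    rng_u, rng_y = [np.random.default_rng(s) for s in ss.spawn(2)]
    u = config.sigma * rng_u.standard_normal(n)
    uniforms = rng_y.random((n, n))

    if config.intercept is not None:
        b0 = float(config.intercept)
        sim = _run_simulation(corpus, config, b0, u, uniforms)
    else:
        # The authority covariate feeds back on realized citations, so the
        # intercept that hits the target rate depends on the simulation it
        # produces.  Iterate pilot pass -> root-find to a fixed point; the
        # same uniforms are reused throughout, keeping output deterministic.
        b0 = float(logit(config.target_rate))
        sim = _run_simulation(corpus, config, b0, u, uniforms)
        for _ in range(8):
            lp_rest = np.asarray(sim["rows"]["lp"], dtype=float) - b0
            if len(lp_rest) == 0:
                break

            def gap(b):
                return float(np.mean(expit(b + lp_rest))) - config.target_rate

            b0_new = float(brentq(gap, -40.0, 15.0, xtol=1e-10))
            sim = _run_simulation(corpus, config, b0_new, u, uniforms)
            done = abs(b0_new - b0) < 1e-3
            b0 = b0_new
            if done:
                break
    pubs = []
    for p, refs in zip(corpus.publications, sim["references"]):
        q = Publication(**{f: getattr(p, f) for f in (
            "id", "title", "authors", "year", "online_date", "study_design",
            "significance", "conclusion", "health_outcome", "sample_size",
            "title_suggestive", "n_affiliations", "jif", "funding",
            "n_references", "corr_gender", "corr_affiliation", "corr_continent")})
        q.references = list(refs)
        pubs.append(q)
    out = Corpus(pubs, dict(corpus.metadata))
    frame = pd.DataFrame(sim["rows"]).rename(
        columns={"citing": "citing_id", "cited": "cited_id"})
    ledger = TruthLedger(
        effects={t: dict(l) for t, l in config.effects.items()},
        intercept=b0, sigma=config.sigma, seed=config.seed, frame=frame,
        group_intercepts=pd.Series(u, index=out.ids),
    )
    return out, ledger


def generate(config: SyntheticConfig) -> tuple[Corpus, TruthLedger]:
    """Convenience: draw publications, then simulate their citations."""
    return simulate_citations(generate_corpus(config), config)


# ---------------------------------------------------------------------------
# Parameter recovery


#: The level whose odds ratio is reported for each determinant.
PRIMARY_LEVEL = {
    "significance": "yes", "conclusion": "in_line", "design": "cross_sectional",
    "sample_size": "high", "title": "suggestive", "n_affiliations": "high",
    "jif": "high", "funding": "not_reported", "n_references": "high",
    "gender": "male", "corr_affiliation": "private", "authority": "high",
    "self_citation": "yes",
}


@dataclass
class RecoveryReport:
    """Machine-readable outcome of a parameter-recovery experiment."""

    estimates: pd.DataFrame  # one row per (replicate, term)
    n_replicates: int
    n_failed: int
    config: SyntheticConfig

    def summary(self) -> pd.DataFrame:
        """Per-term aggregates: mean OR, log-scale bias, RMSE, coverage."""
        recs = []
        for term, g in self.estimates.groupby("term", sort=False):
            truth = float(g["truth_log_or"].iloc[0])
            bias = float((g["beta"] - truth).mean())
            recs.append({
                "term": term,
                "level": g["level"].iloc[0],
                "truth_or": math.exp(truth),
                "mean_or": float(g["or"].mean()),
                "geomean_or": float(np.exp(g["beta"].mean())),
                "mean_log_or": float(g["beta"].mean()),
                "bias_log_or": bias,
                "rmse_log_or": float(np.sqrt(((g["beta"] - truth) ** 2).mean())),
                "coverage": float(g["covered"].mean()),
                "n": int(len(g)),
            })
        return pd.DataFrame(recs)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
            "summary": self.summary().to_dict(orient="records"),
            "estimates": self.estimates.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Expand one integer seed into n independent replicate seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF) for child in ss.spawn(n)]


def recovery_experiment(config: SyntheticConfig,
                        n_replicates: int = 100,
                        terms: Sequence[str] = ("significance", "conclusion",
                                                "self_citation"),
                        seed: int | None = None,
                        K: int = 15,
                        adaptive: bool = True,
                        max_failure_fraction: float = 0.2) -> RecoveryReport:
    """Generate corpora, fit one crude model per term, aggregate recovery.

    Each replicate gets an independent seed expanded from ``seed`` (or
    ``config.seed``); for every requested determinant the crude
    random-intercept model is fitted to the replicate's path data and
    the estimate of the term's primary level is recorded together with
    its Wald interval and whether it covers the generative truth.
    Individual fit failures are recorded, not fatal, unless more than
    ``max_failure_fraction`` of fits fail.
    """
    if n_replicates < 2:
        raise ConfigError("need at least 2 replicates")
    base_seed = config.seed if seed is None else seed
    seeds = replicate_seeds(base_seed, n_replicates)
    records = []
    failures = 0
    for r, s in enumerate(seeds):
        corpus, truth = generate(replace(config, seed=s))
        pathset = mark_realized(
            enumerate_potential_paths(corpus, config.rule), corpus)
        ledger = build_authority_ledger(corpus, pathset)
        for term in terms:
            level = PRIMARY_LEVEL[term]
            truth_log = config.effect(term, level)
            try:
                dm = build_design_rows(pathset, corpus, ledger=ledger,
                                       covariates=(term,))
                data = GroupedDesign.from_design(dm)
                model = fit_random_intercept_logistic(data, K=K, adaptive=adaptive)
                col = f"{term}[{level}]"
                k = model.colnames.index(col)
                b, se = float(model.beta[k]), float(model.se[k])
                lo, hi = b - 1.96 * se, b + 1.96 * se
                records.append({
                    "replicate": r, "seed": s, "term": term, "level": level,
                    "truth_log_or": truth_log, "beta": b, "se": se,
                    "or": math.exp(b), "ci_low": math.exp(lo),
                    "ci_high": math.exp(hi),
                    "covered": bool(lo <= truth_log <= hi),
                    "sigma_hat": model.sigma,
                    "converged": model.converged,
                    "error": "",
                })
            except (SeparationError, NotEstimableError, FitError) as exc:
                failures += 1
                records.append({
                    "replicate": r, "seed": s, "term": term, "level": level,
                    "truth_log_or": truth_log, "beta": np.nan, "se": np.nan,
                    "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "covered": False, "sigma_hat": np.nan, "converged": False,
                    "error": str(exc),
                })
    total = n_replicates * len(terms)
    if failures > max_failure_fraction * total:
        raise FitError(
            f"{failures}/{total} recovery fits failed; experiment aborted")
    est = pd.DataFrame(records)
    est = est[est["error"] == ""].reset_index(drop=True)
    return RecoveryReport(estimates=est, n_replicates=n_replicates,
                          n_failed=failures, config=config)
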
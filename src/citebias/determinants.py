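"""Per-path covariate engineering for citation models.

Covariates describe the *cited* publication of each potential citation
path (the citing side only defines the grouping).  Most determinants are
static publication attributes; two are relational:

* **authority** -- the cited publication's authority score at the time
  of the citing publication: the maximum, over its co-authors, of the
  cumulative number of citations those authors' publications have
  received within the network up to the lookup year.  Authority is
  therefore path-specific (it grows over the life of the network).
* **self-citation** -- whether at least one author appears on both the
  citing and the cited publication.

Skewed continuous determinants (sample size, impact factor, affiliation
count, reference count, authority) are reduced to low/mid/high tertile
categories; cutoffs are the empirical 1/3 and 2/3 type-1 (inverse-CDF)
quantiles, values at or below a cutoff going to the lower category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .corpus import (
    Conclusion,
    Corpus,
    Funding,
    Gender,
    CorrAffiliation,
    Publication,
)
from .errors import CategorizationError, ConfigError
from .paths import PathSet

__all__ = [
    "AuthorityLedger",
    "build_authority_ledger",
    "publication_authority",
    "self_citation",
    "CategorySpec",
    "tertile_categories",
    "DesignMatrix",
    "build_design_rows",
    "code_concordance",
    "MODEL_DETERMINANTS",
    "TERTILE_LABELS",
]

TERTILE_LABELS = ("low", "mid", "high")


# ---------------------------------------------------------------------------
# Authority


@dataclass
class AuthorityLedger:
    """Cumulative within-network citations received per (author, year).

    ``counts[a, t]`` is the number of realized citations received, in
    years <= year ``years[t]``, by publications co-authored by author
    ``a`` (every co-author is credited in full).  With
    ``mode="per_year"`` the entries are single-year increments instead
    of running totals.
    """

    authors: dict[str, int]
    years: np.ndarray  # consecutive calendar years covered
    counts: np.ndarray  # shape (n_authors, n_years)
    mode: Literal["cumulative", "per_year"] = "cumulative"

    def score(self, author: str, year: int) -> int:
        """A(author, year); 0 before the first covered year or for
        authors absent from the network."""
        a = self.authors.get(author)
        if a is None or year < self.years[0]:
            return 0
        t = min(int(year) - int(self.years[0]), len(self.years) - 1)
        if self.mode == "per_year" and year > self.years[-1]:
            return 0
        return int(self.counts[a, t])


def build_authority_ledger(corpus: Corpus, pathset: PathSet,
                           mode: Literal["cumulative", "per_year"] = "cumulative",
                           ) -> AuthorityLedger:
    """Tally realized citations to every co-author of each cited publication.

    A citation realized by a citing publication that appeared in year
    *t* counts toward year *t*; cumulative mode then accumulates over
    years so that ``A(a, t)`` is non-decreasing in *t*.
    """
    if not pathset.marked:
        raise ConfigError("pathset must be marked before building the ledger")
    years_all = [p.online_date.year for p in corpus]
    y0, y1 = min(years_all), max(years_all)
    years = np.arange(y0, y1 + 1)
    authors: dict[str, int] = {}
    for p in corpus:
        for a in p.authors:
            authors.setdefault(a, len(authors))
    counts = np.zeros((len(authors), len(years)), dtype=np.int64)
    realized = pathset.df[pathset.df["y"] == 1]
    for row in realized.itertuples(index=False):
        cited = corpus.publication(row.cited_id)
        t = int(row.citing_year) - y0
        for a in cited.authors:
            counts[authors[a], t] += 1
    if mode == "cumulative":
        counts = np.cumsum(counts, axis=1)
    return AuthorityLedger(authors=authors, years=years, counts=counts, mode=mode)


def publication_authority(pub: Publication, at_year: int,
                          ledger: AuthorityLedger, offset: int = 1) -> int:
    """Authority of a publication for a path whose citing side appeared
    in ``at_year``: the maximum score over its co-authors, evaluated at
    ``at_year - offset`` (default 1: only information available before
    the citing publication appeared)."""
    year = int(at_year) - offset
    return max((ledger.score(a, year) for a in pub.authors), default=0)


def _path_authority_values(corpus: Corpus, pathset: PathSet,
                           ledger: AuthorityLedger, offset: int = 1) -> np.ndarray:
    """Vectorized per-path authority of the cited publication."""
    y0 = int(ledger.years[0])
    n_years = len(ledger.years)
    # pub_auth[i, t] = authority of publication i at calendar year y0 + t
    pub_auth = np.zeros((len(corpus), n_years), dtype=np.int64)
    for i, p in enumerate(corpus.publications):
        idx = [ledger.authors[a] for a in p.authors if a in ledger.authors]
        if idx:
            pub_auth[i] = ledger.counts[idx].max(axis=0)
    pos = {pid: k for k, pid in enumerate(corpus.ids)}
    cited_idx = pathset.df["cited_id"].map(pos).to_numpy()
    t = pathset.df["citing_year"].to_numpy() - offset - y0
    out = np.zeros(len(pathset.df), dtype=np.int64)
    in_range = t >= 0
    t_clip = np.clip(t, 0, n_years - 1)
    vals = pub_auth[cited_idx, t_clip]
    if ledger.mode == "per_year":
        in_range &= t <= n_years - 1
    out[in_range] = vals[in_range]
    return out


# ---------------------------------------------------------------------------
# Self-citation and concordance


def self_citation(citing: Publication, cited: Publication) -> bool:
    """True iff at least one normalized author key appears on both
    publications (symmetric in its arguments)."""
    return bool(citing.author_set & cited.author_set)


_DEFINITE = {Conclusion.IN_LINE, Conclusion.NOT_IN_LINE}


def code_concordance(pathset: PathSet, corpus: Corpus) -> pd.DataFrame:
    """Concordance coding of every path.

    A path is *eligible* iff both the citing and the cited conclusion
    are definite (in line / not in line with the harm hypothesis);
    eligible paths are *concordant* iff the conclusions agree.  Paths
    with mixed or unclear conclusions on either side are flagged
    ineligible and excluded from the concordance model.
    """
    conc = {p.id: p.conclusion for p in corpus}
    citing = pathset.df["citing_id"].map(conc)
    cited = pathset.df["cited_id"].map(conc)
    eligible = citing.isin(_DEFINITE) & cited.isin(_DEFINITE)
    concordant = eligible & (citing == cited)
    return pd.DataFrame({"eligible": eligible.to_numpy(),
                         "concordant": concordant.to_numpy()},
                        index=pathset.df.index)


# ---------------------------------------------------------------------------
# Tertiles


@dataclass(frozen=True)
class CategorySpec:
    """A three-way categorization of a continuous determinant.

    Assignment: value <= ``cutoffs[0]`` -> low; <= ``cutoffs[1]`` -> mid;
    else high.  Ties at a cutoff go to the lower category.
    """

    name: str
    cutoffs: tuple[float, float]
    level: Literal["publication", "path"] = "publication"
    labels: tuple[str, str, str] = TERTILE_LABELS

    def __post_init__(self) -> None:
        if not self.cutoffs[0] < self.cutoffs[1]:
            raise CategorizationError(
                f"{self.name}: cutoffs must be strictly increasing, got {self.cutoffs}")

    def assign(self, values: Sequence[float] | np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        out = np.full(v.shape, self.labels[2], dtype=object)
        out[v <= self.cutoffs[1]] = self.labels[1]
        out[v <= self.cutoffs[0]] = self.labels[0]
        return out


def tertile_categories(values: Sequence[float] | np.ndarray, name: str,
                       level: Literal["publication", "path"] = "publication",
                       ) -> CategorySpec:
    """Empirical tertile cutoffs (type-1 / inverse-CDF quantiles).

    Requires at least 3 distinct values and distinct cutoffs; in the
    absence of ties at the cutoffs the three category sizes differ by at
    most one.
    """
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 3:
        raise CategorizationError(
            f"{name}: need >= 3 distinct values to form tertiles")
    c1, c2 = np.quantile(v, [1 / 3, 2 / 3], method="inverted_cdf")
    if not c1 < c2:
        raise CategorizationError(
            f"{name}: tied tertile cutoffs ({c1}); distribution too discrete")
    return CategorySpec(name=name, cutoffs=(float(c1), float(c2)), level=level)


# ---------------------------------------------------------------------------
# Determinant registry and design rows

#: (levels in fixed order, first level = reference)
_CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "significance": ("no", "yes", "mixed", "not_reported"),
    "conclusion": ("not_in_line", "in_line", "mixed", "unclear"),
    "design": ("narrative_review", "cohort", "cross_sectional",
               "case_control", "systematic_review"),
    "sample_size": TERTILE_LABELS,
    "title": ("not_suggestive", "suggestive"),
    "n_affiliations": TERTILE_LABELS,
    "jif": TERTILE_LABELS,
    "funding": ("reported", "not_reported"),
    "n_references": TERTILE_LABELS,
    "gender": ("female", "male"),
    "corr_affiliation": ("public", "private"),
    "authority": TERTILE_LABELS,
    "self_citation": ("no", "yes"),
    "concordance": ("discordant", "concordant"),
}

#: Determinants modelled as predictors of citation, in reporting order.
MODEL_DETERMINANTS = (
    "significance", "conclusion", "design", "sample_size", "title",
    "n_affiliations", "jif", "funding", "n_references", "gender",
    "corr_affiliation", "authority", "self_citation",
)

_TERTILE_ATTRS = {"sample_size": "sample_size", "n_affiliations": "n_affiliations",
                  "jif": "jif", "n_references": "n_references"}


def _cited_attr(corpus: Corpus, pathset: PathSet, fn: Callable) -> np.ndarray:
    table = {p.id: fn(p) for p in corpus}
    return pathset.df["cited_id"].map(table).to_numpy()


def _term_categories(term: str, corpus: Corpus, pathset: PathSet,
                     ledger: AuthorityLedger | None,
                     specs: dict[str, CategorySpec],
                     authority_offset: int,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-path category labels and eligibility for one determinant."""
    n = len(pathset.df)
    eligible = np.ones(n, dtype=bool)
    if term == "significance":
        cats = _cited_attr(corpus, pathset, lambda p: p.significance.value)
    elif term == "conclusion":
        cats = _cited_attr(corpus, pathset, lambda p: p.conclusion.value)
    elif term == "design":
        cats = _cited_attr(corpus, pathset, lambda p: p.study_design.value)
    elif term == "title":
        cats = _cited_attr(
            corpus, pathset,
            lambda p: "suggestive" if p.title_suggestive else "not_suggestive")
    elif term == "funding":
        cats = _cited_attr(
            corpus, pathset,
            lambda p: "not_reported" if p.funding is Funding.NOT_REPORTED
            else "reported")
        eligible = _cited_attr(
            corpus, pathset, lambda p: p.funding is not Funding.NOT_APPLICABLE
        ).astype(bool)
    elif term == "gender":
        cats = _cited_attr(corpus, pathset, lambda p: p.corr_gender.value)
        eligible = _cited_attr(
            corpus, pathset, lambda p: p.corr_gender is not Gender.UNKNOWN
        ).astype(bool)
    elif term == "corr_affiliation":
        # "Private vs public sector": university and government are public.
        public = {CorrAffiliation.UNIVERSITY, CorrAffiliation.GOVERNMENT}
        cats = _cited_attr(
            corpus, pathset,
            lambda p: "public" if p.corr_affiliation in public else "private")
    elif term == "self_citation":
        pubs = {p.id: p for p in corpus}
        cats = np.array(
            ["yes" if self_citation(pubs[j], pubs[i]) else "no"
             for j, i in zip(pathset.df["citing_id"], pathset.df["cited_id"])],
            dtype=object)
    elif term == "authority":
        if ledger is None:
            raise ConfigError("authority determinant requires an AuthorityLedger")
        values = _path_authority_values(corpus, pathset, ledger, authority_offset)
        spec = specs.get("authority")
        if spec is None:
            spec = tertile_categories(values, "authority", level="path")
            specs["authority"] = spec
        cats = spec.assign(values)
    elif term in _TERTILE_ATTRS:
        attr = _TERTILE_ATTRS[term]
        raw = _cited_attr(corpus, pathset, lambda p: getattr(p, attr))
        eligible = np.array([v is not None for v in raw])
        spec = specs.get(term)
        if spec is None:
            pub_values = [getattr(p, attr) for p in corpus
                          if getattr(p, attr) is not None]
            spec = tertile_categories(pub_values, term, level="publication")
            specs[term] = spec
        cats = np.full(len(raw), "", dtype=object)
        vals = np.array([v if v is not None else np.nan for v in raw], dtype=float)
        cats[eligible] = spec.assign(vals[eligible])
    elif term == "concordance":
        cc = code_concordance(pathset, corpus)
        eligible = cc["eligible"].to_numpy()
        cats = np.where(cc["concordant"].to_numpy(), "concordant", "discordant")
        cats = cats.astype(object)
    else:
        raise ConfigError(f"unknown determinant {term!r}")
    return cats, eligible


@dataclass
class DesignMatrix:
    """Indicator-coded design rows for a set of determinants.

    ``frame`` has one row per eligible path: identity columns
    (``citing_id``, ``cited_id``), the group label (= citing id), the
    outcome ``y`` and one 0/1 column per non-reference level named
    ``term[level]``.  ``blocks`` maps each term to its columns and
    ``references`` to its reference level; rows ineligible for *any*
    requested term are dropped (``n_excluded`` counts them).
    """

    frame: pd.DataFrame
    blocks: dict[str, list[str]]
    references: dict[str, str]
    specs: dict[str, CategorySpec] = field(default_factory=dict)
    n_excluded: int = 0

    @property
    def terms(self) -> list[str]:
        return list(self.blocks)

    @property
    def columns(self) -> list[str]:
        return [c for cols in self.blocks.values() for c in cols]


def build_design_rows(pathset: PathSet, corpus: Corpus,
                      ledger: AuthorityLedger | None = None,
                      specs: dict[str, CategorySpec] | None = None,
                      covariates: Sequence[str] = ("significance",),
                      authority_offset: int = 1) -> DesignMatrix:
    """One indicator-coded row per path for the requested covariates.

    Reference levels follow the reporting convention: significance=no,
    conclusion=not in line, design=narrative review, lowest tertile for
    categorized continuous determinants, self-citation=no.  Tertile
    specs are computed from this corpus unless supplied via ``specs``
    (authority at path level, all others at publication level).
    """
    if not pathset.marked:
        raise ConfigError("mark_realized must run before building design rows")
    specs = dict(specs) if specs else {}
    cats: dict[str, np.ndarray] = {}
    eligible = np.ones(len(pathset.df), dtype=bool)
    for term in covariates:
        if term not in _CATEGORICAL_LEVELS:
            raise ConfigError(f"unknown covariate name {term!r}")
        c, e = _term_categories(term, corpus, pathset, ledger, specs,
                                authority_offset)
        cats[term] = c
        eligible &= e

    frame = pathset.df.loc[eligible, ["citing_id", "cited_id", "y"]].copy()
    frame["group"] = frame["citing_id"]
    blocks: dict[str, list[str]] = {}
    references: dict[str, str] = {}
    for term in covariates:
        levels = _CATEGORICAL_LEVELS[term]
        references[term] = levels[0]
        cols = []
        c = cats[term][eligible]
        for lvl in levels[1:]:
            col = f"{term}[{lvl}]"
            frame[col] = (c == lvl).astype(np.int8)
            cols.append(col)
        blocks[term] = cols
    frame = frame.reset_index(drop=True)
    return DesignMatrix(frame=frame, blocks=blocks, references=references,
                        specs=specs, n_excluded=int((~eligible).sum()))


def export_design_matrix(dm: DesignMatrix, path: str | Path) -> None:
    """Audit export: one CSV row per path with named indicator columns."""
    dm.frame.to_csv(path, index=False)
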
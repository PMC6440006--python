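"""Potential-citation-path enumeration and citation-pattern summaries.

The unit of analysis throughout the package is the *potential citation
path*: an ordered pair (citing, cited) in which the cited publication was
available before the citing one was written.  Every realized citation
(an entry in a reference list) corresponds to exactly one potential path
with outcome ``y = 1``; all other admissible pairs have ``y = 0``.

True submission dates are rarely observable, so admissibility is
delegated to a configurable :class:`TemporalRule`.  The default compares
online dates at the finest precision both publications share and admits
same-date pairs in both directions (same-year citation demonstrably
occurs in real networks).  A strict variant and a submission-lag variant
(cited must precede citing by at least ``lag_months``) are provided.
Realized references that the rule would exclude are force-included with
a warning rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .corpus import Corpus
from .errors import CorpusIntegrityError

__all__ = [
    "TemporalRule",
    "PotentialCitationPath",
    "PathSet",
    "CitationSummary",
    "enumerate_potential_paths",
    "mark_realized",
    "summarize_citations",
    "export_edge_list",
    "export_graphml",
]


@dataclass(frozen=True)
class TemporalRule:
    """Admissibility rule for ordering publications in time.

    resolution
        ``"finest"`` compares month-precision dates when both ends have
        them, else years; ``"year"`` always compares years only.
    admit_ties
        Whether pairs equal at the comparison precision are admissible
        in *both* directions (the default, since neither order can be
        ruled out).  ``False`` gives the strict rule.
    lag_months
        Minimum number of months by which the cited publication must
        precede the citing one, emulating a submission-to-online lag.
        Only applied when both ends carry month precision.
    """

    resolution: Literal["finest", "year"] = "finest"
    admit_ties: bool = True
    lag_months: int = 0

    def admissibility_matrix(self, corpus: Corpus) -> np.ndarray:
        """Boolean matrix ``A[j, i]`` = publication *j* may cite *i*."""
        n = len(corpus)
        years = np.array([p.online_date.year for p in corpus], dtype=np.int64)
        months = np.array(
            [p.online_date.month_index if p.online_date.month_index is not None else -1
             for p in corpus],
            dtype=np.int64,
        )
        use_months = (months[:, None] >= 0) & (months[None, :] >= 0)
        if self.resolution == "year":
            use_months[:] = False
        # delta[j, i] = citing time minus cited time, in months
        dy = (years[:, None] - years[None, :]) * 12
        dm = months[:, None] - months[None, :]
        delta = np.where(use_months, dm, dy)
        if self.lag_months > 0:
            adm = np.where(use_months, delta >= self.lag_months, delta > 0)
            if self.admit_ties:
                adm |= (~use_months) & (delta == 0)
        else:
            adm = delta > 0
            if self.admit_ties:
                adm |= delta == 0
        np.fill_diagonal(adm, False)
        return adm

    def describe(self) -> str:
        tie = "ties both directions" if self.admit_ties else "strict"
        lag = f", lag >= {self.lag_months} months" if self.lag_months else ""
        return f"{self.resolution} resolution, {tie}{lag}"


@dataclass(frozen=True)
class PotentialCitationPath:
    """One ordered (citing, cited) pair with its realization indicator."""

    citing_id: str
    cited_id: str
    y: int
    citing_year: int
    cited_year: int


@dataclass
class PathSet:
    """All potential citation paths of a corpus under one temporal rule.

    The tabular representation (``df``) holds one row per path with
    columns ``citing_id, cited_id, y, citing_year, cited_year, forced``;
    ``forced`` marks realized references the rule alone would exclude.
    ``corpus_ids`` fixes the corpus identity so that summaries can count
    publications that never appear in any path.
    """

    df: pd.DataFrame
    rule: TemporalRule
    corpus_ids: tuple[str, ...]
    warnings: list[str] = field(default_factory=list)
    marked: bool = False

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_realized(self) -> int:
        return int(self.df["y"].sum())

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield PotentialCitationPath(
                row.citing_id, row.cited_id, int(row.y),
                int(row.citing_year), int(row.cited_year))


def enumerate_potential_paths(corpus: Corpus,
                              rule: TemporalRule | None = None) -> PathSet:
    """Enumerate every temporally admissible (citing, cited) pair.

    Realized reference pairs that the rule excludes are force-included
    (flagged in the ``forced`` column and in ``PathSet.warnings``): the
    existence of a citation proves the path was possible.  The result is
    unmarked (all ``y = 0``); call :func:`mark_realized` next.
    """
    rule = rule or TemporalRule()
    ids = np.array(corpus.ids, dtype=object)
    years = np.array([p.online_date.year for p in corpus], dtype=np.int64)
    adm = rule.admissibility_matrix(corpus)

    # Force-include realized references that fail the rule.
    pos = {pid: k for k, pid in enumerate(ids)}
    warnings: list[str] = []
    forced = np.zeros_like(adm)
    for citing, cited in corpus.reference_edges():
        j, i = pos[citing], pos[cited]
        if not adm[j, i]:
            forced[j, i] = True
            warnings.append(
                f"realized citation {citing} -> {cited} violates the temporal "
                f"rule ({rule.describe()}); force-included")
    allowed = adm | forced

    jj, ii = np.nonzero(allowed)
    df = pd.DataFrame(
        {
            "citing_id": ids[jj],
            "cited_id": ids[ii],
            "y": np.zeros(len(jj), dtype=np.int8),
            "citing_year": years[jj],
            "cited_year": years[ii],
            "forced": forced[jj, ii],
        }
    )
    df = df.sort_values(["citing_id", "cited_id"], kind="stable").reset_index(drop=True)
    return PathSet(df=df, rule=rule, corpus_ids=tuple(ids), warnings=warnings)


def mark_realized(pathset: PathSet, corpus: Corpus) -> PathSet:
    """Set ``y = 1`` exactly for pairs present in reference lists.

    Idempotent; raises :class:`CorpusIntegrityError` if a reference edge
    has no corresponding path (cannot happen for a pathset enumerated
    from the same corpus, where such edges are force-included).
    """
    if tuple(corpus.ids) != pathset.corpus_ids:
        raise CorpusIntegrityError("pathset was not built from this corpus")
    edges = set(corpus.reference_edges())
    pairs = list(zip(pathset.df["citing_id"], pathset.df["cited_id"]))
    missing = edges - set(pairs)
    if missing:
        raise CorpusIntegrityError(
            f"realized citations absent from the path set: {sorted(missing)[:5]}")
    y = np.fromiter(((p in edges) for p in pairs), dtype=np.int8, count=len(pairs))
    df = pathset.df.copy()
    df["y"] = y
    return replace(pathset, df=df, marked=True)


@dataclass
class CitationSummary:
    """Distributional summary of the realized citations in a path set."""

    received: pd.Series  # citations received, indexed by publication id
    median: float
    n_zero_cited: int
    n_paths: int
    n_realized: int

    @property
    def realized_fraction(self) -> float:
        return self.n_realized / self.n_paths if self.n_paths else 0.0

    @property
    def percent_realized(self) -> float:
        """Realized citations as a percentage of potential paths."""
        return 100.0 * self.realized_fraction


def percent_realized(n_realized: int, n_paths: int) -> float:
    """Realized citations as a percentage of potential paths."""
    return 100.0 * n_realized / n_paths if n_paths else 0.0


def summarize_citations(pathset: PathSet) -> CitationSummary:
    """Per-publication received-citation counts and the overall rate.

    The median uses the lower-median convention (element at index
    ``(n-1)//2`` of the sorted counts), which keeps it integer-valued.
    """
    received = pd.Series(0, index=list(pathset.corpus_ids), dtype=int)
    if len(pathset.df):
        got = pathset.df.loc[pathset.df["y"] == 1, "cited_id"].value_counts()
        received.loc[got.index] = got.astype(int)
    counts = np.sort(received.to_numpy())
    median = float(counts[(len(counts) - 1) // 2]) if len(counts) else 0.0
    return CitationSummary(
        received=received,
        median=median,
        n_zero_cited=int((received == 0).sum()),
        n_paths=len(pathset),
        n_realized=pathset.n_realized,
    )


def export_edge_list(pathset: PathSet, path: str | Path) -> None:
    """Write the full path table (citing_id, cited_id, y, years) as CSV."""
    cols = ["citing_id", "cited_id", "y", "citing_year", "cited_year"]
    pathset.df[cols].to_csv(path, index=False)


def export_graphml(pathset: PathSet, corpus: Corpus, path: str | Path) -> None:
    """Export the realized-citation digraph as GraphML for external viewers."""
    import networkx as nx

    g = nx.DiGraph()
    for p in corpus:
        g.add_node(p.id, year=p.year, study_design=p.study_design.value,
                   conclusion=p.conclusion.value)
    realized = pathset.df[pathset.df["y"] == 1]
    for row in realized.itertuples(index=False):
        g.add_edge(row.citing_id, row.cited_id)
    nx.write_graphml(g, str(path))
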
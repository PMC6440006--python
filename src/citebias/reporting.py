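"""Publication-style output tables and run logging.

Produces the two table shapes a citation-bias analysis reports:
descriptives (per determinant category: number of publications, number
of potential citation paths, percent realized -- one decimal) and the
crude/adjusted odds-ratio tables (two decimals, "1.00 (ref)" rows).
Machine-readable JSON with full precision is written alongside every
formatted table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .corpus import Corpus, Funding
from .determinants import (
    CategorySpec,
    TERTILE_LABELS,
    tertile_categories,
)
from .inference import AnalysisSuite
from .paths import PathSet, TemporalRule, enumerate_potential_paths, mark_realized

__all__ = ["describe_corpus", "format_describe", "suite_tables",
           "corpus_hash", "write_run_log"]


# Descriptive blocks: (determinant, per-publication category function or
# tertile attribute, category order).
def _describe_blocks(corpus: Corpus) -> list[tuple[str, dict[str, str], list[str]]]:
    blocks = []

    def block(name, fn, order):
        blocks.append((name, {p.id: fn(p) for p in corpus}, order))

    block("significance", lambda p: p.significance.value,
          ["yes", "no", "mixed", "not_reported"])
    block("conclusion", lambda p: p.conclusion.value,
          ["in_line", "not_in_line", "mixed", "unclear"])
    block("health_outcome", lambda p: p.health_outcome.value,
          ["reproductive_outcomes", "metabolic_diseases",
           "intermediate_health_factors", "hormone_production", "birth_outcomes",
           "behavioral_outcomes", "cancer", "other"])
    block("design", lambda p: p.study_design.value,
          ["cohort", "cross_sectional", "case_control", "narrative_review",
           "systematic_review"])
    for attr in ("sample_size", "n_affiliations", "jif", "n_references"):
        values = [getattr(p, attr) for p in corpus if getattr(p, attr) is not None]
        try:
            spec = tertile_categories(values, attr)
        except Exception:
            spec = None
        if spec is None:
            continue
        table = {}
        for p in corpus:
            v = getattr(p, attr)
            table[p.id] = spec.assign([v])[0] if v is not None else "not_applicable"
        order = list(TERTILE_LABELS) + (
            ["not_applicable"] if "not_applicable" in table.values() else [])
        blocks.append((attr, table, order))
    block("title", lambda p: "suggestive" if p.title_suggestive else "not_suggestive",
          ["suggestive", "not_suggestive"])
    block("funding", lambda p: p.funding.value,
          [f.value for f in Funding])
    block("gender", lambda p: p.corr_gender.value, ["male", "female", "unknown"])
    block("corr_affiliation", lambda p: p.corr_affiliation.value,
          ["university", "government", "industry", "other"])
    block("continent", lambda p: p.corr_continent.value,
          ["america", "asia", "europe", "australia", "africa", "middle_east"])
    return blocks


def describe_corpus(corpus: Corpus, pathset: PathSet | None = None,
                    rule: TemporalRule | None = None) -> pd.DataFrame:
    """Descriptive table: per determinant category, the number of
    publications, the number of potential citation paths in which such a
    publication is the cited side, and the percent of those realized."""
    if pathset is None:
        pathset = mark_realized(enumerate_potential_paths(corpus, rule), corpus)
    df = pathset.df
    recs = []
    for name, table, order in _describe_blocks(corpus):
        cats = df["cited_id"].map(table)
        pub_counts = pd.Series(list(table.values())).value_counts()
        for cat in order:
            mask = (cats == cat).to_numpy()
            n_paths = int(mask.sum())
            n_real = int(df.loc[mask, "y"].sum())
            recs.append({
                "determinant": name,
                "category": cat,
                "n_publications": int(pub_counts.get(cat, 0)),
                "n_paths": n_paths,
                "n_realized": n_real,
                "pct_realized": 100.0 * n_real / n_paths if n_paths else 0.0,
            })
    return pd.DataFrame(recs)


def format_describe(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable descriptives: percentages at one decimal."""
    out = table.copy()
    out["paths (% realized)"] = [
        f"{r.n_paths} ({r.pct_realized:.1f}%)" for r in table.itertuples()]
    return out[["determinant", "category", "n_publications", "paths (% realized)"]]


def suite_tables(suite: AnalysisSuite) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(full-precision tidy table, formatted two-decimal table)."""
    tidy = suite.to_frame()
    fmt = tidy.copy()

    def cell(or_, lo, hi, ref):
        if ref:
            return "1.00 (ref)"
        if pd.isna(or_):
            return "NA"
        return f"{or_:.2f} ({lo:.2f}-{hi:.2f})"

    fmt["crude"] = [cell(r.crude_or, r.crude_low, r.crude_high, r.reference)
                    for r in tidy.itertuples()]
    fmt["adjusted"] = [
        "" if r.determinant == "design"
        else cell(r.adjusted_or, r.adjusted_low, r.adjusted_high, r.reference)
        for r in tidy.itertuples()]
    return tidy, fmt[["determinant", "level", "crude", "adjusted", "note"]]


def corpus_hash(corpus: Corpus) -> str:
    """Stable content hash of a corpus (for run logs)."""
    doc = json.dumps([p.to_record() for p in corpus.publications],
                     sort_keys=True, ensure_ascii=False)
    return hashlib.sha256(doc.encode("utf-8")).hexdigest()[:16]


def write_run_log(path: str | Path, *, corpus: Corpus, rule: TemporalRule,
                  config: dict | None = None,
                  suite: AnalysisSuite | None = None) -> None:
    """Record everything needed to reproduce a run: configuration,
    corpus hash, temporal rule, and per-model convergence diagnostics."""
    log: dict = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "corpus_hash": corpus_hash(corpus),
        "n_publications": len(corpus),
        "rule": asdict(rule),
        "config": config or {},
    }
    if suite is not None:
        log["n_paths"] = len(suite.pathset)
        log["n_realized"] = suite.pathset.n_realized
        log["models"] = {
            name: {
                "estimable": r.estimable,
                "crude_converged": r.crude_model.converged if r.crude_model else None,
                "crude_loglik": r.crude_model.loglik if r.crude_model else None,
                "crude_sigma": r.crude_model.sigma if r.crude_model else None,
                "adjusted_converged": (r.adjusted_model.converged
                                       if r.adjusted_model else None),
                "error": r.crude_error or r.adjusted_error or "",
            }
            for name, r in suite.results.items()
        }
    Path(path).write_text(json.dumps(log, indent=1), encoding="utf-8")
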
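"""Coded-publication data model, corpus I/O and validation.

A *corpus* is the closed set of publications on one research question,
together with the within-corpus reference lists that define the citation
network.  Every publication carries the coded characteristics that later
serve as candidate determinants of citation: study outcome (statistical
significance and authors' conclusion), study design, health-outcome
category, sample size, journal impact factor, affiliation count, funding
source, reference count and corresponding-author attributes.

JSON is the canonical on-disk format; a CSV pair (``publications.csv`` +
``references.csv``) is provided for spreadsheet-friendly interchange.
Reading is strict: unknown enum tokens and dangling reference ids are
errors, never silently coerced.
"""

from __future__ import annotations

import csv
import datetime as _dt
import enum
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import CorpusIntegrityError, CorpusSchemaError

__all__ = [
    "StudyDesign",
    "Significance",
    "Conclusion",
    "HealthOutcome",
    "Funding",
    "Gender",
    "CorrAffiliation",
    "Continent",
    "REVIEW_DESIGNS",
    "OnlineDate",
    "Publication",
    "Corpus",
    "ValidationReport",
    "normalize_author",
    "read_corpus",
    "write_corpus",
    "validate_corpus",
]


class StudyDesign(enum.StrEnum):
    COHORT = "cohort"
    CROSS_SECTIONAL = "cross_sectional"
    CASE_CONTROL = "case_control"
    NARRATIVE_REVIEW = "narrative_review"
    SYSTEMATIC_REVIEW = "systematic_review"


#: Designs that present no new data: never scored on statistical
#: significance and carry no sample size.
REVIEW_DESIGNS = frozenset({StudyDesign.NARRATIVE_REVIEW, StudyDesign.SYSTEMATIC_REVIEW})


class Significance(enum.StrEnum):
    YES = "yes"
    NO = "no"
    MIXED = "mixed"
    NOT_REPORTED = "not_reported"


class Conclusion(enum.StrEnum):
    IN_LINE = "in_line"
    NOT_IN_LINE = "not_in_line"
    MIXED = "mixed"
    UNCLEAR = "unclear"


class HealthOutcome(enum.StrEnum):
    REPRODUCTIVE = "reproductive_outcomes"
    METABOLIC = "metabolic_diseases"
    INTERMEDIATE = "intermediate_health_factors"
    HORMONE = "hormone_production"
    BIRTH = "birth_outcomes"
    BEHAVIORAL = "behavioral_outcomes"
    CANCER = "cancer"
    OTHER = "other"


class Funding(enum.StrEnum):
    NOT_FOR_PROFIT = "not_for_profit"
    FOR_PROFIT = "for_profit"
    BOTH = "both"
    NOT_REPORTED = "not_reported"
    NOT_APPLICABLE = "not_applicable"


class Gender(enum.StrEnum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class CorrAffiliation(enum.StrEnum):
    UNIVERSITY = "university"
    GOVERNMENT = "government"
    INDUSTRY = "industry"
    OTHER = "other"


class Continent(enum.StrEnum):
    AMERICA = "america"
    ASIA = "asia"
    EUROPE = "europe"
    AUSTRALIA = "australia"
    AFRICA = "africa"
    MIDDLE_EAST = "middle_east"


_ENUM_FIELDS: dict[str, type[enum.StrEnum]] = {
    "study_design": StudyDesign,
    "significance": Significance,
    "conclusion": Conclusion,
    "health_outcome": HealthOutcome,
    "funding": Funding,
    "corr_gender": Gender,
    "corr_affiliation": CorrAffiliation,
    "corr_continent": Continent,
}


def _coerce_enum(name: str, value: object) -> enum.StrEnum:
    cls = _ENUM_FIELDS[name]
    if isinstance(value, cls):
        return value
    try:
        return cls(str(value))
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise CorpusSchemaError(
            f"unknown {name} value {value!r}; allowed: {allowed}"
        ) from None


@dataclass(frozen=True, order=True)
class OnlineDate:
    """Calendar date a publication first became available online.

    Bibliographic exports are heterogeneous, so the month and day are
    optional; comparisons between dates of different precision fall back
    to the coarsest common precision (handled by the temporal rule, not
    here -- the default ordering is lexicographic with missing parts
    treated as 0, which is only used for deterministic sorting).
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not 1000 <= self.year <= 9999:
            raise CorpusSchemaError(f"implausible year {self.year}")
        if self.month is not None and not 1 <= self.month <= 12:
            raise CorpusSchemaError(f"invalid month {self.month}")
        if self.day is not None:
            if self.month is None:
                raise CorpusSchemaError("day given without month")
            _dt.date(self.year, self.month, self.day)  # validates

    @property
    def month_index(self) -> int | None:
        """Months since year 0, or None when only the year is known."""
        if self.month is None:
            return None
        return self.year * 12 + (self.month - 1)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)

    def __str__(self) -> str:
        s = f"{self.year:04d}"
        if self.month is not None:
            s += f"-{self.month:02d}"
            if self.day is not None:
                s += f"-{self.day:02d}"
        return s

    @classmethod
    def parse(cls, text: str | int) -> "OnlineDate":
        if isinstance(text, int):
            return cls(text)
        m = re.fullmatch(r"(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?", str(text).strip())
        if not m:
            raise CorpusSchemaError(f"cannot parse online date {text!r}")
        y, mo, d = m.groups()
        return cls(int(y), int(mo) if mo else None, int(d) if d else None)


def normalize_author(name: str) -> str:
    """Normalize an author name to a lowercase ASCII ``"surname, initials"`` key.

    Diacritics are stripped; given names are reduced to their initials.
    Keys are compared by exact string match only -- no disambiguation of
    distinct authors who share a normalized key is attempted.

    >>> normalize_author("Müller-Lyer, Franz C.")
    'muller-lyer, fc'
    """
    ascii_name = (
        unicodedata.normalize("NFKD", name).encode("ascii", "ignore").decode("ascii")
    )
    ascii_name = ascii_name.strip().lower()
    if not ascii_name:
        raise CorpusSchemaError(f"author name {name!r} normalizes to empty string")
    if "," in ascii_name:
        surname, _, rest = ascii_name.partition(",")
    else:
        tokens = ascii_name.split()
        surname, rest = tokens[-1], " ".join(tokens[:-1])
    surname = re.sub(r"[^a-z0-9\- ]", "", surname).strip()
    tokens = [t for t in re.split(r"[\s.]+", rest.strip()) if t and t[0].isalnum()]
    if len(tokens) == 1 and tokens[0].isalpha() and len(tokens[0]) <= 3:
        initials = tokens[0]  # already an initials block ("fc"), keep it
    else:
        initials = "".join(t[0] for t in tokens)
    key = f"{surname}, {initials}" if initials else surname
    if not surname:
        raise CorpusSchemaError(f"author name {name!r} has no usable surname")
    return key


# Field order used for stable serialization (JSON object keys / CSV columns).
_FIELD_ORDER = [
    "id",
    "title",
    "authors",
    "year",
    "online_date",
    "study_design",
    "significance",
    "conclusion",
    "health_outcome",
    "sample_size",
    "title_suggestive",
    "n_affiliations",
    "jif",
    "funding",
    "n_references",
    "corr_gender",
    "corr_affiliation",
    "corr_continent",
    "references",
]


@dataclass
class Publication:
    """One coded publication in the network.

    ``authors`` holds normalized author keys (see :func:`normalize_author`);
    ``references`` holds the ids of the *within-corpus* publications this
    one cites.  ``sample_size`` is ``None`` for reviews, which present no
    new data; ``n_references`` counts the full reference list of the
    publication (not just within-corpus references).
    """

    id: str
    title: str
    authors: list[str]
    year: int
    online_date: OnlineDate
    study_design: StudyDesign
    significance: Significance
    conclusion: Conclusion
    health_outcome: HealthOutcome
    sample_size: int | None
    title_suggestive: bool
    n_affiliations: int
    jif: float
    funding: Funding
    n_references: int
    corr_gender: Gender
    corr_affiliation: CorrAffiliation
    corr_continent: Continent
    references: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not str(self.id):
            raise CorpusSchemaError("publication id must be nonempty")
        for name in _ENUM_FIELDS:
            setattr(self, name, _coerce_enum(name, getattr(self, name)))
        if isinstance(self.online_date, (str, int)):
            self.online_date = OnlineDate.parse(self.online_date)
        self.authors = list(self.authors)
        self.references = list(self.references)

    @property
    def is_review(self) -> bool:
        return self.study_design in REVIEW_DESIGNS

    @property
    def author_set(self) -> frozenset[str]:
        return frozenset(self.authors)

    def to_record(self) -> dict:
        rec = {}
        for name in _FIELD_ORDER:
            v = getattr(self, name)
            if isinstance(v, enum.StrEnum):
                v = v.value
            elif isinstance(v, OnlineDate):
                v = str(v)
            rec[name] = v
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Publication":
        missing = [k for k in _FIELD_ORDER if k not in rec and k != "references"]
        if missing:
            raise CorpusSchemaError(f"publication record missing fields: {missing}")
        kw = {k: rec[k] for k in _FIELD_ORDER if k in rec}
        kw["online_date"] = OnlineDate.parse(kw["online_date"])
        kw["year"] = int(kw["year"])
        ss = kw.get("sample_size")
        kw["sample_size"] = None if ss in (None, "", "NA") else int(ss)
        kw["title_suggestive"] = _parse_bool(kw["title_suggestive"])
        kw["n_affiliations"] = int(kw["n_affiliations"])
        kw["jif"] = float(kw["jif"])
        kw["n_references"] = int(kw["n_references"])
        return cls(**kw)


def _parse_bool(v: object) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise CorpusSchemaError(f"cannot parse boolean {v!r}")


@dataclass
class Corpus:
    """The closed publication network under analysis."""

    publications: list[Publication]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {p.id: p for p in self.publications}

    def __len__(self) -> int:
        return len(self.publications)

    def __iter__(self) -> Iterator[Publication]:
        return iter(self.publications)

    def __contains__(self, pub_id: str) -> bool:
        return pub_id in self._index

    def publication(self, pub_id: str) -> Publication:
        try:
            return self._index[pub_id]
        except KeyError:
            raise CorpusIntegrityError(f"unknown publication id {pub_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.publications]

    def reference_edges(self) -> list[tuple[str, str]]:
        """All (citing_id, cited_id) pairs from the reference lists."""
        return [(p.id, ref) for p in self.publications for ref in p.references]

    def subset(self, keep_ids: Iterable[str]) -> "Corpus":
        """A corpus restricted to ``keep_ids``; reference lists are pruned."""
        keep = set(keep_ids)
        pubs = []
        for p in self.publications:
            if p.id not in keep:
                continue
            q = Publication(**{**{k: getattr(p, k) for k in _FIELD_ORDER}})
            q.references = [r for r in p.references if r in keep]
            pubs.append(q)
        meta = dict(self.metadata)
        meta["subset_of"] = f"{len(self)} publications"
        return Corpus(pubs, meta)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_corpus`: the corpus is acceptable iff
    ``errors`` is empty."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_corpus(corpus: Corpus) -> ValidationReport:
    """Check every corpus invariant; violations are reported, not raised.

    Rules checked per publication: nonempty author list; references
    resolve within the corpus and exclude the publication itself;
    reviews are not scored on statistical significance and have no
    sample size (non-reviews must have one); counts are positive and
    the impact factor nonnegative.
    """
    report = ValidationReport()
    seen: set[str] = set()
    ids = {p.id for p in corpus.publications}
    for p in corpus.publications:
        e = report.errors.append
        if p.id in seen:
            e((p.id, "unique_id", "duplicate publication id"))
        seen.add(p.id)
        if not p.authors:
            e((p.id, "authors_nonempty", "publication has no authors"))
        for ref in p.references:
            if ref == p.id:
                e((p.id, "no_self_reference", "publication cites itself"))
            elif ref not in ids:
                e((p.id, "reference_closure", f"reference {ref!r} not in corpus"))
        if p.is_review:
            if p.significance is not Significance.NOT_REPORTED:
                e((p.id, "review_significance",
                   "reviews present no new data and are not scored on "
                   f"statistical significance (got {p.significance.value!r})"))
            if p.sample_size is not None:
                e((p.id, "review_sample_size", "reviews carry no sample size"))
        else:
            if p.sample_size is None:
                e((p.id, "sample_size_present", "non-review without sample size"))
            elif p.sample_size <= 0:
                e((p.id, "sample_size_positive", f"sample size {p.sample_size} <= 0"))
        if p.n_affiliations < 1:
            e((p.id, "n_affiliations_positive", f"{p.n_affiliations} affiliations"))
        if p.jif < 0:
            e((p.id, "jif_nonnegative", f"impact factor {p.jif} < 0"))
        if p.n_references < 0:
            e((p.id, "n_references_nonnegative", f"{p.n_references} references"))
        if p.online_date.year != p.year:
            report.warnings.append(
                (p.id, "year_consistency",
                 f"publication year {p.year} != online year {p.online_date.year}"))
        if len(set(p.references)) != len(p.references):
            report.warnings.append(
                (p.id, "duplicate_references", "reference list contains duplicates"))
    if not corpus.publications:
        report.errors.append(("", "nonempty", "corpus has no publications"))
    return report


# ---------------------------------------------------------------------------
# I/O

_JSON_FORMAT = "citebias-corpus"


def write_corpus(corpus: Corpus, path: str | Path, format: str = "json") -> None:
    """Serialize a corpus losslessly (UTF-8, stable field order).

    ``format="json"`` writes a single file.  ``format="csv_pair"`` treats
    ``path`` as a directory and writes ``publications.csv`` (RFC 4180,
    authors pipe-delimited within their cell) plus ``references.csv``
    with columns ``citing_id, cited_id``.
    """
    path = Path(path)
    if format == "json":
        doc = {
            "format": _JSON_FORMAT,
            "version": 1,
            "metadata": corpus.metadata,
            "publications": [p.to_record() for p in corpus.publications],
        }
        path.write_text(json.dumps(doc, indent=1, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    elif format == "csv_pair":
        path.mkdir(parents=True, exist_ok=True)
        cols = [c for c in _FIELD_ORDER if c != "references"]
        with open(path / "publications.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for p in corpus.publications:
                rec = p.to_record()
                row = []
                for c in cols:
                    v = rec[c]
                    if c == "authors":
                        v = "|".join(v)
                    elif v is None:
                        v = ""
                    row.append(v)
                w.writerow(row)
        with open(path / "references.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["citing_id", "cited_id"])
            for citing, cited in corpus.reference_edges():
                w.writerow([citing, cited])
    else:
        raise CorpusSchemaError(f"unknown corpus format {format!r}")


def read_corpus(path: str | Path, format: str = "json") -> Corpus:
    """Read and type-check a corpus file.

    Raises :class:`CorpusSchemaError` for structural problems (missing
    mandatory column, unknown enum token) and
    :class:`CorpusIntegrityError` for dangling reference ids or
    duplicate publication ids.
    """
    path = Path(path)
    if format == "json":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise CorpusSchemaError(f"{path}: invalid JSON ({exc})") from exc
        if "publications" not in doc:
            raise CorpusSchemaError(f"{path}: missing 'publications' key")
        pubs = [Publication.from_record(rec) for rec in doc["publications"]]
        corpus = Corpus(pubs, doc.get("metadata", {}))
    elif format == "csv_pair":
        pub_path, ref_path = path / "publications.csv", path / "references.csv"
        with open(pub_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            cols = reader.fieldnames or []
            missing = [c for c in _FIELD_ORDER
                       if c not in cols and c != "references"]
            if missing:
                raise CorpusSchemaError(
                    f"{pub_path}: missing mandatory columns {missing}")
            pubs = []
            for rec in reader:
                rec = dict(rec)
                rec["authors"] = [a for a in rec["authors"].split("|") if a]
                rec["references"] = []
                pubs.append(Publication.from_record(rec))
        edges: list[tuple[str, str]] = []
        with open(ref_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if set(reader.fieldnames or []) < {"citing_id", "cited_id"}:
                raise CorpusSchemaError(
                    f"{ref_path}: needs columns citing_id, cited_id")
            edges = [(r["citing_id"], r["cited_id"]) for r in reader]
        index = {p.id: p for p in pubs}
        dangling = sorted({e for pair in edges for e in pair if e not in index})
        if dangling:
            raise CorpusIntegrityError(
                f"{ref_path}: reference ids not in publication table: {dangling}")
        for citing, cited in edges:
            index[citing].references.append(cited)
        corpus = Corpus(pubs, {})
    else:
        raise CorpusSchemaError(f"unknown corpus format {format!r}")

    ids = [p.id for p in corpus.publications]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise CorpusIntegrityError(f"duplicate publication ids: {dupes}")
    id_set = set(ids)
    dangling = sorted({r for p in corpus.publications for r in p.references
                       if r not in id_set})
    if dangling:
        raise CorpusIntegrityError(f"dangling reference ids: {dangling}")
    return corpus
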
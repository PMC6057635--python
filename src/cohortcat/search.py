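"""Deterministic indexing and querying of studies and variables.

The catalogue holds two inverted indexes over variables — token -> locators
(from label, name and question text) and term ref -> locators — plus the
study/dataset maps. Query evaluation is answerable entirely from the indexes
and is, by construction and by property test, equivalent to a brute-force
linear scan.

Tokenization: case-fold, split on any non-alphanumeric run, no stemming, no
stop-words. A trailing ``*`` on a query token requests prefix matching.
Ranking is a transparent count of satisfied clauses with a lexicographic
tie-break — deterministic, not a relevance model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import Dataset, Study, ValidationReport, resolve_links, validate_dataset, validate_study
from .taxonomy import Taxonomy, TermRef, validate_annotations

__all__ = [
    "tokenize",
    "Catalogue",
    "StudyQuery",
    "VariableQuery",
    "SearchHit",
    "SearchResult",
    "QueryError",
    "CatalogueBuildError",
    "build_index",
    "search_studies",
    "search_variables",
    "facet_counts",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)

# locator for a variable: (study_id, dataset_id, variable_name)
Locator = tuple[str, str, str]


def tokenize(text: str) -> list[str]:
    """Case-folded alphanumeric runs, in order of appearance."""
    return _TOKEN_RE.findall(text.casefold())


class QueryError(ValueError):
    """Malformed query (bad range, unresolvable term ref)."""


class CatalogueBuildError(ValueError):
    """Index build refused; carries the offending ValidationReport."""

    def __init__(self, report: ValidationReport):
        super().__init__(str(report))
        self.report = report


@dataclass
class Catalogue:
    studies: dict[str, Study]
    datasets: dict[str, Dataset]
    taxonomy: Taxonomy
    text_index: dict[str, set[Locator]] = field(default_factory=dict)
    term_index: dict[TermRef, set[Locator]] = field(default_factory=dict)
    # derived lookup tables
    variables: dict[Locator, object] = field(default_factory=dict)
    scopes: dict[str, tuple[str, str, str]] = field(default_factory=dict)  # dataset -> link ids

    def locators(self) -> list[Locator]:
        return sorted(self.variables)


@dataclass(frozen=True)
class StudyQuery:
    participants_min: Optional[int] = None
    participants_max: Optional[int] = None
    start_year_range: Optional[tuple[int, int]] = None
    countries: tuple[str, ...] = ()
    data_sources: frozenset = frozenset()
    age_range: Optional[tuple[float, float]] = None

    def clauses(self) -> list[str]:
        present = []
        if self.participants_min is not None:
            present.append("participants_min")
        if self.participants_max is not None:
            present.append("participants_max")
        if self.start_year_range is not None:
            present.append("start_year_range")
        if self.countries:
            present.append("countries")
        if self.data_sources:
            present.append("data_sources")
        if self.age_range is not None:
            present.append("age_range")
        return present


@dataclass(frozen=True)
class VariableQuery:
    """Conjunctive text tokens (trailing ``*`` = prefix), OR across term
    refs, optional scope restriction. Empty query means match-all."""

    text: tuple[str, ...] = ()
    terms: tuple[TermRef, ...] = ()
    study_id: Optional[str] = None
    population_id: Optional[str] = None
    dce_id: Optional[str] = None


@dataclass(frozen=True)
class SearchHit:
    locator: object  # Locator for variables, study id for studies
    score: float


@dataclass(frozen=True)
class SearchResult:
    hits: tuple[SearchHit, ...]

    def __len__(self) -> int:
        return len(self.hits)

    def locators(self) -> list:
        return [h.locator for h in self.hits]


def _ordered(pairs: Iterable[tuple[object, float]]) -> SearchResult:
    hits = sorted(pairs, key=lambda p: (-p[1], p[0]))
    return SearchResult(hits=tuple(SearchHit(loc, score) for loc, score in hits))


def build_index(
    studies: Sequence[Study], datasets: Sequence[Dataset], taxonomy: Taxonomy
) -> Catalogue:
    """Validate everything, then build the inverted indexes.

    Any validation *error* (study invariants, link resolution, dangling
    annotations) refuses the build with a :class:`CatalogueBuildError`
    carrying the merged report; warnings do not block.
    """
    report = ValidationReport()
    for s in studies:
        report.extend(validate_study(s))
    for d in datasets:
        report.extend(validate_dataset(d))
    report.extend(resolve_links(studies, datasets))
    for d in datasets:
        report.extend(validate_annotations(d, taxonomy))
    if not report.ok():
        raise CatalogueBuildError(report)

    cat = Catalogue(
        studies={s.id: s for s in studies},
        datasets={d.id: d for d in datasets},
        taxonomy=taxonomy,
    )
    for d in datasets:
        assert d.link is not None
        cat.scopes[d.id] = (d.link.study_id, d.link.population_id, d.link.dce_id)
        for v in d.variables:
            loc: Locator = (d.link.study_id, d.id, v.name)
            cat.variables[loc] = v
            for tok in set(tokenize(v.label) + tokenize(v.name) + tokenize(v.question_text or "")):
                cat.text_index.setdefault(tok, set()).add(loc)
            for ref in v.annotations:
                cat.term_index.setdefault(TermRef(*ref), set()).add(loc)
    return cat


# ---------------------------------------------------------------------------
# study search

def _study_matches(study: Study, query: StudyQuery) -> bool:
    if query.participants_min is not None:
        if study.number_of_participants is None or study.number_of_participants < query.participants_min:
            return False
    if query.participants_max is not None:
        if study.number_of_participants is None or study.number_of_participants > query.participants_max:
            return False
    if query.start_year_range is not None:
        lo, hi = query.start_year_range
        if study.start_year is None or not (lo <= study.start_year <= hi):
            return False
    if query.countries:
        wanted = set(query.countries)
        found = set()
        for pop in study.populations:
            found |= set(pop.selection_criteria.countries)
        if not (wanted & found):
            return False
    if query.data_sources:
        collected = set()
        for pop in study.populations:
            for dce in pop.data_collection_events:
                collected |= set(dce.data_sources)
        if not set(query.data_sources) <= collected:
            return False
    if query.age_range is not None:
        lo, hi = query.age_range
        overlap = False
        for pop in study.populations:
            crit = pop.selection_criteria
            pop_lo = crit.age_min if crit.age_min is not None else float("-inf")
            pop_hi = crit.age_max if crit.age_max is not None else float("inf")
            if pop_lo <= hi and lo <= pop_hi:
                overlap = True
                break
        if not overlap:
            return False
    return True


def search_studies(catalogue: Catalogue, query: StudyQuery) -> SearchResult:
    """Studies satisfying ALL supplied filters; score = satisfied clause count."""
    for lo_hi, label in (
        ((query.participants_min, query.participants_max), "participants"),
        (query.start_year_range or (None, None), "start_year_range"),
        (query.age_range or (None, None), "age_range"),
    ):
        lo, hi = lo_hi
        if lo is not None and hi is not None and lo > hi:
            raise QueryError(f"{label}: min {lo} exceeds max {hi}")
    score = float(len(query.clauses()))
    return _ordered(
        (sid, score) for sid, study in catalogue.studies.items() if _study_matches(study, query)
    )


# ---------------------------------------------------------------------------
# variable search

def _text_token_set(catalogue: Catalogue, token: str) -> set[Locator]:
    token = token.casefold()
    if token.endswith("*"):
        prefix = token[:-1]
        out: set[Locator] = set()
        for tok, locs in catalogue.text_index.items():
            if tok.startswith(prefix):
                out |= locs
        return out
    return set(catalogue.text_index.get(token, ()))


def _in_scope(catalogue: Catalogue, loc: Locator, query: VariableQuery) -> bool:
    study_id, pop_id, dce_id = catalogue.scopes[loc[1]]
    if query.study_id is not None and study_id != query.study_id:
        return False
    if query.population_id is not None and pop_id != query.population_id:
        return False
    if query.dce_id is not None and dce_id != query.dce_id:
        return False
    return True


def search_variables(catalogue: Catalogue, query: VariableQuery) -> SearchResult:
    """Variables matching every text token, at least one term ref (when
    supplied), and the scope; score = matched text tokens + matched refs."""
    for ref in query.terms:
        if catalogue.taxonomy.resolve(TermRef(*ref)) is None:
            raise QueryError(f"unresolvable term reference {ref[0]}/{ref[1]}")

    if query.text:
        candidate: Optional[set[Locator]] = None
        for token in query.text:
            hits = _text_token_set(catalogue, token)
            candidate = hits if candidate is None else candidate & hits
        assert candidate is not None
    else:
        candidate = set(catalogue.variables)

    if query.terms:
        term_hits: set[Locator] = set()
        for ref in query.terms:
            term_hits |= catalogue.term_index.get(TermRef(*ref), set())
        candidate &= term_hits

    out = []
    query_refs = {TermRef(*r) for r in query.terms}
    for loc in candidate:
        if not _in_scope(catalogue, loc, query):
            continue
        var = catalogue.variables[loc]
        score = float(len(query.text)) + float(len(query_refs & set(var.annotations)))
        out.append((loc, score))
    return _ordered(out)


def facet_counts(
    catalogue: Catalogue, query: VariableQuery, facet: str
) -> dict:
    """Counts over the query's match set, partitioned by facet.

    ``facet`` is one of ``study``, ``domain``, ``term``. Under domain/term
    facets a variable contributes once per *matching* annotation: when the
    query supplies term filters only annotations in that list count,
    otherwise all of the variable's annotations count — so facet sums can
    exceed the match-set size.
    """
    if facet not in ("study", "domain", "term"):
        raise QueryError(f"unknown facet {facet!r}")
    result = search_variables(catalogue, query)
    counts: dict = {}
    query_refs = {TermRef(*r) for r in query.terms}
    for hit in result.hits:
        loc = hit.locator
        if facet == "study":
            counts[loc[0]] = counts.get(loc[0], 0) + 1
            continue
        refs = set(catalogue.variables[loc].annotations)
        if query_refs:
            refs &= query_refs
        for ref in refs:
            key = ref[0] if facet == "domain" else TermRef(*ref)
            counts[key] = counts.get(key, 0) + 1
    return counts
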
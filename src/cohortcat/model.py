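"""Typed entities and validation for the cohort metadata model.

The hierarchy is Study -> Population -> DataCollectionEvent, with Datasets
(lists of Variables, each carrying Categories and taxonomy annotations)
attached to a single data-collection event via a ``DatasetLink``.

Validation never raises on bad content: every violated invariant becomes an
issue in a :class:`ValidationReport` with a locator path, so callers can
collect all problems in one pass. Missing *recommended* metadata (objectives,
access) yields warnings, not errors, because catalogues must tolerate varying
levels of completeness.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Any, Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "TOKEN_PATTERN",
    "RECRUITMENT_SOURCES",
    "DATA_SOURCES",
    "VALUE_TYPES",
    "SEX_VALUES",
    "PartialDate",
    "Person",
    "Access",
    "SelectionCriteria",
    "Category",
    "Variable",
    "DatasetLink",
    "Dataset",
    "DataCollectionEvent",
    "Population",
    "Study",
    "ValidationIssue",
    "ValidationReport",
    "validate_study",
    "validate_dataset",
    "resolve_links",
    "study_to_dict",
    "study_from_dict",
    "dataset_to_dict",
    "dataset_from_dict",
    "dump_study_yaml",
    "load_study_yaml",
]

TOKEN_PATTERN = re.compile(r"[A-Za-z0-9_-]+\Z")

RECRUITMENT_SOURCES = frozenset(
    {"general_population", "specific_population", "participants_of_other_study", "other"}
)
DATA_SOURCES = frozenset(
    {
        "questionnaires",
        "physical_measures",
        "cognitive_measures",
        "biological_samples",
        "administrative_databases",
        "other",
    }
)
VALUE_TYPES = frozenset({"integer", "decimal", "text", "boolean", "date"})
SEX_VALUES = frozenset({"female", "male", "all"})

_PARTIAL_DATE_RE = re.compile(r"(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?\Z")


@dataclass(frozen=True, order=False)
class PartialDate:
    """ISO date with year, year-month, or full precision.

    Ordering compares the *earliest* concrete interpretation: a bare year
    means January 1st, a year-month means the 1st of that month. This makes
    range checks deterministic and conservative.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        m = _PARTIAL_DATE_RE.match(str(text).strip())
        if not m:
            raise ValueError(f"not a partial ISO date (YYYY[-MM[-DD]]): {text!r}")
        year = int(m.group(1))
        month = int(m.group(2)) if m.group(2) else None
        day = int(m.group(3)) if m.group(3) else None
        # delegate range checking to datetime.date
        date(year, month or 1, day or 1)
        return cls(year, month, day)

    def earliest(self) -> date:
        return date(self.year, self.month or 1, self.day or 1)

    def __le__(self, other: "PartialDate") -> bool:
        return self.earliest() <= other.earliest()

    def __lt__(self, other: "PartialDate") -> bool:
        return self.earliest() < other.earliest()

    def __str__(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"


@dataclass(frozen=True)
class Person:
    name: str
    role: Optional[str] = None
    email: Optional[str] = None


@dataclass(frozen=True)
class Access:
    data: Optional[str] = None
    samples: Optional[str] = None


@dataclass(frozen=True)
class SelectionCriteria:
    age_min: Optional[float] = None
    age_max: Optional[float] = None
    sex: Optional[str] = None
    countries: tuple[str, ...] = ()
    other: Optional[str] = None


@dataclass(frozen=True)
class Category:
    code: str
    label: str = ""
    is_missing: bool = False


@dataclass(frozen=True)
class Variable:
    """A documented variable of a data dictionary.

    ``annotations`` is a frozenset of ``(domain_name, term_name)`` TermRefs
    (see :mod:`cohortcat.taxonomy`); categorical semantics apply only when
    ``categories`` is non-empty.
    """

    name: str
    label: str = ""
    value_type: str = "text"
    unit: Optional[str] = None
    question_text: Optional[str] = None
    categories: tuple[Category, ...] = ()
    annotations: frozenset = frozenset()


@dataclass(frozen=True)
class DatasetLink:
    study_id: str
    population_id: str
    dce_id: str


@dataclass(frozen=True)
class Dataset:
    id: str
    name: str = ""
    description: str = ""
    link: Optional[DatasetLink] = None
    variables: tuple[Variable, ...] = ()

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass(frozen=True)
class DataCollectionEvent:
    id: str
    name: str = ""
    description: str = ""
    start_date: Optional[PartialDate] = None
    end_date: Optional[PartialDate] = None
    data_sources: frozenset = frozenset()


@dataclass(frozen=True)
class Population:
    id: str
    name: str = ""
    description: str = ""
    recruitment_sources: frozenset = frozenset()
    selection_criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    number_of_participants: Optional[int] = None
    data_collection_events: tuple[DataCollectionEvent, ...] = ()


@dataclass(frozen=True)
class Study:
    id: str
    name: str = ""
    acronym: Optional[str] = None
    objectives: Optional[str] = None
    website: Optional[str] = None
    investigators: tuple[Person, ...] = ()
    contacts: tuple[Person, ...] = ()
    start_year: Optional[int] = None
    end_year: Optional[int] = None
    number_of_participants: Optional[int] = None
    number_with_samples: Optional[int] = None
    access: Access = field(default_factory=Access)
    logo_ref: Optional[str] = None
    populations: tuple[Population, ...] = ()


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    path: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, severity: str, path: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, path, message))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def ok(self) -> bool:
        return not self.errors

    def extend(self, other: "ValidationReport") -> "ValidationReport":
        self.issues.extend(other.issues)
        return self

    def __str__(self) -> str:
        if not self.issues:
            return "OK: no issues"
        return "\n".join(f"{i.severity.upper()}: {i.path}: {i.message}" for i in self.issues)


def _check_token(report: ValidationReport, path: str, value: str, what: str) -> None:
    if not value or not TOKEN_PATTERN.match(value):
        report.add("error", path, f"{what} id must match [A-Za-z0-9_-]+, got {value!r}")


def validate_study(study: Study) -> ValidationReport:
    """Check every model invariant of one study; report, never raise."""
    report = ValidationReport()
    spath = f"study[{study.id}]"
    _check_token(report, spath, study.id, "study")

    if study.number_of_participants is not None and study.number_of_participants < 0:
        report.add("error", spath, "number_of_participants must be non-negative")
    if study.number_with_samples is not None and study.number_with_samples < 0:
        report.add("error", spath, "number_with_samples must be non-negative")
    if (
        study.number_with_samples is not None
        and study.number_of_participants is not None
        and study.number_with_samples > study.number_of_participants
    ):
        report.add(
            "error",
            spath,
            f"samples exceed participants ({study.number_with_samples} > "
            f"{study.number_of_participants})",
        )
    if (
        study.start_year is not None
        and study.end_year is not None
        and study.end_year < study.start_year
    ):
        report.add("error", spath, f"end_year {study.end_year} precedes start_year {study.start_year}")

    if not study.objectives:
        report.add("warning", spath, "missing recommended field: objectives")
    if study.access.data is None and study.access.samples is None:
        report.add("warning", spath, "missing recommended field: access")

    seen_pops: set[str] = set()
    for pop in study.populations:
        ppath = f"{spath}.populations[{pop.id}]"
        _check_token(report, ppath, pop.id, "population")
        if pop.id in seen_pops:
            report.add("error", ppath, f"duplicate population id {pop.id!r}")
        seen_pops.add(pop.id)

        for tag in pop.recruitment_sources:
            if tag not in RECRUITMENT_SOURCES:
                report.add("error", ppath, f"unknown recruitment source tag {tag!r}")
        crit = pop.selection_criteria
        if crit.age_min is not None and crit.age_max is not None and crit.age_min > crit.age_max:
            report.add("error", ppath, f"age_min {crit.age_min} exceeds age_max {crit.age_max}")
        if crit.sex is not None and crit.sex not in SEX_VALUES:
            report.add("error", ppath, f"unknown sex value {crit.sex!r}")
        if pop.number_of_participants is not None and pop.number_of_participants < 0:
            report.add("error", ppath, "number_of_participants must be non-negative")

        seen_dces: set[str] = set()
        for dce in pop.data_collection_events:
            dpath = f"{ppath}.data_collection_events[{dce.id}]"
            _check_token(report, dpath, dce.id, "data collection event")
            if dce.id in seen_dces:
                report.add("error", dpath, f"duplicate DCE id {dce.id!r}")
            seen_dces.add(dce.id)
            if dce.start_date is not None and dce.end_date is not None:
                if dce.end_date < dce.start_date:
                    report.add(
                        "error",
                        dpath,
                        f"end_date {dce.end_date} precedes start_date {dce.start_date} "
                        "(earliest-interpretation ordering)",
                    )
            for tag in dce.data_sources:
                if tag not in DATA_SOURCES:
                    report.add("error", dpath, f"unknown data source tag {tag!r}")
    return report


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Dataset-local invariants: unique variable names, unique category codes."""
    report = ValidationReport()
    dpath = f"dataset[{dataset.id}]"
    _check_token(report, dpath, dataset.id, "dataset")
    seen_vars: set[str] = set()
    for var in dataset.variables:
        vpath = f"{dpath}.variables[{var.name}]"
        if not var.name or not TOKEN_PATTERN.match(var.name):
            report.add("error", vpath, f"variable name must match [A-Za-z0-9_-]+, got {var.name!r}")
        if var.name in seen_vars:
            report.add("error", vpath, f"duplicate variable name {var.name!r}")
        seen_vars.add(var.name)
        if var.value_type not in VALUE_TYPES:
            report.add("error", vpath, f"unknown value_type {var.value_type!r}")
        seen_codes: set[str] = set()
        for cat in var.categories:
            if not cat.code:
                report.add("error", vpath, "category code must be non-empty")
            if cat.code in seen_codes:
                report.add("error", vpath, f"duplicate category code {cat.code!r}")
            seen_codes.add(cat.code)
    return report


def resolve_links(studies: Sequence[Study], datasets: Sequence[Dataset]) -> ValidationReport:
    """Check that every dataset link names an existing study/population/DCE.

    Many datasets may attach to the same DCE; id collisions among studies or
    datasets are errors.
    """
    report = ValidationReport()
    index: dict[str, dict[str, set[str]]] = {}
    for study in studies:
        if study.id in index:
            report.add("error", f"study[{study.id}]", f"duplicate study id {study.id!r}")
            continue
        index[study.id] = {
            pop.id: {dce.id for dce in pop.data_collection_events} for pop in study.populations
        }
    seen_ds: set[str] = set()
    for ds in datasets:
        dpath = f"dataset[{ds.id}]"
        if ds.id in seen_ds:
            report.add("error", dpath, f"duplicate dataset id {ds.id!r}")
        seen_ds.add(ds.id)
        link = ds.link
        if link is None:
            report.add("error", dpath, "dataset has no link to a data collection event")
            continue
        pops = index.get(link.study_id)
        if pops is None:
            report.add("error", dpath, f"link names missing study {link.study_id!r}")
            continue
        dces = pops.get(link.population_id)
        if dces is None:
            report.add(
                "error",
                dpath,
                f"link names missing population {link.population_id!r} in study {link.study_id!r}",
            )
            continue
        if link.dce_id not in dces:
            report.add(
                "error",
                dpath,
                f"link names missing DCE {link.dce_id!r} in "
                f"{link.study_id}/{link.population_id}",
            )
    return report


# ---------------------------------------------------------------------------
# YAML (de)serialization. One document per study, snake_case field names.

def _drop_none(d: dict) -> dict:
    return {k: v for k, v in d.items() if v not in (None, (), [], {})}


def _person_to_dict(p: Person) -> dict:
    return _drop_none({"name": p.name, "role": p.role, "email": p.email})


def study_to_dict(study: Study) -> dict:
    return _drop_none(
        {
            "id": study.id,
            "name": study.name,
            "acronym": study.acronym,
            "objectives": study.objectives,
            "website": study.website,
            "investigators": [_person_to_dict(p) for p in study.investigators],
            "contacts": [_person_to_dict(p) for p in study.contacts],
            "start_year": study.start_year,
            "end_year": study.end_year,
            "number_of_participants": study.number_of_participants,
            "number_with_samples": study.number_with_samples,
            "access": _drop_none({"data": study.access.data, "samples": study.access.samples}),
            "logo_ref": study.logo_ref,
            "populations": [_population_to_dict(p) for p in study.populations],
        }
    )


def _population_to_dict(pop: Population) -> dict:
    crit = pop.selection_criteria
    return _drop_none(
        {
            "id": pop.id,
            "name": pop.name,
            "description": pop.description,
            "recruitment_sources": sorted(pop.recruitment_sources),
            "selection_criteria": _drop_none(
                {
                    "age_min": crit.age_min,
                    "age_max": crit.age_max,
                    "sex": crit.sex,
                    "countries": list(crit.countries),
                    "other": crit.other,
                }
            ),
            "number_of_participants": pop.number_of_participants,
            "data_collection_events": [_dce_to_dict(d) for d in pop.data_collection_events],
        }
    )


def _dce_to_dict(dce: DataCollectionEvent) -> dict:
    return _drop_none(
        {
            "id": dce.id,
            "name": dce.name,
            "description": dce.description,
            "start_date": str(dce.start_date) if dce.start_date else None,
            "end_date": str(dce.end_date) if dce.end_date else None,
            "data_sources": sorted(dce.data_sources),
        }
    )


def _person_from_dict(d: Mapping[str, Any]) -> Person:
    return Person(name=d["name"], role=d.get("role"), email=d.get("email"))


def study_from_dict(d: Mapping[str, Any]) -> Study:
    access = d.get("access") or {}
    return Study(
        id=str(d["id"]),
        name=d.get("name", ""),
        acronym=d.get("acronym"),
        objectives=d.get("objectives"),
        website=d.get("website"),
        investigators=tuple(_person_from_dict(p) for p in d.get("investigators", [])),
        contacts=tuple(_person_from_dict(p) for p in d.get("contacts", [])),
        start_year=d.get("start_year"),
        end_year=d.get("end_year"),
        number_of_participants=d.get("number_of_participants"),
        number_with_samples=d.get("number_with_samples"),
        access=Access(data=access.get("data"), samples=access.get("samples")),
        logo_ref=d.get("logo_ref"),
        populations=tuple(_population_from_dict(p) for p in d.get("populations", [])),
    )


def _population_from_dict(d: Mapping[str, Any]) -> Population:
    crit = d.get("selection_criteria") or {}
    return Population(
        id=str(d["id"]),
        name=d.get("name", ""),
        description=d.get("description", ""),
        recruitment_sources=frozenset(d.get("recruitment_sources", [])),
        selection_criteria=SelectionCriteria(
            age_min=crit.get("age_min"),
            age_max=crit.get("age_max"),
            sex=crit.get("sex"),
            countries=tuple(crit.get("countries", [])),
            other=crit.get("other"),
        ),
        number_of_participants=d.get("number_of_participants"),
        data_collection_events=tuple(
            _dce_from_dict(e) for e in d.get("data_collection_events", [])
        ),
    )


def _dce_from_dict(d: Mapping[str, Any]) -> DataCollectionEvent:
    return DataCollectionEvent(
        id=str(d["id"]),
        name=d.get("name", ""),
        description=d.get("description", ""),
        start_date=PartialDate.parse(d["start_date"]) if d.get("start_date") else None,
        end_date=PartialDate.parse(d["end_date"]) if d.get("end_date") else None,
        data_sources=frozenset(d.get("data_sources", [])),
    )


def dataset_to_dict(dataset: Dataset) -> dict:
    """Dataset descriptor (no variables — those live in the dictionary CSVs)."""
    d: dict[str, Any] = {"id": dataset.id, "name": dataset.name, "description": dataset.description}
    if dataset.link is not None:
        d["link"] = {
            "study_id": dataset.link.study_id,
            "population_id": dataset.link.population_id,
            "dce_id": dataset.link.dce_id,
        }
    annotations = {
        v.name: sorted(f"{dom}/{term}" for dom, term in v.annotations)
        for v in dataset.variables
        if v.annotations
    }
    if annotations:
        d["annotations"] = annotations
    return d


def dataset_from_dict(d: Mapping[str, Any], variables: Iterable[Variable] = ()) -> Dataset:
    link = d.get("link")
    variables = tuple(variables)
    annotations: Mapping[str, list[str]] = d.get("annotations") or {}
    if annotations:
        annotated = []
        for v in variables:
            refs = annotations.get(v.name)
            if refs:
                pairs = frozenset(tuple(r.split("/", 1)) for r in refs)
                v = replace(v, annotations=pairs)
            annotated.append(v)
        variables = tuple(annotated)
    return Dataset(
        id=str(d["id"]),
        name=d.get("name", ""),
        description=d.get("description", ""),
        link=DatasetLink(link["study_id"], link["population_id"], link["dce_id"]) if link else None,
        variables=variables,
    )


def dump_study_yaml(study: Study) -> str:
    return yaml.safe_dump(study_to_dict(study), sort_keys=False, allow_unicode=True)


def load_study_yaml(text: str) -> Study:
    return study_from_dict(yaml.safe_load(text))
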
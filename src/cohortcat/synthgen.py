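"""Deterministic synthetic-data generators.

Three generators back the test suite and the CLI: random catalogues for
property tests, the packaged two-study comparison-table fixture expanded
into a fully annotated catalogue, and labelled variables with controllable
vocabulary overlap for classifier evaluation. Every generator threads a
single ``random.Random(seed)`` instance — no global RNG — so identical specs
produce byte-identical serialized output across processes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .model import (
    Access,
    Category,
    DataCollectionEvent,
    Dataset,
    DatasetLink,
    PartialDate,
    Person,
    Population,
    SelectionCriteria,
    Study,
    Variable,
)
from .taxonomy import Taxonomy, TermRef, builtin_taxonomy

__all__ = [
    "CatalogueSpec",
    "LabelledSetSpec",
    "generate_catalogue",
    "table3_fixture",
    "generate_labelled_variables",
]

_WORDS = (
    "age weight height smoking alcohol diet income education housing sleep "
    "blood pressure cholesterol glucose activity stress employment marital "
    "birth pregnancy child vaccine allergy asthma diabetes heart cancer "
    "medication vitamin supplement hospital visit symptom pain fatigue mood "
    "anxiety memory reading work school neighbourhood air noise water"
).split()

_SOURCES = ("questionnaires", "physical_measures", "biological_samples", "administrative_databases")
_COUNTRIES = ("CA", "FR", "GB", "SE", "CH", "NL")


@dataclass(frozen=True)
class CatalogueSpec:
    n_studies: int = 3
    populations_per_study: tuple[int, int] = (1, 2)
    dces_per_population: tuple[int, int] = (1, 3)
    variables_per_dce: tuple[int, int] = (2, 8)
    annotation_rate: float = 0.8
    taxonomy: Optional[Taxonomy] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("populations_per_study", "dces_per_population", "variables_per_dce"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name}: empty range ({lo}, {hi})")
        if not (0.0 <= self.annotation_rate <= 1.0):
            raise ValueError(f"annotation_rate must be in [0,1], got {self.annotation_rate}")
        if self.n_studies < 0:
            raise ValueError("n_studies must be non-negative")


def _label(rng: random.Random) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(rng.randint(2, 4)))


def _variable(rng: random.Random, name: str, refs: list[TermRef], rate: float) -> Variable:
    value_type = rng.choice(("integer", "decimal", "text", "boolean"))
    categories: tuple[Category, ...] = ()
    if rng.random() < 0.4:
        n = rng.randint(2, 4)
        categories = tuple(Category(code=str(i), label=f"level {i}") for i in range(n))
        if rng.random() < 0.5:
            categories += (Category(code="9", label="Missing", is_missing=True),)
        value_type = "integer"
    annotations = frozenset()
    if rng.random() < rate and refs:
        annotations = frozenset(rng.sample(refs, k=rng.randint(1, min(2, len(refs)))))
    return Variable(
        name=name,
        label=_label(rng),
        value_type=value_type,
        unit=rng.choice(("years", "kg", "cm", None)),
        question_text=_label(rng) + "?" if rng.random() < 0.5 else None,
        categories=categories,
        annotations=annotations,
    )


def generate_catalogue(spec: CatalogueSpec) -> tuple[list[Study], list[Dataset]]:
    """Random catalogue passing every validator with zero errors."""
    rng = random.Random(spec.seed)
    taxonomy = spec.taxonomy or builtin_taxonomy()
    refs = taxonomy.term_refs()
    studies: list[Study] = []
    datasets: list[Dataset] = []
    for s in range(1, spec.n_studies + 1):
        sid = f"study{s}"
        populations = []
        for p in range(1, rng.randint(*spec.populations_per_study) + 1):
            pid = f"pop{p}"
            age_min = rng.choice((None, 0, 18, 45))
            age_max = None if age_min is None else age_min + rng.randint(10, 60)
            dces = []
            year = rng.randint(1990, 2015)
            for e in range(1, rng.randint(*spec.dces_per_population) + 1):
                did = f"dce{e}"
                start = year + e - 1
                dces.append(
                    DataCollectionEvent(
                        id=did,
                        name=f"Wave {e}",
                        description=_label(rng),
                        start_date=PartialDate(start),
                        end_date=PartialDate(start + rng.randint(0, 2)),
                        data_sources=frozenset(
                            rng.sample(_SOURCES, k=rng.randint(1, len(_SOURCES)))
                        ),
                    )
                )
                n_vars = rng.randint(*spec.variables_per_dce)
                datasets.append(
                    Dataset(
                        id=f"{sid}_{pid}_{did}_ds",
                        name=f"{sid} {pid} wave {e} dataset",
                        description=_label(rng),
                        link=DatasetLink(sid, pid, did),
                        variables=tuple(
                            _variable(rng, f"v{i}", refs, spec.annotation_rate)
                            for i in range(1, n_vars + 1)
                        ),
                    )
                )
            populations.append(
                Population(
                    id=pid,
                    name=f"Population {p}",
                    description=_label(rng),
                    recruitment_sources=frozenset({rng.choice(("general_population", "specific_population"))}),
                    selection_criteria=SelectionCriteria(
                        age_min=age_min,
                        age_max=age_max,
                        sex=rng.choice(("female", "male", "all")),
                        countries=(rng.choice(_COUNTRIES),),
                    ),
                    number_of_participants=rng.randint(100, 20000),
                    data_collection_events=tuple(dces),
                )
            )
        n_participants = rng.randint(500, 100000)
        studies.append(
            Study(
                id=sid,
                name=f"Synthetic Study {s}",
                acronym=f"SS{s}",
                objectives=_label(rng),
                website=f"https://example.org/{sid}",
                investigators=(Person(name=f"Investigator {s}", role="PI"),),
                contacts=(Person(name=f"Contact {s}", email=f"contact{s}@example.org"),),
                start_year=rng.randint(1980, 2010),
                end_year=rng.choice((None, 2030)),
                number_of_participants=n_participants,
                number_with_samples=rng.randint(0, n_participants),
                access=Access(data="on request", samples="on request"),
                populations=tuple(populations),
            )
        )
    return studies, datasets


def table3_fixture() -> tuple[list[Study], list[Dataset], tuple[list[TermRef], list[str]]]:
    """Expand the packaged two-birth-cohort comparison transcription.

    For every (event, term) cell value k the expansion creates exactly k
    variables annotated with that term, attached to one dataset per event.
    Returns (studies, datasets, (selected term refs, selected study ids)).
    Pure: repeated calls return structurally identical objects.
    """
    doc = json.loads(
        resources.files("cohortcat.data").joinpath("table3.json").read_text("utf-8")
    )
    columns = [TermRef(c["domain"], c["term"]) for c in doc["columns"]]
    studies: list[Study] = []
    datasets: list[Dataset] = []
    for sdoc in doc["studies"]:
        sid = sdoc["id"]
        populations = []
        for pdoc in sdoc["populations"]:
            pid = pdoc["id"]
            dces = []
            for edoc in pdoc["events"]:
                eid = edoc["id"]
                dces.append(
                    DataCollectionEvent(
                        id=eid,
                        name=edoc["name"],
                        description=f"{pdoc['name']} — {edoc['name']}",
                        start_date=PartialDate(sdoc["start_year"]),
                        data_sources=frozenset({"questionnaires"}),
                    )
                )
                variables = []
                for col, count in enumerate(edoc["counts"]):
                    ref = columns[col]
                    for k in range(1, count + 1):
                        variables.append(
                            Variable(
                                name=f"v{eid}_c{col}_{k}",
                                label=f"{ref.term_name} item {k} at {edoc['name']}",
                                value_type="text",
                                annotations=frozenset({ref}),
                            )
                        )
                datasets.append(
                    Dataset(
                        id=f"{sid}_{pid}_{eid}",
                        name=f"{sdoc['name']} {pdoc['name']} {edoc['name']}",
                        description="expanded comparison-table cell counts",
                        link=DatasetLink(sid, pid, eid),
                        variables=tuple(variables),
                    )
                )
            populations.append(
                Population(
                    id=pid,
                    name=pdoc["name"],
                    description=f"{pdoc['name']} of {sdoc['name']}",
                    recruitment_sources=frozenset({"general_population"}),
                    data_collection_events=tuple(dces),
                )
            )
        studies.append(
            Study(
                id=sid,
                name=sdoc["name"],
                acronym=sdoc["acronym"],
                objectives=f"Birth cohort: {sdoc['name']}",
                start_year=sdoc["start_year"],
                access=Access(data="on request"),
                populations=tuple(populations),
            )
        )
    return studies, datasets, (columns, [s["id"] for s in doc["studies"]])


@dataclass(frozen=True)
class LabelledSetSpec:
    n_classes: int = 5
    n_examples: int = 500
    tokens_per_label: tuple[int, int] = (3, 8)
    vocab_size_per_class: int = 30
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0,1]")
        lo, hi = self.tokens_per_label
        if lo > hi or lo < 1:
            raise ValueError(f"tokens_per_label: bad range ({lo}, {hi})")
        if self.n_examples < 1 or self.vocab_size_per_class < 1:
            raise ValueError("n_examples and vocab_size_per_class must be >= 1")


def generate_labelled_variables(spec: LabelledSetSpec) -> list[tuple[Variable, TermRef]]:
    """Labelled variables whose per-class vocabularies share a controlled
    fraction of tokens with a common pool.

    Each class vocabulary has ``vocab_size_per_class`` tokens of which
    ``round(overlap_fraction * size)`` come from a pool shared by all
    classes; the rest are class-unique. Labels are bags of tokens drawn
    uniformly from the class vocabulary. Classes are balanced (round-robin).
    """
    rng = random.Random(spec.seed)
    n_shared = round(spec.overlap_fraction * spec.vocab_size_per_class)
    shared = [f"shared{i}" for i in range(n_shared)]
    classes = [TermRef("synthetic", f"class{c}") for c in range(spec.n_classes)]
    vocabs = {
        ref: shared + [f"c{c}tok{i}" for i in range(spec.vocab_size_per_class - n_shared)]
        for c, ref in enumerate(classes)
    }
    out: list[tuple[Variable, TermRef]] = []
    for j in range(spec.n_examples):
        ref = classes[j % spec.n_classes]
        n_tokens = rng.randint(*spec.tokens_per_label)
        label = " ".join(rng.choice(vocabs[ref]) for _ in range(n_tokens))
        out.append((Variable(name=f"x{j}", label=label, value_type="text"), ref))
    return out
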
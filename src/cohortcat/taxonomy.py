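"""Variable-classification taxonomy (domains -> terms) and annotation machinery.

The packaged taxonomy has 18 domains and 135 terms in total. Only a handful
of term names are publicly fixed (Education; Income, possessions, and
benefits; Tobacco; Alcohol; Pregnancy, childbirth and the puerperium
(O00-O9A)); remaining terms carry stable ``<domain-slug>_sub<k>`` placeholder
names so that counts — the contract — are exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import NamedTuple, Optional

import yaml

from .model import Dataset, ValidationReport, Variable

__all__ = [
    "TermRef",
    "Term",
    "Domain",
    "Taxonomy",
    "TaxonomyError",
    "AnnotationError",
    "load_taxonomy",
    "save_taxonomy",
    "builtin_taxonomy",
    "annotate_variable",
    "validate_annotations",
    "parse_term_ref",
]


class TaxonomyError(ValueError):
    """Raised on a structurally invalid taxonomy document."""


class AnnotationError(ValueError):
    """Raised when a term reference does not resolve against the taxonomy."""


class TermRef(NamedTuple):
    """Reference to one term: ``(domain_name, term_name)``.

    A NamedTuple so it compares and hashes equal to a plain 2-tuple — the
    metadata model stores annotations as bare pairs without importing this
    module.
    """

    domain_name: str
    term_name: str

    def __str__(self) -> str:
        return f"{self.domain_name}/{self.term_name}"


def parse_term_ref(text: str) -> TermRef:
    """Parse ``"Domain/Term"`` (first slash splits; term may contain none)."""
    if "/" not in text:
        raise ValueError(f"term reference must be 'Domain/Term', got {text!r}")
    domain, term = text.split("/", 1)
    return TermRef(domain, term)


@dataclass(frozen=True)
class Term:
    name: str
    label: str = ""
    keywords: tuple[str, ...] = ()


@dataclass(frozen=True)
class Domain:
    name: str
    description: Optional[str] = None
    terms: tuple[Term, ...] = ()


@dataclass(frozen=True)
class Taxonomy:
    name: str = ""
    version: str = ""
    domains: tuple[Domain, ...] = ()

    def domain(self, name: str) -> Optional[Domain]:
        for d in self.domains:
            if d.name == name:
                return d
        return None

    def resolve(self, ref: TermRef) -> Optional[Term]:
        """Exact, case-sensitive lookup; None when unresolvable."""
        d = self.domain(ref[0])
        if d is None:
            return None
        for t in d.terms:
            if t.name == ref[1]:
                return t
        return None

    @property
    def term_count(self) -> int:
        return sum(len(d.terms) for d in self.domains)

    def term_refs(self) -> list[TermRef]:
        return [TermRef(d.name, t.name) for d in self.domains for t in d.terms]


def load_taxonomy(document: str) -> Taxonomy:
    """Parse a YAML taxonomy document; duplicate domain/term names are errors."""
    data = yaml.safe_load(document) or {}
    domains: list[Domain] = []
    seen_domains: set[str] = set()
    for ddict in data.get("domains") or []:
        dname = str(ddict["name"])
        if dname in seen_domains:
            raise TaxonomyError(f"duplicate domain name {dname!r}")
        seen_domains.add(dname)
        terms: list[Term] = []
        seen_terms: set[str] = set()
        for tdict in ddict.get("terms") or []:
            tname = str(tdict["name"])
            if not tname:
                raise TaxonomyError(f"empty term name in domain {dname!r}")
            if tname in seen_terms:
                raise TaxonomyError(f"duplicate term {tname!r} in domain {dname!r}")
            seen_terms.add(tname)
            terms.append(
                Term(
                    name=tname,
                    label=tdict.get("label", tname),
                    keywords=tuple(tdict.get("keywords") or ()),
                )
            )
        domains.append(Domain(name=dname, description=ddict.get("description"), terms=tuple(terms)))
    return Taxonomy(
        name=data.get("name", ""), version=str(data.get("version", "")), domains=tuple(domains)
    )


def save_taxonomy(taxonomy: Taxonomy) -> str:
    doc = {
        "name": taxonomy.name,
        "version": taxonomy.version,
        "domains": [
            {
                "name": d.name,
                **({"description": d.description} if d.description else {}),
                "terms": [
                    {
                        "name": t.name,
                        "label": t.label,
                        **({"keywords": list(t.keywords)} if t.keywords else {}),
                    }
                    for t in d.terms
                ],
            }
            for d in taxonomy.domains
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


@lru_cache(maxsize=1)
def builtin_taxonomy() -> Taxonomy:
    """The packaged 18-domain / 135-term variable classification."""
    text = resources.files("cohortcat.data").joinpath("taxonomy.yaml").read_text("utf-8")
    return load_taxonomy(text)


def slugify(text: str) -> str:
    """Lowercase token slug: non-alphanumeric runs collapse to underscores."""
    return re.sub(r"[^a-z0-9]+", "_", text.lower()).strip("_")


def annotate_variable(variable: Variable, ref: TermRef, taxonomy: Taxonomy) -> Variable:
    """Return a copy of *variable* with *ref* added to its annotation set.

    Set semantics: re-annotating with an existing ref is a no-op. The input
    variable is never modified.
    """
    ref = TermRef(*ref)
    if taxonomy.resolve(ref) is None:
        raise AnnotationError(
            f"term {ref.term_name!r} in domain {ref.domain_name!r} not found in taxonomy"
        )
    return replace(variable, annotations=variable.annotations | {ref})


def validate_annotations(dataset: Dataset, taxonomy: Taxonomy) -> ValidationReport:
    """Error per unresolvable annotation; warning per unannotated variable."""
    report = ValidationReport()
    for var in dataset.variables:
        vpath = f"dataset[{dataset.id}].variables[{var.name}]"
        if not var.annotations:
            report.add("warning", vpath, "variable has no annotations")
            continue
        for ref in sorted(var.annotations):
            if taxonomy.resolve(TermRef(*ref)) is None:
                report.add(
                    "error",
                    vpath,
                    f"annotation {ref[0]}/{ref[1]} does not resolve against taxonomy "
                    f"{taxonomy.name!r}",
                )
    return report
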
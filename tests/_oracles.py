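"""Independent brute-force oracles for the search module.

Deliberately written without touching the package's indexes or tokenizer:
a linear scan over the raw entities with its own tokenization, so that
agreement with the indexed engine is a meaningful check.
"""

from __future__ import annotations

import random


def scan_tokenize(text):
    out, cur = [], []
    for ch in text.casefold():
        if ch.isalnum():
            cur.append(ch)
        else:
            if cur:
                out.append("".join(cur))
                cur = []
    if cur:
        out.append("".join(cur))
    return out


def _variable_tokens(var):
    toks = set(scan_tokenize(var.label)) | set(scan_tokenize(var.name))
    if var.question_text:
        toks |= set(scan_tokenize(var.question_text))
    return toks


def scan_variables(studies, datasets, query):
    """All (study_id, dataset_id, variable_name) locators matching *query*."""
    hits = []
    for ds in datasets:
        if ds.link is None:
            continue
        if query.study_id is not None and ds.link.study_id != query.study_id:
            continue
        if query.population_id is not None and ds.link.population_id != query.population_id:
            continue
        if query.dce_id is not None and ds.link.dce_id != query.dce_id:
            continue
        for var in ds.variables:
            toks = _variable_tokens(var)
            ok = True
            for q in query.text:
                q = q.casefold()
                if q.endswith("*"):
                    if not any(t.startswith(q[:-1]) for t in toks):
                        ok = False
                        break
                elif q not in toks:
                    ok = False
                    break
            if not ok:
                continue
            if query.terms:
                refs = {tuple(r) for r in var.annotations}
                if not refs & {tuple(t) for t in query.terms}:
                    continue
            hits.append((ds.link.study_id, ds.id, var.name))
    return sorted(hits)


def scan_studies(studies, query):
    """All study ids matching every supplied StudyQuery clause."""
    out = []
    for s in studies:
        if query.participants_min is not None and (
            s.number_of_participants is None
            or s.number_of_participants < query.participants_min
        ):
            continue
        if query.participants_max is not None and (
            s.number_of_participants is None
            or s.number_of_participants > query.participants_max
        ):
            continue
        if query.start_year_range is not None:
            lo, hi = query.start_year_range
            if s.start_year is None or s.start_year < lo or s.start_year > hi:
                continue
        if query.countries:
            all_countries = set()
            for p in s.populations:
                all_countries |= set(p.selection_criteria.countries)
            if not all_countries & set(query.countries):
                continue
        if query.data_sources:
            tags = set()
            for p in s.populations:
                for e in p.data_collection_events:
                    tags |= set(e.data_sources)
            if not set(query.data_sources).issubset(tags):
                continue
        if query.age_range is not None:
            qlo, qhi = query.age_range
            if not any(
                (p.selection_criteria.age_min is None or p.selection_criteria.age_min <= qhi)
                and (p.selection_criteria.age_max is None or qlo <= p.selection_criteria.age_max)
                for p in s.populations
            ):
                continue
        out.append(s.id)
    return sorted(out)


_QUERY_WORDS = (
    "age weight smoking alcohol diet income sleep blood glucose stress "
    "birth child vaccine asthma diabetes heart pain mood memory work air"
).split()


def random_variable_query(rng: random.Random, catalogue_terms, studies):
    """Seeded random VariableQuery over realistic clause combinations."""
    from cohortcat.search import VariableQuery

    text = []
    if rng.random() < 0.7:
        for _ in range(rng.randint(1, 2)):
            w = rng.choice(_QUERY_WORDS)
            if rng.random() < 0.3:
                w = w[: rng.randint(2, max(2, len(w) - 1))] + "*"
            text.append(w)
    terms = tuple(rng.sample(catalogue_terms, k=rng.randint(1, 3))) if rng.random() < 0.5 else ()
    study_id = population_id = dce_id = None
    if studies and rng.random() < 0.4:
        s = rng.choice(studies)
        study_id = s.id
        if s.populations and rng.random() < 0.5:
            p = rng.choice(s.populations)
            population_id = p.id
            if p.data_collection_events and rng.random() < 0.5:
                dce_id = rng.choice(p.data_collection_events).id
    return VariableQuery(
        text=tuple(text), terms=terms, study_id=study_id,
        population_id=population_id, dce_id=dce_id,
    )


def random_study_query(rng: random.Random):
    from cohortcat.search import StudyQuery

    kwargs = {}
    if rng.random() < 0.5:
        kwargs["participants_min"] = rng.randint(0, 60000)
    if rng.random() < 0.4:
        lo = kwargs.get("participants_min", 0)
        kwargs["participants_max"] = lo + rng.randint(0, 80000)
    if rng.random() < 0.4:
        lo = rng.randint(1980, 2010)
        kwargs["start_year_range"] = (lo, lo + rng.randint(0, 25))
    if rng.random() < 0.4:
        kwargs["countries"] = tuple(rng.sample(("CA", "FR", "GB", "SE", "CH", "NL", "US"), k=rng.randint(1, 3)))
    if rng.random() < 0.4:
        kwargs["data_sources"] = frozenset(
            rng.sample(("questionnaires", "physical_measures", "biological_samples"), k=rng.randint(1, 2))
        )
    if rng.random() < 0.3:
        lo = rng.choice((0, 10, 18, 40, 65))
        kwargs["age_range"] = (float(lo), float(lo + rng.randint(0, 40)))
    return StudyQuery(**kwargs)
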
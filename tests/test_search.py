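import random

import pytest

from cohortcat.model import Dataset, DatasetLink, Variable
from cohortcat.search import (
    CatalogueBuildError,
    QueryError,
    StudyQuery,
    VariableQuery,
    build_index,
    facet_counts,
    search_studies,
    search_variables,
    tokenize,
)
from cohortcat.synthgen import CatalogueSpec, generate_catalogue
from cohortcat.taxonomy import TermRef

from _oracles import random_study_query, random_variable_query, scan_studies, scan_variables

TOBACCO = TermRef("Lifestyle and behaviours", "Tobacco")


class TestTokenize:
    def test_casefold_and_split(self):
        assert tokenize("Current Smoker (cigarettes/day)!") == [
            "current", "smoker", "cigarettes", "day",
        ]

    def test_underscore_splits(self):
        assert tokenize("v_name_2") == ["v", "name", "2"]

    def test_empty(self):
        assert tokenize("  --  ") == []


class TestBuildIndex:
    def test_table3_has_two_studies(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        assert set(catalogue.studies) == {"AOBF", "APrON"}

    def test_empty_inputs(self, taxonomy):
        catalogue = build_index([], [], taxonomy)
        assert len(search_variables(catalogue, VariableQuery())) == 0
        assert len(search_studies(catalogue, StudyQuery())) == 0

    def test_rebuild_identical(self, table3, taxonomy):
        studies, datasets, _ = table3
        a = build_index(studies, datasets, taxonomy)
        b = build_index(studies, datasets, taxonomy)
        assert a.text_index == b.text_index and a.term_index == b.term_index

    def test_refuses_dangling_link(self, taxonomy):
        ds = Dataset(id="DS", link=DatasetLink("ghost", "p", "d"))
        with pytest.raises(CatalogueBuildError) as exc:
            build_index([], [ds], taxonomy)
        assert not exc.value.report.ok()

    def test_refuses_dangling_annotation(self, table3, taxonomy):
        studies, datasets, _ = table3
        bad = Dataset(
            id="bad",
            link=datasets[0].link,
            variables=(Variable(name="v", annotations=frozenset({TermRef("Ghost", "X")})),),
        )
        with pytest.raises(CatalogueBuildError):
            build_index(studies, list(datasets) + [bad], taxonomy)

    def test_scan_equivalence_on_fixture(self, table3, table3_catalogue):
        studies, datasets, (columns, _) = table3
        catalogue, _ = table3_catalogue
        query = VariableQuery(terms=(columns[2], columns[3]))
        indexed = sorted(h.locator for h in search_variables(catalogue, query).hits)
        assert indexed == scan_variables(studies, datasets, query)


class TestSearchStudies:
    def test_no_filters_all_studies_lexicographic(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        result = search_studies(catalogue, StudyQuery())
        assert result.locators() == ["AOBF", "APrON"]
        assert all(h.score == 0 for h in result.hits)

    def test_participants_min_too_large(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        assert len(search_studies(catalogue, StudyQuery(participants_min=10**9))) == 0

    def test_start_year_filter(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        result = search_studies(catalogue, StudyQuery(start_year_range=(2009, 2009)))
        assert result.locators() == ["APrON"]
        assert result.hits[0].score == 1

    def test_malformed_range_raises(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        with pytest.raises(QueryError):
            search_studies(catalogue, StudyQuery(participants_min=10, participants_max=5))


class TestSearchVariables:
    def test_tobacco_scoped_to_apron_first_trimester(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        result = search_variables(
            catalogue,
            VariableQuery(terms=(TOBACCO,), study_id="APrON",
                          population_id="mothers", dce_id="tri1"),
        )
        assert len(result) == 15

    def test_text_tokens_conjunctive(self, taxonomy, smoke_dataset_catalogue):
        catalogue = smoke_dataset_catalogue
        result = search_variables(catalogue, VariableQuery(text=("current", "smoker")))
        assert [loc[2] for loc in result.locators()] == ["smoke"]

    def test_prefix_token(self, smoke_dataset_catalogue):
        result = search_variables(smoke_dataset_catalogue, VariableQuery(text=("smok*",)))
        assert [loc[2] for loc in result.locators()] == ["smoke"]

    def test_empty_catalogue_zero_hits(self, taxonomy):
        catalogue = build_index([], [], taxonomy)
        assert len(search_variables(catalogue, VariableQuery(text=("anything",)))) == 0

    def test_unresolvable_term_raises(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        with pytest.raises(QueryError):
            search_variables(catalogue, VariableQuery(terms=(TermRef("Ghost", "X"),)))

    def test_match_all_query(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        assert len(search_variables(catalogue, VariableQuery())) == len(catalogue.variables)

    def test_score_counts_tokens_and_terms(self, smoke_dataset_catalogue):
        result = search_variables(
            smoke_dataset_catalogue,
            VariableQuery(text=("current", "smoker"), terms=(TOBACCO,)),
        )
        assert result.hits[0].score == 3  # 2 tokens + 1 matched term

    def test_deterministic_ordering(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        q = VariableQuery(terms=(TOBACCO,))
        assert search_variables(catalogue, q) == search_variables(catalogue, q)


@pytest.fixture()
def smoke_dataset_catalogue(taxonomy, smoke_dataset, table3):
    """The 2-variable dictionary fixture attached to an AOBF event, with
    `smoke` annotated Tobacco."""
    from dataclasses import replace

    studies, _, _ = table3
    variables = []
    for v in smoke_dataset.variables:
        if v.name == "smoke":
            v = replace(v, annotations=frozenset({TOBACCO}))
        variables.append(v)
    ds = replace(
        smoke_dataset, id="smokeds", link=DatasetLink("AOBF", "mothers", "gest24w"),
        variables=tuple(variables),
    )
    return build_index(studies, [ds], taxonomy)


class TestFacets:
    def test_match_all_by_study_equals_per_study_totals(self, table3, table3_catalogue):
        studies, datasets, _ = table3
        catalogue, _ = table3_catalogue
        counts = facet_counts(catalogue, VariableQuery(), "study")
        expected = {}
        for ds in datasets:
            expected[ds.link.study_id] = expected.get(ds.link.study_id, 0) + len(ds.variables)
        assert counts == expected

    def test_zero_hit_query_empty_mapping(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        assert facet_counts(catalogue, VariableQuery(text=("zzznope",)), "term") == {}

    def test_term_facet_sums_can_exceed_match_set(self, taxonomy, table3):
        from dataclasses import replace

        studies, _, _ = table3
        alcohol = TermRef("Lifestyle and behaviours", "Alcohol")
        var = Variable(name="both", label="drinks and smokes",
                       annotations=frozenset({TOBACCO, alcohol}))
        ds = Dataset(id="multi", link=DatasetLink("AOBF", "mothers", "gest24w"),
                     variables=(var,))
        catalogue = build_index(studies, [ds], taxonomy)
        counts = facet_counts(catalogue, VariableQuery(), "term")
        assert sum(counts.values()) == 2 > 1
        assert facet_counts(catalogue, VariableQuery(), "domain") == {
            "Lifestyle and behaviours": 2
        }

    def test_unknown_facet(self, table3_catalogue):
        catalogue, _ = table3_catalogue
        with pytest.raises(QueryError):
            facet_counts(catalogue, VariableQuery(), "colour")


class TestScanEquivalenceProperty:
    """Indexed search == brute-force linear scan on seeded random inputs.

    A reduced version runs here; the full 50x20 criterion lives in
    test_acceptance.py.
    """

    @pytest.mark.parametrize("seed", range(10))
    def test_variables_agree_with_oracle(self, seed, taxonomy):
        studies, datasets = generate_catalogue(
            CatalogueSpec(n_studies=3, variables_per_dce=(0, 15), seed=seed)
        )
        catalogue = build_index(studies, datasets, taxonomy)
        terms = taxonomy.term_refs()
        rng = random.Random(1000 + seed)
        for _ in range(10):
            query = random_variable_query(rng, terms, studies)
            indexed = sorted(h.locator for h in search_variables(catalogue, query).hits)
            assert indexed == scan_variables(studies, datasets, query)

    @pytest.mark.parametrize("seed", range(10))
    def test_studies_agree_with_oracle(self, seed, taxonomy):
        studies, datasets = generate_catalogue(CatalogueSpec(n_studies=5, seed=seed))
        catalogue = build_index(studies, datasets, taxonomy)
        rng = random.Random(2000 + seed)
        for _ in range(10):
            query = random_study_query(rng)
            indexed = sorted(h.locator for h in search_studies(catalogue, query).hits)
            assert indexed == scan_studies(studies, query)

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_clause_never_enlarges_hits(self, seed, taxonomy):
        studies, datasets = generate_catalogue(CatalogueSpec(seed=seed))
        catalogue = build_index(studies, datasets, taxonomy)
        rng = random.Random(3000 + seed)
        terms = taxonomy.term_refs()
        for _ in range(10):
            q = random_variable_query(rng, terms, studies)
            base = set(h.locator for h in search_variables(catalogue, q).hits)
            narrowed = VariableQuery(
                text=q.text + ("smoking",), terms=q.terms,
                study_id=q.study_id, population_id=q.population_id, dce_id=q.dce_id,
            )
            assert set(h.locator for h in search_variables(catalogue, narrowed).hits) <= base
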
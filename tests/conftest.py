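import pytest

from cohortcat.classifier import train_classifier
from cohortcat.dictionary_io import DIALECTS, read_dictionary
from cohortcat.model import Variable
from cohortcat.search import build_index
from cohortcat.synthgen import table3_fixture
from cohortcat.taxonomy import TermRef, builtin_taxonomy

# inline dictionary fixture: two variables, `smoke` with 3 categories (1 missing)
VARIABLES_CSV = (
    "name,label,valueType,unit\n"
    'age,"Age of participant",integer,years\n'
    'smoke,"Current smoker",integer,\n'
)
CATEGORIES_CSV = (
    "variable,code,label,missing\n"
    "smoke,0,No,false\n"
    "smoke,1,Yes,false\n"
    "smoke,9,Refused,true\n"
)


@pytest.fixture(scope="session")
def taxonomy():
    return builtin_taxonomy()


@pytest.fixture(scope="session")
def table3():
    """(studies, datasets, (columns, study_ids)) from the packaged fixture."""
    return table3_fixture()


@pytest.fixture(scope="session")
def table3_catalogue(table3, taxonomy):
    studies, datasets, selection = table3
    return build_index(studies, datasets, taxonomy), selection


@pytest.fixture()
def smoke_dataset():
    return read_dictionary(VARIABLES_CSV, CATEGORIES_CSV, DIALECTS["plain_csv"])


@pytest.fixture(scope="session")
def toy_examples():
    return [
        (Variable(name="ex1", label="alcohol wine"), TermRef("toy", "A")),
        (Variable(name="ex2", label="tobacco smoke"), TermRef("toy", "B")),
    ]


@pytest.fixture(scope="session")
def toy_model(toy_examples):
    return train_classifier(toy_examples, alpha=1.0)
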
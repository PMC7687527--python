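import pytest

from mttt.reference_model import load_catalog, load_gene_model, load_haplogroup_tree
from mttt.synthetic import load_alignment_spec, load_cohort_spec


@pytest.fixture(scope="session")
def model():
    return load_gene_model()


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def tree():
    return load_haplogroup_tree()


@pytest.fixture(scope="session")
def cohort_spec():
    return load_cohort_spec(seed=11)


@pytest.fixture(scope="session")
def alignment_spec():
    return load_alignment_spec(seed=11)


@pytest.fixture(scope="session")
def study_result():
    """One full default study run shared across tests."""
    from mttt.pipeline import run_study

    return run_study(seed=11)
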
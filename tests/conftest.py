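import pytest

from melosem import study_params, feature_table, generate_corpus


@pytest.fixture(scope="session")
def study_corpus():
    """The default 19-pianist x 32-word synthetic corpus, seed 0."""
    return generate_corpus(study_params())


@pytest.fixture(scope="session")
def study_table(study_corpus):
    """Feature table of the default corpus (computed once per session)."""
    return feature_table(study_corpus)
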
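import pytest

from lcmvar.io_formats import CallerConfig, load_cohort_variants, load_panel


@pytest.fixture(scope="session")
def cohort_records():
    return load_cohort_variants()


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture
def config():
    return CallerConfig()
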
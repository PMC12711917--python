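import pytest

from calmlobe import datasets


@pytest.fixture(scope="session")
def schema_records():
    return datasets.schema_carriers()


@pytest.fixture(scope="session")
def schema_counts(schema_records):
    return datasets.schema_strata_counts(schema_records)
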
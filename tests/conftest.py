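import pytest
from hypothesis import HealthCheck, settings

from sigpep import io_formats, sp_properties

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def screened_table():
    """The packaged 29-peptide screening table: (records, reference frame)."""
    return io_formats.load_screened_peptides()


@pytest.fixture(scope="session")
def screened_records(screened_table):
    return screened_table[0]


@pytest.fixture(scope="session")
def screened_df(screened_table):
    return screened_table[1]


@pytest.fixture(scope="session")
def secretion_labels(screened_df):
    return dict(zip(screened_df.id, screened_df.secretion))


@pytest.fixture(scope="session")
def helix_flags(screened_df):
    return {row.id: bool(row.tm_helix) for row in screened_df.itertuples()}


@pytest.fixture(scope="session")
def screened_props(screened_records, helix_flags):
    return sp_properties.property_table(screened_records, helix_flags)
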
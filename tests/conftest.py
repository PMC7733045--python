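import pandas as pd
import pytest

from h2020index import (
    apply_country_filter,
    compute_index_table,
    load_registry,
    make_fixture_roster,
)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def roster(registry):
    """Packaged deterministic 53-country fixture: (ObservationTable, metadata)."""
    return make_fixture_roster(registry)


@pytest.fixture(scope="session")
def roster_index(registry, roster):
    table, _ = roster
    return compute_index_table(table, registry)


def make_raw(rows):
    """Raw long-format frame from (country, indicator_id, year, value) tuples."""
    return pd.DataFrame(rows, columns=["country", "indicator_id", "year", "value"])
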
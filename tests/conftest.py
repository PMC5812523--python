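import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from raretaxa import OtuTable, SyntheticSpec, generate, to_relative_abundance

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 OTUs x 2 samples with known totals (8, 8, 4)."""
    return OtuTable(
        pd.DataFrame(
            [[6, 2], [3, 5], [1, 3]],
            index=["otu1", "otu2", "otu3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture(scope="session")
def default_community():
    """One seeded default synthetic community shared across tests."""
    return generate(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def default_relabund(default_community):
    table, _meta, _truth = default_community
    return to_relative_abundance(table)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
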
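import pandas as pd
import pytest

from isomirflow import classify as cls
from isomirflow import synthetic as syn

MIXED_PROPORTIONS = {
    "identical": 0.40,
    "shorter": 0.15,
    "end_sub": 0.08,
    "end_add": 0.08,
    "internal_mm": 0.08,
    "precursor_only": 0.06,
    "contaminant": 0.08,
    "junk": 0.07,
}


@pytest.fixture(scope="session")
def reference_set():
    return syn.simulate_reference_set(n_mirnas=40, seed=101)


@pytest.fixture(scope="session")
def ref_index(reference_set):
    return cls.build_index(reference_set.mature, reference_set.precursor)


@pytest.fixture(scope="session")
def mixed_reads(reference_set):
    """A moderate mixed-class read fixture shared across unit tests."""
    reads, truth = syn.simulate_reads(
        reference_set, MIXED_PROPORTIONS, n_reads=4000, seed=202)
    return reads, truth


@pytest.fixture
def toy_de_table():
    """A small hand-built called DE table."""
    return pd.DataFrame(
        {
            "log2fc": [0.5, -1.5, 2.5, 0.2, -0.4],
            "pvalue": [0.001, 0.002, 0.003, 0.2, 0.5],
            "fdr": [0.005, 0.005, 0.005, 0.25, 0.5],
            "is_de": [True, True, True, False, False],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
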
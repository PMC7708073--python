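import numpy as np
import pytest

from hybridnn import builtin_set, load_reference_table, reference_duplexes


@pytest.fixture(scope="session")
def pset():
    return builtin_set("hybrid_100mM_NaCl")


@pytest.fixture(scope="session")
def ref_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def ref_duplexes(ref_table):
    return reference_duplexes(ref_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
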
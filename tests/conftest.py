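import numpy as np
import pytest

import hilltau as ht

SYNERGY_PAIR = ("Orox PK", "Anox 20")


@pytest.fixture(scope="session")
def table1_records():
    return ht.load_table1()


@pytest.fixture(scope="session")
def table1_fit(table1_records):
    """Default potency fit of the packaged design table: singles-derived
    slopes, synergy for the amine/phenolic pair with lam = 2."""
    return ht.fit_potency(table1_records, synergy_pairs=[SYNERGY_PAIR], lam=2.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170522)
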
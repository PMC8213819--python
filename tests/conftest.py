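import numpy as np
import pytest

import crescan as cs


@pytest.fixture(scope="session")
def small_study():
    """One seeded synthetic study, shared across tests (read-only)."""
    sim, aln, track = cs.simulate_study(seed=11)
    return sim, aln, track


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
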
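import numpy as np
import pytest

import cnescan as cs


@pytest.fixture(scope="session")
def template():
    return cs.default_cne_template()


@pytest.fixture(scope="session")
def small_family():
    """A small, moderately diverged family (fast to align in unit tests)."""
    spec = cs.FamilySpec(n_sequences=8, sub_rate=0.15, seed=42)
    seqs, truth = cs.simulate_family(spec)
    return seqs, truth


@pytest.fixture(scope="session")
def small_family_alignment(small_family):
    seqs, truth = small_family
    return cs.align_family(seqs), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20140416)


def random_dna(rng, n, at=0.5):
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, n, p=p)])
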
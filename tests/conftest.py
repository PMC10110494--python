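import numpy as np
import pytest

from dupliscan.synthetic_data import DuplicationConfig, generate_locus, simulate_rnaseq

DEFAULT_WEIGHTS = {"geneA.1": 0.6, "geneB.1": 0.3, "geneB.2": 0.1}


@pytest.fixture(scope="session")
def default_truth():
    """A default synthetic tandem-duplication locus (divergence 0.013)."""
    return generate_locus(DuplicationConfig(seed=11))


@pytest.fixture(scope="session")
def clean_truth():
    """A locus with an unmutated duplicate (substitution rate 0)."""
    return generate_locus(DuplicationConfig(seed=11, substitution_rate=0.0))


@pytest.fixture(scope="session")
def default_reads(default_truth):
    """Error-free 75 bp reads from the default locus at moderate depth."""
    return simulate_rnaseq(
        default_truth, DEFAULT_WEIGHTS, n_reads=4000, read_length=75,
        error_rate=0.0, seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))
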
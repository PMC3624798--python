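import numpy as np
import pytest

from pairprob import FragmentModel, GenomeInfo, PairParams


@pytest.fixture
def genome():
    return GenomeInfo({"chr1": 1_000_000, "chr7": 1_000_000})


@pytest.fixture
def normal_model():
    return FragmentModel("normal", 400.0, 50.0)


@pytest.fixture
def params_factory(genome):
    def make(d=0.01, T=4.0, e=10, correction=False, two_g=None):
        return PairParams(d=d, T=T, e=e,
                          two_g=two_g if two_g is not None else genome.two_g,
                          apply_cutoff_correction=correction)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20130214)
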
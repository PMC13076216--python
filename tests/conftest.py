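import numpy as np
import pytest

from minvep import DomainSpec, ProteinRecord, generate_family


class UniformScorer:
    """Every amino acid equally likely at every position."""

    def position_log_probs(self, sequence):
        return np.full((len(sequence), 20), np.log(1 / 20))


class OneHotScorer:
    """Degenerate scorer: probability 1 on the wild-type letter."""

    def position_log_probs(self, sequence):
        from minvep.alphabet import sequence_to_indices

        idx = sequence_to_indices(sequence)
        logp = np.full((len(sequence), 20), -np.inf)
        logp[np.arange(len(sequence)), np.maximum(idx, 0)] = 0.0
        return logp


@pytest.fixture
def uniform_scorer():
    return UniformScorer()


@pytest.fixture
def onehot_scorer():
    return OneHotScorer()


@pytest.fixture
def protein():
    return ProteinRecord("P1", "MAVGLKD" * 5)


@pytest.fixture(scope="session")
def small_family():
    domains = [DomainSpec("d1", 6, 15, conservation=0.95)]
    return generate_family(10, 40, domains, seed=11)


@pytest.fixture(scope="session")
def blindspot_bench():
    from minvep.pipeline import blindspot_benchmark

    return blindspot_benchmark(seed=0)
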
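import numpy as np
import pytest

from tindex import BNNConfig, SyntheticCohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return BNNConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A quick, strongly-structured cohort for pipeline-level tests."""
    spec = SyntheticCohortSpec(
        n_samples=80, n_genes=300, male_module_size=40, female_module_size=40, seed=11
    )
    return spec, *simulate_cohort(spec)


def random_sequences(n, max_tau, seed, with_weights=True):
    """Random (labels, weights, p_gamma) triples for oracle cross-checks."""
    rng = np.random.default_rng(seed)
    out = []
    for trial in range(n):
        tau = int(rng.integers(0, max_tau + 1))
        labels = rng.integers(0, 2, tau).astype(float)
        if with_weights and trial % 2:
            weights = rng.uniform(0.3, 3.0, tau)
        else:
            weights = np.ones(tau)
        p_gamma = (0.01, 0.05, 0.5)[trial % 3]
        out.append((labels, weights, p_gamma))
    return out
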
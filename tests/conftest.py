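import numpy as np
import pytest

from corescale import SyntheticConfig, TraitMatrix, generate


@pytest.fixture(scope="session")
def trial_truth():
    """Genotypic truth at full trial scale: 168 accessions x 20 traits,
    30% exact-duplicate accessions."""
    cfg = SyntheticConfig(seed=2026, redundancy_fraction=0.3,
                          redundancy_jitter=0.0)
    _, truth = generate(cfg)
    return truth


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(11)
    return TraitMatrix([f"a{i}" for i in range(12)],
                       [f"t{j}" for j in range(4)],
                       rng.normal(50, 10, (12, 4)))


def random_matrix(rng, n, t, scale=10.0):
    return TraitMatrix([f"a{i}" for i in range(n)],
                       [f"t{j}" for j in range(t)],
                       rng.normal(50, scale, (n, t)))
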
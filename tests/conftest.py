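import numpy as np
import pytest

from metasig import MetaboliteMatrix, StudyConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study design: 280 metabolites x 12 samples."""
    config = StudyConfig(seed=1)
    matrix, truth = generate_study(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def small_study():
    """A compact noiseless study for fast exact checks."""
    config = StudyConfig(
        n_metabolites=60,
        n_per_group={"A": 4, "B": 4},
        n_signatures=3,
        noise_cv=0.0,
        seed=5,
    )
    matrix, truth = generate_study(config)
    return config, matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_matrix(rng, n_m=20, n_s=8, seed=None):
    if seed is not None:
        rng = np.random.default_rng(seed)
    values = rng.gamma(2.0, size=(n_m, n_s))
    return MetaboliteMatrix(
        values=values,
        metabolite_ids=[f"M{i}" for i in range(n_m)],
        sample_ids=[f"S{j}" for j in range(n_s)],
    )
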
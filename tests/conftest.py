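import numpy as np
import pytest

from skatekin.simulate import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """Minutes-scale population: 400 adults, 15 cohorts, 180 samples."""
    base = dict(n0=400, r=0.0, phi=0.85, age_maturity=5,
                cohort_years=(2000, 2014), survey_years=(2010, 2012, 2014),
                samples_per_year=(60, 60, 60), sample_age_range=(2, 10),
                n_loci=300, seed=3)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def tiny_matrix():
    """20 x 25 genotype matrix with missingness, for brute-force checks."""
    from skatekin.matrix import GenotypeMatrix
    rng = np.random.default_rng(17)
    p = rng.uniform(0.05, 0.5, 25)
    calls = rng.binomial(2, p, (20, 25)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = -1
    samples = np.array([f"s{i}" for i in range(20)], dtype=object)
    loci = np.array([f"l{j}" for j in range(25)], dtype=object)
    return GenotypeMatrix(calls, samples, loci)
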
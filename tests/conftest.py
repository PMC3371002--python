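import numpy as np
import pytest

from tolmpt import ClassMixture, Dataset, MPTParams, SimConfig, study_scenario, simulate


@pytest.fixture(scope="session")
def study_mixture() -> ClassMixture:
    """The two-class mixture at the study's fitted parameter values."""
    return ClassMixture(
        weights=(0.73, 0.27),
        params=(MPTParams(0.76, 0.82, 0.78), MPTParams(0.71, 0.78, 0.0)),
        T=2,
    )


@pytest.fixture(scope="session")
def one_class_mixture() -> ClassMixture:
    return ClassMixture(weights=(1.0,), params=(MPTParams(0.75, 0.8, 0.6),), T=2)


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """Three hand-picked subjects for brute-force likelihood oracles."""
    return Dataset(np.array([[2, 1, 0, 0], [1, 1, 1, 1], [2, 2, 0, 0]]), T=2)


@pytest.fixture(scope="session")
def study_cohort() -> Dataset:
    """One seeded 60-subject cohort from the study scenario."""
    return simulate(study_scenario(seed=42)).dataset


def random_mixture(rng: np.random.Generator, K: int, T: int = 2) -> ClassMixture:
    """A random valid mixture for property tests, bounded away from edges."""
    weights = rng.dirichlet(np.ones(K) * 2.0)
    params = tuple(MPTParams(*rng.uniform(0.05, 0.95, size=3)) for _ in range(K))
    return ClassMixture(tuple(weights), params, T=T)
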
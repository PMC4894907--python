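import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plscrp import DataBlock, standardize

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_block(values, prefix="v", dtype_role="continuous"):
    values = np.asarray(values, dtype=float)
    return DataBlock(
        values=values,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        variable_ids=[f"{prefix}{j}" for j in range(values.shape[1])],
        dtype_role=dtype_role,
    )


def random_std_pair(n, d1, d2, seed=0):
    """Two independent standardized Gaussian blocks sharing a sample axis."""
    rng = np.random.default_rng(seed)
    b1 = standardize(make_block(rng.standard_normal((n, d1)), "a"))
    b2 = standardize(make_block(rng.standard_normal((n, d2)), "b"))
    return b1, b2


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def causal_scenario():
    """One standard high-dimensional-phenotype dataset with planted signal."""
    from plscrp import make_scenario

    pheno, geno, truth = make_scenario("pheno_high", seed=7)
    return standardize(pheno), standardize(geno), truth
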
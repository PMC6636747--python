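import numpy as np
import pytest

from micdeg.simulate import DatasetSpec, GroupSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lognormal_group_1():
    """First log-normal benchmark group (weak DE contrast)."""
    return GroupSpec("lognormal", "lognormal-1",
                     (5.0, 1.5), (5.0, 1.5), (4.5, 1.0), (5.0, 2.0))


@pytest.fixture
def lognormal_group_2():
    """Second log-normal benchmark group (clear DE contrast)."""
    return GroupSpec("lognormal", "lognormal-2",
                     (5.0, 1.5), (5.0, 1.5), (5.0, 1.0), (6.0, 1.1))


@pytest.fixture
def small_spec():
    return DatasetSpec(n_genes=400, frac_de=0.05)


@pytest.fixture
def small_dataset(lognormal_group_2, small_spec):
    return generate_dataset(lognormal_group_2, small_spec, rng=7, replicate=0)
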
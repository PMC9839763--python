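import numpy as np
import pytest

from morphoscape import datasets


def pytest_collection_modifyitems(items):
    # keep the cheap unit tests first so failures surface before the
    # long-running equivalence sweeps
    items.sort(key=lambda it: it.path.name == "test_acceptance.py")


@pytest.fixture(scope="session")
def patch_tables():
    """The four printed 9x7 mean-patch-size year tables."""
    return datasets.load_mean_patch_size()


@pytest.fixture(scope="session")
def printed_coords():
    """Printed axis coordinates, long format."""
    return datasets.load_axis_coordinates()


@pytest.fixture(scope="session")
def printed_shares():
    """Printed per-class core shares and annual rates."""
    return datasets.load_core_shares()


@pytest.fixture(scope="session")
def printed_changes():
    """Printed annual change of mean patch size."""
    return datasets.load_annual_change()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape, p=None):
    p = rng.uniform(0.2, 0.8) if p is None else p
    return rng.uniform(size=shape) < p
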
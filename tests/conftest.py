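import numpy as np
import pytest

from ersirt import (
    GroupSpec,
    MnrmItem,
    ScoringMatrix,
    TreeItem,
    make_item_set,
    sample_persons,
    simulate,
)


@pytest.fixture(scope="session")
def ers_scoring():
    return ScoringMatrix.ers(4)


@pytest.fixture(scope="session")
def symmetric_item():
    """Slope-1.5 item with thresholds (-1, 0, 1): intercepts (0, 1.5, 1.5, 0)."""
    return MnrmItem.from_thresholds([-1.0, 0.0, 1.0], (1.5, 1.5))


@pytest.fixture(scope="session")
def asymmetric_item():
    return MnrmItem.from_thresholds([0.0, 1.0, 2.0], (1.5, 1.5))


@pytest.fixture(scope="session")
def tree_item():
    return TreeItem(
        node1_slope=1.4,
        node1_intercept=-0.3,
        agree_slope=0.5,
        ers_slope=1.2,
        node2_intercept=0.4,
        node3_intercept=-0.6,
    )


@pytest.fixture(scope="session")
def theta2_grid():
    return np.linspace(-3.0, 3.0, 25)


@pytest.fixture(scope="session")
def small_mnrm_data():
    """Two-group MNRM sample: 5 items, 150 persons per group, ERS shift +1."""
    items = make_item_set([-1.0, 0.0, 1.0], n_items=5)
    persons = sample_persons(
        (GroupSpec.standard(0.0), GroupSpec.standard(1.0)), 150, seed=421
    )
    data = simulate("mnrm", items, persons, seed=422)
    return items, data
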
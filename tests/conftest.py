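import numpy as np
import pytest

import crowdcourt as cc


@pytest.fixture(scope="session")
def circles():
    """A moderately hard two-ring dataset shared across ensemble tests."""
    return cc.make_circles_clusters(2000, factor=0.85, noise_sd=0.1, seed=424242)


@pytest.fixture(scope="session")
def circles_split(circles):
    return cc.split_train_test(circles, 0.3, seed=77)


@pytest.fixture(scope="session")
def balanced_test():
    """A label-balanced dummy test set for stub-judge hearings."""
    n = 2000
    X = np.zeros((n, 2))
    y = np.tile([0, 1], n // 2)
    return cc.LabeledDataset(X, y, name="balanced-dummy")
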
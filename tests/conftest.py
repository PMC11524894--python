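import numpy as np
import pytest

from lungquant import default_legend
from lungquant.masks import TissueMask


@pytest.fixture(scope="session")
def legend():
    return default_legend()


@pytest.fixture
def make_mask(legend):
    """Build a TissueMask from a 2-D array of class ids (default legend)."""

    def _make(labels, mpp=1.0, origin=None):
        leg = default_legend(mpp=mpp)
        return TissueMask(
            labels=np.asarray(labels, dtype=np.int64),
            legend=leg,
            origin_slide=origin,
        )

    return _make


@pytest.fixture
def random_mask(legend):
    """Random mask over all legend classes with a seeded generator."""

    def _make(seed, shape=(64, 64), n_classes=None, mpp=1.0):
        rng = np.random.default_rng(seed)
        n = n_classes or legend.n_classes
        labels = rng.integers(0, n, size=shape)
        leg = default_legend(mpp=mpp)
        return TissueMask(labels=labels.astype(np.int64), legend=leg)

    return _make
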
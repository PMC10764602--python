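import numpy as np
import pytest

from aftbml import BartConfig, ScenarioConfig, generate
from aftbml._compiled import INTERNAL, LEAF, N_NODES
from aftbml.aft import AFTPosterior


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_posterior(mu, draw_values, sigma2, split=None, n_features=1,
                   config=None):
    """Synthetic posterior with one tree per draw.

    ``draw_values``: per retained draw, either a scalar (single-leaf tree,
    constant prediction) or a (left, right) pair used with ``split =
    (feature, threshold)`` for a depth-1 tree.  Synthetic stand-in for a
    fitted AFTPosterior in unit tests.
    """
    M = len(draw_values)
    ntype = np.zeros((M, 1, N_NODES), np.int8)
    var = np.full((M, 1, N_NODES), -1, np.int32)
    cut = np.zeros((M, 1, N_NODES))
    leaf = np.zeros((M, 1, N_NODES))
    for m, val in enumerate(draw_values):
        if np.ndim(val) == 0:
            ntype[m, 0, 0] = LEAF
            leaf[m, 0, 0] = val
        else:
            feat, thr = split
            ntype[m, 0, 0] = INTERNAL
            var[m, 0, 0] = feat
            cut[m, 0, 0] = thr
            ntype[m, 0, 1] = LEAF
            ntype[m, 0, 2] = LEAF
            leaf[m, 0, 1], leaf[m, 0, 2] = val
    sigma2 = np.broadcast_to(np.asarray(sigma2, float), (M,)).copy()
    cfg = config if config is not None else BartConfig(n_trees=1, n_draws=M)
    return AFTPosterior(mu, ntype, var, cut, leaf, sigma2, cfg, n_features)


@pytest.fixture(scope="session")
def scenario1_small():
    return generate(ScenarioConfig(1, 400, seed=42))


@pytest.fixture(scope="session")
def tiny_config():
    """Sampler settings small enough for second-scale unit tests."""
    return BartConfig(n_trees=30, n_burn=150, n_draws=50, thin=2, seed=7)
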
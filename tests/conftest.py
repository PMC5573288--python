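import numpy as np
import pytest

import spanmf as sp
from spanmf.segmentation import relabel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """Noiseless separable 24x24 phantom, 4 tissues."""
    return sp.make_phantom(sp.PhantomConfig(grid_shape=(24, 24), seed=7))


def dice_against_truth(H, W, ph) -> dict[str, float]:
    """Segment abundances, anchor sources to the phantom's ground truth and
    Dice-score the three BraTS classes."""
    perm = sp.match_sources(W, ph.W_true)
    seg = sp.segment_abundances(H, grid_shape=ph.config.grid_shape)
    seg.labels = relabel(seg.labels, perm)
    seg.class_of_source = ph.class_of_source
    return sp.dice_report(seg, ph.label_map_true).as_dict()
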
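"""Shared fixtures: small rendered timelapses and partitions, built once."""

import numpy as np
import pytest

from chemotirf import puncta, synthgen
from chemotirf.core import SpotGeometry
from chemotirf.regions import partition_cell
from chemotirf.synthgen import GeneratorConfig


@pytest.fixture(scope="session")
def mixed_fate_scene():
    """A mid-size TIRF timelapse with every planted fate plus designed
    negatives, detected and linked once for the whole session."""
    gc = GeneratorConfig(field_px=384, n_frames=40, n_puncta=40,
                         cell_halfaxes_um=(15.0, 8.0), second_channel=False,
                         fate_fractions={"static": 0.4, "lateral": 0.2,
                                         "disappearing": 0.25},
                         n_reappearing=5, n_gradual=5, seed=21)
    stack, gt = synthgen.make_tirf_timelapse(gc)
    dets = puncta.detect_stack(stack)
    tracks = puncta.link_puncta(dets, n_frames=stack.n_frames)
    puncta.classify_all(tracks, stack)
    return stack, gt, dets, tracks


@pytest.fixture(scope="session")
def ellipse_partition():
    """Partition of an elliptical cell mask, front toward +x."""
    mask = synthgen._ellipse_mask((240, 320), (160.0, 120.0), (140.0, 90.0))
    spot = SpotGeometry(kind="line", point_um=(32.0, 0.0), normal=(1.0, 0.0))
    return mask, partition_cell(mask, 0.1, spot)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
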
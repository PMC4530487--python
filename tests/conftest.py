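import numpy as np
import pytest

from bonefe.imageproc import BoneMask, SpanCrop
from bonefe.microfe import Material, build_model


def make_bar_mask(vox_um=100.0, n_len=12, n_side=3):
    """Small solid rectangular bar, shaft along axis 0."""
    return BoneMask(np.ones((n_len, n_side, n_side), dtype=bool), vox_um)


def bar_crop(mask: BoneMask, inset_vox=2):
    s = mask.voxel_size_mm
    n = mask.grid.shape[0]
    return SpanCrop((inset_vox * s, (n - inset_vox) * s), margin_mm=0.0)


def make_bar_model(mask=None, material=None, **kwargs):
    mask = mask if mask is not None else make_bar_mask()
    return build_model(
        mask, material or Material(), bar_crop(mask), **kwargs
    )


@pytest.fixture
def bar_mask():
    return make_bar_mask()


@pytest.fixture
def bar_model(bar_mask):
    return make_bar_model(bar_mask)
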
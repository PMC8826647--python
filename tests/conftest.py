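import numpy as np
import pytest
from hypothesis import settings

from periquant.model import CellRecord, EmbryoFrame, Tissue

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def simple_frame():
    """Three VE/AVE cells in a trivial frame (origin 0, axis z)."""
    cells = [
        CellRecord("a", Tissue.AVE, [3.0, 4.0, 0.0]),
        CellRecord("b", Tissue.VE, [0.0, 0.0, 10.0]),
        CellRecord("c", Tissue.VE, [-5.0, 0.0, 0.0]),
    ]
    return EmbryoFrame("e1", cells)


def make_frame(ave_xy, ve_xy, axis=(0, 0, 1), origin=(0, 0, 0)):
    """Frame from explicit (x, y, z) positions for AVE and plain-VE cells."""
    cells = [
        CellRecord(f"ave{i}", Tissue.AVE, p) for i, p in enumerate(ave_xy)
    ] + [CellRecord(f"ve{i}", Tissue.VE, p) for i, p in enumerate(ve_xy)]
    return EmbryoFrame("e", cells, origin=np.asarray(origin, float), axis=axis)
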
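import logging

import numpy as np
import pytest

from morphodyn import tissue
from morphodyn.render import RenderParams, render_stack

logging.getLogger("morphodyn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def meristem_run():
    """One default meristem simulation shared across tests."""
    return tissue.simulate("meristem", 48.0, seed=1)


@pytest.fixture(scope="session")
def small_sheet():
    """A 50-cell centroidal tessellation, no dynamics."""
    return tissue.init_tissue(50, 21.0, 5.0, seed=1)


@pytest.fixture(scope="session")
def rendered_sheet(small_sheet):
    """Noiseless render of the 50-cell sheet with a known EdU pattern."""
    snap = small_sheet.copy()
    for i, c in enumerate(snap.cells):
        c.edu_positive = i % 3 == 0
    img, gt = render_stack(snap, RenderParams())
    return snap, img, gt
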
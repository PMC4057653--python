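import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pupilkit.phantom import PhantomSpec, render_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def circle119_frame():
    """Rendered 119-px circle phantom, the smallest of the test set."""
    return render_phantom(PhantomSpec(shape="circle", major_axis_px=119, minor_axis_px=119))


@pytest.fixture(scope="session")
def ellipse_160x119_frame():
    """Ellipse phantom with the horizontal screen axis longer."""
    return render_phantom(
        PhantomSpec(shape="ellipse", major_axis_px=160, minor_axis_px=119, major_axis="x")
    )
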
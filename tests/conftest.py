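import numpy as np
import pytest

from shgqpm.optics import DispersionModel, OpticalConfig, beam_geometry
from shgqpm.structure import (
    FibrilEnsembleSpec,
    FibrilModel,
    DEFAULT_BOX,
    generate_random,
    voxelize,
)

SMALL_BOX = (400.0, 400.0, 800.0)


@pytest.fixture(scope="session")
def opt800():
    return OpticalConfig(lambda_fund=800.0, NA=0.8)


@pytest.fixture(scope="session")
def geom800(opt800):
    return beam_geometry(opt800, DispersionModel())


@pytest.fixture(scope="session")
def small_model():
    """Three well-separated polar disks in a small box (hand-placed)."""
    fib = np.array(
        [
            [-80.0, -200.0, 60.0, +1.0],
            [90.0, 120.0, 50.0, -1.0],
            [0.0, 300.0, 40.0, +1.0],
        ]
    )
    return FibrilModel(fibrils=fib, box=SMALL_BOX)


@pytest.fixture(scope="session")
def random_model_60():
    spec = FibrilEnsembleSpec(
        mean_diameter=60.0, fill_fraction=0.25, polarity_mode="random", seed=1
    )
    return generate_random(spec, DEFAULT_BOX)
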
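import numpy as np
import pytest

from actinorder.polarimetry import PolarizationStack
from actinorder.synthetic import (
    AcquisitionConfig,
    DEFAULT_ANGLES,
    forward_simulate,
    make_preset_scene,
)


@pytest.fixture(scope="session")
def angles10():
    return DEFAULT_ANGLES.copy()


@pytest.fixture(scope="session")
def scene_90h():
    return make_preset_scene("90h", shape=(192, 192), seed=0)


@pytest.fixture(scope="session")
def stack_90h_noiseless(scene_90h):
    return forward_simulate(scene_90h, AcquisitionConfig(noise="none"))


def constant_psi_stack(rho_deg, psi_deg, shape=(4, 4), angles=None, budget=1e4):
    """Noiseless single-(rho, psi) stack used across polarimetry tests."""
    from actinorder.polarimetry import cone_modulation

    if angles is None:
        angles = DEFAULT_ANGLES
    k = len(angles)
    m = cone_modulation(psi_deg)
    pages = np.stack(
        [
            np.full(shape, budget / k * (1 + m * np.cos(2 * np.deg2rad(a - rho_deg))))
            for a in angles
        ]
    )
    return PolarizationStack(data=pages, angles=np.asarray(angles, dtype=float))
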
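import numpy as np
import pytest

from edpilot.virtual_microscope import (
    Crystal,
    GonioModel,
    VirtualMicroscope,
    VirtualScene,
)


@pytest.fixture
def plain_scene():
    """Crystal-free scene with a compact beam disc that stays on-detector
    even when steered far off-centre."""
    return VirtualScene(gonio=GonioModel(seed=11), imaging_beam_radius_px=40.0)


@pytest.fixture
def crystal_scene():
    """One well-visible crystal, non-eucentric ground truth, no jitter."""
    return VirtualScene(
        crystals=[Crystal(0.5, 0.3, 300)],
        gonio=GonioModel(z_euc_true=-30.0, seed=5),
    )


@pytest.fixture
def runout_scene():
    """Reproducible goniometer runout, crystal at the eucentric plane."""
    return VirtualScene(
        crystals=[Crystal(1.0, 0.5, 300)],
        gonio=GonioModel(
            z_euc_true=0.0, runout_amplitude=1.5, runout_phase=30.0, seed=7
        ),
    )


@pytest.fixture
def tiny_scene():
    """Small detector for protocol tests where render speed matters."""
    return VirtualScene(
        detector_shape=(64, 64),
        imaging_beam_radius_px=20.0,
        beam_response=np.array([[20.0, 1.0], [-1.0, -18.0]]),
        gonio=GonioModel(seed=3),
    )


def ground_truth_marks(scope: VirtualMicroscope, alphas, crystal_index: int = 0):
    """Operator marks taken from the simulator's noise-free projection."""
    return [(a, *scope.crystal_pixel(crystal_index, alpha=a)) for a in alphas]
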
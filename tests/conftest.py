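import numpy as np
import pytest

from octenergy.phantom import PhantomConfig, synth_bscan_stack
from octenergy.registration import register_and_average


def small_config(**overrides) -> PhantomConfig:
    """Desk-scale acquisition geometry used throughout the tests:
    320 x 480 px at 1.6 x 2.8 um/px so the 350-624 um analysis regions
    fit on both sides of the nerve head."""
    kw = dict(rows=320, cols=480, axial_px_um=1.6, lateral_px_um=2.8,
              curvature_um=15.0, n_frames=1, seed=0)
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def nf_flat():
    """Noise-free flat (zero-curvature) single-frame phantom."""
    return synth_bscan_stack(small_config(curvature_um=0.0, seed=1))


@pytest.fixture(scope="session")
def nf_curved():
    """Noise-free phantom with 40 um peak-to-edge curvature."""
    return synth_bscan_stack(small_config(curvature_um=40.0, seed=2))


@pytest.fixture(scope="session")
def speckled_average():
    """Registered average of a 6-frame speckled, jittered stack."""
    cfg = small_config(speckle_sigma=0.08, max_jitter_rot_deg=0.5,
                       max_jitter_shift_px=2.0, n_frames=6, seed=3)
    stack, truth = synth_bscan_stack(cfg)
    reg = register_and_average(stack, rot_max_deg=1.0)
    return stack, truth, reg


def trace_error(seg, truth, layer):
    return np.asarray(seg[layer].depth) - np.asarray(truth.boundaries[layer])
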
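import numpy as np
import pytest

from eventscope import (CameraConfig, ChannelSettings, Frame, SampleParams,
                        VirtualMicroscope, init_colony)

BF = ChannelSettings("brightfield", exposure_ms=50.0, led_intensity_pct=0.0)


@pytest.fixture
def quiet_camera():
    """Noise-free small camera for deterministic pixel-level assertions."""
    return CameraConfig(width=128, height=128, read_noise_sd=0.0,
                        shot_noise=False)


@pytest.fixture
def camera():
    return CameraConfig(width=192, height=192)


def make_colony(n, seed, half_um=24.0, params=None, **kwargs):
    """Colony centred on the origin in a square chamber."""
    return init_colony(n, (-half_um, -half_um, half_um, half_um), seed=seed,
                       params=params, **kwargs)


def make_scope(state, cam, seed=0):
    return VirtualMicroscope(state, cam, noise_seed=seed)


def bf_frame(mic, noise=False, t_sim=0.0):
    """Acquire a brightfield frame without photodose bookkeeping."""
    img = mic.render(BF, noise=noise)
    return Frame(pixels=np.clip(np.round(img), 0, 65535).astype(np.uint16),
                 channel_settings=BF, stage=mic.pose, t_sim=t_sim)


@pytest.fixture
def scatter_scene(quiet_camera):
    """12 well-separated unbudded cells fully inside the FOV."""
    half = quiet_camera.width * quiet_camera.pixel_size_um / 2 - 4
    state = init_colony(12, (-half, -half, half, half), seed=42,
                        cycle_randomized=False)
    from eventscope.sample import _relax
    for _ in range(30):
        _relax(state)
    return state, make_scope(state, quiet_camera, seed=42)
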
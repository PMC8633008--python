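import numpy as np
import pytest

from cardiophen.synthetic import (
    BeatSpec,
    StackSpec,
    StriationSpec,
    make_beat_trajectories,
    make_striation_image,
    make_zstack,
)


@pytest.fixture
def organized_roi():
    image, truth = make_striation_image(
        StriationSpec(seed=3, noise_sd=0.05, image_size=(96, 96))
    )
    return image, truth


@pytest.fixture
def scrambled_roi():
    image, truth = make_striation_image(
        StriationSpec(seed=3, noise_sd=0.05, image_size=(96, 96), disorganization=1.0)
    )
    return image, truth


@pytest.fixture
def sinusoid_recording():
    """Noiseless 1 Hz, 1 px sinusoid at 30 fps (the closed-form anchor)."""
    spec = BeatSpec(
        n_markers=12, beat_frequency=1.0, displacement_amplitude=1.0,
        fps=30.0, duration=10.0, jitter_sd=0.0, seed=0,
    )
    return make_beat_trajectories(spec)


@pytest.fixture
def noiseless_stack():
    """5 slices, signal 200 over a 100-px^2 square, background 50 (CTF 75000)."""
    spec = StackSpec(
        n_slices=5,
        slice_size=(64, 64),
        signal_region=((10.0, 10.0), (20.0, 10.0), (20.0, 20.0), (10.0, 20.0)),
        signal_level=200.0,
        background_level=50.0,
        noise_sd=0.0,
        seed=0,
    )
    stack, truth = make_zstack(spec)
    return spec, stack, truth


BACKGROUND_ROI = ((40.0, 40.0), (60.0, 40.0), (60.0, 60.0), (40.0, 60.0))
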
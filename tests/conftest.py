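import numpy as np
import pytest

from filatrace import FilamentSpec, SceneSpec, render_scene


@pytest.fixture
def single_filament_scene():
    """One clean horizontal filament from (32,10) to (32,50), no noise."""
    spec = SceneSpec((64, 64), filaments=[
        FilamentSpec(np.array([[32.0, 10.0], [32.0, 50.0]]))])
    image, truth = render_scene(spec)
    return spec, image, truth


@pytest.fixture
def noisy_scene():
    """Three well-separated filaments with moderate noise (SNR ~ 6.7)."""
    from filatrace import random_scene
    spec = random_scene(3, seed=1)
    image, truth = render_scene(spec)
    return spec, image, truth
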
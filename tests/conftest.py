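import pytest

from ma_screen.synth import (
    LesionSpec,
    SceneSpec,
    high_contrast_sampler,
    render_fundus,
    sample_scene,
)


@pytest.fixture(scope="session")
def default_scene():
    """A sampled scene with all anatomy present, rendered once per session."""
    spec = sample_scene(seed=5)
    img, ann = render_fundus(spec)
    return spec, img, ann


@pytest.fixture(scope="session")
def clean_ma_scene():
    """Noiseless scene with 10 well-separated microaneurysms and no other
    structures: ground truth for connected-component and threshold oracles."""
    centers = [
        (180, 200), (300, 150), (420, 210), (520, 300), (430, 400),
        (300, 430), (190, 380), (260, 290), (380, 300), (480, 170),
    ]
    spec = SceneSpec(
        optic_disc=None,
        vessel_tree=None,
        mas=[LesionSpec(c, 8.0, 70.0) for c in centers],
        noise_sigma=0.0,
        illumination_gradient=0.0,
        non_overlapping=True,
        seed=11,
    )
    img, ann = render_fundus(spec)
    return spec, img, ann


@pytest.fixture(scope="session")
def recovery_scene():
    """One high-contrast scene from the recovery-study family."""
    spec = sample_scene(high_contrast_sampler(), seed=1)
    img, ann = render_fundus(spec)
    return spec, img, ann
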
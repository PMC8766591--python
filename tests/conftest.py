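import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fascore

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scene():
    """One representative synthetic scene."""
    return fascore.random_scene(0)


@pytest.fixture(scope="session")
def rendered(scene):
    return fascore.render_scene(scene)


@pytest.fixture(scope="session")
def lesion_mask(scene):
    from fascore.synthetic import lesion_region_mask

    return lesion_region_mask(scene)


@pytest.fixture(scope="session")
def tiny_segmenter():
    """A small segmenter trained quickly on a handful of scenes (shared)."""
    from fascore.segmentation import UnetSegmenter

    scenes = [fascore.random_scene(200 + s) for s in range(8)]
    X = [fascore.render_scene(s) for s in scenes]
    y = [s.lesion_mask for s in scenes]
    est = UnetSegmenter(
        n_levels=3, base_channels=8, train_size=128, epochs=30, batch_size=2,
        learning_rate=3e-3, random_state=0,
    )
    return est.fit(X, y)


def nested_mottle_scene(seed, coverage, lesion_scale=1.0):
    """Scenes sharing vessels/lesion/illumination whose mottle sets are nested:
    a higher coverage strictly contains a lower one (same band-pass field).
    Vessels are excluded from the lesion so the lesion Score is pure mottle."""
    from scipy.ndimage import gaussian_filter
    from fascore.synthetic import (
        SyntheticScene, _draw_lesion, _draw_vessel_tree, illumination_field,
    )

    rng = np.random.default_rng(seed)
    shape = (496, 496)
    vessels = _draw_vessel_tree(shape, rng)
    lesion = _draw_lesion(shape, rng, 2)
    if lesion_scale > 1.0:
        from scipy.ndimage import binary_dilation

        lesion = binary_dilation(lesion, iterations=int(10 * (lesion_scale - 1.0) * 10))
        lesion = lesion.astype(np.uint8)
    vessels = (vessels & ~lesion).astype(np.uint8)
    noise = np.random.default_rng(seed + 7).normal(size=shape)
    band = gaussian_filter(noise, 2.0) - gaussian_filter(noise, 6.0)
    inside = band[lesion.astype(bool)]
    cut = np.quantile(inside, 1.0 - coverage)
    mottle = ((band > cut) & lesion.astype(bool)).astype(np.uint8)
    illum = illumination_field(shape, 0.2, "bump", rng=np.random.default_rng(seed + 11))
    return SyntheticScene(
        width=496, height=496, vessel_map=vessels, lesion_mask=lesion,
        mottle_map=mottle, illumination=illum, rng_seed=seed,
    )
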
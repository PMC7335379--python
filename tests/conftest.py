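import numpy as np
import pytest

import microtissue as mt


@pytest.fixture(scope="session")
def clean_scene():
    """One noise-free, gradient-free default scene with ground truth."""
    scene = mt.TissueSceneParams(noise_sd=0.0, seed=42)
    return scene, mt.render_timelapse(scene)


@pytest.fixture(scope="session")
def default_scene():
    scene = mt.TissueSceneParams(seed=11)
    return scene, mt.render_timelapse(scene)


@pytest.fixture(scope="session")
def gradient_scene():
    """Illumination-corrupted scene where absolute intensities cannot
    separate the silhouette."""
    scene = mt.TissueSceneParams(seed=11, illumination_gradient=0.8)
    return scene, mt.render_timelapse(scene)


@pytest.fixture(scope="session")
def default_migration():
    scene = mt.GelSceneParams()
    rows = [scene.row_of(w) for w in scene.ladder_weights]
    return mt.calibrate_migration(rows, scene.ladder_weights)


def frame_at(scene, rendered, i):
    return mt.ImageFrame(
        rendered.stack[i], scene.pixel_size, float(rendered.timestamps[i])
    )


@pytest.fixture(scope="session")
def study_readouts():
    """A default-size cohort (~41 tendons) with default effects."""
    cohort = mt.generate_cohort(mt.CohortParams(seed=3))
    return mt.generate_readouts(cohort, mt.EffectParams(), seed=4)


@pytest.fixture(scope="session")
def big_readouts():
    """500 tendons for coefficient-recovery checks."""
    cohort = mt.generate_cohort(
        mt.CohortParams(n_patients=500, p_second_tendon=0.0,
                        p_semitendinosus=30 / 41, seed=21)
    )
    return mt.generate_readouts(cohort, mt.EffectParams(), seed=22)
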
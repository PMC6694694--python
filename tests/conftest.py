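import numpy as np
import pytest

from fundusdr.config import RunConfig
from fundusdr.pipeline import preprocess_scene
from fundusdr.synthetic import LesionLoad, SceneSpec, render_scene


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def clean_scene():
    """A lesion-free synthetic scene with ground truth."""
    return render_scene(SceneSpec(seed=501))


@pytest.fixture(scope="session")
def lesion_scene():
    """A scene with hemorrhages, microaneurysms and exudates."""
    spec = SceneSpec(
        seed=502,
        lesion_loads={
            "microaneurysm": LesionLoad((3, 3), (9.0, 28.0), 0.85),
            "hemorrhage": LesionLoad((5, 5), (60.0, 400.0), 0.85),
            "exudate": LesionLoad((4, 4), (80.0, 350.0), 0.85),
        },
    )
    return render_scene(spec)


@pytest.fixture(scope="session")
def lesion_prep(lesion_scene, config):
    image, _ = lesion_scene
    return preprocess_scene(image, config)


@pytest.fixture(scope="session")
def clean_prep(clean_scene, config):
    image, _ = clean_scene
    return preprocess_scene(image, config)


@pytest.fixture(scope="session")
def detection_suite(config):
    """The 20-scene detection benchmark (shared: it is the expensive one)."""
    from fundusdr.benchmarks import run_detection_suite

    return run_detection_suite(seed=0, config=config)


@pytest.fixture(scope="session")
def cohort_run(config):
    """Full-pipeline analysis of the default 39/29/23 cohort."""
    from fundusdr.benchmarks import run_cohort

    return run_cohort(seed=0, config=config)


@pytest.fixture(scope="session")
def cohort_truth_summaries():
    """Ground-truth group summaries of the default cohort (render only)."""
    from fundusdr.synthetic import default_cohort_spec, simulate_cohort

    _, summaries = simulate_cohort(default_cohort_spec(0))
    return summaries


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
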
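import numpy as np
import pytest

from mscad.phantom import PhantomSpec, Sphere
from mscad.pipeline import PipelineConfig


def small_spec(**overrides) -> PhantomSpec:
    """A 64^3 phantom with one lesion per category — fast unit-test scale."""
    kwargs = dict(
        grid_shape=(64, 64, 64),
        brain_axes=(21.0, 26.0, 19.0),
        lesions_tp1=(Sphere((-8, -10, 0), 3.0),),
        lesions_new=(Sphere((7, 5, 2), 3.0),),
        lesions_reversed=(Sphere((0, 10, -3), 3.0),),
        seed=11,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def clean_spec(**overrides) -> PhantomSpec:
    """Small phantom without noise, bias or motion."""
    kwargs = dict(
        noise_sigma=0.0,
        bias_amplitude=0.0,
        rotation_deg=(0.0, 0.0, 0.0),
        translation_mm=(0.0, 0.0, 0.0),
    )
    kwargs.update(overrides)
    return small_spec(**kwargs)


@pytest.fixture(scope="session")
def quiet_config() -> PipelineConfig:
    return PipelineConfig(out_dir=None, write_overlays=False, seed=7)


@pytest.fixture(scope="session")
def change_study():
    """20-seed phantom recovery study at the default study conditions."""
    from mscad.validation import run_change_study

    return run_change_study(n_seeds=20, base_seed=0)


@pytest.fixture(scope="session")
def stable_study():
    """20-seed no-new-lesion study (motion, bias and noise still present)."""
    from mscad.validation import run_stable_study

    return run_stable_study(n_seeds=20, base_seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
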
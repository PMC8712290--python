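import numpy as np
import pytest

from svca.kinetic_classes import ClassBuildConfig, build_class_sets_loo, prepare_tissue_mask
from svca.petio import DynamicImage, FrameSchedule, MaskImage
from svca.synthdata import PhantomSpec, default_schedule, generate_cohort


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return default_schedule()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_dynamic(rng) -> tuple[DynamicImage, MaskImage]:
    """A 10x10x10 x 6-frame random positive image plus a blobby binary mask."""
    sched = FrameSchedule(np.arange(6) * 10.0, np.arange(1, 7) * 10.0)
    vox = rng.gamma(2.0, 1.0, size=(10, 10, 10, 6))
    img = DynamicImage(vox, sched, np.eye(4))
    mask = np.zeros((10, 10, 10))
    mask[2:8, 2:8, 2:8] = 1.0
    return img, MaskImage(mask, np.eye(4), kind="binary")


def _loo_setup(noise_level: float, jitter: float, seed: int = 42):
    spec = PhantomSpec(noise_level=noise_level, seed=seed)
    cohort, truths = generate_cohort(12, spec, inter_subject_jitter=jitter)
    classes = build_class_sets_loo(cohort, ClassBuildConfig(), held_out="s12")
    subject, truth = cohort[11], truths[11]
    candidate = prepare_tissue_mask(subject.masks["gm_prob"], 0.5, 0)
    return subject, truth, classes, candidate


@pytest.fixture(scope="session")
def loo_noiseless():
    """12-subject noiseless phantom cohort, leave-one-out classes for s12."""
    return _loo_setup(0.0, 0.03)


@pytest.fixture(scope="session")
def loo_noisy():
    """Same cohort at the generator's default noise level."""
    return _loo_setup(0.1, 0.03)


@pytest.fixture(scope="session")
def loo_very_noisy():
    return _loo_setup(0.3, 0.03)
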
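import numpy as np
import pytest

from msilowsig.patching import AnnotationImage
from msilowsig.preproc import IntensityCube
from msilowsig.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """Small but structurally complete synthetic study (fast to generate)."""
    return SynthConfig(
        n_samples=3,
        grid_h=24,
        grid_w=24,
        n_channels=60,
        n_signal_channels=4,
        n_isotopes_per_signal=1,
        n_replicates_per_signal=1,
        n_morphology_channels=12,
        n_anti_channels=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


def make_cube(intensities, sample_id="s1", mz=None, background=None) -> IntensityCube:
    intensities = np.asarray(intensities, dtype=float)
    h, w, p = intensities.shape
    if mz is None:
        mz = 600.0 + np.arange(p)
    if background is None:
        background = np.zeros((h, w), dtype=bool)
    return IntensityCube(
        sample_id=sample_id,
        mz=np.asarray(mz, dtype=float),
        intensities=intensities,
        background_mask=np.asarray(background, dtype=bool),
    )


def make_annotation(values, sample_id="s1") -> AnnotationImage:
    return AnnotationImage(sample_id, np.asarray(values, dtype=float))
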
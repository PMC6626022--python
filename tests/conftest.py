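import numpy as np
import pytest

from mmscope.config import PipelineConfig
from mmscope.modality import Modality
from mmscope.synthetic import FixtureSpec, generate_series


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def brightfield_series():
    """A default 8-channel brightfield series with its ground truth."""
    spec = FixtureSpec(seed=1, n_frames=3)
    frames, gt = generate_series(spec)
    return spec, frames, gt


@pytest.fixture(scope="session")
def phase_series():
    spec = FixtureSpec(seed=2, n_frames=2, modality=Modality.PHASE)
    frames, gt = generate_series(spec)
    return spec, frames, gt


@pytest.fixture(scope="session")
def lineage_series():
    """Three channels, a division entering frame 3 and a lysis entering
    frame 5, with rigid drift."""
    spec = FixtureSpec(
        seed=7,
        n_channels=3,
        n_frames=6,
        growth_rate=4,
        division_length=49,
        initial_lengths=[[37.0, 25.0], [30.0, 26.0], [28.0]],
        lysis_schedule=((5, 1, 0),),
        drift=(1.0, -2.0),
    )
    frames, gt = generate_series(spec)
    return spec, frames, gt


def combined_label_image(bacteria_set, shape):
    """Stack a BacteriaSet into one frame-wide label image."""
    out = np.zeros(shape, dtype=np.int32)
    for b in bacteria_set.bacteria:
        out[b.mask] = b.id
    return out
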
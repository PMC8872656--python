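import numpy as np
import pytest

from arraypulse.model import ArrayRecording, ChannelLayout, FootprintSpec
from arraypulse.synthetic import BeatModel, GaussComponent, healthy_beat_model


@pytest.fixture
def layout() -> ChannelLayout:
    return ChannelLayout.default()


@pytest.fixture
def footprint() -> FootprintSpec:
    return FootprintSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def sharp_beat_model() -> BeatModel:
    """A beat with narrow, well-separated components and a deep notch;
    its fiducials are sharply defined, which makes it the right subject
    for detector-accuracy checks (the cohort presets have a physiological
    plateau where sub-sample timing is not identifiable)."""
    return BeatModel(
        percussion=GaussComponent(1.0, 0.15, 0.05),
        tidal=GaussComponent(0.45, 0.38, 0.06),
        dicrotic=GaussComponent(0.25, 0.65, 0.06),
    )


def separable_recording(
    beat: np.ndarray, gains: np.ndarray, n_beats: int = 5, fs: float = 100.0
) -> ArrayRecording:
    """Every channel = spatial gain x one repeated beat shape (noiseless)."""
    train = np.tile(beat, n_beats)
    return ArrayRecording(np.outer(train, gains), fs=fs)


@pytest.fixture(scope="session")
def healthy_beat() -> np.ndarray:
    model = healthy_beat_model()
    n = 83  # one period at 72 bpm, 100 Hz
    return model.evaluate(np.arange(n) / n)
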
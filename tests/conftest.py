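import numpy as np
import pytest

from lungscreen.audio_io import AudioRecording, ClassLabel
from lungscreen.preprocessing import Segment
from lungscreen.synthetic import SyntheticSpec, generate_corpus


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Ten recordings per class: enough to exercise every stage quickly."""
    return SyntheticSpec(counts_per_class={label: 10 for label in ClassLabel}, seed=123)


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    recordings, manifest = generate_corpus(small_spec)
    return recordings, manifest


@pytest.fixture(scope="session")
def small_feature_table(small_corpus):
    from lungscreen.pipeline import corpus_feature_table

    recordings, _ = small_corpus
    return corpus_feature_table(recordings)


@pytest.fixture
def noise_segment() -> Segment:
    """A 6 s normalized white-noise segment at the working rate."""
    rng = np.random.default_rng(7)
    x = rng.standard_normal(24000)
    x /= np.max(np.abs(x))
    return Segment(samples=x, sample_rate=4000, origin=("noise", 0))


@pytest.fixture
def tone_recording() -> AudioRecording:
    """A 300 Hz passband tone, 2 s at 4 kHz."""
    t = np.arange(8000) / 4000
    return AudioRecording(samples=0.5 * np.sin(2 * np.pi * 300 * t), sample_rate=4000)
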
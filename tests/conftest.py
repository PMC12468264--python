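import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mvmdeeg import ClassSpec, MVMDConfig, ToneSpec, gen_multichannel_tones

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TWO_TONE = ToneSpec(freqs=(10.0, 25.0), fs=128.0, duration=4.0, channels=2, seed=7)


@pytest.fixture(scope="session")
def two_tone_noiseless():
    """2 channels sharing 10 Hz and 25 Hz tones, fs=128, N=512, no noise."""
    return gen_multichannel_tones(TWO_TONE)


@pytest.fixture(scope="session")
def two_tone_snr20():
    """Same tones with 20 dB additive white Gaussian noise."""
    spec = ToneSpec(**{**TWO_TONE.__dict__, "snr_db": 20.0})
    return gen_multichannel_tones(spec)


@pytest.fixture(scope="session")
def mvmd_cfg():
    return MVMDConfig(n_modes=2, alpha=2000.0)


@pytest.fixture(scope="session")
def class_set_2():
    """Separable alpha-vs-beta 2-class epoch set (80 one-second epochs)."""
    spec = ClassSpec(n_epochs=40, seed=1)
    from mvmdeeg import gen_classification_set

    epochs, labels = gen_classification_set(spec)
    return spec, epochs, labels


@pytest.fixture(scope="session")
def desk_model_kwargs():
    """Reduced architecture for CPU-speed training tests."""
    return dict(
        conv_filters=8, gru_hidden=32, token_dim=64, n_heads=4, encoder_layers=1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
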
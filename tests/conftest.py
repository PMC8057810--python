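import warnings

import numpy as np
import pytest

from usvkit import synth
from usvkit.classify import ClassLabel
from usvkit.pipeline import detect_usvs
from usvkit.spectrogram import (SpectrogramImage, StftParams, adjust_contrast,
                                apply_high_pass, compute_spectrogram)

# skimage 0.26 still warns about its own morphology API churn
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_spec(power_db: np.ndarray, freq0_hz: float = 45_000.0,
              df_hz: float = 244.140625, dt_s: float = 0.000512) -> SpectrogramImage:
    """Wrap a raw dB matrix in a SpectrogramImage with USV-scale axes."""
    n_f, n_t = power_db.shape
    return SpectrogramImage(
        power_db=np.asarray(power_db, dtype=np.float64),
        freq_axis_hz=freq0_hz + df_hz * np.arange(n_f),
        time_axis_s=dt_s * (np.arange(n_t) + 0.5),
        params=StftParams(),
    )


def detect_template(tpl, seed=0, **session_kw):
    """Render one template into a quiet session and run full detection."""
    duration = tpl.start_s + tpl.duration_ms / 1000.0 + 0.1
    sess = synth.synthesize_session([tpl], duration_s=duration, seed=seed,
                                    **session_kw)
    return sess, detect_usvs(sess.waveform)


@pytest.fixture(scope="session")
def vocal_labels():
    return [lab for lab in ClassLabel if lab is not ClassLabel.NOISE]


@pytest.fixture(scope="session")
def small_session():
    """A 4 s session with four calls and two bursts, shared across tests."""
    rng = np.random.default_rng(7)
    tpls = []
    t = 0.2
    for lab in (ClassLabel.FLAT, ClassLabel.UP_FM, ClassLabel.CHEVRON,
                ClassLabel.STEP_UP):
        tpl = synth.make_template(lab, t, rng)
        tpls.append(tpl)
        t = tpl.start_s + tpl.duration_ms / 1000.0 + 0.6
    return synth.synthesize_session(tpls, n_bursts=2, duration_s=t + 0.3, seed=8)


@pytest.fixture(scope="session")
def small_detection(small_session):
    spec = apply_high_pass(compute_spectrogram(small_session.waveform))
    gray = adjust_contrast(spec)
    return spec, gray
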
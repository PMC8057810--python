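"""Spectrogram computation and gray-scale conversion.

The detection pipeline treats the time-frequency plane as a picture: a
short-time Fourier transform gives a dB power matrix, a high-pass crop
removes the audible band, and a normalisation/contrast step maps it into
[0, 1].  Everything downstream (thresholding, morphology, contrast scoring)
operates on that image with one fixed convention: rows are frequency bins
ascending, columns are time frames, coordinates are (row, col).

Polarity matters and is carried explicitly on :class:`GrayImage`.  The
normalised image is built from the *magnitude* of the dB values, so strong
signal (high power, small |dB|) maps to LOW intensity ("signal_low").
Binarisation runs on the complement, where signal is bright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .audio import AudioRecording

__all__ = [
    "StftParams",
    "SpectrogramImage",
    "GrayImage",
    "compute_spectrogram",
    "apply_high_pass",
    "adjust_contrast",
]

# floor applied to linear power before taking log, to keep dB finite on
# digitally silent pixels
_POWER_FLOOR = np.finfo(np.float64).tiny * 1e8


@dataclass(frozen=True)
class StftParams:
    """Short-time Fourier transform settings.

    Defaults follow the standard high-resolution configuration for 250 kHz
    USV recordings: 1024-point FFT of 256-sample Hamming windows with
    half-overlap (hop 128), i.e. ~244 Hz bin spacing and 0.512 ms frames.
    """

    nfft: int = 1024
    window_len: int = 256
    hop: int = 128
    window_shape: str = "hamming"

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.window_len <= self.nfft):
            raise ValueError("require 0 < hop <= window_len <= nfft")


@dataclass
class SpectrogramImage:
    """dB power matrix with explicit frequency/time axes (bin centers)."""

    power_db: np.ndarray  # (n_freq, n_frames)
    freq_axis_hz: np.ndarray
    time_axis_s: np.ndarray
    params: StftParams = field(default_factory=StftParams)

    def __post_init__(self) -> None:
        if self.power_db.shape != (self.freq_axis_hz.size, self.time_axis_s.size):
            raise ValueError("power_db shape inconsistent with axes")
        if self.freq_axis_hz.size > 1 and not np.all(np.diff(self.freq_axis_hz) > 0):
            raise ValueError("freq_axis_hz must be strictly increasing")
        if self.time_axis_s.size > 1 and not np.all(np.diff(self.time_axis_s) > 0):
            raise ValueError("time_axis_s must be strictly increasing")

    @property
    def frame_dt_s(self) -> float:
        if self.time_axis_s.size > 1:
            return float(self.time_axis_s[1] - self.time_axis_s[0])
        return float(self.params.hop)  # degenerate single-frame case

    @property
    def freq_step_hz(self) -> float:
        return float(self.freq_axis_hz[1] - self.freq_axis_hz[0])


@dataclass
class GrayImage:
    """Normalised image in [0, 1] plus the bookkeeping of how it was made.

    ``polarity`` is ``"signal_low"`` when strong signal maps to small values
    (the normalised-|dB| image) and ``"signal_high"`` for its complement.
    """

    intensity: np.ndarray
    polarity: str = "signal_low"
    gamma: float = 1.0
    lo: float = 0.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if self.polarity not in ("signal_low", "signal_high"):
            raise ValueError("polarity must be 'signal_low' or 'signal_high'")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not self.lo < self.hi:
            raise ValueError("lo must be < hi")

    def complement(self) -> "GrayImage":
        other = "signal_high" if self.polarity == "signal_low" else "signal_low"
        return GrayImage(1.0 - self.intensity, polarity=other,
                         gamma=self.gamma, lo=self.lo, hi=self.hi)

    def as_signal_high(self) -> "GrayImage":
        return self if self.polarity == "signal_high" else self.complement()

    def as_signal_low(self) -> "GrayImage":
        return self if self.polarity == "signal_low" else self.complement()


def compute_spectrogram(rec: AudioRecording, params: StftParams | None = None) -> SpectrogramImage:
    """STFT power in decibels: ``10 log10 |X(m, w)|^2``.

    Frames are taken without edge padding, so the number of columns is
    exactly ``floor((n_samples - window_len) / hop) + 1``.  Window tapering
    uses the configured shape (Hamming by default) and each windowed chunk is
    zero-padded to ``nfft`` points.
    """
    params = params or StftParams()
    n = rec.n_samples
    if n < params.window_len:
        raise ValueError(
            f"recording of {n} samples shorter than one {params.window_len}-sample window"
        )
    freqs, times, sxx = sps.spectrogram(
        rec.samples,
        fs=rec.sample_rate_hz,
        window=sps.get_window(params.window_shape, params.window_len),
        nperseg=params.window_len,
        noverlap=params.window_len - params.hop,
        nfft=params.nfft,
        detrend=False,
        scaling="spectrum",
        mode="magnitude",
    )
    power = np.maximum(sxx.astype(np.float64) ** 2, _POWER_FLOOR)
    power_db = 10.0 * np.log10(power)
    return SpectrogramImage(
        power_db=power_db,
        freq_axis_hz=freqs.astype(np.float64),
        time_axis_s=times.astype(np.float64),
        params=params,
    )


def apply_high_pass(spec: SpectrogramImage, cutoff_hz: float = 45_000.0) -> SpectrogramImage:
    """Drop rows below ``cutoff_hz`` (default 45 kHz, the audible-noise cut).

    Returns the sub-image whose first retained row center is >= the cutoff;
    axes are truncated consistently.  A cutoff of 0 is the identity.
    """
    nyquist = float(spec.freq_axis_hz[-1])
    if cutoff_hz > nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz above highest bin {nyquist} Hz")
    keep = spec.freq_axis_hz >= cutoff_hz
    return SpectrogramImage(
        power_db=spec.power_db[keep],
        freq_axis_hz=spec.freq_axis_hz[keep],
        time_axis_s=spec.time_axis_s,
        params=spec.params,
    )


def adjust_contrast(
    spec: SpectrogramImage,
    gamma: float = 1.0,
    lo: float = 0.0,
    hi: float = 1.0,
) -> GrayImage:
    """Map |dB| values into [0, 1] with an optional gamma curve.

    The image is ``((|P_dB| / max|P_dB| - lo) / (hi - lo)) ** gamma`` clipped
    to [0, 1].  With the defaults (gamma=1, lo=0, hi=1) this is the plain
    normalised-|dB| image.  Because spectral power is below 1 (negative dB),
    strong signal has *small* |dB| and therefore maps to LOW intensity; the
    returned polarity is ``"signal_low"``.
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    mag = np.abs(spec.power_db)
    peak = mag.max()
    if peak == 0 or np.ptp(mag) == 0:
        warnings.warn("all-constant spectrogram; returning all-zero image")
        return GrayImage(np.zeros_like(mag), polarity="signal_low",
                         gamma=gamma, lo=lo, hi=hi)
    scaled = np.clip((mag / peak - lo) / (hi - lo), 0.0, 1.0) ** gamma
    return GrayImage(scaled, polarity="signal_low", gamma=gamma, lo=lo, hi=hi)
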
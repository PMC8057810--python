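"""Mono WAV input/output for ultrasonic recordings.

Mouse ultrasonic vocalizations live between roughly 30 and 110 kHz, so
recordings are typically sampled at 250 kHz.  All downstream analysis assumes
a single channel; stereo files are rejected rather than silently mixed down.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioRecording", "load_audio", "write_wav"]

# analysis ceiling: the highest frequency the pipeline cares about (Hz)
DEFAULT_ANALYSIS_CEILING_HZ = 110_000.0

_PCM_SCALE = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31}


@dataclass(frozen=True)
class AudioRecording:
    """A mono recording with samples scaled to [-1, 1]."""

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("mono required: samples must be one-dimensional")
        if samples.size == 0:
            raise ValueError("zero-length audio")
        if not np.all(np.isfinite(samples)):
            raise ValueError("audio contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


def load_audio(path: str | Path, *, min_nyquist_hz: float | None = None) -> AudioRecording:
    """Read a mono PCM WAV file and scale samples to [-1, 1].

    Parameters
    ----------
    path:
        Readable WAV file (PCM 16/32-bit or IEEE float), single channel.
    min_nyquist_hz:
        If given, require ``sample_rate / 2 >= min_nyquist_hz`` so the
        configured analysis ceiling is representable.  Defaults to the
        110 kHz USV ceiling.

    Raises
    ------
    ValueError
        For multichannel input, zero-length audio, or a sampling rate too low
        for ultrasonic content.
    """
    path = Path(path)
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"mono required: {path} has {data.shape[1]} channels")
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    scale = _PCM_SCALE.get(data.dtype)
    samples = data.astype(np.float64)
    if scale is not None:
        samples /= scale
    ceiling = DEFAULT_ANALYSIS_CEILING_HZ if min_nyquist_hz is None else min_nyquist_hz
    if rate < 2 * ceiling:
        raise ValueError(
            f"sample rate {rate} Hz too low: need >= {2 * ceiling:.0f} Hz "
            f"for a {ceiling / 1000:.0f} kHz analysis ceiling"
        )
    return AudioRecording(samples=samples, sample_rate_hz=float(rate))


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as 32-bit float WAV (bit-exact round trip)."""
    wavfile.write(str(path), int(rec.sample_rate_hz), rec.samples.astype(np.float32))
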
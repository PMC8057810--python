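"""Synthetic USV sessions with known ground truth.

Renders frequency-modulated tonal syllables of the 11 vocal shape classes
(30-110 kHz), optional 2x harmonics, a Gaussian background noise floor, and
broadband noise bursts, onto a seed-deterministic waveform with a matching
annotation table.  The generator is the test bed for the whole pipeline:
every template obeys the class-defining geometry with margin (jumps >= 7 kHz,
flat modulation well under 5 kHz, no excursions in the ambiguous 5-6 kHz
modulation band), so a correct rule-based classifier must recover the
generating class on noiseless renderings.

What this world does NOT emulate: reverberation, microphone directionality,
overlapping callers, or the amplitude statistics of real rooms.  Green tests
on this generator establish the geometry of the pipeline, not its field
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .audio import AudioRecording
from .classify import ClassLabel
from .metrics import AnnotationSet

__all__ = [
    "USVTemplate",
    "SyntheticSession",
    "make_template",
    "ideal_track",
    "synthesize_usv",
    "synthesize_session",
    "make_benchmark_session",
    "DEFAULT_SAMPLE_RATE_HZ",
]

DEFAULT_SAMPLE_RATE_HZ = 250_000.0
MIN_CALL_SPACING_S = 0.015   # keeps truth unambiguous under the 10 ms merge
RAMP_MS = 1.0                # cosine amplitude ramps at the segment edges
HARMONIC_LEVEL_DB = -10.0    # harmonic component level relative to the call
NOISE_FLOOR_DBFS = -60.0
CALL_LEVEL_DBFS = -35.0      # default ~25 dB above the floor
BURST_LEVEL_DBFS = -32.0     # broadband bursts: loud external noise, ~28 dB
                             # above the floor so they segment like real
                             # heater/movement noise does
CLUTTER_LEVEL_DBFS = -56.0   # faint narrowband blips, barely above the
                             # adaptive-threshold margin: the low-intensity,
                             # low-contrast events that dominate real
                             # candidate pools and that the Local Median
                             # Filter exists to reject
FREQ_MIN_HZ = 30_000.0
FREQ_MAX_HZ = 110_000.0
# generated trajectories stay above the pipeline's 45 kHz high pass (plus
# margin) so class-defining geometry is never cropped out of the image
GEN_MIN_HZ = 47_000.0


@dataclass(frozen=True)
class USVTemplate:
    """One syllable to render: a trajectory through control points.

    ``freq_control_points`` is a list of (relative time in [0, 1], Hz)
    breakpoints; within a note the trajectory is a monotone spline.
    ``note_gaps`` lists (relative time, gap seconds) silent gaps splitting
    the syllable into notes (used by the step classes).
    """

    label: ClassLabel
    start_s: float
    duration_ms: float
    freq_control_points: tuple
    amplitude_dbfs: float = CALL_LEVEL_DBFS
    harmonic: bool = False
    note_gaps: tuple = ()

    def __post_init__(self) -> None:
        if self.label is ClassLabel.NOISE:
            raise ValueError("templates render vocal classes, not noise")
        if not 2.0 <= self.duration_ms <= 110.0:
            raise ValueError("duration must be within 2-110 ms")
        freqs = [f for _, f in self.freq_control_points]
        if min(freqs) < FREQ_MIN_HZ or max(freqs) > FREQ_MAX_HZ:
            raise ValueError("trajectory outside the 30-110 kHz band")


def synthesize_usv(tpl: USVTemplate, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> np.ndarray:
    """Render one syllable as a phase-continuous FM sinusoid.

    The frequency trajectory interpolates the control points with a monotone
    (shape-preserving) spline; the amplitude envelope applies 1 ms cosine
    ramps per note; silent gaps split the syllable into notes; a flagged
    harmonic adds a co-temporal component at twice the frequency, 10 dB
    down.  Raises if the trajectory (or its harmonic) exceeds Nyquist.
    """
    rel, freqs = zip(*sorted(tpl.freq_control_points))
    top = max(freqs) * (2.0 if tpl.harmonic else 1.0)
    if top >= sample_rate_hz / 2:
        raise ValueError("trajectory exceeds Nyquist")
    duration_s = tpl.duration_ms / 1000.0
    n = int(round(duration_s * sample_rate_hz))
    t_rel = np.arange(n) / max(n - 1, 1)
    if len(rel) == 1:
        inst_freq = np.full(n, freqs[0])
    else:
        inst_freq = PchipInterpolator(np.asarray(rel), np.asarray(freqs))(t_rel)

    # note intervals in samples: everything outside the silent gaps
    silent = []
    for pos, gap in tpl.note_gaps:
        g = int(round(gap * sample_rate_hz))
        center = int(round(pos * (n - 1)))
        silent.append((max(center - g // 2, 0), min(center + g - g // 2, n)))
    silent.sort()
    notes = []
    cursor = 0
    for lo, hi in silent:
        if lo > cursor:
            notes.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < n:
        notes.append((cursor, n))

    envelope = np.zeros(n)
    ramp = int(RAMP_MS / 1000.0 * sample_rate_hz)
    for lo, hi in notes:
        seg = hi - lo
        r = min(ramp, seg // 2)
        env = np.ones(seg)
        if r > 0:
            up = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
            env[:r] = up
            env[seg - r:] = up[::-1]
        envelope[lo:hi] = env

    amp = 10.0 ** (tpl.amplitude_dbfs / 20.0)
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / sample_rate_hz
    wave = amp * envelope * np.sin(phase)
    if tpl.harmonic:
        h_amp = amp * 10.0 ** (HARMONIC_LEVEL_DB / 20.0)
        wave = wave + h_amp * envelope * np.sin(2.0 * phase)
    return wave


def ideal_track(tpl: USVTemplate, dt_ms: float = 0.5):
    """The noiseless 0.5 ms frequency track a perfect detector would see.

    Returns ``(time_s, freq_hz, observed)`` where bins inside silent note
    gaps are marked unobserved (their frequency is the spline value, which a
    detector would interpolate through anyway).  Useful for testing the
    rule-based classifier without rendering audio.
    """
    duration_s = tpl.duration_ms / 1000.0
    n_bins = max(int(np.ceil(duration_s / (dt_ms / 1000.0))), 1)
    centers = tpl.start_s + (np.arange(n_bins) + 0.5) * dt_ms / 1000.0
    rel = (centers - tpl.start_s) / duration_s
    pts = sorted(tpl.freq_control_points)
    if len(pts) == 1:
        freq = np.full(n_bins, pts[0][1])
    else:
        xs, fs = zip(*pts)
        freq = PchipInterpolator(np.asarray(xs), np.asarray(fs))(np.clip(rel, 0, 1))
    observed = np.ones(n_bins, dtype=bool)
    for pos, gap in tpl.note_gaps:
        half = gap / duration_s / 2.0
        observed &= ~((rel > pos - half) & (rel < pos + half))
    return centers, freq, observed


# per-class template geometry; frequencies in kHz for readability
def make_template(
    label: ClassLabel,
    start_s: float,
    rng: np.random.Generator,
    amplitude_dbfs: float = CALL_LEVEL_DBFS,
    harmonic: bool = False,
) -> USVTemplate:
    """Draw a random class-consistent template.

    Geometry keeps a >= 1 kHz margin from every class-defining threshold so
    no template sits on a decision boundary.
    """
    k = 1000.0
    u = rng.uniform

    def pts(*pairs):
        return tuple((p, f * k) for p, f in pairs)

    gaps: tuple = ()
    if label is ClassLabel.FLAT:
        dur = u(20, 60)
        f0 = u(50, 90)
        cp = pts((0.0, f0), (1.0, f0 + u(-1.5, 1.5)))
    elif label is ClassLabel.SHORT:
        dur = u(4, 9)
        f0 = u(50, 90)
        cp = pts((0.0, f0), (1.0, f0 + u(-1.5, 1.5)))
    elif label is ClassLabel.UP_FM:
        dur = u(25, 60)
        f0 = u(47, 70)
        cp = pts((0.0, f0), (1.0, f0 + u(9, 25)))
    elif label is ClassLabel.DOWN_FM:
        dur = u(25, 60)
        f0 = u(72, 95)
        cp = pts((0.0, f0), (1.0, f0 - u(9, 25)))
    elif label is ClassLabel.CHEVRON:
        dur = u(30, 60)
        f0 = u(48, 70)
        rise = u(9, 18)
        cp = pts((0.0, f0), (0.5, f0 + rise), (1.0, f0 + u(-2, 2)))
    elif label is ClassLabel.REV_CHEVRON:
        dur = u(30, 60)
        f0 = u(66, 90)
        dip = u(9, 18)
        cp = pts((0.0, f0), (0.5, f0 - dip), (1.0, f0 + u(-2, 2)))
    elif label is ClassLabel.COMPLEX:
        dur = u(40, 80)
        f0 = u(55, 75)
        a = u(9, 14)
        cp = pts((0.0, f0), (0.25, f0 + a), (0.5, f0 - u(1, 3)),
                 (0.75, f0 + a), (1.0, f0 - u(1, 3)))
    elif label is ClassLabel.STEP_UP:
        dur = u(25, 50)
        f0 = u(47, 70)
        jump = u(8, 18)
        cp = pts((0.0, f0), (0.49, f0), (0.51, f0 + jump), (1.0, f0 + jump))
        gaps = ((0.5, u(0.002, 0.006)),)
    elif label is ClassLabel.STEP_DOWN:
        dur = u(25, 50)
        f0 = u(65, 95)
        jump = u(8, 18)
        cp = pts((0.0, f0), (0.49, f0), (0.51, f0 - jump), (1.0, f0 - jump))
        gaps = ((0.5, u(0.002, 0.006)),)
    elif label is ClassLabel.TWO_STEPS:
        dur = u(35, 60)
        f0 = u(47, 65)
        s1, s2 = u(8, 14), u(8, 14)
        cp = pts((0.0, f0), (0.32, f0), (0.35, f0 + s1), (0.65, f0 + s1),
                 (0.68, f0 + s1 + s2), (1.0, f0 + s1 + s2))
        gaps = ((1 / 3, u(0.002, 0.005)), (2 / 3, u(0.002, 0.005)))
    elif label is ClassLabel.MULTIPLE_STEPS:
        dur = u(50, 90)
        f0 = u(47, 55)
        s1, s2, s3 = (u(8, 12) for _ in range(3))
        cp = pts((0.0, f0), (0.23, f0), (0.27, f0 + s1), (0.48, f0 + s1),
                 (0.52, f0 + s1 + s2), (0.73, f0 + s1 + s2),
                 (0.77, f0 + s1 + s2 + s3), (1.0, f0 + s1 + s2 + s3))
        gaps = ((0.25, u(0.002, 0.005)), (0.5, u(0.002, 0.005)),
                (0.75, u(0.002, 0.005)))
    else:
        raise ValueError(f"no template geometry for {label}")

    if harmonic:
        # the 2x harmonic must stay below Nyquist at the default rate; shift
        # the trajectory down, keeping the fundamental above the detectable
        # floor (a fundamental pushed under the 45 kHz high pass would be
        # cropped and the overtone mistaken for the call)
        cap = DEFAULT_SAMPLE_RATE_HZ / 2.0 / 2.0 * 0.93  # ~58 kHz fundamental
        maxf = max(f for _, f in cp)
        if maxf > cap:
            shift = maxf - cap
            if min(f for _, f in cp) - shift < GEN_MIN_HZ:
                raise ValueError(
                    f"{label.value} geometry too wide to carry a sub-Nyquist harmonic")
            cp = tuple((p, f - shift) for p, f in cp)

    return USVTemplate(label=label, start_s=start_s, duration_ms=float(dur),
                       freq_control_points=cp, amplitude_dbfs=amplitude_dbfs,
                       harmonic=harmonic, note_gaps=gaps)


def make_benchmark_session(
    n_calls: int = 50,
    n_bursts: int = 20,
    n_clutter: int = 60,
    duration_s: float = 60.0,
    seed: int = 0,
) -> "SyntheticSession":
    """The standard end-to-end benchmark world: a 60 s recording with 50
    calls cycling through all 11 classes at ~25 dB SNR (+-3 dB), harmonics
    on some flat/short calls, 20 loud broadband bursts, and 60 faint
    clutter blips (the artifact mass the contrast filter needs).
    """
    rng = np.random.default_rng(seed)
    labels = [lab for lab in ClassLabel if lab is not ClassLabel.NOISE]
    harmonic_ok = {ClassLabel.FLAT, ClassLabel.SHORT}
    templates = []
    t = 0.2
    # spread calls evenly over the session, leaving room for bursts/clutter
    mean_gap = max((duration_s - 2.0) / max(n_calls, 1) - 0.06, 0.05)
    for i in range(n_calls):
        lab = labels[i % len(labels)]
        harmonic = lab in harmonic_ok and (i // len(labels)) % 2 == 0
        tpl = make_template(lab, t, rng,
                            amplitude_dbfs=CALL_LEVEL_DBFS + rng.uniform(-3, 3),
                            harmonic=harmonic)
        templates.append(tpl)
        t = tpl.start_s + tpl.duration_ms / 1000.0 + mean_gap * rng.uniform(0.8, 1.2)
    if t > duration_s - 0.1:
        raise ValueError("calls do not fit in the requested duration")
    return synthesize_session(templates, n_bursts=n_bursts, n_clutter=n_clutter,
                              duration_s=duration_s, seed=seed + 1)


@dataclass
class SyntheticSession:
    """A rendered session: waveform, truth table, and its ingredients."""

    waveform: AudioRecording
    truth: AnnotationSet
    templates: list = field(default_factory=list)
    noise_floor_dbfs: float = NOISE_FLOOR_DBFS
    burst_times_s: np.ndarray | None = None
    seed: int = 0


def synthesize_session(
    templates: list[USVTemplate],
    noise_floor_dbfs: float = NOISE_FLOOR_DBFS,
    n_bursts: int = 0,
    burst_level_dbfs: float = BURST_LEVEL_DBFS,
    n_clutter: int = 0,
    clutter_level_dbfs: float = CLUTTER_LEVEL_DBFS,
    duration_s: float | None = None,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    seed: int = 0,
) -> SyntheticSession:
    """Render templates onto a noisy background, fully seed-deterministic.

    Templates must be spaced >= 15 ms apart (so the 10 ms merge rule cannot
    fuse distinct calls); bursts are band-limited noise (30-120 kHz, 5-20 ms)
    placed at least 15 ms clear of every call and of each other.  The truth
    table has one row per template (label, harmonic flag) plus one ``noise``
    row per burst.

    ``n_clutter`` adds faint narrowband blips (5-7 ms tones just above the
    floor).  They emulate the low-intensity events behind the segmentation
    artifacts that dominate real candidate pools — the population the Local
    Median Filter rejects — and are NOT listed in the truth table, exactly as
    real segmentation artifacts are not annotated events.
    """
    templates = sorted(templates, key=lambda t: t.start_s)
    for a, b in zip(templates[:-1], templates[1:]):
        gap = b.start_s - (a.start_s + a.duration_ms / 1000.0)
        if gap < MIN_CALL_SPACING_S:
            raise ValueError(
                f"templates at {a.start_s:.3f}s and {b.start_s:.3f}s closer than "
                f"{MIN_CALL_SPACING_S * 1000:.0f} ms")
    rng = np.random.default_rng(seed)
    if duration_s is None:
        last = max((t.start_s + t.duration_ms / 1000.0 for t in templates), default=0.5)
        duration_s = last + 0.1
    n = int(round(duration_s * sample_rate_hz))
    floor_amp = 10.0 ** (noise_floor_dbfs / 20.0)
    wave = rng.normal(0.0, floor_amp, size=n)

    for tpl in templates:
        seg = synthesize_usv(tpl, sample_rate_hz)
        lo = int(round(tpl.start_s * sample_rate_hz))
        hi = min(lo + seg.size, n)
        wave[lo:hi] += seg[: hi - lo]

    # occupied intervals (calls) to keep bursts clear of
    occupied = [(t.start_s, t.start_s + t.duration_ms / 1000.0) for t in templates]
    burst_times = []
    guard = MIN_CALL_SPACING_S
    attempts = 0
    while len(burst_times) < n_bursts and attempts < 10000:
        attempts += 1
        b_dur = rng.uniform(0.005, 0.020)
        b_start = rng.uniform(0.0, duration_s - b_dur)
        span = (b_start - guard, b_start + b_dur + guard)
        if any(s < span[1] and e > span[0] for s, e in occupied):
            continue
        occupied.append((b_start, b_start + b_dur))
        burst_times.append(b_start)
        lo = int(round(b_start * sample_rate_hz))
        m = int(round(b_dur * sample_rate_hz))
        burst = rng.normal(0.0, 1.0, size=m)
        # band-limit to the ultrasonic range via FFT masking
        spec_f = np.fft.rfft(burst)
        f = np.fft.rfftfreq(m, 1.0 / sample_rate_hz)
        spec_f[(f < 30_000.0) | (f > 120_000.0)] = 0.0
        burst = np.fft.irfft(spec_f, m)
        rms = np.sqrt(np.mean(burst ** 2))
        if rms > 0:
            burst *= 10.0 ** (burst_level_dbfs / 20.0) / rms
        ramp = max(int(0.001 * sample_rate_hz), 1)
        env = np.ones(m)
        up = 0.5 * (1 - np.cos(np.pi * np.arange(min(ramp, m // 2)) / ramp))
        env[: up.size] = up
        env[m - up.size:] = up[::-1]
        wave[lo: lo + m] += burst * env
    if len(burst_times) < n_bursts:
        raise ValueError("could not place all bursts with the required spacing")

    placed_clutter = 0
    attempts = 0
    while placed_clutter < n_clutter and attempts < 20000:
        attempts += 1
        c_dur = rng.uniform(0.005, 0.007)
        c_start = rng.uniform(0.0, duration_s - c_dur)
        span = (c_start - guard, c_start + c_dur + guard)
        if any(s < span[1] and e > span[0] for s, e in occupied):
            continue
        occupied.append((c_start, c_start + c_dur))
        placed_clutter += 1
        m = int(round(c_dur * sample_rate_hz))
        lo = int(round(c_start * sample_rate_hz))
        f0 = rng.uniform(48_000.0, 108_000.0)
        amp = 10.0 ** (clutter_level_dbfs / 20.0)
        tone = amp * np.sin(2.0 * np.pi * f0 * np.arange(m) / sample_rate_hz)
        ramp = max(int(0.001 * sample_rate_hz), 1)
        env = np.ones(m)
        up = 0.5 * (1 - np.cos(np.pi * np.arange(min(ramp, m // 2)) / ramp))
        env[: up.size] = up
        env[m - up.size:] = up[::-1]
        wave[lo: lo + m] += tone * env
    if placed_clutter < n_clutter:
        raise ValueError("could not place all clutter blips with the required spacing")

    peak = np.abs(wave).max()
    if peak > 1.0:
        wave /= peak * 1.01
    wave = wave.astype(np.float32).astype(np.float64)  # bit-exact WAV round trip

    starts = [t.start_s for t in templates] + burst_times
    labels = [t.label.value for t in templates] + ["noise"] * len(burst_times)
    harm = [t.harmonic for t in templates] + [False] * len(burst_times)
    truth = AnnotationSet(start_s=np.asarray(starts), label=labels,
                          harmonic=np.asarray(harm))
    return SyntheticSession(
        waveform=AudioRecording(samples=wave, sample_rate_hz=sample_rate_hz),
        truth=truth, templates=list(templates),
        noise_floor_dbfs=noise_floor_dbfs,
        burst_times_s=np.asarray(burst_times), seed=seed,
    )
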
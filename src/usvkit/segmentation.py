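"""Segmentation of USV candidates from the gray spectrogram image.

The stages mirror a classical document-binarisation pipeline applied to
bioacoustics:

1. adaptive binarisation with a local-mean threshold computed in O(1) per
   pixel from an integral image;
2. morphological refinement (opening, directional dilations, small-object
   removal);
3. connected-component extraction with a 10 ms merge rule — blobs closer in
   time than the minimum observed inter-syllable interval belong to the same
   syllable;
4. per-candidate feature tracks (mean frequency / intensity every 0.5 ms),
   harmonic detection, and fixed-size image export for the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import morphology as skmorph
from skimage.measure import label as sklabel
from skimage.transform import resize as skresize

from .spectrogram import GrayImage, SpectrogramImage

__all__ = [
    "IntegralImage",
    "BinaryMask",
    "USVCandidate",
    "CandidateImage",
    "integral_image",
    "adaptive_binarize",
    "refine_morphology",
    "extract_candidates",
    "summarize_tracks",
    "detect_harmonic",
    "render_candidate_image",
    "TRACK_DT_MS",
    "MERGE_GAP_MS",
    "MIN_COMPONENT_PIXELS",
]

log = logging.getLogger(__name__)

TRACK_DT_MS = 0.5          # feature-track bin width
MERGE_GAP_MS = 10.0        # blobs closer than this belong to one syllable
MIN_COMPONENT_PIXELS = 60  # ~2 ms syllable at default resolution
CANDIDATE_IMAGE_SIZE = 227
CANDIDATE_WINDOW_MS = 220.0  # twice the longest USV seen in mice


@dataclass(frozen=True)
class IntegralImage:
    """Summed-area table: cell (x, y) holds the sum of all values above-left
    inclusive, built with the recurrence
    ``I(x,y) = f(x,y) + I(x-1,y) + I(x,y-1) - I(x-1,y-1)``."""

    summed: np.ndarray

    def rect_sum(self, r1, c1, r2, c2):
        """Sum of f over rows r1..r2 and cols c1..c2 (inclusive corners)."""
        s = self.summed
        total = s[r2, c2].astype(np.float64, copy=True)
        r1 = np.asarray(r1)
        c1 = np.asarray(c1)
        top = np.where(r1 > 0, s[np.maximum(r1 - 1, 0), c2], 0.0)
        left = np.where(c1 > 0, s[r2, np.maximum(c1 - 1, 0)], 0.0)
        corner = np.where((r1 > 0) & (c1 > 0),
                          s[np.maximum(r1 - 1, 0), np.maximum(c1 - 1, 0)], 0.0)
        return total - top - left + corner


@dataclass
class BinaryMask:
    """0/1 foreground mask; foreground = putative vocal segments."""

    mask: np.ndarray
    sensitivity_t: float = 0.2
    neighborhood_s: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.mask = m.astype(bool)


def integral_image(img: GrayImage | np.ndarray) -> IntegralImage:
    values = img.intensity if isinstance(img, GrayImage) else np.asarray(img)
    if values.size == 0:
        raise ValueError("empty image")
    return IntegralImage(values.astype(np.float64).cumsum(axis=0).cumsum(axis=1))


def _local_mean(values: np.ndarray, s: int) -> np.ndarray:
    """Mean over an s x s window centred on each pixel, truncated at borders
    and divided by the true number of pixels in the truncated window."""
    h, w = values.shape
    half = s // 2
    padded = np.zeros((h + 1, w + 1), dtype=np.float64)
    padded[1:, 1:] = values
    cs = padded.cumsum(axis=0).cumsum(axis=1)
    r = np.arange(h)
    c = np.arange(w)
    r1 = np.maximum(r - half, 0)
    r2 = np.minimum(r + half, h - 1)
    c1 = np.maximum(c - half, 0)
    c2 = np.minimum(c + half, w - 1)
    # box sums via the padded cumulative table
    box = (cs[np.ix_(r2 + 1, c2 + 1)] - cs[np.ix_(r1, c2 + 1)]
           - cs[np.ix_(r2 + 1, c1)] + cs[np.ix_(r1, c1)])
    counts = np.outer(r2 - r1 + 1, c2 - c1 + 1)
    return box / counts


def adaptive_binarize(img: GrayImage, t: float = 0.2, s: int | None = None) -> BinaryMask:
    """Local-mean adaptive thresholding.

    A pixel is foreground when its value on the signal-low image is at least
    a fraction ``t`` *below* the local mean of an ``s`` x ``s`` neighbourhood:
    ``dark(x, y) <= (1 - t) * C(x, y)``.  On the complement (signal-high)
    image this is the classic Bradley rule with dark foreground.  ``t``
    defaults to 0.2; ``s`` defaults to the smallest odd integer >= 1/8 of the
    smaller image dimension.
    """
    if not 0 < t < 1:
        raise ValueError("sensitivity t must be in (0, 1)")
    dark = img.as_signal_low().intensity
    h, w = dark.shape
    if s is None:
        s = int(np.ceil(min(h, w) / 8.0))
        if s % 2 == 0:
            s += 1
        s = max(s, 3)
    if s < 3 or s % 2 == 0:
        raise ValueError("neighbourhood s must be odd and >= 3")
    if s > min(h, w):
        raise ValueError(f"neighbourhood s={s} larger than image {dark.shape}")
    if np.ptp(dark) == 0:
        # no pixel deviates from its local mean: nothing to segment
        return BinaryMask(np.zeros_like(dark, dtype=bool), t, s)
    local = _local_mean(dark, s)
    return BinaryMask(dark <= (1.0 - t) * local, t, s)


def refine_morphology(mask: BinaryMask) -> BinaryMask:
    """Morphological clean-up, in order: (i) opening with a 4 x 2 rectangle;
    (ii) dilation with a length-4 vertical line; (iii) removal of
    8-connected components with fewer than 60 pixels; (iv) dilation with a
    length-4 horizontal line."""
    m = mask.mask.astype(bool)
    m = skmorph.opening(m, footprint=np.ones((4, 2), dtype=bool))
    m = skmorph.dilation(m, footprint=np.ones((4, 1), dtype=bool))
    m = skmorph.remove_small_objects(m, max_size=MIN_COMPONENT_PIXELS - 1,
                                     connectivity=2)
    m = skmorph.dilation(m, footprint=np.ones((1, 4), dtype=bool))
    return BinaryMask(m, mask.sensitivity_t, mask.neighborhood_s)


@dataclass
class USVCandidate:
    """A segmented syllable candidate.

    ``components`` keeps the constituent connected blobs (a syllable may be
    several blobs merged by the 10 ms rule, or a call plus its harmonic);
    tracks are filled by :func:`summarize_tracks` and refined by
    :func:`detect_harmonic`.
    """

    id: int
    pixels: np.ndarray                       # (n, 2) array of (row, col)
    components: list = field(default_factory=list)
    start_s: float = 0.0
    end_s: float = 0.0
    freq_min_hz: float = 0.0
    freq_max_hz: float = 0.0
    track_time_s: np.ndarray | None = None
    track_freq_hz: np.ndarray | None = None
    track_intensity_db: np.ndarray | None = None
    track_observed: np.ndarray | None = None
    track_bandwidth_hz: np.ndarray | None = None
    harmonic: bool = False
    harmonic_track: dict | None = None
    main_pixels: np.ndarray | None = None  # pixels minus harmonic components
    contrast: float | None = None

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0

    @property
    def mean_intensity_db(self) -> float:
        if self.track_intensity_db is None:
            return float("nan")
        return float(np.mean(self.track_intensity_db))


def _component_pixels(mask: np.ndarray) -> list[np.ndarray]:
    labels = sklabel(mask, connectivity=2)
    comps = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        comps.append(np.column_stack([rows, cols]))
    return comps


def extract_candidates(mask: BinaryMask, spec: SpectrogramImage) -> list[USVCandidate]:
    """Connected components merged by the 10 ms rule, sorted by start time.

    Blobs whose time gap (end of one to start of the next) is below 10 ms are
    transitively combined into a single candidate; overlapping blobs (e.g. a
    call and its harmonic) merge for the same reason.
    """
    if mask.mask.shape != spec.power_db.shape:
        raise ValueError("mask and spectrogram shapes differ")
    comps = _component_pixels(mask.mask)
    if not comps:
        return []
    times = spec.time_axis_s
    spans = [(times[px[:, 1].min()], times[px[:, 1].max()]) for px in comps]
    order = np.argsort([s[0] for s in spans], kind="stable")
    gap_s = MERGE_GAP_MS / 1000.0

    groups: list[list[int]] = []
    group_end = -np.inf
    for idx in order:
        start, end = spans[idx]
        if groups and start - group_end < gap_s:
            groups[-1].append(idx)
        else:
            groups.append([idx])
        group_end = max(group_end, end)

    out = []
    for cid, members in enumerate(groups):
        pieces = [comps[i] for i in members]
        pixels = np.concatenate(pieces)
        rows = pixels[:, 0]
        cols = pixels[:, 1]
        out.append(
            USVCandidate(
                id=cid,
                pixels=pixels,
                components=pieces,
                start_s=float(times[cols.min()]),
                end_s=float(times[cols.max()]),
                freq_min_hz=float(spec.freq_axis_hz[rows.min()]),
                freq_max_hz=float(spec.freq_axis_hz[rows.max()]),
            )
        )
    return out


def _bin_track(pixels: np.ndarray, spec: SpectrogramImage,
               start_s: float, end_s: float):
    """Per-0.5 ms mean frequency, mean dB intensity, spread, and an observed
    flag; bins with no pixels are linearly interpolated from neighbours."""
    dt = TRACK_DT_MS / 1000.0
    n_bins = max(int(np.ceil((end_s - start_s) / dt)), 1)
    centers = start_s + (np.arange(n_bins) + 0.5) * dt
    t_pix = spec.time_axis_s[pixels[:, 1]]
    f_pix = spec.freq_axis_hz[pixels[:, 0]]
    i_pix = spec.power_db[pixels[:, 0], pixels[:, 1]]
    idx = np.clip(((t_pix - start_s) / dt).astype(int), 0, n_bins - 1)

    freq = np.full(n_bins, np.nan)
    inten = np.full(n_bins, np.nan)
    spread = np.zeros(n_bins)
    observed = np.zeros(n_bins, dtype=bool)
    for b in np.unique(idx):
        sel = idx == b
        freq[b] = f_pix[sel].mean()
        inten[b] = i_pix[sel].mean()
        spread[b] = f_pix[sel].max() - f_pix[sel].min()
        observed[b] = True
    if not observed.all():
        known = np.nonzero(observed)[0]
        missing = np.nonzero(~observed)[0]
        freq[missing] = np.interp(missing, known, freq[known])
        inten[missing] = np.interp(missing, known, inten[known])
        spread[missing] = np.interp(missing, known, spread[known])
    return centers, freq, inten, spread, observed


def summarize_tracks(cand: USVCandidate, spec: SpectrogramImage) -> USVCandidate:
    """Fill the candidate's 0.5 ms feature tracks from its pixels."""
    if cand.pixels.size == 0:
        raise ValueError("candidate has no pixels")
    centers, freq, inten, spread, observed = _bin_track(
        cand.pixels, spec, cand.start_s, cand.end_s)
    cand.track_time_s = centers
    cand.track_freq_hz = freq
    cand.track_intensity_db = inten
    cand.track_bandwidth_hz = spread
    cand.track_observed = observed
    return cand


def detect_harmonic(cand: USVCandidate, spec: SpectrogramImage) -> USVCandidate:
    """Flag harmonic components and separate them from the main track.

    The longest-duration component is the main component; durations within
    2 ms of each other are treated as tied and resolved by higher mean
    intensity (an overtone can cover marginally more frames than its
    fundamental through spectral smear, but it is always weaker).  Any other
    component that overlaps the main one in time, is itself continuous, sits
    above the main component's frequencies at roughly its octave (mean
    frequency ratio 1.7-2.4), and is at least 3 dB weaker is a harmonic — an extra feature of the syllable, never a separate call.  The
    intensity requirement keeps fragmented broadband clutter (co-temporal
    pieces of equal loudness) from being stripped into a clean tonal track.

    When harmonics are found, the main track is recomputed without their
    pixels (a 0.5 ms bin averaging the fundamental with its octave would
    report a frequency between the two) and the harmonic pixels get their
    own track.
    """
    if not cand.components:
        cand.components = [cand.pixels]
    spans = []
    for px in cand.components:
        cmin, cmax = px[:, 1].min(), px[:, 1].max()
        spans.append((spec.time_axis_s[cmin], spec.time_axis_s[cmax]))
    durations = [e - s for s, e in spans]
    mean_int = [spec.power_db[px[:, 0], px[:, 1]].mean() for px in cand.components]
    best = max(durations)
    tied = [i for i, d in enumerate(durations) if best - d <= 0.002]
    main_idx = max(tied, key=lambda i: mean_int[i])
    main_start, main_end = spans[main_idx]
    main_mean_freq = spec.freq_axis_hz[cand.components[main_idx][:, 0]].mean()

    harmonic_parts = []
    for i, (s, e) in enumerate(spans):
        if i == main_idx:
            continue
        overlaps = (s <= main_end) and (e >= main_start)
        px = cand.components[i]
        cols = np.unique(px[:, 1])
        continuous = cols.size == cols.max() - cols.min() + 1
        ratio = spec.freq_axis_hz[px[:, 0]].mean() / main_mean_freq
        near_octave = 1.7 <= ratio <= 2.4
        weaker = mean_int[i] <= mean_int[main_idx] - 3.0
        if overlaps and continuous and near_octave and weaker:
            harmonic_parts.append(i)

    cand.harmonic = bool(harmonic_parts)
    if cand.harmonic:
        harm_px = np.concatenate([cand.components[i] for i in harmonic_parts])
        main_px = np.concatenate(
            [px for i, px in enumerate(cand.components) if i not in harmonic_parts])
        cand.main_pixels = main_px
        centers, freq, inten, spread, observed = _bin_track(
            main_px, spec, cand.start_s, cand.end_s)
        cand.track_time_s = centers
        cand.track_freq_hz = freq
        cand.track_intensity_db = inten
        cand.track_bandwidth_hz = spread
        cand.track_observed = observed
        h_start = spec.time_axis_s[harm_px[:, 1].min()]
        h_end = spec.time_axis_s[harm_px[:, 1].max()]
        h = _bin_track(harm_px, spec, float(h_start), float(h_end))
        cand.harmonic_track = {
            "time_s": h[0], "freq_hz": h[1], "intensity_db": h[2],
        }
    return cand


@dataclass(frozen=True)
class CandidateImage:
    """A 227 x 227 raster of the candidate centred in a 220 ms window."""

    pixels227: np.ndarray
    candidate_id: int
    window_span_ms: float = CANDIDATE_WINDOW_MS

    def __post_init__(self) -> None:
        if self.pixels227.shape != (CANDIDATE_IMAGE_SIZE, CANDIDATE_IMAGE_SIZE):
            raise ValueError("candidate image must be 227 x 227")


def render_candidate_image(
    cand: USVCandidate,
    spec: SpectrogramImage,
    gray: GrayImage | None = None,
) -> CandidateImage:
    """Export the classifier input image: a 220 ms window centred on the
    candidate midpoint over the full retained frequency range, resampled to
    227 x 227 and normalised to [0, 1] with signal bright."""
    if gray is None:
        from .spectrogram import adjust_contrast
        gray = adjust_contrast(spec)
    bright = gray.as_signal_high().intensity
    if cand.duration_ms > CANDIDATE_WINDOW_MS:
        log.warning("candidate %d (%.1f ms) longer than the %d ms window; cropping",
                    cand.id, cand.duration_ms, int(CANDIDATE_WINDOW_MS))
    dt = spec.frame_dt_s
    half_cols = int(round(CANDIDATE_WINDOW_MS / 1000.0 / dt / 2))
    mid_t = 0.5 * (cand.start_s + cand.end_s)
    mid_col = int(round((mid_t - spec.time_axis_s[0]) / dt))
    n_cols = 2 * half_cols
    background = float(np.median(bright))
    window = np.full((bright.shape[0], n_cols), background)
    lo = mid_col - half_cols
    hi = mid_col + half_cols
    src_lo = max(lo, 0)
    src_hi = min(hi, bright.shape[1])
    window[:, src_lo - lo: src_hi - lo] = bright[:, src_lo:src_hi]
    window = window[::-1]  # image convention: high frequency at the top
    img = skresize(window, (CANDIDATE_IMAGE_SIZE, CANDIDATE_IMAGE_SIZE),
                   anti_aliasing=True, mode="edge")
    span = np.ptp(img)
    img = (img - img.min()) / span if span > 0 else np.zeros_like(img)
    return CandidateImage(pixels227=img, candidate_id=cand.id)
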
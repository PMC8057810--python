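"""Local Median Filter: contrast scoring and CDF-curvature thresholding.

Segmentation artifacts — blobs the binariser hallucinates out of background
texture — have little contrast against their surroundings, while real calls
are markedly darker (stronger) than their local background.  Each candidate
gets a contrast ratio ``C_k = median(candidate pixels) / median(bounding
window)`` on the signal-low gray image, so real calls score well below 1 and
artifacts score near 1.  The per-file rejection threshold tau is placed at
the inflection (maximum curvature) of the cumulative distribution of the
``C_k``, found on a 35-point downsampling of the empirical CDF; when no
interior curvature maximum exists the conservative default tau = 0.92 is
used.  Candidates with ``C_k <= tau`` are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import USVCandidate
from .spectrogram import GrayImage, SpectrogramImage

__all__ = [
    "ContrastResult",
    "ThresholdEstimate",
    "contrast_score",
    "estimate_threshold",
    "filter_candidates",
    "parametric_curvature",
    "FALLBACK_TAU",
    "CDF_POINTS",
]

FALLBACK_TAU = 0.92
CDF_POINTS = 35
# bounding-window margins around the candidate extent
WINDOW_FREQ_PAD_HZ = 2500.0
WINDOW_TIME_PAD_S = 0.1
# scores below this count are too few for a meaningful CDF knee
MIN_SCORES_FOR_KNEE = 5
# the knee separates a majority of genuine calls below from a minority of
# low-contrast artifacts above, so it must keep at least half of the
# candidates and reject at least a tenth of them
KNEE_CDF_RANGE = (0.5, 0.9)
# ... and the artifact mass entered at the knee must be a mass: at least
# KNEE_MIN_RISE of the CDF must accumulate within KNEE_RISE_SPAN of the
# value range after the bend (curvature alone favours bends next to flat
# plateaus, where a single stray candidate can imitate a foot)
KNEE_MIN_RISE = 0.10
KNEE_RISE_SPAN = 0.10


@dataclass(frozen=True)
class ContrastResult:
    """Contrast of one candidate against its local background."""

    candidate_id: int
    x_hat: float        # median candidate-pixel intensity (signal-low units)
    w_hat: float        # median intensity of the bounding window
    c_k: float          # x_hat / w_hat
    window: tuple       # (row_lo, row_hi, col_lo, col_hi), inclusive


@dataclass
class ThresholdEstimate:
    """Per-file rejection threshold and the CDF it came from."""

    tau: float
    cdf_points: np.ndarray          # (n, 2) of (C_k value, cumulative fraction)
    curvature: np.ndarray           # kappa at each interior downsampled point
    used_fallback: bool


def contrast_score(cand: USVCandidate, img: GrayImage,
                   spec: SpectrogramImage) -> ContrastResult:
    """Median candidate intensity over median bounding-window intensity.

    The window extends the candidate's frequency extent by 2.5 kHz and its
    time extent by 100 ms on each side, clipped to the image; candidate
    pixels are included in the window median (they are a small fraction of
    it, so the window median tracks the background).  When harmonic
    components have been identified, the candidate median is taken over the
    main trace only: overtones are ~10 dB weaker features and would drag the
    syllable's contrast toward the background.
    """
    if cand.pixels.size == 0:
        raise ValueError("candidate has no pixels")
    own_pixels = cand.main_pixels if cand.main_pixels is not None else cand.pixels
    low = img.as_signal_low().intensity
    if low.shape != spec.power_db.shape:
        raise ValueError("gray image and spectrogram shapes differ")

    f = spec.freq_axis_hz
    t = spec.time_axis_s
    row_lo = int(np.searchsorted(f, cand.freq_min_hz - WINDOW_FREQ_PAD_HZ, "left"))
    row_hi = int(np.searchsorted(f, cand.freq_max_hz + WINDOW_FREQ_PAD_HZ, "right")) - 1
    col_lo = int(np.searchsorted(t, cand.start_s - WINDOW_TIME_PAD_S, "left"))
    col_hi = int(np.searchsorted(t, cand.end_s + WINDOW_TIME_PAD_S, "right")) - 1
    row_lo = max(row_lo, 0)
    col_lo = max(col_lo, 0)
    row_hi = min(row_hi, low.shape[0] - 1)
    col_hi = min(col_hi, low.shape[1] - 1)
    if row_hi < row_lo or col_hi < col_lo:
        raise ValueError("degenerate bounding window after clipping")

    x_hat = float(np.median(low[own_pixels[:, 0], own_pixels[:, 1]]))
    w_hat = float(np.median(low[row_lo:row_hi + 1, col_lo:col_hi + 1]))
    if w_hat == 0:
        raise ValueError("window median is zero; contrast undefined")
    return ContrastResult(
        candidate_id=cand.id,
        x_hat=x_hat,
        w_hat=w_hat,
        c_k=x_hat / w_hat,
        window=(row_lo, row_hi, col_lo, col_hi),
    )


def parametric_curvature(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed curvature at interior points of a sampled plane curve.

    Each triple of consecutive points is fit with a local second-order
    parametric arc (x(t), y(t)) at t = -1, 0, 1; central differences give the
    derivatives and the curvature is ``(x'y'' - x''y') / (x'^2 + y'^2)^1.5``.
    For a curve traversed left to right the sign is that of the second
    derivative: negative where the curve bends down (concave).  Returns one
    value per interior point (length ``len(x) - 2``).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        return np.empty(0)
    dx = (x[2:] - x[:-2]) / 2.0
    dy = (y[2:] - y[:-2]) / 2.0
    ddx = x[2:] - 2.0 * x[1:-1] + x[:-2]
    ddy = y[2:] - 2.0 * y[1:-1] + y[:-2]
    denom = (dx ** 2 + dy ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dx * ddy - ddx * dy) / denom
    kappa[~np.isfinite(kappa)] = 0.0
    return kappa


def estimate_threshold(scores: list[ContrastResult] | np.ndarray) -> ThresholdEstimate:
    """Place tau at the maximum-curvature point of the contrast CDF.

    The empirical CDF of the ``C_k`` is downsampled to 35 points equally
    spaced along the value axis (cumulative fractions linearly interpolated),
    curvature is evaluated at every interior point, and tau is the value at
    the curvature maximum (ties broken toward the smallest ``C_k``, the most
    conservative rejection).  Degenerate inputs — fewer than 5 scores, a flat
    or monotone curvature profile, or a maximum sitting at the end of the
    evaluable range — fall back to tau = 0.92.
    """
    if isinstance(scores, np.ndarray) or (scores and isinstance(scores[0], (int, float, np.floating))):
        values = np.asarray(scores, dtype=np.float64)
    else:
        values = np.asarray([s.c_k for s in scores], dtype=np.float64)
    if values.size == 0:
        raise ValueError("need at least one contrast score")

    vmax = float(values.max())

    def fallback(points, curv):
        return ThresholdEstimate(tau=FALLBACK_TAU, cdf_points=points,
                                 curvature=curv, used_fallback=True)

    sorted_v = np.sort(values)
    ecdf_y = np.arange(1, sorted_v.size + 1) / sorted_v.size
    if values.size < MIN_SCORES_FOR_KNEE or sorted_v[0] == sorted_v[-1]:
        pts = np.column_stack([sorted_v, ecdf_y])
        return fallback(pts, np.empty(0))

    xs = np.linspace(sorted_v[0], sorted_v[-1], CDF_POINTS)
    ys = np.interp(xs, sorted_v, ecdf_y)
    points = np.column_stack([xs, ys])

    # curvature is scale-dependent; normalise both axes to [0, 1] so the
    # knee location does not depend on the units of C_k
    xn = (xs - xs[0]) / (xs[-1] - xs[0])
    kappa = parametric_curvature(xn, ys)

    # the threshold sits at the foot of the low-contrast artifact mass: the
    # point where the CDF, after covering the genuine-call majority, bends
    # upward into the artifact rise.  That is a concave-UP bend (positive
    # signed curvature for a left-to-right curve) in the upper half of the
    # CDF; the filter's premise is that calls are the majority, so a valid
    # knee keeps at least half of the candidates and rejects at least a
    # tenth (CDF height in [0.5, 0.9]).  Among interior positive-curvature
    # extrema in that band the strongest wins, ties toward smaller C_k; no
    # valid extremum means no knee -> fallback.
    if kappa.size == 0 or np.all(np.abs(kappa) < 1e-8):
        return fallback(points, kappa)
    lo_y, hi_y = KNEE_CDF_RANGE
    valid = []
    for j in range(1, kappa.size - 1):
        if kappa[j] <= 0:
            continue
        if not (kappa[j] > kappa[j - 1] and kappa[j] > kappa[j + 1]):
            continue
        point = j + 1  # kappa[j] belongs to downsampled point j+1
        if not lo_y <= ys[point] <= hi_y:
            continue
        after_x = xs[point] + KNEE_RISE_SPAN * (xs[-1] - xs[0])
        after_y = np.interp(after_x, xs, ys)
        if after_y - ys[point] < KNEE_MIN_RISE:
            continue
        valid.append(j)
    if not valid:
        return fallback(points, kappa)
    best = min(valid, key=lambda j: (-kappa[j], j))
    tau = float(xs[best + 1])
    if not 0 < tau <= vmax:
        return fallback(points, kappa)
    return ThresholdEstimate(tau=tau, cdf_points=points, curvature=kappa,
                             used_fallback=False)


def filter_candidates(
    cands: list[USVCandidate],
    scores: list[ContrastResult],
    tau: float,
) -> list[USVCandidate]:
    """Keep candidates with ``C_k <= tau`` (inclusive), preserving order.

    Also writes each candidate's ``contrast`` attribute.  A candidate
    without a matching score is an error.
    """
    by_id = {s.candidate_id: s for s in scores}
    kept = []
    for cand in cands:
        score = by_id.get(cand.id)
        if score is None:
            raise ValueError(f"no contrast score for candidate {cand.id}")
        cand.contrast = score.c_k
        if score.c_k <= tau:
            kept.append(cand)
    return kept
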
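"""Syllable classification: 11 USV shape classes plus noise.

Two classifiers share one label vocabulary:

* a deterministic rule-based classifier over the 0.5 ms frequency track,
  applying the field's standard shape definitions (steps are >= 6 kHz jumps
  between notes no more than 10 ms apart; flat/short means modulation
  <= 5 kHz split at 12 ms duration; chevrons need a peak/trough >= 6 kHz
  from both endpoints; two or more directional changes > 6 kHz make a
  complex call);
* an optional trainable image classifier over the 227 x 227 candidate
  images, exposing class posteriors, trained with SGD + momentum, batch 128,
  a 90/10 split reshuffled every epoch, and 3-epoch early-stopping patience.

Shapes oscillating between 5 and 6 kHz of modulation are deliberately left
ambiguous (no class is defined there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from skimage.transform import resize as skresize
from sklearn.neural_network import MLPClassifier

from .segmentation import TRACK_DT_MS, CandidateImage, USVCandidate

__all__ = [
    "ClassLabel",
    "USV_LABELS",
    "ClassPosterior",
    "TrainingConfig",
    "rule_based_classify",
    "classify_track",
    "train_classifier",
    "predict_posterior",
    "decide_usv_vs_noise",
]


class ClassLabel(str, Enum):
    COMPLEX = "complex"
    STEP_UP = "step_up"
    STEP_DOWN = "step_down"
    TWO_STEPS = "two_steps"
    MULTIPLE_STEPS = "multiple_steps"
    UP_FM = "up_fm"
    DOWN_FM = "down_fm"
    FLAT = "flat"
    SHORT = "short"
    CHEVRON = "chevron"
    REV_CHEVRON = "rev_chevron"
    NOISE = "noise"


#: the 11 vocal classes, excluding noise
USV_LABELS = tuple(lab for lab in ClassLabel if lab is not ClassLabel.NOISE)

STEP_JUMP_HZ = 6000.0        # minimum inter-note jump for step classes
STEP_MAX_GAP_MS = 10.0       # maximum silence between notes of one syllable
FLAT_MODULATION_HZ = 5000.0  # at most this modulation counts as constant
SHORT_MAX_DURATION_MS = 12.0
CHANGE_EXCURSION_HZ = 6000.0  # a directional change must move this far
SMOOTH_WINDOW_MS = 2.0
# tonal syllables concentrate energy in a narrow band per time step; tracks
# that are broadband (high instantaneous bandwidth) or span more of the
# ultrasonic range than any syllable class can are noise, not calls
NOISE_BANDWIDTH_MEDIAN_HZ = 15000.0
NOISE_BANDWIDTH_P90_HZ = 20000.0
NOISE_SPAN_HZ = 45000.0


@dataclass(frozen=True)
class ClassPosterior:
    """Probability vector over the 12 classes."""

    probs: dict

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior sums to {total}, not 1")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("negative probability")

    @property
    def top_label(self) -> ClassLabel:
        return max(self.probs, key=self.probs.get)

    @property
    def p_usv(self) -> float:
        return 1.0 - self.probs.get(ClassLabel.NOISE, 0.0)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimiser settings for the image classifier (SGD with momentum)."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 100
    val_fraction: float = 0.10
    patience_epochs: int = 3
    seed: int = 0
    hidden_units: int = 64
    input_size: int = 32  # candidate images are downsampled to this square

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        for name in ("batch_size", "max_epochs", "patience_epochs",
                     "hidden_units", "input_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")


# ---------------------------------------------------------------------------
# rule-based classifier
# ---------------------------------------------------------------------------

def _segment_notes(freq: np.ndarray, observed: np.ndarray,
                   time_s: np.ndarray):
    """Split a track into notes at >= 6 kHz jumps between consecutive
    observed points no more than 10 ms apart.

    Interpolated gap bins are skipped: a step across a short silent gap must
    read as a discontinuity, not as the ramp interpolation drew through it.
    Returns ``(notes, jumps)``: index arrays (over the full track) for each
    note, and the signed inter-note frequency jumps measured between the
    observed samples on either side of each boundary.
    """
    obs_idx = np.flatnonzero(observed)
    if obs_idx.size == 0:
        obs_idx = np.arange(freq.size)
    boundaries = [0]
    jumps = []
    for a, b in zip(obs_idx[:-1], obs_idx[1:]):
        gap_ms = (time_s[b] - time_s[a]) * 1000.0
        if abs(freq[b] - freq[a]) >= STEP_JUMP_HZ and gap_ms <= STEP_MAX_GAP_MS:
            boundaries.append(b)
            jumps.append(float(freq[b] - freq[a]))
    boundaries.append(freq.size)
    notes = [np.arange(boundaries[i], boundaries[i + 1])
             for i in range(len(boundaries) - 1)]
    return [n for n in notes if n.size > 0], jumps


def _monotone_runs(freq: np.ndarray) -> list[float]:
    """Signed excursions of the monotone runs of a track, after iteratively
    merging runs smaller than the 6 kHz directional-change threshold.

    The run count minus one is the number of directional changes > 6 kHz.
    """
    d = np.diff(freq)
    d = d[d != 0]
    if d.size == 0:
        return [0.0]
    # collapse to alternating signed run excursions
    runs = []
    for step in d:
        if runs and np.sign(step) == np.sign(runs[-1]):
            runs[-1] += step
        else:
            runs.append(float(step))
    # iteratively absorb sub-threshold wiggles into their neighbours
    while len(runs) > 1:
        smallest = min(range(len(runs)), key=lambda i: abs(runs[i]))
        if abs(runs[smallest]) >= CHANGE_EXCURSION_HZ:
            break
        merged = runs[:]
        if smallest == 0:
            wiggle = merged.pop(0)
            merged[0] += wiggle
        elif smallest == len(runs) - 1:
            wiggle = merged.pop()
            merged[-1] += wiggle
        else:
            wiggle = merged.pop(smallest)
            after = merged.pop(smallest)
            merged[smallest - 1] += wiggle + after
        # re-collapse in case neighbours now share a sign
        collapsed = []
        for step in merged:
            if collapsed and np.sign(step) == np.sign(collapsed[-1]):
                collapsed[-1] += step
            else:
                collapsed.append(step)
        runs = collapsed
    return runs


def _smooth(freq: np.ndarray) -> np.ndarray:
    win = max(int(round(SMOOTH_WINDOW_MS / TRACK_DT_MS)), 1)
    if freq.size <= win:
        return freq
    kernel = np.ones(win) / win
    pad = np.pad(freq, (win // 2, win - 1 - win // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def classify_track(
    freq_hz: np.ndarray,
    time_s: np.ndarray | None = None,
    observed: np.ndarray | None = None,
    bandwidth_hz: np.ndarray | None = None,
) -> ClassLabel:
    """Deterministic decision tree over a 0.5 ms frequency track.

    Precedence follows note count first (multiple steps > two steps >
    step up/down), then single-note shape (complex > chevron/reverse
    chevron > up/down frequency modulation > flat/short); anything that
    matches no rule — including broadband tracks — is noise.
    """
    freq_hz = np.asarray(freq_hz, dtype=np.float64)
    if freq_hz.size == 0:
        raise ValueError("empty frequency track")
    if time_s is None:
        time_s = np.arange(freq_hz.size) * TRACK_DT_MS / 1000.0
    if observed is None:
        observed = np.ones(freq_hz.size, dtype=bool)
    if bandwidth_hz is not None:
        bandwidth_hz = np.asarray(bandwidth_hz, dtype=np.float64)
        broadband = (np.median(bandwidth_hz) > NOISE_BANDWIDTH_MEDIAN_HZ
                     or np.percentile(bandwidth_hz, 90) > NOISE_BANDWIDTH_P90_HZ)
        span = (np.max(freq_hz + bandwidth_hz / 2)
                - np.min(freq_hz - bandwidth_hz / 2))
        if broadband or span > NOISE_SPAN_HZ:
            return ClassLabel.NOISE

    notes, jumps = _segment_notes(freq_hz, observed, time_s)
    if len(notes) >= 4:
        return ClassLabel.MULTIPLE_STEPS
    if len(notes) == 3:
        return ClassLabel.TWO_STEPS
    if len(notes) == 2:
        return ClassLabel.STEP_UP if jumps[0] > 0 else ClassLabel.STEP_DOWN

    smooth = _smooth(freq_hz)
    runs = _monotone_runs(smooth)
    changes = len(runs) - 1
    modulation = float(np.ptp(smooth))
    duration_ms = (time_s[-1] - time_s[0]) * 1000.0 + TRACK_DT_MS

    if changes >= 2:
        return ClassLabel.COMPLEX
    if changes == 1:
        up_then_down = runs[0] > 0
        peak = smooth.max() if up_then_down else smooth.min()
        start, end = smooth[0], smooth[-1]
        if up_then_down and min(peak - start, peak - end) >= CHANGE_EXCURSION_HZ:
            return ClassLabel.CHEVRON
        if not up_then_down and min(start - peak, end - peak) >= CHANGE_EXCURSION_HZ:
            return ClassLabel.REV_CHEVRON
    net = float(smooth[-1] - smooth[0])
    if net >= CHANGE_EXCURSION_HZ:
        return ClassLabel.UP_FM
    if net <= -CHANGE_EXCURSION_HZ:
        return ClassLabel.DOWN_FM
    if modulation <= FLAT_MODULATION_HZ:
        if duration_ms <= SHORT_MAX_DURATION_MS:
            return ClassLabel.SHORT
        return ClassLabel.FLAT
    return ClassLabel.NOISE


def rule_based_classify(cand: USVCandidate) -> ClassLabel:
    """Classify a candidate from its feature tracks (see classify_track)."""
    if cand.track_freq_hz is None:
        raise ValueError("candidate has no frequency track; run summarize_tracks")
    return classify_track(
        cand.track_freq_hz,
        time_s=cand.track_time_s,
        observed=cand.track_observed,
        bandwidth_hz=cand.track_bandwidth_hz,
    )


# ---------------------------------------------------------------------------
# trainable image classifier
# ---------------------------------------------------------------------------


@dataclass
class ImageClassifier:
    """A trained classifier handle with its label vocabulary."""

    mlp: MLPClassifier
    classes: list
    config: TrainingConfig
    validation_accuracy: list = field(default_factory=list)


def _image_features(img: CandidateImage, size: int) -> np.ndarray:
    small = skresize(img.pixels227, (size, size), anti_aliasing=True, mode="edge")
    return small.ravel()


def train_classifier(
    images: list[CandidateImage],
    labels: list[ClassLabel],
    cfg: TrainingConfig | None = None,
) -> ImageClassifier:
    """Train the image classifier with the standard recipe.

    Images are downsampled and flattened into a one-hidden-layer network
    trained by mini-batch SGD with momentum and weight decay.  A stratified
    90/10 train/validation split is drawn once; the training set is
    reshuffled every epoch and training halts when validation accuracy has
    not improved for ``patience_epochs`` consecutive epochs.
    """
    cfg = cfg or TrainingConfig()
    if len(images) != len(labels) or not images:
        raise ValueError("need matching, non-empty images and labels")
    X = np.stack([_image_features(im, cfg.input_size) for im in images])
    y = np.asarray([ClassLabel(lab).value for lab in labels])

    rng = np.random.default_rng(cfg.seed)
    classes = sorted(set(y))
    val_idx: list[int] = []
    for cls in classes:
        members = np.flatnonzero(y == cls)
        n_val = int(round(len(members) * cfg.val_fraction))
        val_idx.extend(rng.permutation(members)[:n_val])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    X_tr, y_tr = X[~val_mask], y[~val_mask]
    X_val, y_val = X[val_mask], y[val_mask]
    missing = set(classes) - set(y_tr)
    if missing:
        raise ValueError(f"classes absent from training split: {sorted(missing)}")

    mlp = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        solver="sgd",
        learning_rate_init=cfg.learning_rate,
        momentum=cfg.momentum,
        nesterovs_momentum=False,
        alpha=cfg.weight_decay,
        batch_size=min(cfg.batch_size, max(len(y_tr), 1)),
        max_iter=1,
        shuffle=False,
        random_state=cfg.seed,
        warm_start=False,
    )

    order = np.arange(len(y_tr))
    best_acc = -np.inf
    stall = 0
    trace = []
    import warnings
    for _ in range(cfg.max_epochs):
        rng.shuffle(order)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-epoch partial_fit never converges
            mlp.partial_fit(X_tr[order], y_tr[order], classes=classes)
        acc = float(np.mean(mlp.predict(X_val) == y_val)) if len(y_val) else 1.0
        trace.append(acc)
        if acc > best_acc:
            best_acc = acc
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience_epochs:
                break
    return ImageClassifier(mlp=mlp, classes=classes, config=cfg,
                           validation_accuracy=trace)


def predict_posterior(model: ImageClassifier, img: CandidateImage) -> ClassPosterior:
    """Class-probability vector for one candidate image.

    Classes absent from the training vocabulary get probability zero, so the
    posterior always covers all 12 labels.
    """
    feats = _image_features(img, model.config.input_size)[None, :]
    proba = model.mlp.predict_proba(feats)[0]
    probs = {lab: 0.0 for lab in ClassLabel}
    for cls, p in zip(model.mlp.classes_, proba):
        probs[ClassLabel(cls)] = float(p)
    total = sum(probs.values())
    probs = {k: v / total for k, v in probs.items()}
    return ClassPosterior(probs=probs)


def decide_usv_vs_noise(post: ClassPosterior,
                        flag_threshold: float = 0.7) -> tuple[bool, bool]:
    """Compare P(USV) = sum of the 11 vocal classes against P(noise).

    Returns ``(is_usv, low_confidence)``; the call is a USV when its summed
    vocal probability exceeds the noise probability, and it is flagged for
    manual review when neither side reaches ``flag_threshold``.
    """
    p_noise = post.probs.get(ClassLabel.NOISE, 0.0)
    is_usv = post.p_usv > p_noise
    low_confidence = max(post.p_usv, p_noise) < flag_threshold
    return is_usv, low_confidence
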
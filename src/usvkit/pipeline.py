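"""End-to-end detection: audio in, labeled syllable table out.

One call runs the full chain — spectrogram, 45 kHz high pass, contrast
adjustment, adaptive binarisation, morphology, candidate extraction and
merging, feature tracks, harmonic detection, the Local Median Filter, and
rule-based classification — and returns everything a study needs: the kept
candidates, their labels, the per-file contrast threshold, and a tidy
`pandas` table ready for CSV export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioRecording
from .classify import ClassLabel, rule_based_classify
from .contrast_filter import (ThresholdEstimate, contrast_score,
                              estimate_threshold, filter_candidates)
from .segmentation import (USVCandidate, adaptive_binarize, detect_harmonic,
                           extract_candidates, refine_morphology,
                           summarize_tracks)
from .spectrogram import (GrayImage, SpectrogramImage, StftParams,
                          adjust_contrast, apply_high_pass,
                          compute_spectrogram)

__all__ = ["DetectionResult", "detect_usvs"]


@dataclass
class DetectionResult:
    """Everything the detection chain produced for one recording."""

    spec: SpectrogramImage
    gray: GrayImage
    candidates: list[USVCandidate]        # all candidates, before the filter
    kept: list[USVCandidate]              # survivors of the Local Median Filter
    labels: dict                          # candidate id -> ClassLabel
    threshold: ThresholdEstimate
    table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for cand in self.kept:
            label = self.labels[cand.id]
            rows.append({
                "id": cand.id,
                "start_s": cand.start_s,
                "end_s": cand.end_s,
                "duration_ms": cand.duration_ms,
                "min_freq_hz": cand.freq_min_hz,
                "max_freq_hz": cand.freq_max_hz,
                "mean_intensity_db": cand.mean_intensity_db,
                "harmonic": cand.harmonic,
                "contrast_ck": cand.contrast,
                "label": label.value,
                "is_usv": label is not ClassLabel.NOISE,
            })
        self.table = pd.DataFrame(
            rows, columns=["id", "start_s", "end_s", "duration_ms",
                           "min_freq_hz", "max_freq_hz", "mean_intensity_db",
                           "harmonic", "contrast_ck", "label", "is_usv"])

    @property
    def usv_table(self) -> pd.DataFrame:
        return self.table[self.table["is_usv"]].reset_index(drop=True)

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def write_threshold_json(self, path: str | Path) -> None:
        payload = {
            "tau": self.threshold.tau,
            "used_fallback": self.threshold.used_fallback,
            "cdf_points": np.asarray(self.threshold.cdf_points).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def detect_usvs(
    rec: AudioRecording,
    stft: StftParams | None = None,
    highpass_hz: float = 45_000.0,
    sensitivity_t: float = 0.2,
    neighborhood_s: int | None = None,
    gamma: float = 1.0,
) -> DetectionResult:
    """Run the full detection chain on one recording.

    Candidates that survive the Local Median Filter are classified with the
    rule-based classifier; noise-labeled survivors stay in the table (marked
    ``is_usv=False``) because they are what the performance metrics count as
    true/false negatives.
    """
    spec = compute_spectrogram(rec, stft)
    spec = apply_high_pass(spec, highpass_hz)
    gray = adjust_contrast(spec, gamma=gamma)
    mask = adaptive_binarize(gray, t=sensitivity_t, s=neighborhood_s)
    mask = refine_morphology(mask)
    candidates = extract_candidates(mask, spec)
    for cand in candidates:
        summarize_tracks(cand, spec)
        detect_harmonic(cand, spec)

    if not candidates:
        empty = ThresholdEstimate(tau=0.92, cdf_points=np.empty((0, 2)),
                                  curvature=np.empty(0), used_fallback=True)
        return DetectionResult(spec=spec, gray=gray, candidates=[], kept=[],
                               labels={}, threshold=empty)

    scores = [contrast_score(c, gray, spec) for c in candidates]
    threshold = estimate_threshold(scores)
    kept = filter_candidates(candidates, scores, threshold.tau)
    labels = {c.id: rule_based_classify(c) for c in kept}
    return DetectionResult(spec=spec, gray=gray, candidates=candidates,
                           kept=kept, labels=labels, threshold=threshold)
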
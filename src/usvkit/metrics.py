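"""Detection-performance scoring against manual annotations.

Detections are matched to annotated syllable onsets one-to-one within a
+/- 5 ms tolerance (greedy, smallest time difference first), and the
resulting confusion counts feed per-file rates and across-file aggregates
(mean, SEM, median, Student-t 95% CI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationSet",
    "ConfusionCounts",
    "PerformanceReport",
    "match_to_ground_truth",
    "performance_report",
]

DEFAULT_TOLERANCE_MS = 5.0

METRIC_COLUMNS = ("accuracy", "sensitivity", "specificity", "fnr", "fpr", "fdr")


@dataclass
class AnnotationSet:
    """Ground-truth annotations: one row per event (USV or noise)."""

    start_s: np.ndarray
    label: list                      # "usv"/"noise" or a specific class name
    harmonic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=np.float64)
        if len(self.label) != self.start_s.size:
            raise ValueError("labels and start times differ in length")
        order = np.argsort(self.start_s, kind="stable")
        self.start_s = self.start_s[order]
        self.label = [self.label[i] for i in order]
        if self.harmonic is not None:
            self.harmonic = np.asarray(self.harmonic)[order]

    @classmethod
    def from_csv(cls, path) -> "AnnotationSet":
        df = pd.read_csv(path)
        required = {"start_s", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation CSV needs columns {sorted(required)}")
        harmonic = df["harmonic"].to_numpy() if "harmonic" in df.columns else None
        return cls(start_s=df["start_s"].to_numpy(),
                   label=list(df["label"]), harmonic=harmonic)

    def is_usv(self) -> np.ndarray:
        return np.array([str(lab).lower() != "noise" for lab in self.label])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


def match_to_ground_truth(
    detections: np.ndarray,
    annotations: AnnotationSet,
    tol_ms: float = DEFAULT_TOLERANCE_MS,
    detection_is_usv: np.ndarray | None = None,
) -> ConfusionCounts:
    """Greedy one-to-one onset matching within ``tol_ms``.

    ``detections`` are candidate start times; ``detection_is_usv`` says what
    the pipeline called each one (default: all USV).  Matched USV annotations
    count as TP when the detection was labeled USV and FN when it was labeled
    noise; unmatched USV annotations are FN; detections matching no USV
    annotation are TN when labeled noise, FP when labeled USV.  Pairs are
    taken by ascending |dt|, ties broken by earlier annotation.
    """
    if tol_ms <= 0:
        raise ValueError("tolerance must be positive")
    det = np.asarray(detections, dtype=np.float64)
    if detection_is_usv is None:
        detection_is_usv = np.ones(det.size, dtype=bool)
    detection_is_usv = np.asarray(detection_is_usv, dtype=bool)
    ann_t = annotations.start_s
    ann_usv = annotations.is_usv()
    usv_idx = np.flatnonzero(ann_usv)

    tol_s = tol_ms / 1000.0
    pairs = []
    for d in range(det.size):
        dt = np.abs(ann_t[usv_idx] - det[d])
        for j in np.flatnonzero(dt <= tol_s):
            pairs.append((dt[j], usv_idx[j], d))
    pairs.sort(key=lambda p: (p[0], p[1]))

    ann_matched = set()
    det_matched = set()
    tp = fn = 0
    for _, a, d in pairs:
        if a in ann_matched or d in det_matched:
            continue
        ann_matched.add(a)
        det_matched.add(d)
        if detection_is_usv[d]:
            tp += 1
        else:
            fn += 1  # a real USV the pipeline called noise
    fn += len(usv_idx) - len(ann_matched)  # missed entirely
    unmatched = [d for d in range(det.size) if d not in det_matched]
    fp = int(np.sum(detection_is_usv[unmatched]))
    tn = len(unmatched) - fp
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def _rates(c: ConfusionCounts) -> dict:
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else np.nan

    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.tn + c.fp)
    return {
        "accuracy": ratio(c.tp + c.tn, c.tp + c.fn + c.tn + c.fp),
        "sensitivity": sens,
        "specificity": spec,
        "fnr": 100.0 - sens if np.isfinite(sens) else np.nan,
        "fpr": 100.0 - spec if np.isfinite(spec) else np.nan,
        "fdr": ratio(c.fp, c.fp + c.tp),
    }


@dataclass
class PerformanceReport:
    """Per-file rates (percent) plus across-file aggregates."""

    per_file: pd.DataFrame
    aggregate: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = {}
        for metric in METRIC_COLUMNS:
            v = self.per_file[metric].to_numpy(dtype=np.float64)
            v = v[np.isfinite(v)]
            n = v.size
            if n == 0:
                rows[metric] = dict.fromkeys(
                    ("mean", "sem", "median", "ci95_low", "ci95_high"), np.nan)
                continue
            mean = v.mean()
            sem = v.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            if n > 1:
                half = stats.t.ppf(0.975, n - 1) * sem
                ci = (mean - half, mean + half)
            else:
                ci = (np.nan, np.nan)
            rows[metric] = {"mean": mean, "sem": sem, "median": float(np.median(v)),
                            "ci95_low": ci[0], "ci95_high": ci[1]}
        self.aggregate = pd.DataFrame(rows).T


def performance_report(per_file_counts: list[ConfusionCounts]) -> PerformanceReport:
    """Compute per-file rates and mean/SEM/median/95% CI aggregates.

    Rates with a zero denominator are reported as NaN for that file and
    excluded from the aggregates (with a warning).
    """
    if not per_file_counts:
        raise ValueError("need counts for at least one file")
    records = []
    for i, c in enumerate(per_file_counts):
        row = {"file": i + 1, "tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp}
        row.update(_rates(c))
        records.append(row)
    per_file = pd.DataFrame.from_records(records)
    bad = per_file[list(METRIC_COLUMNS)].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"undefined rates in files {per_file.loc[bad, 'file'].tolist()}; "
            "excluded from aggregates")
    return PerformanceReport(per_file=per_file)
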
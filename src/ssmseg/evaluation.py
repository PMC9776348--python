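"""Tolerance-zone event matching and precision/recall/F1 metrics.

A detection counts as a true positive when it falls inside the tolerance
zone around a ground-truth event (``± tolerance`` samples, default the
feature-extraction window size). Each truth event absorbs at most one
detection: further detections inside an already-matched zone are false
positives, truth events with no detection in zone are false negatives.
Matching is greedy in truth order — each truth event takes the nearest
still-unassigned detection within tolerance, ties going to the earlier
detection — which makes the counts deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalResult", "match_events", "prf", "macro_f1", "evaluate_events"]


@dataclass
class EvalResult:
    """Counts, metrics and matched pairs of one evaluation run."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    tolerance: int
    matched_pairs: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tolerance": self.tolerance,
            "matched_pairs": [[int(a), int(b)] for a, b in self.matched_pairs],
        }


def _check_sorted(x: np.ndarray, name: str) -> None:
    if x.size > 1 and np.any(np.diff(x) < 0):
        raise ValueError(f"{name} must be sorted ascending")


def match_events(truth, detected, tolerance: int):
    """Match detections to truth events within ``± tolerance`` samples.

    Returns ``(tp, fp, fn, matched_pairs)`` with ``matched_pairs`` a list
    of ``(truth, detection)`` sample-index tuples. Conservation holds by
    construction: ``tp + fn == len(truth)`` and ``tp + fp == len(detected)``.
    """
    truth = np.asarray(truth, dtype=np.int64)
    detected = np.asarray(detected, dtype=np.int64)
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    _check_sorted(truth, "truth")
    _check_sorted(detected, "detected")

    assigned = np.zeros(detected.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for t in truth:
        best, best_dist = -1, tolerance + 1
        for j, d in enumerate(detected):
            if assigned[j]:
                continue
            dist = abs(int(d) - int(t))
            if dist < best_dist:  # strict: distance ties keep the earlier detection
                best, best_dist = j, dist
        if best >= 0:
            assigned[best] = True
            pairs.append((int(t), int(detected[best])))
    tp = len(pairs)
    fp = int(detected.size - tp)
    fn = int(truth.size - tp)
    return tp, fp, fn, pairs


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from counts; any 0/0 is 0 by convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def macro_f1(f1_scores) -> float:
    """Unweighted mean of per-dataset F1 scores (computed at full precision)."""
    scores = list(f1_scores)
    if not scores:
        raise ValueError("macro_f1 needs at least one score")
    return float(np.mean(scores))


def evaluate_events(truth, detected, tolerance: int) -> EvalResult:
    """Run the matching and package counts, metrics and pairs."""
    tp, fp, fn, pairs = match_events(truth, detected, tolerance)
    precision, recall, f1 = prf(tp, fp, fn)
    return EvalResult(tp, fp, fn, precision, recall, f1, int(tolerance), pairs)
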
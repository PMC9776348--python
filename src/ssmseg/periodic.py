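"""Similarity function and periodic (valley) segmentation.

For a cyclic signal, frames near period starts sit on the sparse parts of
the recurrence structure: they are similar to the matching phase of every
other cycle but dissimilar to everything else. Summing the SSM column-wise
yields the similarity function; its local minima (valleys) mark the period
starts. Valley picking reuses the peak-picking machinery on the negated,
min-max-normalized curve.

Each similarity-function value is also the average similarity of a frame
to all frames (up to the factor ``m``), so frames ranked by ascending
value are candidate anomalies; :func:`anomaly_ranking` exposes that
ordering without attaching any detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ssmseg.novelty import EventSet, NoveltyCurve, pick_peaks
from ssmseg.ssm import SelfSimilarityMatrix

__all__ = ["SimilarityCurve", "similarity_function", "pick_valleys", "anomaly_ranking"]


@dataclass
class SimilarityCurve:
    """Column sums of the SSM over frames (optionally smoothed)."""

    values: np.ndarray
    window_starts: np.ndarray
    w: int

    def sample_of(self, frames) -> np.ndarray:
        frames = np.asarray(frames, dtype=np.int64)
        return self.window_starts[frames] + self.w // 2


def similarity_function(ssm: SelfSimilarityMatrix, smooth: int = 0) -> SimilarityCurve:
    """Sum the SSM column-wise: ``sf(x) = sum_i S(i, x)``.

    ``smooth`` > 1 applies a centred moving average of that length
    afterwards (edges use the partial window); default is no smoothing.
    """
    values = ssm.values.sum(axis=0)
    if smooth > 1:
        kernel = np.ones(smooth)
        values = np.convolve(values, kernel, mode="same") / np.convolve(
            np.ones_like(values), kernel, mode="same"
        )
    return SimilarityCurve(values, ssm.window_starts.copy(), ssm.config.w)


def pick_valleys(
    curve: SimilarityCurve,
    strategy: str = "threshold",
    theta: float = 0.3,
    top_n: int | None = None,
    peak_fraction: float | None = None,
    min_separation: int = 0,
) -> EventSet:
    """Detect period-start events as valleys of the similarity function.

    Equivalent to :func:`ssmseg.novelty.pick_peaks` applied to the negated,
    min-max-normalized curve; all strategies and the suppression rule carry
    over unchanged.
    """
    neg = -np.asarray(curve.values, dtype=float)
    lo, hi = float(neg.min()), float(neg.max())
    norm = np.zeros_like(neg) if hi == lo else (neg - lo) / (hi - lo)
    as_curve = NoveltyCurve(norm, neg, curve.window_starts, curve.w)
    return pick_peaks(
        as_curve,
        strategy=strategy,
        theta=theta,
        top_n=top_n,
        peak_fraction=peak_fraction,
        min_separation=min_separation,
        event_type="periodic_valley",
    )


def anomaly_ranking(curve: SimilarityCurve) -> np.ndarray:
    """Frames ordered by ascending average similarity to the whole record.

    The lower a frame's similarity-function value, the more unlike the rest
    of the signal it is; the head of this ranking is where anomalies would
    be looked for. No threshold is attached — this is a read-only ordering.
    """
    return np.argsort(curve.values, kind="stable")
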
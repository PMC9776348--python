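"""Checkerboard-kernel novelty function and peak picking.

A transition between two homogeneous blocks on the SSM diagonal looks like
a 2x2 checkerboard: high similarity within each block, low similarity
across. Correlating a Gaussian-tapered checkerboard kernel along the
diagonal therefore yields a curve — the novelty function — whose peaks
mark change points.

The kernel has half-size ``L`` (total size ``D = 2L + 1``; the centre row
and column are zero) and combines a homogeneity part (positive diagonal
quadrants) with a cross-similarity part (negative anti-diagonal quadrants):
``K_N(a, b) = sign(a) * sign(b)`` for ``a, b in [-L, L]``, tapered by the
radial Gaussian ``phi(a, b) = exp(-(a^2 + b^2) / (2 L^2 sigma^2))`` and
normalized by the sum of absolute values so the curve scale is comparable
across kernel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ssmseg.ssm import SelfSimilarityMatrix

__all__ = [
    "CheckerboardKernel",
    "NoveltyCurve",
    "EventSet",
    "build_kernel",
    "novelty_function",
    "pick_peaks",
    "default_kernel_half_size",
]

PEAK_STRATEGIES = ("threshold", "top_n", "peak_fraction")


@dataclass(frozen=True)
class CheckerboardKernel:
    """Gaussian-tapered checkerboard kernel of size ``D x D``, ``D = 2L+1``."""

    L: int
    sigma: float
    values: np.ndarray
    normalized: bool

    @property
    def D(self) -> int:
        return 2 * self.L + 1


def build_kernel(L: int, sigma: float = 0.5, normalize: bool = True) -> CheckerboardKernel:
    """Construct the checkerboard kernel with half-size ``L`` and taper ``sigma``.

    ``sigma`` is dimensionless relative to the kernel half-size: the taper
    is ``exp(-(a^2 + b^2) / (2 L^2 sigma^2))``, so the same ``sigma`` gives
    the same relative weighting at any ``L``. With ``normalize`` the kernel
    is divided by the sum of its absolute values.
    """
    if L < 1:
        raise ValueError(f"kernel half-size L must be >= 1, got {L}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    grid = np.arange(-L, L + 1)
    sign = np.sign(grid)
    k_n = np.outer(sign, sign).astype(float)
    taper = np.exp(-(grid[:, None] ** 2 + grid[None, :] ** 2) / (2.0 * L**2 * sigma**2))
    values = taper * k_n
    if normalize:
        values = values / np.abs(values).sum()
    return CheckerboardKernel(L, sigma, values, normalize)


def default_kernel_half_size(m: int) -> int:
    """Default kernel half-size scaled to the SSM side: ``D ~ 0.2 m``."""
    return max(1, int(round(0.2 * m)) // 2)


@dataclass
class NoveltyCurve:
    """Novelty function over frames, min-max normalized to ``[0, 1]``.

    ``raw`` keeps the unnormalized correlation values; ``values`` is the
    normalized curve peak picking operates on (an all-constant raw curve
    normalizes to all zeros).
    """

    values: np.ndarray
    raw: np.ndarray
    window_starts: np.ndarray
    w: int

    def sample_of(self, frames) -> np.ndarray:
        frames = np.asarray(frames, dtype=np.int64)
        return self.window_starts[frames] + self.w // 2


@dataclass
class EventSet:
    """Detected events in frame and sample domains."""

    frame_indices: np.ndarray
    sample_indices: np.ndarray
    scores: np.ndarray
    event_type: str

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        self.sample_indices = np.asarray(self.sample_indices, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (self.frame_indices.size == self.sample_indices.size == self.scores.size):
            raise ValueError("frame_indices, sample_indices and scores must align")

    def __len__(self) -> int:
        return self.frame_indices.size


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def novelty_function(
    ssm: SelfSimilarityMatrix,
    kernel: CheckerboardKernel,
    exclude_border: bool = True,
    smooth: int | None = None,
) -> NoveltyCurve:
    """Correlate the kernel along the SSM diagonal (zero-padded borders).

    For each frame ``c``: ``nf(c) = sum_{a,b in [-L, L]} K(a, b) *
    S(c + a, c + b)``, with ``S`` taken as zero outside the matrix; this
    exact correlation is kept in ``raw``. The displayed curve (``values``)
    is post-processed for peak picking:

    * ``smooth`` — centred moving average, default ``L // 2``. A genuine
      block transition produces a peak about ``2 L`` frames wide, whereas
      single-frame feature-noise stripes in the SSM produce much narrower
      bumps; averaging at half the kernel half-size attenuates the latter
      and barely touches the former. Pass ``smooth=0`` to disable.
    * ``exclude_border`` — within ``L`` frames of either end the kernel
      hangs over the zero padding, which mimics a block transition and
      inflates the curve; the first and last ``L`` values are pinned to
      the interior minimum so border artifacts can never become peaks.
    * min-max normalization to ``[0, 1]`` (an all-constant curve maps to
      all zeros).
    """
    L, D, m = kernel.L, kernel.D, ssm.m
    if D > m:
        raise ValueError(f"kernel size D={D} exceeds SSM side m={m}")
    padded = np.zeros((m + 2 * L, m + 2 * L))
    padded[L : L + m, L : L + m] = ssm.values
    raw = np.empty(m)
    for c in range(m):
        raw[c] = float(np.sum(kernel.values * padded[c : c + D, c : c + D]))
    shown = raw.copy()
    if smooth is None:
        smooth = L // 2
    if smooth > 1:
        window = np.ones(smooth)
        shown = np.convolve(shown, window, mode="same") / np.convolve(
            np.ones(m), window, mode="same"
        )
    margin = L + (smooth // 2 if smooth > 1 else 0)  # smoothing bleeds the border ramp inward
    if exclude_border and m > 2 * margin:
        interior_min = shown[margin : m - margin].min()
        shown[:margin] = interior_min
        shown[m - margin :] = interior_min
    return NoveltyCurve(_minmax(shown), raw, ssm.window_starts.copy(), ssm.config.w)


def _select_candidates(values: np.ndarray) -> np.ndarray:
    """Strict interior local maxima, in index order."""
    peaks, _ = sps.find_peaks(values)
    return peaks


def _suppress(frames: np.ndarray, heights: np.ndarray, min_separation: int) -> np.ndarray:
    """Greedy non-maximum suppression; higher wins, ties go to the earlier frame."""
    if min_separation <= 0 or frames.size <= 1:
        return frames
    # visit by descending height, earlier frame first on ties
    order = np.lexsort((frames, -heights))
    keep: list[int] = []
    for idx in order:
        f = frames[idx]
        if all(abs(f - k) >= min_separation for k in keep):
            keep.append(int(f))
    return np.asarray(sorted(keep), dtype=np.int64)


def pick_peaks(
    curve: NoveltyCurve,
    strategy: str = "threshold",
    theta: float = 0.3,
    top_n: int | None = None,
    peak_fraction: float | None = None,
    min_separation: int = 0,
    event_type: str = "novelty_peak",
) -> EventSet:
    """Select change-point events from the normalized novelty curve.

    Candidates are strict local maxima. The strategy keeps: values
    ``>= theta`` (``"threshold"``), the ``top_n`` highest (``"top_n"``), or
    the top ``peak_fraction`` of candidates ranked by height
    (``"peak_fraction"``). Surviving peaks closer than ``min_separation``
    frames are thinned greedily, keeping the higher peak (ties resolve to
    the earlier frame).
    """
    values = np.asarray(curve.values, dtype=float)
    cand = _select_candidates(values)
    heights = values[cand]
    if strategy == "threshold":
        if not (0.0 <= theta <= 1.0):
            raise ValueError(f"theta must be in [0, 1], got {theta}")
        keep = cand[heights >= theta]
    elif strategy == "top_n":
        if top_n is None or top_n < 0:
            raise ValueError("top_n must be a non-negative integer")
        order = np.lexsort((cand, -heights))[:top_n]
        keep = np.sort(cand[order])
    elif strategy == "peak_fraction":
        if peak_fraction is None or not (0.0 < peak_fraction <= 1.0):
            raise ValueError(f"peak_fraction must be in (0, 1], got {peak_fraction}")
        n_keep = int(np.ceil(peak_fraction * cand.size))
        order = np.lexsort((cand, -heights))[:n_keep]
        keep = np.sort(cand[order])
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {PEAK_STRATEGIES}")
    keep = _suppress(keep, values[keep], min_separation)
    return EventSet(keep, curve.sample_of(keep), values[keep], event_type)
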
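"""Per-segment similarity profiles and profile-based clustering.

A segment's similarity profile is its average similarity to every frame of
the record: the mean over the segment's SSM rows, one value per column.
Segments that behave alike — even at different positions and lengths —
have close profiles, so plain Euclidean distance between profiles drives
an agglomerative clustering that labels the segments produced by novelty
or periodic segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ssmseg.novelty import EventSet
from ssmseg.ssm import SelfSimilarityMatrix

__all__ = [
    "Segment",
    "SimilarityProfile",
    "segments_from_events",
    "similarity_profile",
    "cluster_segments",
]

LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class Segment:
    """Half-open frame range ``[start_frame, end_frame)`` with optional label."""

    start_frame: int
    end_frame: int
    start_sample: Optional[int] = None
    end_sample: Optional[int] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError(f"invalid segment [{self.start_frame}, {self.end_frame})")

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class SimilarityProfile:
    """Average similarity of one segment to every frame (length ``m``)."""

    segment: Segment
    values: np.ndarray


def segments_from_events(events, m: int) -> list[Segment]:
    """Cut ``[0, m)`` at each event frame.

    ``events`` may be an :class:`EventSet` or a sequence of frame indices;
    an empty event list yields the single segment ``[0, m)``.
    """
    frames = events.frame_indices if isinstance(events, EventSet) else np.asarray(events, dtype=np.int64)
    frames = np.asarray(frames, dtype=np.int64)
    if frames.size and (np.any(frames < 0) | np.any(frames >= m)):
        raise ValueError(f"event frames must lie in [0, {m})")
    if frames.size != np.unique(frames).size:
        raise ValueError("duplicate event frames")
    cuts = [0, *np.sort(frames).tolist(), m]
    cuts = [c for i, c in enumerate(cuts) if i == 0 or c != cuts[i - 1]]  # drop a cut at 0
    return [Segment(a, b) for a, b in zip(cuts[:-1], cuts[1:])]


def similarity_profile(ssm: SelfSimilarityMatrix, segment: Segment) -> SimilarityProfile:
    """Mean over the segment's SSM rows: ``P(c) = (1/l) sum_{i in seg} S(i, c)``."""
    if segment.end_frame > ssm.m:
        raise ValueError(f"segment {segment} exceeds matrix side m={ssm.m}")
    rows = ssm.values[segment.start_frame : segment.end_frame]
    start_s, end_s = ssm.sample_of([segment.start_frame, segment.end_frame - 1])
    located = Segment(
        segment.start_frame, segment.end_frame, int(start_s), int(end_s), segment.label
    )
    return SimilarityProfile(located, rows.mean(axis=0))


def cluster_segments(
    profiles: list[SimilarityProfile],
    linkage: str = "average",
    k: Optional[int] = None,
    distance_cut: Optional[float] = None,
    z_score: bool = False,
):
    """Agglomerative clustering of segments by Euclidean profile distance.

    Exactly one of ``k`` (cluster count) and ``distance_cut`` (cophenetic
    distance threshold) selects the flat clustering. Labels are integers
    ``0..c-1`` renumbered by order of first appearance, so they are
    deterministic. Returns ``(labels, merge_tree)`` where ``merge_tree`` is
    the SciPy linkage matrix (rows: merged pair, distance, new size),
    suitable for dendrogram rendering or serialization.

    ``z_score`` optionally standardizes each profile before comparison;
    default compares the raw average-similarity values.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    if (k is None) == (distance_cut is None):
        raise ValueError("specify exactly one of k and distance_cut")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    if k is not None and not (1 <= k <= len(profiles)):
        raise ValueError(f"k must be in [1, {len(profiles)}], got {k}")

    X = np.vstack([p.values for p in profiles])
    if z_score:
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0.0] = 1.0
        X = (X - X.mean(axis=1, keepdims=True)) / sd
    tree = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage)
    if k is not None:
        raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(tree, t=distance_cut, criterion="distance")
    # renumber by first appearance for deterministic labels
    labels = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        labels[i] = mapping.setdefault(int(r), len(mapping))
    return labels, tree
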
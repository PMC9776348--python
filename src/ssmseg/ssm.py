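"""Self-similarity matrix computation and persistence.

With the feature matrix doubly normalized, the SSM is simply the Gram
matrix of its columns: ``SSM = FM^T @ FM``. Entry ``(i, j)`` is the cosine
similarity between frames ``i`` and ``j`` — 1 for identical feature
vectors, 0 for orthogonal ones. Homogeneous stretches of the signal show
up as bright square blocks on the diagonal; recurring patterns as diagonal
stripes off it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ssmseg.features import FeatureMatrix, WindowingConfig

__all__ = ["SelfSimilarityMatrix", "compute_ssm", "save_ssm", "load_ssm"]

_SYM_TOL = 1e-9


@dataclass
class SelfSimilarityMatrix:
    """An ``m x m`` cosine-similarity matrix with frame metadata.

    ``window_starts``, ``config`` and ``fs`` are carried over from the
    feature matrix so detections in the frame domain can be mapped back to
    sample indices. Frames whose feature column was all-zero have zero
    rows/columns (including a zero diagonal entry).
    """

    values: np.ndarray
    window_starts: np.ndarray
    config: WindowingConfig
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("SSM must be square")
        if v.shape[0] != self.window_starts.size:
            raise ValueError(f"declared m={self.window_starts.size} does not match matrix side {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise ValueError("SSM contains non-finite values")
        if np.max(np.abs(v - v.T)) > _SYM_TOL:
            raise ValueError("SSM is not symmetric")
        if v.size and (v.min() < -1 - _SYM_TOL or v.max() > 1 + _SYM_TOL):
            raise ValueError("SSM entries outside [-1, 1]")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def sample_of(self, frames) -> np.ndarray:
        frames = np.asarray(frames, dtype=np.int64)
        return self.window_starts[frames] + self.config.w // 2


def compute_ssm(fm: FeatureMatrix) -> SelfSimilarityMatrix:
    """Cosine self-similarity of all frame pairs of a normalized FM."""
    if not fm.normalized:
        raise ValueError("feature matrix must be normalized before computing the SSM")
    values = fm.values.T @ fm.values
    # symmetrize away float round-off from the BLAS product
    values = 0.5 * (values + values.T)
    np.clip(values, -1.0, 1.0, out=values)
    return SelfSimilarityMatrix(values, fm.window_starts.copy(), fm.config, fm.fs)


def save_ssm(ssm: SelfSimilarityMatrix, path) -> None:
    """Write the matrix as dense CSV plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, ssm.values, delimiter=",")
    meta = {
        "m": ssm.m,
        "w": ssm.config.w,
        "overlap_frac": ssm.config.overlap_frac,
        "hop": ssm.config.hop,
        "fs": ssm.fs,
        "window_starts": ssm.window_starts.tolist(),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_ssm(path) -> SelfSimilarityMatrix:
    """Read a matrix written by :func:`save_ssm`, validating its sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("m", "w", "overlap_frac", "fs", "window_starts"):
        if key not in meta:
            raise ValueError(f"metadata sidecar {sidecar} missing field {key!r}")
    values = np.atleast_2d(np.loadtxt(path, delimiter=","))
    if values.shape[0] != meta["m"]:
        raise ValueError(f"declared m={meta['m']} does not match matrix side {values.shape[0]}")
    config = WindowingConfig(meta["w"], meta["overlap_frac"])
    return SelfSimilarityMatrix(values, np.asarray(meta["window_starts"]), config, meta["fs"])
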
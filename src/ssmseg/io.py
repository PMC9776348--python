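"""Readers, writers, run configuration and the end-to-end pipeline.

File conventions: signals, feature matrices, curves, events and labels are
delimited text (CSV); metadata, configuration echoes, evaluation results
and merge trees are JSON. All indices in output files are 0-based sample
indices; times in seconds are ``sample / fs``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ssmseg import __version__
from ssmseg.evaluation import evaluate_events
from ssmseg.features import FeatureMatrix, WindowingConfig, extract_features, normalize_fm
from ssmseg.novelty import EventSet, build_kernel, novelty_function, pick_peaks
from ssmseg.periodic import pick_valleys, similarity_function
from ssmseg.profiles import cluster_segments, segments_from_events, similarity_profile
from ssmseg.ssm import compute_ssm, save_ssm
from ssmseg.synth import TimeSeriesRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "write_events",
    "read_events",
    "save_fm",
    "load_fm",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to/from JSON.

    The effective configuration (defaults resolved) is echoed into the
    output directory as ``config.json`` so any run can be repeated
    byte-for-byte from that file alone.
    """

    input: str
    fs: float
    out_dir: str = "ssmseg_out"
    channels: Optional[list[str]] = None
    w: int = 250
    overlap_frac: float = 0.95
    features: Optional[list[str]] = None
    kernel_L: Optional[int] = None
    sigma: float = 0.5
    strategy: str = "threshold"
    theta: float = 0.3
    top_n: Optional[int] = None
    peak_fraction: Optional[float] = None
    min_separation: Optional[int] = None  # None: kernel width D = 2L+1 frames
    mode: str = "novelty"  # novelty | periodic | both
    n_clusters: Optional[int] = None
    linkage: str = "average"
    tolerance: Optional[int] = None
    truth: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs is None or self.fs <= 0:
            raise ValueError("fs must be a positive sampling rate in Hz")
        WindowingConfig(self.w, self.overlap_frac)  # validate
        if self.mode not in ("novelty", "periodic", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def read_timeseries(path, fs: float, channels=None) -> TimeSeriesRecord:
    """Read a delimited text signal into a record.

    Accepts an optional header and an optional leading time column, which
    is detected by name (``time``/``t``/``timestamp``) or by being a
    strictly increasing first column in an otherwise headerless file. If a
    time column is present and its median step disagrees with ``1/fs`` by
    more than 1 %, a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    first_line = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first_line = line
                break
    if not first_line:
        raise ValueError(f"empty file {path}")
    sep = max(",;\t", key=first_line.count)
    if first_line.count(sep) == 0:
        sep = ","
    df = pd.read_csv(path, sep=sep)
    # headerless numeric file? pandas will have used the first row as header
    if all(_is_number(c) for c in df.columns):
        df = pd.read_csv(path, sep=sep, header=None)
        df.columns = [f"ch{i}" for i in range(df.shape[1])]
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric cell in column {col!r} at data row {row}")
    df = df.apply(pd.to_numeric)

    first = str(df.columns[0]).strip().lower()
    if first in ("time", "t", "timestamp", "time_s"):
        tcol = df.iloc[:, 0].to_numpy()
        if tcol.size > 1:
            step = float(np.median(np.diff(tcol)))
            if step > 0 and abs(step - 1.0 / fs) > 0.01 / fs:
                logger.warning(
                    "time column step %.6g s disagrees with 1/fs = %.6g s", step, 1.0 / fs
                )
        df = df.iloc[:, 1:]
    if channels:
        missing = [c for c in channels if c not in df.columns]
        if missing:
            raise ValueError(f"channel(s) {missing!r} not in file (has {list(df.columns)})")
        df = df[list(channels)]
    if df.shape[1] == 0:
        raise ValueError(f"no signal channels in {path}")
    return TimeSeriesRecord(df.to_numpy(dtype=float), fs, [str(c) for c in df.columns])


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_timeseries(record: TimeSeriesRecord, path, include_time: bool = True) -> None:
    """Write a record as CSV with header; optionally a leading time column."""
    data = {}
    if include_time:
        data["time"] = np.arange(record.n) / record.fs
    for i, name in enumerate(record.channel_names):
        data[name] = record.samples[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def write_events(events, path, fs: Optional[float] = None) -> None:
    """Write events as CSV (columns: frame, sample, time_s, score, type).

    ``events`` may be an :class:`EventSet` or a plain array of sample
    indices (then only the ``sample`` column is written).
    """
    if isinstance(events, EventSet):
        df = pd.DataFrame(
            {
                "frame": events.frame_indices,
                "sample": events.sample_indices,
                "time_s": events.sample_indices / fs if fs else np.nan,
                "score": events.scores,
                "type": events.event_type,
            }
        )
    else:
        df = pd.DataFrame({"sample": np.asarray(events, dtype=np.int64)})
    df.to_csv(path, index=False, float_format="%.10g")


def read_events(path) -> np.ndarray:
    """Read ground-truth or detected events; returns sorted sample indices."""
    df = pd.read_csv(path)
    if "sample" not in df.columns:
        raise ValueError(f"events file {path} has no 'sample' column")
    return np.sort(df["sample"].to_numpy(dtype=np.int64))


def save_fm(fm: FeatureMatrix, path) -> None:
    """Persist a feature matrix as CSV (rows = features) with JSON sidecar."""
    path = Path(path)
    pd.DataFrame(fm.values, index=fm.feature_names).to_csv(path, header=False, float_format="%.17g")
    meta = {
        "w": fm.config.w,
        "overlap_frac": fm.config.overlap_frac,
        "hop": fm.config.hop,
        "fs": fm.fs,
        "normalized": fm.normalized,
        "window_starts": fm.window_starts.tolist(),
        "feature_names": list(fm.feature_names),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_fm(path) -> FeatureMatrix:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, header=None, index_col=0)
    return FeatureMatrix(
        df.to_numpy(dtype=float),
        meta["feature_names"],
        np.asarray(meta["window_starts"]),
        WindowingConfig(meta["w"], meta["overlap_frac"]),
        meta["fs"],
        normalized=meta["normalized"],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute features -> SSM -> novelty/periodic -> profiles (-> eval).

    Writes every artifact under ``config.out_dir`` and returns them in a
    dict. Any stage failure is re-raised with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    logger.info("ssmseg %s | w=%d overlap=%.3g mode=%s seed=%d",
                __version__, config.w, config.overlap_frac, config.mode, config.seed)
    artifacts: dict = {}
    stage = "read"
    try:
        record = read_timeseries(config.input, config.fs, config.channels)
        artifacts["record"] = record

        stage = "features"
        wc = WindowingConfig(config.w, config.overlap_frac)
        fm = normalize_fm(extract_features(record, wc, config.features))
        save_fm(fm, out / "fm.csv")
        artifacts["fm"] = fm

        stage = "ssm"
        ssm = compute_ssm(fm)
        save_ssm(ssm, out / "ssm.csv")
        artifacts["ssm"] = ssm

        events = None
        if config.mode in ("novelty", "both"):
            stage = "novelty"
            L = config.kernel_L
            if L is None:
                from ssmseg.novelty import default_kernel_half_size

                L = default_kernel_half_size(ssm.m)
            kernel = build_kernel(L, config.sigma)
            curve = novelty_function(ssm, kernel)
            pd.DataFrame({"frame": np.arange(ssm.m), "nf": curve.values, "raw": curve.raw}).to_csv(
                out / "nf.csv", index=False, float_format="%.10g"
            )
            # events closer than the kernel width are not resolvable
            min_sep = config.min_separation if config.min_separation is not None else kernel.D
            events = pick_peaks(
                curve,
                strategy=config.strategy,
                theta=config.theta,
                top_n=config.top_n,
                peak_fraction=config.peak_fraction,
                min_separation=min_sep,
            )
            write_events(events, out / "events.csv", fs=config.fs)
            artifacts["novelty_curve"] = curve
            artifacts["events"] = events
        if config.mode in ("periodic", "both"):
            stage = "periodic"
            sf = similarity_function(ssm)
            pd.DataFrame({"frame": np.arange(ssm.m), "sf": sf.values}).to_csv(
                out / "sf.csv", index=False, float_format="%.10g"
            )
            valleys = pick_valleys(
                sf,
                strategy=config.strategy,
                theta=config.theta,
                top_n=config.top_n,
                peak_fraction=config.peak_fraction,
                min_separation=config.min_separation or 0,
            )
            write_events(valleys, out / "period_events.csv", fs=config.fs)
            artifacts["similarity_curve"] = sf
            artifacts["period_events"] = valleys
            if events is None:
                events = valleys

        stage = "profiles"
        segments = segments_from_events(events if events is not None else [], ssm.m)
        profs = [similarity_profile(ssm, s) for s in segments]
        artifacts["segments"] = segments
        artifacts["profiles"] = profs
        if config.n_clusters is not None and len(profs) >= 2:
            labels, tree = cluster_segments(
                profs, linkage=config.linkage, k=min(config.n_clusters, len(profs))
            )
            pd.DataFrame(
                {
                    "start_frame": [s.start_frame for s in segments],
                    "end_frame": [s.end_frame for s in segments],
                    "start_sample": [p.segment.start_sample for p in profs],
                    "end_sample": [p.segment.end_sample for p in profs],
                    "label": labels,
                }
            ).to_csv(out / "labels.csv", index=False)
            (out / "tree.json").write_text(json.dumps(tree.tolist(), indent=1))
            artifacts["labels"] = labels
            artifacts["tree"] = tree

        if config.truth is not None and events is not None:
            stage = "evaluation"
            truth = read_events(config.truth)
            tol = config.tolerance if config.tolerance is not None else config.w
            result = evaluate_events(truth, np.sort(events.sample_indices), tol)
            (out / "eval.json").write_text(json.dumps(result.as_dict(), indent=1))
            artifacts["eval"] = result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return artifacts
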
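"""Reading and writing PPG records and feature tables in plain-text formats.

A record is stored as a CSV file with header ``time,<ch>,...`` (time in
seconds from record start) plus a JSON sidecar carrying the sampling rate,
record id, sensor location and optional class label.  Feature tables are
CSV files with one row per recording.  Both round-trip losslessly at double
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, RecordError

VALID_LOCATIONS = ("forehead", "ear", "finger", "unknown")
VALID_LABELS = ("BL", "NBL")

#: column order of a feature table, fixed for deterministic output
FEATURE_COLUMNS = ("record_id", "label", "r2", "slope", "pct_change", "abs_change")

# uniform-time-base tolerance in seconds
_TIME_TOL = 1e-6


@dataclass
class PPGRecord:
    """A multi-channel, uniformly sampled photoplethysmogram.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz.
    samples : ndarray, shape (n_samples, n_channels)
        Raw PPG amplitudes in arbitrary units.
    channel_ids : sequence of str
        One name per channel.
    record_id : str
        Unique identifier of the recording.
    location : str
        Sensor site: ``forehead``, ``ear``, ``finger`` or ``unknown``.
    label : str or None
        Class label ``BL`` (blood loss) or ``NBL`` (no blood loss), if known.
    start_time_s : float
        Time offset of the first sample, seconds.
    meta : dict
        Free-form metadata (e.g. truncation flags).
    """

    fs: float
    samples: np.ndarray
    channel_ids: Sequence[str]
    record_id: str = "record"
    location: str = "unknown"
    label: str | None = None
    start_time_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.fs <= 0:
            raise RecordError("sampling frequency must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise RecordError("samples must be a (n_samples, n_channels) matrix "
                              "with at least one sample")
        if len(self.channel_ids) != self.samples.shape[1]:
            raise RecordError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[1]} channels")
        if not np.all(np.isfinite(self.samples)):
            bad = np.argwhere(~np.isfinite(self.samples))[0]
            raise RecordError(f"non-finite sample at row {bad[0]}, "
                              f"channel {self.channel_ids[bad[1]]}")
        if self.location not in VALID_LOCATIONS:
            raise RecordError(f"unknown sensor location {self.location!r}")
        if self.label is not None and self.label not in VALID_LABELS:
            raise RecordError(f"label must be one of {VALID_LABELS}, "
                              f"got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (sample count over sampling rate)."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, including the start offset."""
        return self.start_time_s + np.arange(self.n_samples) / self.fs

    def channel(self, index: int) -> np.ndarray:
        """Samples of one channel as a 1-D array."""
        return self.samples[:, index]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_record(record: PPGRecord, path: str | Path) -> tuple[Path, Path]:
    """Write a record as ``<path>`` CSV plus a ``<path>.json`` sidecar.

    Returns the paths of the two files written.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    df = pd.DataFrame({"time": record.times()})
    for j, ch in enumerate(record.channel_ids):
        df[ch] = record.samples[:, j]
    # 17 significant digits: lossless for IEEE doubles
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "fs": record.fs,
        "record_id": record.record_id,
        "location": record.location,
        "label": record.label,
        "start_time_s": record.start_time_s,
        "channel_ids": list(record.channel_ids),
        **record.meta,
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path, sidecar


def read_record(path: str | Path, sidecar_path: str | Path | None = None) -> PPGRecord:
    """Read a record CSV and its JSON sidecar.

    The time column must advance uniformly at the sidecar's sampling rate
    (within 1e-6 s per step); gaps, NaNs or a mismatched rate are errors.
    """
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "record_id"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key {key!r}")
    fs = float(meta["fs"])

    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time":
        raise FormatError(f"{path}: expected header 'time,<ch1>,...'")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: missing value at data row {row}")
    t = df["time"].to_numpy(float)
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.abs(dt - 1.0 / fs) > _TIME_TOL
        if bad.any():
            row = int(np.argmax(bad))
            raise FormatError(
                f"{path}: non-uniform or inconsistent time base at row {row + 1}: "
                f"step {dt[row]:.9g} s vs expected {1.0 / fs:.9g} s")
    extra = {k: v for k, v in meta.items()
             if k not in ("fs", "record_id", "location", "label",
                          "start_time_s", "channel_ids")}
    return PPGRecord(
        fs=fs,
        samples=df.iloc[:, 1:].to_numpy(float),
        channel_ids=list(df.columns[1:]),
        record_id=str(meta["record_id"]),
        location=meta.get("location", "unknown"),
        label=meta.get("label"),
        start_time_s=float(t[0]),
        meta=extra,
    )


def validate_features(table: pd.DataFrame) -> pd.DataFrame:
    """Check a feature table: required columns, unique ids, finite values."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"feature table lacks columns {missing}")
    table = table.loc[:, list(FEATURE_COLUMNS)].reset_index(drop=True)
    if len(table):
        dup = table["record_id"][table["record_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate record_id {dup.iloc[0]!r}")
        num = table[["r2", "slope", "pct_change", "abs_change"]].to_numpy(float)
        if not np.all(np.isfinite(num)):
            raise FormatError("feature table contains missing/non-finite values")
        r2 = table["r2"].to_numpy(float)
        if (r2 < 0).any() or (r2 > 1).any():
            raise FormatError("r2 outside [0, 1]")
        bad = ~table["label"].isin(VALID_LABELS)
        if bad.any():
            raise FormatError(f"invalid label {table['label'][bad].iloc[0]!r}")
    return table


def write_features(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table as CSV in the canonical column order."""
    path = Path(path)
    validate_features(table).to_csv(path, index=False, float_format="%.17g")
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature table CSV."""
    df = pd.read_csv(Path(path), dtype={"record_id": str, "label": str})
    if df.empty and set(FEATURE_COLUMNS) <= set(df.columns):
        return df.loc[:, list(FEATURE_COLUMNS)]
    return validate_features(df)
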
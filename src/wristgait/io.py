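"""Readers and writers for the package's on-disk artifacts.

Canonical interchange formats are plain text: CSV for signals and stride
annotations, YAML for run configuration, JSON for evaluation reports.

Recording CSV schema
    wrist:      header ``t,ax,ay,az``  (t in seconds, accelerations in g)
    lower back: header ``t,az``        (single vertical axis)
An optional first comment line ``# units=ms2`` declares accelerations in
m/s^2; they are converted to g at read time.

Stride CSV schema
    ``subject_id,bout_id,stride_start_s,stride_end_s,stride_length_cm,stride_speed_cms``
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, FormatError

log = logging.getLogger("wristgait.io")

G_MS2 = 9.80665  # standard gravity, m/s^2 per g

WRIST_COLUMNS = ["t", "ax", "ay", "az"]
LUMBAR_COLUMNS = ["t", "az"]
STRIDE_COLUMNS = [
    "subject_id",
    "bout_id",
    "stride_start_s",
    "stride_end_s",
    "stride_length_cm",
    "stride_speed_cms",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AccelRecording:
    """A timestamped acceleration stream for one subject and device site.

    ``samples`` is an (n, 3) float array in units of g. For a single-axis
    lower-back device only the third column (vertical, ``az``) is meaningful
    and ``single_axis`` is True; ``ax``/``ay`` are stored as zeros.
    Timestamps are seconds since recording start; ``t0`` keeps an optional
    wall-clock offset as metadata.
    """

    subject_id: str
    device_site: str  # "wrist" | "lower_back"
    fs: float
    samples: np.ndarray
    t0: float = 0.0
    single_axis: bool = False

    def __post_init__(self) -> None:
        if self.device_site not in ("wrist", "lower_back"):
            raise ConfigError(f"unknown device_site {self.device_site!r}")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DataError("samples must be an (n, 3) array")
        if np.isnan(self.samples).any():
            raise DataError("NaN samples are not allowed after loading")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def vertical(self) -> np.ndarray:
        """The vertical (az) channel."""
        return self.samples[:, 2]

    def __eq__(self, other: object) -> bool:  # structural, for round trips
        if not isinstance(other, AccelRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.device_site == other.device_site
            and self.single_axis == other.single_axis
            and np.isclose(self.fs, other.fs, rtol=1e-9)
            and np.isclose(self.t0, other.t0, rtol=0, atol=1e-9)
            and self.samples.shape == other.samples.shape
            and np.allclose(self.samples, other.samples, rtol=1e-8, atol=1e-12)
        )


@dataclass
class StrideAnnotation:
    """One reference stride: start/end time (s), length (cm), speed (cm/s)."""

    start_s: float
    end_s: float
    length_cm: float
    speed_cms: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class WalkingBout:
    """Reference strides grouped into one contiguous walking episode."""

    subject_id: str
    bout_id: str
    strides: list[StrideAnnotation] = field(default_factory=list)

    @property
    def start_s(self) -> float:
        return min(s.start_s for s in self.strides)

    @property
    def end_s(self) -> float:
        return max(s.end_s for s in self.strides)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class RunConfig:
    """Top-level run configuration.

    window_s / hop_s / target_fs pin the windowing scheme (10-s windows,
    1-s hop, i.e. 90 % overlap, at 30 Hz). Per-module parameter blocks are
    carried as plain dicts and consumed by the respective modules.
    """

    window_s: float = 10.0
    hop_s: float = 1.0
    target_fs: float = 30.0
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)
    clinical: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ConfigError("window_s must be > 0")
        if not (0 < self.hop_s <= self.window_s):
            raise ConfigError("hop_s must satisfy 0 < hop_s <= window_s")
        if self.target_fs <= 0:
            raise ConfigError("target_fs must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _read_units_header(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        decl = first.lstrip("#").strip()
        if decl.startswith("units="):
            return decl.split("=", 1)[1].strip()
        raise FormatError(f"unrecognized comment header {first!r}")
    return "g"


def _subject_from_stem(stem: str) -> str:
    """Strip the conventional ``_dayN`` / ``_wrist`` / ``_lumbar`` suffixes."""
    import re

    return re.sub(r"(_day\d+)?(_wrist|_lumbar|_lower_back)?$", "", stem)


def read_recording(
    path: str | Path, device_site: str, subject_id: str | None = None
) -> AccelRecording:
    """Read a recording CSV and validate it.

    The sampling rate is inferred from the median timestamp increment and
    checked for jitter <= 1 %. Rows containing NaN are rejected with a count
    logged. Timestamps must be strictly increasing. The subject id defaults
    to the file stem minus conventional day/site suffixes.
    """
    path = Path(path)
    units = _read_units_header(path)
    df = pd.read_csv(path, comment="#")
    expected = WRIST_COLUMNS if device_site == "wrist" else LUMBAR_COLUMNS
    if list(df.columns) != expected:
        raise FormatError(
            f"recording header {list(df.columns)} != expected {expected}"
        )
    # rate inference and jitter check use the raw timestamp column, so a
    # NaN-valued sample row does not masquerade as a timing gap
    t_raw = df["t"].to_numpy(dtype=float)
    t_raw = t_raw[~np.isnan(t_raw)]
    if t_raw.size < 2:
        raise DataError("recording needs at least 2 timestamped samples")
    dt = np.diff(t_raw)
    if (dt <= 0).any():
        raise DataError("timestamps are not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med + 1e-12:
        raise DataError("timestamp jitter exceeds 1 % of the median increment")
    fs = 1.0 / med
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        log.info("read_recording(%s): rejected %d NaN rows", path.name, n_dropped)
    if len(df) < 2:
        raise DataError("recording needs at least 2 valid samples")
    t = df["t"].to_numpy(dtype=float)
    if device_site == "wrist":
        samples = df[["ax", "ay", "az"]].to_numpy(dtype=float)
        single_axis = False
    else:
        az = df["az"].to_numpy(dtype=float)
        samples = np.column_stack([np.zeros_like(az), np.zeros_like(az), az])
        single_axis = True
    if units == "ms2":
        samples = samples / G_MS2
    elif units != "g":
        raise FormatError(f"unknown units declaration {units!r}")
    return AccelRecording(
        subject_id=subject_id or _subject_from_stem(path.stem),
        device_site=device_site,
        fs=fs,
        samples=samples,
        t0=float(t[0]),
        single_axis=single_axis,
    )


def write_recording(rec: AccelRecording, path: str | Path) -> None:
    """Write a recording to the canonical CSV schema (always units of g)."""
    t = rec.t0 + rec.t
    if rec.single_axis:
        df = pd.DataFrame({"t": t, "az": rec.samples[:, 2]})
    else:
        df = pd.DataFrame(
            {
                "t": t,
                "ax": rec.samples[:, 0],
                "ay": rec.samples[:, 1],
                "az": rec.samples[:, 2],
            }
        )
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# strides
# ---------------------------------------------------------------------------

def read_strides(path: str | Path) -> list[WalkingBout]:
    """Read a stride CSV and group strides into walking bouts.

    Strides sharing a ``bout_id`` form one bout; within a bout strides must
    be time-ordered and non-overlapping. Bouts are ordered by the start of
    their first stride.
    """
    df = pd.read_csv(path)
    if list(df.columns) != STRIDE_COLUMNS:
        raise FormatError(f"stride header {list(df.columns)} != {STRIDE_COLUMNS}")
    bouts: list[WalkingBout] = []
    if df.empty:
        return bouts
    for (subject_id, bout_id), grp in df.groupby(
        ["subject_id", "bout_id"], sort=False
    ):
        grp = grp.sort_values("stride_start_s")
        starts = grp["stride_start_s"].to_numpy(dtype=float)
        ends = grp["stride_end_s"].to_numpy(dtype=float)
        if (ends <= starts).any():
            raise DataError(f"bout {bout_id}: stride with non-positive duration")
        if (starts[1:] < ends[:-1] - 1e-9).any():
            raise DataError(f"bout {bout_id}: overlapping strides")
        strides = [
            StrideAnnotation(
                start_s=float(r.stride_start_s),
                end_s=float(r.stride_end_s),
                length_cm=float(r.stride_length_cm),
                speed_cms=float(r.stride_speed_cms),
            )
            for r in grp.itertuples()
        ]
        bouts.append(
            WalkingBout(subject_id=str(subject_id), bout_id=str(bout_id), strides=strides)
        )
    bouts.sort(key=lambda b: b.start_s)
    return bouts


def write_strides(bouts: Iterable[WalkingBout], path: str | Path) -> None:
    rows = []
    for b in bouts:
        for s in b.strides:
            rows.append(
                {
                    "subject_id": b.subject_id,
                    "bout_id": b.bout_id,
                    "stride_start_s": s.start_s,
                    "stride_end_s": s.end_s,
                    "stride_length_cm": s.length_cm,
                    "stride_speed_cms": s.speed_cms,
                }
            )
    pd.DataFrame(rows, columns=STRIDE_COLUMNS).to_csv(
        path, index=False, float_format="%.9g"
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize an evaluation report (nested dict) to JSON, losslessly."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, allow_nan=True)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
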
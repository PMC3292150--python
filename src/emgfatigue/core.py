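"""Domain types for fatigue trials, label streams and feature streams, plus CSV I/O.

A *trial* is one synchronized recording of two sEMG channels (mV) and an
elbow-angle goniometer trace (degrees).  All downstream stages consume whole
seconds: per-second class labels (:class:`LabelSeries`) and per-window scalar
feature streams (:class:`FeatureSeries`).  Windows are half-open ``[t, t+1)``
with 0-based start times; trailing partial seconds are dropped everywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "TrialFormatError",
    "FatigueClass",
    "Trial",
    "LabelSeries",
    "FeatureSeries",
    "read_trial",
    "write_trial",
    "read_labels",
    "write_labels",
    "read_feature",
    "write_feature",
    "align_labels_to_seconds",
]

TRIAL_COLUMNS = ("time_s", "emg_ch1_mV", "emg_ch2_mV", "gonio_deg")


class ValidationError(ValueError):
    """An object or parameter violates a documented invariant."""


class TrialFormatError(ValidationError):
    """A trial/label/feature file does not match the documented CSV layout."""


class FatigueClass(enum.IntEnum):
    """The three muscle states, ordered by severity (NF < TF < F)."""

    NON_FATIGUE = 0
    TRANSITION_TO_FATIGUE = 1
    FATIGUE = 2

    @property
    def code(self) -> str:
        return _CLASS_CODES[self]

    @classmethod
    def from_code(cls, code: str) -> "FatigueClass":
        try:
            return _CODE_CLASSES[code.strip()]
        except KeyError:
            raise ValidationError(
                f"unknown fatigue class code {code!r}; expected one of "
                f"{sorted(_CODE_CLASSES)}"
            ) from None


_CLASS_CODES = {
    FatigueClass.NON_FATIGUE: "NF",
    FatigueClass.TRANSITION_TO_FATIGUE: "TF",
    FatigueClass.FATIGUE: "F",
}
_CODE_CLASSES = {v: k for k, v in _CLASS_CODES.items()}


@dataclass
class Trial:
    """One synchronized two-channel sEMG + goniometer recording.

    Attributes
    ----------
    emg:
        Array of shape ``(2, n)`` in mV.
    gonio_angle:
        Elbow angle in degrees, values within [0, 180].
    """

    emg: np.ndarray
    gonio_angle: np.ndarray
    fs_emg: float = 2000.0
    fs_gonio: float = 2000.0
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.gonio_angle = np.asarray(self.gonio_angle, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (self.fs_emg > 0 and self.fs_gonio > 0):
            raise ValidationError("sampling rates must be positive")
        if self.emg.ndim != 2 or self.emg.shape[0] != 2:
            raise ValidationError(
                f"emg must have shape (2, n); got {self.emg.shape}"
            )
        if self.gonio_angle.ndim != 1:
            raise ValidationError("gonio_angle must be one-dimensional")
        if not np.all(np.isfinite(self.emg)):
            raise ValidationError("emg contains non-finite samples")
        if not np.all(np.isfinite(self.gonio_angle)):
            raise ValidationError("gonio_angle contains non-finite samples")
        if self.gonio_angle.size and (
            self.gonio_angle.min() < 0.0 or self.gonio_angle.max() > 180.0
        ):
            raise ValidationError("gonio_angle values must lie within [0, 180] degrees")
        dur_emg = self.emg.shape[1] / self.fs_emg
        dur_gonio = self.gonio_angle.size / self.fs_gonio
        tol = max(1.0 / self.fs_emg, 1.0 / self.fs_gonio)
        if abs(dur_emg - dur_gonio) > tol + 1e-12:
            raise ValidationError(
                f"emg duration ({dur_emg:.6f} s) and goniometer duration "
                f"({dur_gonio:.6f} s) differ by more than one sample period"
            )

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_emg


@dataclass
class LabelSeries:
    """Per-window class labels; one label per ``window_duration`` seconds."""

    labels: list[FatigueClass] = field(default_factory=list)
    window_duration: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = [FatigueClass(v) for v in self.labels]
        self.validate()

    def validate(self) -> None:
        if self.window_duration <= 0:
            raise ValidationError("window_duration must be positive")
        if not self.labels:
            raise ValidationError("labels must be non-empty")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.window_duration * np.arange(len(self.labels))

    def label_at(self, t: float) -> FatigueClass:
        """Label of the window containing time ``t`` (half-open windows)."""
        idx = int(np.floor((t - self.start_time) / self.window_duration + 1e-9))
        if not 0 <= idx < len(self.labels):
            raise ValidationError(f"time {t} s lies outside the labeled range")
        return self.labels[idx]


@dataclass
class FeatureSeries:
    """A named per-window scalar feature stream with window start times."""

    name: str
    times: np.ndarray
    values: np.ndarray
    window_duration: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times and values must be 1-D and equally long")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"feature {self.name!r} contains non-finite values")
        if self.window_duration <= 0:
            raise ValidationError("window_duration must be positive")

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# CSV I/O
#
# Trial CSV:   header time_s,emg_ch1_mV,emg_ch2_mV,gonio_deg, one row per
#              sample, optional '# key=value' metadata comment lines.
# Label CSV:   header window_start_s,label with label in {NF,TF,F}.
# Feature CSV: '# name=<feature>' comment line, header window_start_s,value.
# ---------------------------------------------------------------------------


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _numeric_column(df: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    raw = df[column]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise TrialFormatError(
            f"{path}: non-numeric or missing value {raw.iloc[row]!r} in column "
            f"{column!r}, data row {row}"
        )
    return converted.to_numpy(dtype=float)


def read_trial(path: str | Path) -> Trial:
    """Read and validate a trial CSV (see module docstring for the layout)."""
    path = Path(path)
    meta = _read_metadata(path)
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise TrialFormatError(f"{path}: empty file") from None
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise TrialFormatError(f"{path}: no data rows")
    cols = {c: _numeric_column(df, c, path) for c in TRIAL_COLUMNS}
    time = cols["time_s"]
    fs_emg = float(meta.get("fs_emg", 0)) or _infer_fs(time, path)
    fs_gonio = float(meta.get("fs_gonio", 0)) or fs_emg
    return Trial(
        emg=np.vstack([cols["emg_ch1_mV"], cols["emg_ch2_mV"]]),
        gonio_angle=cols["gonio_deg"],
        fs_emg=fs_emg,
        fs_gonio=fs_gonio,
        subject_id=meta.get("subject_id", ""),
        trial_id=meta.get("trial_id", ""),
    )


def _infer_fs(time: np.ndarray, path: Path) -> float:
    if time.size < 2:
        return 2000.0
    dt = np.median(np.diff(time))
    if dt <= 0:
        raise TrialFormatError(f"{path}: time_s column is not increasing")
    return 1.0 / dt


def write_trial(trial: Trial, path: str | Path) -> Path:
    """Write a trial CSV, lossless to better than 1e-9 mV / 1e-9 degrees."""
    if trial.n_samples == 0:
        raise ValidationError("refusing to write an empty trial")
    path = Path(path)
    time = np.arange(trial.n_samples) / trial.fs_emg
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject_id={trial.subject_id}\n")
        fh.write(f"# trial_id={trial.trial_id}\n")
        fh.write(f"# fs_emg={trial.fs_emg!r}\n")
        fh.write(f"# fs_gonio={trial.fs_gonio!r}\n")
        fh.write(",".join(TRIAL_COLUMNS) + "\n")
        for i in range(trial.n_samples):
            fh.write(
                f"{float(time[i])!r},{float(trial.emg[0, i])!r},"
                f"{float(trial.emg[1, i])!r},{float(trial.gonio_angle[i])!r}\n"
            )
    return path


def write_labels(series: LabelSeries, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# window_duration_s={series.window_duration!r}\n")
        fh.write("window_start_s,label\n")
        for t, lab in zip(series.times, series.labels):
            fh.write(f"{float(t)!r},{lab.code}\n")
    return path


def read_labels(path: str | Path) -> LabelSeries:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in ("window_start_s", "label"):
        if col not in df.columns:
            raise TrialFormatError(f"{path}: missing column {col!r}")
    times = _numeric_column(df, "window_start_s", path)
    labels = [FatigueClass.from_code(c) for c in df["label"]]
    if "window_duration_s" in meta:
        wd = float(meta["window_duration_s"])
    elif times.size > 1:
        wd = float(np.median(np.diff(times)))
    else:
        wd = 1.0
    return LabelSeries(labels=labels, window_duration=wd,
                       start_time=float(times[0]) if times.size else 0.0)


def write_feature(series: FeatureSeries, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# name={series.name}\n")
        fh.write(f"# window_duration_s={series.window_duration!r}\n")
        fh.write("window_start_s,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")
    return path


def read_feature(path: str | Path) -> FeatureSeries:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in ("window_start_s", "value"):
        if col not in df.columns:
            raise TrialFormatError(f"{path}: missing column {col!r}")
    return FeatureSeries(
        name=meta.get("name", path.stem),
        times=_numeric_column(df, "window_start_s", path),
        values=_numeric_column(df, "value", path),
        window_duration=float(meta.get("window_duration_s", 1.0)),
    )


def align_labels_to_seconds(
    labels_per_sample: Sequence[FatigueClass] | Iterable[FatigueClass],
    fs: float,
) -> LabelSeries:
    """Reduce per-sample labels to one label per full second.

    Each second's label is the majority label of its samples; ties resolve to
    the more severe class.  The trailing partial second is dropped.
    """
    if fs <= 0:
        raise ValidationError("fs must be positive")
    codes = np.asarray([int(v) for v in labels_per_sample], dtype=np.int64)
    n_seconds = int(codes.size // fs) if float(fs).is_integer() else int(
        np.floor(codes.size / fs)
    )
    if n_seconds < 1:
        raise ValidationError("need at least one full second of samples")
    out: list[FatigueClass] = []
    for s in range(n_seconds):
        lo = int(np.floor(s * fs))
        hi = int(np.floor((s + 1) * fs))
        counts = np.bincount(codes[lo:hi], minlength=3)
        best = max(range(3), key=lambda k: (counts[k], k))  # tie -> severe
        out.append(FatigueClass(best))
    return LabelSeries(labels=out, window_duration=1.0, start_time=0.0)
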
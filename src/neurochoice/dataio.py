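"""Recording data model and the package's on-disk CSV layout.

A dataset is a directory of per-subject directories, each holding

* ``eeg.csv``    — one column per channel (header = channel names), microvolts
* ``et.csv``     — columns ``t,x,y,valid`` (t in samples, x/y screen pixels)
* ``trials.csv`` — columns ``stream,start,end,label,product_id`` with 0-based
  half-open [start, end) sample ranges per stream
* ``meta.json``  — sampling rates, screen size, subject id

Missing eye-tracking samples are encoded by ``valid == 0``, never by sentinel
coordinates, so downstream interpolation knows which samples were measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrialAnnotation",
    "EEGRecording",
    "ETRecording",
    "WindowSet",
    "read_recording",
    "write_recording",
    "extract_trial",
]

EEG_FS_DEFAULT = 300.0
ET_FS_DEFAULT = 120.0

#: 19-channel montage emitted by the synthetic generator (10–20 names).
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]


class DataIOError(ValueError):
    """Malformed file or invariant violation in the recording layout."""


@dataclass(frozen=True)
class TrialAnnotation:
    """One product-viewing trial: a half-open sample range with a label."""

    start_sample: int
    end_sample: int
    label: int  # buy=1, no_buy=0
    product_id: str = ""

    def __post_init__(self):
        if not self.start_sample < self.end_sample:
            raise DataIOError(
                f"trial range [{self.start_sample}, {self.end_sample}) is empty"
            )
        if self.label not in (0, 1):
            raise DataIOError(f"label must be 0 or 1, got {self.label}")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts: ``data`` is (n_channels, n_samples)."""

    data: np.ndarray
    channel_names: list[str]
    fs: float = EEG_FS_DEFAULT
    subject_id: str = ""
    trials: list[TrialAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataIOError("EEG data must be a 2-D (channels × samples) matrix")
        if self.data.shape[0] != len(self.channel_names):
            raise DataIOError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise DataIOError("sampling rate must be positive")
        for t in self.trials:
            if t.start_sample < 0 or t.end_sample > self.n_samples:
                raise DataIOError(
                    f"trial [{t.start_sample}, {t.end_sample}) outside "
                    f"[0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ETRecording:
    """Gaze stream in screen pixels with a per-sample validity flag."""

    gaze_x: np.ndarray
    gaze_y: np.ndarray
    valid: np.ndarray
    fs: float = ET_FS_DEFAULT
    screen_size: tuple[int, int] = (1920, 1080)
    subject_id: str = ""
    trials: list[TrialAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.gaze_x) == len(self.gaze_y) == len(self.valid)):
            raise DataIOError("gaze_x, gaze_y and valid must have equal length")
        if self.fs <= 0:
            raise DataIOError("sampling rate must be positive")
        w, h = self.screen_size
        ok = self.valid
        if ok.any():
            x, y = self.gaze_x[ok], self.gaze_y[ok]
            if (x < 0).any() or (x >= w).any() or (y < 0).any() or (y >= h).any():
                raise DataIOError("valid gaze samples fall outside the screen")
        for t in self.trials:
            if t.start_sample < 0 or t.end_sample > self.n_samples:
                raise DataIOError(
                    f"trial [{t.start_sample}, {t.end_sample}) outside "
                    f"[0, {self.n_samples})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.gaze_x)


@dataclass
class WindowSet:
    """Aligned fixed-length segments from both modalities.

    ``eeg_windows[i]`` is 19×300, ``et_windows[i]`` is 120×2 and
    ``gaze_plots[i]`` is a 64×64 uint8 raster; ``alignment[i]`` records the
    (eeg window index, et window index) the fused row i came from.
    """

    eeg_windows: list = field(default_factory=list)
    et_windows: list = field(default_factory=list)
    gaze_plots: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)
    alignment: list = field(default_factory=list)
    trial_keys: list = field(default_factory=list)  # (subject, trial) per row

    def __len__(self) -> int:
        return len(self.labels)

    def validate(self):
        n = len(self.labels)
        for name in ("eeg_windows", "et_windows", "gaze_plots",
                     "subject_ids", "alignment", "trial_keys"):
            seq = getattr(self, name)
            if seq and len(seq) != n:
                raise DataIOError(f"{name} length {len(seq)} != n labels {n}")
        for img in self.gaze_plots:
            a = np.asarray(img)
            if a.min() < 0 or a.max() > 255:
                raise DataIOError("gaze plot pixel values outside [0, 255]")


# ---------------------------------------------------------------------------
# on-disk layout


def _meta_path(d: Path) -> Path:
    return d / "meta.json"


def read_recording(path, kind: str):
    """Read one subject directory into an :class:`EEGRecording` or
    :class:`ETRecording` (``kind`` in ``{"eeg", "et"}``)."""
    d = Path(path)
    if kind not in ("eeg", "et"):
        raise ValueError(f"kind must be 'eeg' or 'et', got {kind!r}")
    try:
        meta = json.loads(_meta_path(d).read_text())
    except FileNotFoundError:
        raise DataIOError(f"missing metadata sidecar {_meta_path(d)}")
    trials = _read_trials(d, kind)
    if kind == "eeg":
        df = pd.read_csv(d / "eeg.csv", float_precision="round_trip")
        fs = float(meta.get("eeg_fs", EEG_FS_DEFAULT))
        if fs <= 0:
            raise DataIOError("eeg_fs must be positive")
        names = list(df.columns)
        declared = meta.get("channel_names")
        if declared is not None and list(declared) != names:
            raise DataIOError(
                f"channel mismatch: header has {len(names)} columns, "
                f"metadata declares {len(declared)} names"
            )
        return EEGRecording(
            data=df.to_numpy(dtype=float).T,
            channel_names=names,
            fs=fs,
            subject_id=meta.get("subject_id", d.name),
            trials=trials,
        )
    df = pd.read_csv(d / "et.csv", float_precision="round_trip")
    for col in ("t", "x", "y", "valid"):
        if col not in df.columns:
            raise DataIOError(f"et.csv missing column {col!r}")
    return ETRecording(
        gaze_x=df["x"].to_numpy(float),
        gaze_y=df["y"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
        fs=float(meta.get("et_fs", ET_FS_DEFAULT)),
        screen_size=tuple(meta.get("screen_size", (1920, 1080))),
        subject_id=meta.get("subject_id", d.name),
        trials=trials,
    )


def _read_trials(d: Path, stream: str) -> list[TrialAnnotation]:
    p = d / "trials.csv"
    if not p.exists():
        return []
    df = pd.read_csv(p)
    out = []
    for i, row in df.iterrows():
        if str(row["stream"]) != stream:
            continue
        try:
            out.append(
                TrialAnnotation(
                    start_sample=int(row["start"]),
                    end_sample=int(row["end"]),
                    label=int(row["label"]),
                    product_id=str(row.get("product_id", "")),
                )
            )
        except (ValueError, KeyError) as e:
            raise DataIOError(f"trials.csv row {i}: {e}")
    return out


def write_recording(rec, path) -> Path:
    """Write a recording into the subject-directory layout; inverse of
    :func:`read_recording` (numeric fields round-trip exactly via repr)."""
    d = Path(path)
    if d.exists() and not d.is_dir():
        raise IOError(f"{d} exists and is not a directory")
    d.mkdir(parents=True, exist_ok=True)
    meta = {}
    if _meta_path(d).exists():
        meta = json.loads(_meta_path(d).read_text())
    if isinstance(rec, EEGRecording):
        pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(
            d / "eeg.csv", index=False, float_format="%.17g"
        )
        meta.update(
            eeg_fs=rec.fs, channel_names=rec.channel_names, subject_id=rec.subject_id
        )
        _write_trials(d, rec.trials, "eeg")
    elif isinstance(rec, ETRecording):
        pd.DataFrame(
            {
                "t": np.arange(rec.n_samples),
                "x": rec.gaze_x,
                "y": rec.gaze_y,
                "valid": rec.valid.astype(int),
            }
        ).to_csv(d / "et.csv", index=False, float_format="%.17g")
        meta.update(
            et_fs=rec.fs,
            screen_size=list(rec.screen_size),
            subject_id=rec.subject_id,
        )
        _write_trials(d, rec.trials, "et")
    else:
        raise TypeError(f"cannot write {type(rec).__name__}")
    _meta_path(d).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return d


def _write_trials(d: Path, trials, stream: str):
    p = d / "trials.csv"
    rows = []
    if p.exists():
        old = pd.read_csv(p)
        rows = old[old["stream"] != stream].to_dict("records")
    rows += [
        dict(
            stream=stream,
            start=t.start_sample,
            end=t.end_sample,
            label=t.label,
            product_id=t.product_id,
        )
        for t in trials
    ]
    pd.DataFrame(rows, columns=["stream", "start", "end", "label", "product_id"]).to_csv(
        p, index=False
    )


def extract_trial(rec, trial: TrialAnnotation):
    """Slice one trial out of a recording; sample values are untouched."""
    if trial.start_sample < 0 or trial.end_sample > rec.n_samples:
        raise IndexError(
            f"trial [{trial.start_sample}, {trial.end_sample}) outside "
            f"recording of {rec.n_samples} samples"
        )
    sl = slice(trial.start_sample, trial.end_sample)
    local = TrialAnnotation(0, trial.n_samples, trial.label, trial.product_id)
    if isinstance(rec, EEGRecording):
        return EEGRecording(
            data=rec.data[:, sl].copy(),
            channel_names=list(rec.channel_names),
            fs=rec.fs,
            subject_id=rec.subject_id,
            trials=[local],
        )
    if isinstance(rec, ETRecording):
        return ETRecording(
            gaze_x=rec.gaze_x[sl].copy(),
            gaze_y=rec.gaze_y[sl].copy(),
            valid=rec.valid[sl].copy(),
            fs=rec.fs,
            screen_size=rec.screen_size,
            subject_id=rec.subject_id,
            trials=[local],
        )
    raise TypeError(f"cannot slice {type(rec).__name__}")
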
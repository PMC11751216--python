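"""Synthetic multimodal recordings with controllable class structure.

The generator emulates the acquisition the pipeline targets — 19-channel EEG
at 300 Hz and a 120 Hz gaze stream, organised as per-product trials labelled
buy / no-buy — with just enough statistical structure for every downstream
stage to have something real to do:

* EEG trials are sums of band-limited noise (delta–gamma, 1/f-like weights);
  buy trials multiply the alpha-band (8–13 Hz) *amplitude* by
  ``alpha_power_ratio``.
* Gaze trials are scanpaths of alternating fixations (lognormal durations,
  class-shifted mean) and ballistic saccades (class-shiftable amplitude).
* Blinks produce simultaneous high-amplitude low-frequency frontal EEG
  transients and runs of invalid gaze samples — a cross-modal artifact for
  the cleaning stages to remove. Line noise and muscle bursts are added on
  top of the EEG.

Everything is deterministic under ``SynthConfig.seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .dataio import (
    DEFAULT_CHANNELS,
    EEGRecording,
    ETRecording,
    TrialAnnotation,
    write_recording,
)

__all__ = ["SynthConfig", "ClassEffect", "ArtifactRates",
           "generate_eeg_trial", "generate_et_trial", "generate_dataset",
           "generate_subject"]

# conventional clinical bands truncated at the 45 Hz filter edge
BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
         "beta": (13.0, 30.0), "gamma": (30.0, 45.0)}

# resting-EEG-like RMS amplitude per band, microvolts (1/f-ish decay)
BAND_RMS = {"delta": 8.0, "theta": 5.0, "alpha": 6.0, "beta": 3.0, "gamma": 1.5}

# frontal emphasis of blink transients over the default 19-channel montage
_BLINK_TOPO = np.array(
    [1.0, 1.0, 0.6, 0.5, 0.45, 0.5, 0.6,
     0.2, 0.15, 0.1, 0.15, 0.2,
     0.05, 0.05, 0.05, 0.05, 0.05,
     0.02, 0.02]
)
_MUSCLE_CHANNELS = [2, 6, 7, 11, 12, 16]  # temporal / lateral sites


@dataclass(frozen=True)
class ClassEffect:
    """How buy trials differ from no-buy trials."""

    alpha_power_ratio: float = 0.8     # ×alpha amplitude in buy trials
    fixation_duration_shift: float = 50.0   # ms added to mean fixation duration
    saccade_amplitude_shift: float = 20.0   # px added to mean saccade amplitude


@dataclass(frozen=True)
class ArtifactRates:
    blinks_per_minute: float = 15.0
    line_noise_amplitude: float = 2.0  # µV at 50 Hz
    muscle_burst_rate: float = 4.0     # bursts per minute

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 8
    trials_per_subject: int = 12
    buy_fraction: float = 0.3
    eeg_fs: float = 300.0
    et_fs: float = 120.0
    n_channels: int = 19
    trial_duration: float = 2.0  # seconds
    class_effect: ClassEffect = field(default_factory=ClassEffect)
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    screen_size: tuple[int, int] = (1920, 1080)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.buy_fraction < 1:
            raise ValueError("buy_fraction must lie in (0, 1)")
        if self.trial_duration < 1.0:
            raise ValueError("trial_duration must be >= 1 s")
        if self.n_subjects < 1 or self.trials_per_subject < 2:
            raise ValueError("need >= 1 subject and >= 2 trials per subject")


def _band_noise(n, fs, lo, hi, rms, rng, n_rows=None):
    """Gaussian noise band-limited to [lo, hi] Hz with target per-row RMS.

    Returns shape (n,) when ``n_rows`` is None, else (n_rows, n).
    """
    pad = int(fs)
    shape = (n + 2 * pad,) if n_rows is None else (n_rows, n + 2 * pad)
    x = rng.standard_normal(shape)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)[..., pad:pad + n]
    s = y.std(axis=-1, keepdims=True)
    return y * np.divide(rms, s, out=np.ones_like(s), where=s > 0)


def _poisson_times(rate_per_minute, duration_s, rng):
    n = rng.poisson(rate_per_minute * duration_s / 60.0)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def generate_eeg_trial(cfg: SynthConfig, label: int, rng, blink_times=None):
    """One trial's EEG as an :class:`EEGRecording` slice (19 × duration·fs)."""
    n = int(round(cfg.trial_duration * cfg.eeg_fs))
    data = np.zeros((cfg.n_channels, n))
    for band, (lo, hi) in BANDS.items():
        rms = BAND_RMS[band]
        if band == "alpha" and label == 1:
            rms *= cfg.class_effect.alpha_power_ratio
        data += _band_noise(n, cfg.eeg_fs, lo, hi, rms, rng,
                            n_rows=cfg.n_channels)

    ar = cfg.artifact_rates
    if blink_times is None:
        blink_times = _poisson_times(ar.blinks_per_minute, cfg.trial_duration, rng)
    t = np.arange(n) / cfg.eeg_fs
    for bt in blink_times:
        dur = 0.35  # s, typical blink transient
        mask = (t >= bt) & (t < bt + dur)
        if not mask.any():
            continue
        phase = (t[mask] - bt) / dur
        bump = 120.0 * np.sin(np.pi * phase) ** 2  # smooth, ~0.5–2 Hz content
        topo = _BLINK_TOPO[: cfg.n_channels, None]
        data[:, mask] += topo * bump[None, :]

    if ar.line_noise_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        data += ar.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)[None, :]

    for bt in _poisson_times(ar.muscle_burst_rate, cfg.trial_duration, rng):
        mask = (t >= bt) & (t < bt + 0.2)
        m = int(mask.sum())
        if m < 10:
            continue
        for ch in _MUSCLE_CHANNELS:
            if ch < cfg.n_channels:
                data[ch, mask] += _band_noise(m, cfg.eeg_fs, 20, 45, 25.0, rng)

    return EEGRecording(
        data=data,
        channel_names=DEFAULT_CHANNELS[: cfg.n_channels],
        fs=cfg.eeg_fs,
        trials=[TrialAnnotation(0, n, label)],
    )


def generate_et_trial(cfg: SynthConfig, label: int, rng, blink_times=None):
    """One trial's gaze stream as an :class:`ETRecording` slice."""
    n = int(round(cfg.trial_duration * cfg.et_fs))
    w, h = cfg.screen_size
    eff = cfg.class_effect
    fix_mean_ms = 250.0 + (eff.fixation_duration_shift if label == 1 else 0.0)
    sacc_mean_px = 150.0 + (eff.saccade_amplitude_shift if label == 1 else 0.0)

    x = np.empty(n)
    y = np.empty(n)
    cx, cy = rng.uniform(0.25 * w, 0.75 * w), rng.uniform(0.25 * h, 0.75 * h)
    i = 0
    while i < n:
        # fixation: lognormal duration around the class mean, small jitter
        dur_ms = rng.lognormal(np.log(fix_mean_ms), 0.35)
        m = min(n - i, max(int(round(dur_ms / 1000.0 * cfg.et_fs)), 1))
        x[i:i + m] = cx + rng.normal(0, 2.0, m)
        y[i:i + m] = cy + rng.normal(0, 2.0, m)
        i += m
        if i >= n:
            break
        # ballistic saccade to the next fixation centre
        amp = abs(rng.normal(sacc_mean_px, 40.0))
        ang = rng.uniform(0, 2 * np.pi)
        nx = np.clip(cx + amp * np.cos(ang), 0.05 * w, 0.95 * w)
        ny = np.clip(cy + amp * np.sin(ang), 0.05 * h, 0.95 * h)
        m = min(n - i, max(int(round(0.03 * cfg.et_fs)), 1))
        frac = np.linspace(0, 1, m, endpoint=False) + 1.0 / m
        x[i:i + m] = cx + frac * (nx - cx)
        y[i:i + m] = cy + frac * (ny - cy)
        cx, cy = nx, ny
        i += m

    x = np.clip(x, 0, w - 1)
    y = np.clip(y, 0, h - 1)

    valid = np.ones(n, dtype=bool)
    if blink_times is None:
        blink_times = _poisson_times(
            cfg.artifact_rates.blinks_per_minute, cfg.trial_duration, rng
        )
    t = np.arange(n) / cfg.et_fs
    for bt in blink_times:
        valid[(t >= bt) & (t < bt + 0.25)] = False

    return ETRecording(
        gaze_x=x, gaze_y=y, valid=valid,
        fs=cfg.et_fs, screen_size=cfg.screen_size,
        trials=[TrialAnnotation(0, n, label)],
    )


def _subject_labels(cfg: SynthConfig, rng) -> np.ndarray:
    """Exact-count label assignment; both classes always present."""
    n = cfg.trials_per_subject
    n_buy = int(round(cfg.buy_fraction * n))
    n_buy = min(max(n_buy, 1), n - 1)
    labels = np.array([1] * n_buy + [0] * (n - n_buy))
    rng.shuffle(labels)
    return labels


def generate_subject(cfg: SynthConfig, subject_idx: int):
    """Continuous per-subject recordings (trials concatenated back to back)."""
    ss = np.random.SeedSequence([cfg.seed, subject_idx])
    rng = np.random.default_rng(ss)
    labels = _subject_labels(cfg, rng)

    eeg_parts, et_parts = [], []
    eeg_trials, et_trials = [], []
    ne = int(round(cfg.trial_duration * cfg.eeg_fs))
    nt = int(round(cfg.trial_duration * cfg.et_fs))
    for k, lab in enumerate(labels):
        blink_times = _poisson_times(
            cfg.artifact_rates.blinks_per_minute, cfg.trial_duration, rng
        )
        eeg = generate_eeg_trial(cfg, int(lab), rng, blink_times=blink_times)
        et = generate_et_trial(cfg, int(lab), rng, blink_times=blink_times)
        eeg_parts.append(eeg.data)
        et_parts.append((et.gaze_x, et.gaze_y, et.valid))
        pid = f"P{k:03d}"
        eeg_trials.append(TrialAnnotation(k * ne, (k + 1) * ne, int(lab), pid))
        et_trials.append(TrialAnnotation(k * nt, (k + 1) * nt, int(lab), pid))

    sid = f"S{subject_idx:02d}"
    eeg_rec = EEGRecording(
        data=np.concatenate(eeg_parts, axis=1),
        channel_names=DEFAULT_CHANNELS[: cfg.n_channels],
        fs=cfg.eeg_fs, subject_id=sid, trials=eeg_trials,
    )
    et_rec = ETRecording(
        gaze_x=np.concatenate([p[0] for p in et_parts]),
        gaze_y=np.concatenate([p[1] for p in et_parts]),
        valid=np.concatenate([p[2] for p in et_parts]),
        fs=cfg.et_fs, screen_size=cfg.screen_size, subject_id=sid,
        trials=et_trials,
    )
    return eeg_rec, et_rec


def generate_dataset(cfg: SynthConfig, out_dir) -> Path:
    """Write ``n_subjects`` subject directories plus a manifest; returns the
    dataset root. Regeneration with the same config is byte-identical."""
    root = Path(out_dir)
    if root.exists() and not root.is_dir():
        raise IOError(f"{root} exists and is not a directory")
    root.mkdir(parents=True, exist_ok=True)
    digests = {}
    for s in range(cfg.n_subjects):
        eeg, et = generate_subject(cfg, s)
        d = root / eeg.subject_id
        write_recording(eeg, d)
        write_recording(et, d)
        h = hashlib.sha256()
        for f in sorted(p.name for p in d.iterdir()):
            h.update((d / f).read_bytes())
        digests[eeg.subject_id] = h.hexdigest()
    manifest = {
        "config": _cfg_dict(cfg),
        "seed": cfg.seed,
        "subjects": digests,
        "content_hash": hashlib.sha256(
            json.dumps(digests, sort_keys=True).encode()
        ).hexdigest(),
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return root


def _cfg_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["screen_size"] = list(d["screen_size"])
    return d
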
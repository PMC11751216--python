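"""Handcrafted features.

EEG, per channel: mean, population variance, bias-corrected skewness and
excess kurtosis; Welch band powers over the five clinical bands
(δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz); mean and SD of the DWT
coefficients at each detail level and the final approximation.

Eye tracking, per window: mean fixation duration, fixation count, mean
saccade amplitude (Euclidean distance between consecutive fixation
centroids) and saccade count.

Note the deliberate asymmetry in the moment statistics: the variance uses the
population divisor N while the skewness/kurtosis standardization uses the
sample SD (divisor N−1) inside their bias-corrected forms — the set is kept
exactly as specified even though it mixes conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

from .gaze_prep import Fixation

__all__ = ["HandFeatureConfig", "stat_features", "welch_band_powers",
           "dwt_features", "et_hand_features", "eeg_hand_vector",
           "eeg_hand_matrix", "et_hand_matrix", "BAND_EDGES"]

BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class HandFeatureConfig:
    fs: float = 300.0
    welch_nperseg: int = 150   # 2 Hz resolution on a 1-s window at 300 Hz
    wavelet: str = "db4"
    dwt_level: int = 4

    @property
    def eeg_width_per_channel(self) -> int:
        return 4 + len(BAND_EDGES) + 2 * (self.dwt_level + 1)


def stat_features(x: np.ndarray):
    """(mean, population variance, skewness G1, excess kurtosis G2).

    A constant signal has undefined skew/kurtosis; both are reported as 0 and
    the degeneracy is signalled via the returned flag.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    mu = x.mean()
    var_pop = ((x - mu) ** 2).mean()
    s = np.sqrt(((x - mu) ** 2).sum() / (n - 1))  # sample SD
    if s == 0:
        return mu, var_pop, 0.0, 0.0, True
    z = (x - mu) / s
    g1 = n / ((n - 1) * (n - 2)) * (z ** 3).sum()
    g2 = (
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * (z ** 4).sum()
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )
    return mu, var_pop, g1, g2, False


def welch_band_powers(x: np.ndarray, cfg: HandFeatureConfig = HandFeatureConfig()):
    """Mean Welch PSD within each clinical band (Hann segments, 50 % overlap)."""
    x = np.asarray(x, dtype=float)
    if x.size < cfg.welch_nperseg:
        raise ValueError(
            f"window of {x.size} samples shorter than Welch segment "
            f"({cfg.welch_nperseg})"
        )
    if cfg.fs / 2 < max(hi for _, hi in BAND_EDGES.values()):
        raise ValueError("sampling rate too low for the configured band grid")
    f, pxx = signal.welch(x, fs=cfg.fs, window="hann",
                          nperseg=cfg.welch_nperseg,
                          noverlap=cfg.welch_nperseg // 2)
    out = np.empty(len(BAND_EDGES))
    top = max(hi for _, hi in BAND_EDGES.values())
    for i, (lo, hi) in enumerate(BAND_EDGES.values()):
        # half-open bins so boundary frequencies belong to one band only
        sel = (f >= lo) & ((f < hi) | (hi == top) & (f == hi))
        out[i] = pxx[sel].mean() if sel.any() else 0.0
    return out


def dwt_features(x: np.ndarray, cfg: HandFeatureConfig = HandFeatureConfig()):
    """Per-level (mean, SD) of the DWT coefficients.

    Ordering: final approximation first, then details from coarsest (level L)
    to finest (level 1) — the order `pywt.wavedec` returns.
    """
    x = np.asarray(x, dtype=float)
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(cfg.wavelet).dec_len)
    if cfg.dwt_level > max_level:
        raise ValueError(
            f"dwt_level={cfg.dwt_level} too deep for {x.size} samples "
            f"(max {max_level})"
        )
    coeffs = pywt.wavedec(x, cfg.wavelet, level=cfg.dwt_level)
    return np.array([(c.mean(), c.std()) for c in coeffs]).ravel()


def eeg_hand_vector(window: np.ndarray,
                    cfg: HandFeatureConfig = HandFeatureConfig()) -> np.ndarray:
    """Full handcrafted vector for one (n_channels × n_samples) EEG window."""
    window = np.asarray(window, dtype=float)
    parts = []
    for ch in window:
        mu, var, g1, g2, _ = stat_features(ch)
        parts.append([mu, var, g1, g2])
        parts.append(welch_band_powers(ch, cfg))
        parts.append(dwt_features(ch, cfg))
    return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])


def eeg_hand_matrix(windows, cfg: HandFeatureConfig = HandFeatureConfig()):
    return np.stack([eeg_hand_vector(w, cfg) for w in windows])


def eeg_hand_names(n_channels: int,
                   cfg: HandFeatureConfig = HandFeatureConfig()) -> list[str]:
    names = []
    levels = [f"a{cfg.dwt_level}"] + [f"d{l}" for l in
                                      range(cfg.dwt_level, 0, -1)]
    for ch in range(n_channels):
        names += [f"eeg{ch}_{s}" for s in ("mean", "var", "skew", "kurt")]
        names += [f"eeg{ch}_welch_{b}" for b in BAND_EDGES]
        for lv in levels:
            names += [f"eeg{ch}_dwt_{lv}_mean", f"eeg{ch}_dwt_{lv}_sd"]
    return names


def et_hand_features(fixations: list[Fixation]):
    """(mean fixation duration ms, fixation count, mean saccade amplitude px,
    saccade count, degenerate_flag).

    With no fixations everything is 0 and the flag is set; with one fixation
    the saccade amplitude is 0 with the flag set.
    """
    if not fixations:
        return np.zeros(4), True
    durs = np.array([f.duration_ms for f in fixations])
    cents = np.array([f.centroid for f in fixations])
    n_fix = len(fixations)
    if n_fix < 2:
        return np.array([durs.mean(), 1.0, 0.0, 0.0]), True
    hops = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    return np.array([durs.mean(), float(n_fix), hops.mean(),
                     float(len(hops))]), False


def et_hand_matrix(fixation_lists):
    return np.stack([et_hand_features(fx)[0] for fx in fixation_lists])


ET_HAND_NAMES = ["et_fix_duration_mean", "et_fix_count",
                 "et_saccade_amplitude_mean", "et_saccade_count"]
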
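"""Eye-tracking preprocessing: gap interpolation, windowing, gaze-plot
rasterization, and I-DT fixation detection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .dataio import ETRecording

__all__ = ["GazeConfig", "Fixation", "interpolate_gaps", "segment_et",
           "render_gaze_plot", "detect_fixations"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GazeConfig:
    window_s: float = 1.0
    overlap: float = 0.5
    canvas: tuple[int, int] = (64, 64)
    idt_dispersion: float = 50.0     # px, (max−min x) + (max−min y)
    idt_min_duration: float = 100.0  # ms
    max_gap_interp: float = 300.0    # ms; longer gaps stay invalid (None = no cap)
    accumulate: bool = False         # gaze plots: visit counts instead of binary

    def __post_init__(self):
        cw, ch = self.canvas
        if cw <= 0 or ch <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.idt_min_duration <= 0:
            raise ValueError("idt_min_duration must be positive")


@dataclass(frozen=True)
class Fixation:
    start_ms: float
    end_ms: float
    centroid: tuple[float, float]

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def _invalid_runs(valid: np.ndarray):
    """Yield (start, stop) index pairs of contiguous invalid runs."""
    idx = np.flatnonzero(~valid)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)


def interpolate_gaps(rec: ETRecording, cfg: GazeConfig = GazeConfig()) -> ETRecording:
    """Fill short invalid runs by the straight line between bracketing samples.

    Runs longer than ``max_gap_interp`` are left invalid; invalid runs touching
    the recording edge are filled by holding the nearest valid sample.
    """
    if rec.valid.sum() < 2:
        raise ValueError("need at least two valid samples to interpolate")
    x = rec.gaze_x.copy()
    y = rec.gaze_y.copy()
    valid = rec.valid.copy()
    n = rec.n_samples
    max_len = np.inf if cfg.max_gap_interp is None else \
        cfg.max_gap_interp / 1000.0 * rec.fs
    for a, b in _invalid_runs(rec.valid):
        if a == 0 or b == n:  # edge run: nearest-valid hold
            src = b if a == 0 else a - 1
            x[a:b] = x[src]
            y[a:b] = y[src]
            valid[a:b] = True
            continue
        if b - a > max_len:
            continue
        # straight line between the bracketing valid samples
        t = np.arange(a, b)
        for arr in (x, y):
            arr[a:b] = np.interp(t, [a - 1, b], [arr[a - 1], arr[b]])
        valid[a:b] = True
    w, h = rec.screen_size
    np.clip(x, 0, w - 1, out=x)
    np.clip(y, 0, h - 1, out=y)
    return replace(rec, gaze_x=x, gaze_y=y, valid=valid)


def segment_et(rec: ETRecording, cfg: GazeConfig = GazeConfig()):
    """1-s gaze windows with 50 % overlap, as (n_samples × 2) [x, y] arrays.

    Returns ``(windows, labels, subject_ids, trial_indices)``; a trial of L
    samples yields floor((L − win)/hop) + 1 windows.
    """
    win = int(round(cfg.window_s * rec.fs))
    hop = int(round(win * (1 - cfg.overlap)))
    windows, labels, subjects, trial_idx = [], [], [], []
    for ti, tr in enumerate(rec.trials):
        if tr.n_samples < win:
            log.warning("ET trial %d shorter than one window; skipped", ti)
            continue
        for s in range(tr.start_sample, tr.end_sample - win + 1, hop):
            windows.append(
                np.column_stack([rec.gaze_x[s:s + win], rec.gaze_y[s:s + win]])
            )
            labels.append(tr.label)
            subjects.append(rec.subject_id)
            trial_idx.append(ti)
    return windows, np.array(labels, dtype=int), subjects, trial_idx


def render_gaze_plot(window: np.ndarray, screen_size,
                     cfg: GazeConfig = GazeConfig()) -> np.ndarray:
    """Rasterize gaze samples onto a black canvas: visited pixels become white.

    Pixel (col, row) = (floor(x/W·cols), floor(y/H·rows)), clipped to the
    canvas; repeated visits are idempotent (binary mode, the default) or
    counted and min–max scaled to 0–255 (``cfg.accumulate``).
    """
    w, h = screen_size
    if w <= 0 or h <= 0:
        raise ValueError("screen size must be positive")
    cols, rows = cfg.canvas
    pts = np.asarray(window, dtype=float)
    cx = np.clip(np.floor(np.clip(pts[:, 0], 0, w - 1) / w * cols), 0, cols - 1)
    cy = np.clip(np.floor(np.clip(pts[:, 1], 0, h - 1) / h * rows), 0, rows - 1)
    img = np.zeros((rows, cols), dtype=np.uint8)
    if cfg.accumulate:
        counts = np.zeros((rows, cols), dtype=float)
        np.add.at(counts, (cy.astype(int), cx.astype(int)), 1.0)
        mx = counts.max()
        if mx > 0:
            img = np.round(counts / mx * 255).astype(np.uint8)
    else:
        img[cy.astype(int), cx.astype(int)] = 255
    return img


def detect_fixations(rec: ETRecording, cfg: GazeConfig = GazeConfig()):
    """Dispersion-based (I-DT) fixation detection on interpolated gaze.

    A window of samples grows while (max−min of x) + (max−min of y) stays
    within ``idt_dispersion``; when it can grow no further it is emitted as a
    fixation if it lasted at least ``idt_min_duration``. Fixations are
    non-overlapping and time-ordered.
    """
    x, y = rec.gaze_x, rec.gaze_y
    n = rec.n_samples
    min_len = max(int(np.ceil(cfg.idt_min_duration / 1000.0 * rec.fs)), 2)
    out = []
    i = 0
    while i + min_len <= n:
        j = i + min_len
        if _dispersion(x[i:j], y[i:j]) > cfg.idt_dispersion:
            i += 1
            continue
        while j < n and _dispersion(x[i:j + 1], y[i:j + 1]) <= cfg.idt_dispersion:
            j += 1
        out.append(
            Fixation(
                start_ms=i / rec.fs * 1000.0,
                end_ms=j / rec.fs * 1000.0,
                centroid=(float(x[i:j].mean()), float(y[i:j].mean())),
            )
        )
        i = j
    return out


def _dispersion(xs, ys):
    return (xs.max() - xs.min()) + (ys.max() - ys.min())
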
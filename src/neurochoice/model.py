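"""Top-level pipeline objects: build windows, extract features, classify.

`ConsumerChoicePipeline` is the model-like entry point: construct it from a
dataset directory or a synthetic-data config, call :meth:`crossvalidate` (or
:meth:`fit`), and get a :class:`PipelineResults` carrying per-fold metrics
and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import eeg_clean, feats_deep, feats_hand, fuse_classify, gaze_prep
from .dataio import WindowSet, read_recording
from .eeg_clean import CleanerConfig
from .eval_report import compute_metrics, report, summary_text
from .feats_deep import TrainingConfig
from .feats_hand import HandFeatureConfig
from .fuse_classify import SMOTEConfig, fuse, predict_stacking, smote_balance
from .gaze_prep import GazeConfig
from .synthgen import SynthConfig, generate_subject

__all__ = ["PipelineConfig", "ConsumerChoicePipeline", "PipelineResults",
           "build_windows"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with desk-scale defaults.

    ``mode`` selects the feature families (deep, handcrafted or both);
    ``modality`` restricts to one input stream. ``deep_layer="flatten"``
    gives the 14,016/2,704-dim deep vectors (16,720 fused); the default
    ``"last_dense"`` gives the compact 64/84-dim vectors, which keep repeated
    ensemble fits affordable. Extractor training is bounded by the epoch and
    subsample settings; raise them for a longer, closer-to-asymptotic fit.
    """

    mode: str = "full"             # full | deep_only | hand_only
    modality: str = "both"         # both | eeg | et
    deep_layer: str = "last_dense"  # last_dense | flatten
    folds: int = 10
    seed: int = 42
    smote: SMOTEConfig | None = field(default_factory=SMOTEConfig)
    smote_scope: str = "train_fold"
    stacking_folds: int = 5
    meta_input: str = "proba"
    #: fold    — retrain extractors inside every CV fold (leakage-safe, slow)
    #: holdout — train extractors once on a dedicated trial partition that is
    #:           then excluded from CV evaluation (leakage-safe, one training)
    #: global  — train once on everything (fast; extractor sees evaluated
    #:           labels, so supervised deep features can leak)
    extractor_scope: str = "fold"
    extractor_holdout_fraction: float = 0.25
    #: None = window-level CV; "trial" keeps all windows of a trial in one
    #: fold (overlapping windows share half their samples, so ungrouped CV
    #: leaks trial fingerprints); "subject" additionally groups by subject.
    group_by: str | None = None
    cleaner: CleanerConfig = field(default_factory=CleanerConfig)
    gaze: GazeConfig = field(default_factory=GazeConfig)
    hand: HandFeatureConfig = field(default_factory=HandFeatureConfig)
    eeg_train: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(loss="mse", epochs=1))
    et_train: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(loss="bce", epochs=10))
    eeg_max_train: int | None = 96
    et_max_train: int | None = 192
    skip_asr: bool = False
    skip_force: bool = False

    def __post_init__(self):
        if self.mode not in ("full", "deep_only", "hand_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.modality not in ("both", "eeg", "et"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.extractor_scope not in ("fold", "holdout", "global"):
            raise ValueError(
                "extractor_scope must be 'fold', 'holdout' or 'global'")
        if not 0 < self.extractor_holdout_fraction < 1:
            raise ValueError("extractor_holdout_fraction must lie in (0, 1)")
        if self.group_by not in (None, "trial", "subject"):
            raise ValueError("group_by must be None, 'trial' or 'subject'")


def build_windows(eeg_rec, et_rec, config: PipelineConfig = PipelineConfig()
                  ) -> WindowSet:
    """Clean, segment and align one subject's recordings into a WindowSet."""
    ew, el, es, e_trial = eeg_clean.clean_recording(
        eeg_rec, config.cleaner, skip_asr=config.skip_asr,
        skip_force=config.skip_force)
    et_interp = gaze_prep.interpolate_gaps(et_rec, config.gaze)
    gw, gl, gs, gt_idx = gaze_prep.segment_et(et_interp, config.gaze)
    eeg_keys = [(eeg_rec.subject_id, t) for t in e_trial]
    et_keys = [(et_rec.subject_id, t) for t in gt_idx]
    pairs = fuse_classify.align_windows(eeg_keys, et_keys)
    ws = WindowSet()
    for i, j in pairs:
        ws.eeg_windows.append(ew[i])
        ws.et_windows.append(gw[j])
        ws.gaze_plots.append(
            gaze_prep.render_gaze_plot(gw[j], et_rec.screen_size, config.gaze))
        ws.labels.append(int(el[i]))
        ws.subject_ids.append(es[i])
        ws.alignment.append((i, j))
        ws.trial_keys.append(eeg_keys[i])
    ws.validate()
    return ws


def _merge(sets: list[WindowSet]) -> WindowSet:
    out = WindowSet()
    for ws in sets:
        out.eeg_windows += ws.eeg_windows
        out.et_windows += ws.et_windows
        out.gaze_plots += ws.gaze_plots
        out.labels += ws.labels
        out.subject_ids += ws.subject_ids
        out.alignment += ws.alignment
        out.trial_keys += ws.trial_keys
    out.validate()
    return out


class ConsumerChoicePipeline:
    """End-to-end buy/no-buy prediction from multimodal windows."""

    def __init__(self, windows: WindowSet, config: PipelineConfig = PipelineConfig()):
        if len(windows) == 0:
            raise ValueError("empty window set")
        self.windows = windows
        self.config = config
        self.labels = np.asarray(windows.labels, dtype=int)
        self._hand_cache = None
        self._deep_cache = {}
        self._eeg_input = None
        self._gaze_input = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_synthetic(cls, synth_cfg: SynthConfig,
                       config: PipelineConfig = PipelineConfig()):
        sets = []
        for s in range(synth_cfg.n_subjects):
            eeg, et = generate_subject(synth_cfg, s)
            sets.append(build_windows(eeg, et, config))
        return cls(_merge(sets), config)

    def with_config(self, config: PipelineConfig) -> "ConsumerChoicePipeline":
        """Same windows under a different configuration, sharing extracted
        feature caches (valid because hand features are config-independent
        given the same hand config, and deep caches are keyed by training
        scope)."""
        other = ConsumerChoicePipeline(self.windows, config)
        if config.hand == self.config.hand and config.gaze == self.config.gaze:
            other._hand_cache = self._hand_cache
        same_deep = (config.deep_layer == self.config.deep_layer
                     and config.eeg_train == self.config.eeg_train
                     and config.et_train == self.config.et_train
                     and config.seed == self.config.seed)
        if same_deep:
            other._deep_cache = self._deep_cache
        other._eeg_input = self._eeg_input
        other._gaze_input = self._gaze_input
        return other

    @classmethod
    def from_dataset(cls, path, config: PipelineConfig = PipelineConfig()):
        root = Path(path)
        sets = []
        for d in sorted(p for p in root.iterdir() if p.is_dir()):
            eeg = read_recording(d, "eeg")
            et = read_recording(d, "et")
            sets.append(build_windows(eeg, et, config))
        if not sets:
            raise ValueError(f"no subject directories under {root}")
        return cls(_merge(sets), config)

    # -- feature extraction ------------------------------------------------
    def _prepared_inputs(self):
        if self._eeg_input is None:
            self._eeg_input = feats_deep.prepare_eeg_input(self.windows.eeg_windows)
            self._gaze_input = feats_deep.prepare_gaze_input(self.windows.gaze_plots)
        return self._eeg_input, self._gaze_input

    def hand_blocks(self) -> dict:
        if self._hand_cache is None:
            self._hand_cache = {
                "eeg_hand": feats_hand.eeg_hand_matrix(
                    self.windows.eeg_windows, self.config.hand),
                "et_hand": self._et_hand(),
            }
        return dict(self._hand_cache)

    def _et_hand(self):
        cfg = self.config
        fs = 120.0  # ET windows are resampled views at the acquisition rate
        fix_lists = []
        for w in self.windows.et_windows:
            from .dataio import ETRecording
            rec = ETRecording(gaze_x=w[:, 0], gaze_y=w[:, 1],
                              valid=np.ones(len(w), bool), fs=fs,
                              screen_size=(10 ** 9, 10 ** 9))
            fix_lists.append(gaze_prep.detect_fixations(rec, cfg.gaze))
        return feats_hand.et_hand_matrix(fix_lists)

    def deep_blocks(self, train_idx=None) -> dict:
        """Train the two extractors (on ``train_idx`` windows, or all) and
        extract deep features for every window."""
        key = "all" if train_idx is None else tuple(np.sort(train_idx))
        if key in self._deep_cache:
            return dict(self._deep_cache[key])
        cfg = self.config
        Xe, Xg = self._prepared_inputs()
        idx = np.arange(len(self.labels)) if train_idx is None \
            else np.asarray(train_idx)
        cnn = feats_deep.build_cnn_lstm(seed=cfg.seed)
        feats_deep.train_extractor(cnn, Xe[idx], self.labels[idx],
                                   cfg.eeg_train, max_samples=cfg.eeg_max_train)
        lenet = feats_deep.build_lenet5(seed=cfg.seed)
        feats_deep.train_extractor(lenet, Xg[idx], self.labels[idx],
                                   cfg.et_train, max_samples=cfg.et_max_train)
        blocks = {
            "eeg_deep": feats_deep.extract_features(cnn, Xe, cfg.deep_layer),
            "et_deep": feats_deep.extract_features(lenet, Xg, cfg.deep_layer),
        }
        self._deep_cache[key] = blocks
        return dict(blocks)

    def feature_blocks(self, train_idx=None) -> dict:
        cfg = self.config
        blocks = {}
        if cfg.mode in ("full", "hand_only"):
            blocks.update(self.hand_blocks())
        if cfg.mode in ("full", "deep_only"):
            blocks.update(self.deep_blocks(train_idx))
        if cfg.modality == "eeg":
            blocks = {k: v for k, v in blocks.items() if k.startswith("eeg")}
        elif cfg.modality == "et":
            blocks = {k: v for k, v in blocks.items() if k.startswith("et")}
        return blocks

    def fused(self, train_idx=None):
        return fuse(self.feature_blocks(train_idx), self.labels,
                    self.windows.subject_ids, self.config.mode)

    # -- fitting / evaluation ---------------------------------------------
    def fit(self) -> "PipelineResults":
        """Fit the stacking ensemble on all windows (extractors trained
        globally); in-sample evaluation only — prefer crossvalidate()."""
        cfg = self.config
        fm = self.fused()
        X, y = fm.X, fm.labels
        if cfg.smote is not None:
            X, y = smote_balance(X, y, cfg.smote)
        model = fuse_classify.fit_stacking(
            X, y, folds=cfg.stacking_folds, seed=cfg.seed,
            meta_input=cfg.meta_input)
        pred, score = predict_stacking(model, fm.X)
        res = {
            "fold_assignments": np.zeros(len(fm.labels), dtype=int),
            "fold_metrics": [compute_metrics(fm.labels, pred, score)],
            "overall": compute_metrics(fm.labels, pred, score),
            "oof_predictions": pred,
            "oof_scores": score,
        }
        return PipelineResults(self, res, fm.width, model=model)

    def crossvalidate(self) -> "PipelineResults":
        cfg = self.config
        groups = self._groups()
        if cfg.extractor_scope == "holdout" and cfg.mode != "hand_only":
            hold_idx, eval_idx = self.extractor_holdout_split()
            fm = self.fused(train_idx=hold_idx)
            res = fuse_classify.crossvalidate(
                fm.X[eval_idx], fm.labels[eval_idx], folds=cfg.folds,
                seed=cfg.seed, smote=cfg.smote, smote_scope=cfg.smote_scope,
                stacking_folds=cfg.stacking_folds, meta_input=cfg.meta_input,
                groups=None if groups is None
                else [groups[i] for i in eval_idx])
            return PipelineResults(self, res, fm.width, eval_index=eval_idx)
        if cfg.extractor_scope in ("global", "holdout") \
                or cfg.mode == "hand_only":
            fm = self.fused()
            res = fuse_classify.crossvalidate(
                fm.X, fm.labels, folds=cfg.folds, seed=cfg.seed,
                smote=cfg.smote, smote_scope=cfg.smote_scope,
                stacking_folds=cfg.stacking_folds, meta_input=cfg.meta_input,
                groups=groups)
            return PipelineResults(self, res, fm.width)
        return self._crossvalidate_fold_scope(groups)

    def extractor_holdout_split(self):
        """Partition trials into an extractor-training set and an evaluation
        set (per subject, proportional per class, seeded). Returns
        (holdout window indices, evaluation window indices)."""
        frac = self.config.extractor_holdout_fraction
        rng = np.random.default_rng(self.config.seed)
        keys = self.windows.trial_keys
        y = self.labels
        # unique trials per subject with their label, in first-seen order
        trial_label = {}
        for k, lab in zip(keys, y):
            trial_label.setdefault(k, int(lab))
        by_subject = {}
        for k in trial_label:
            by_subject.setdefault(k[0], []).append(k)
        holdout = set()
        for subj in sorted(by_subject):
            for lab in (0, 1):
                ks = [k for k in by_subject[subj] if trial_label[k] == lab]
                n_h = int(round(frac * len(ks)))
                if ks and n_h > 0:
                    pick = rng.choice(len(ks), size=min(n_h, len(ks)),
                                      replace=False)
                    holdout.update(ks[i] for i in pick)
        # extractor training needs both classes
        held_labels = {trial_label[k] for k in holdout}
        for lab in (0, 1):
            if lab not in held_labels:
                k = next(k for k in trial_label if trial_label[k] == lab)
                holdout.add(k)
        hold_idx = np.array([i for i, k in enumerate(keys) if k in holdout])
        eval_idx = np.array([i for i, k in enumerate(keys) if k not in holdout])
        return hold_idx, eval_idx

    def _groups(self):
        if self.config.group_by == "trial":
            return ["/".join(map(str, k)) for k in self.windows.trial_keys]
        if self.config.group_by == "subject":
            return list(self.windows.subject_ids)
        return None

    def _crossvalidate_fold_scope(self, groups):
        """Leakage-safe CV: extractors are retrained inside every fold on the
        training windows only."""
        cfg = self.config
        y = self.labels
        if groups is not None:
            skf = StratifiedGroupKFold(n_splits=cfg.folds, shuffle=True,
                                       random_state=cfg.seed)
        else:
            skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                                  random_state=cfg.seed)
        assignments = np.full(len(y), -1, dtype=int)
        oof_pred = np.full(len(y), -1, dtype=int)
        oof_score = np.full(len(y), np.nan)
        fold_metrics = []
        width = None
        split = skf.split(np.zeros(len(y)), y, groups) if groups is not None \
            else skf.split(np.zeros(len(y)), y)
        for fold, (tr, va) in enumerate(split):
            assignments[va] = fold
            fm = self.fused(train_idx=tr)
            width = fm.width
            Xtr, ytr = fm.X[tr], y[tr]
            if cfg.smote is not None:
                Xtr, ytr = smote_balance(Xtr, ytr, cfg.smote)
            model = fuse_classify.fit_stacking(
                Xtr, ytr, folds=cfg.stacking_folds, seed=cfg.seed,
                meta_input=cfg.meta_input)
            pred, score = predict_stacking(model, fm.X[va])
            oof_pred[va] = pred
            oof_score[va] = score
            fold_metrics.append(compute_metrics(y[va], pred, score))
        res = {
            "fold_assignments": assignments,
            "fold_metrics": fold_metrics,
            "overall": compute_metrics(y, oof_pred, oof_score),
            "oof_predictions": oof_pred,
            "oof_scores": oof_score,
        }
        return PipelineResults(self, res, width)


@dataclass
class PipelineResults:
    """Cross-validation (or fit) results plus provenance."""

    pipeline: ConsumerChoicePipeline
    cv: dict
    fused_width: int
    model: object = None
    eval_index: np.ndarray = None  # rows evaluated (holdout scope)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.cv["fold_metrics"]]))

    @property
    def overall(self):
        return self.cv["overall"]

    def to_report(self, name: str = "run") -> dict:
        cfg = asdict(self.pipeline.config)
        cfg["fused_width"] = self.fused_width
        return report([(name, self.cv)], cfg)

    def summary(self) -> str:
        rep = self.to_report()
        o = rep["runs"][0]
        lines = [
            "Consumer-choice pipeline results",
            f"  windows: {len(self.pipeline.labels)}   "
            f"fused width: {self.fused_width}   "
            f"mode: {self.pipeline.config.mode}/{self.pipeline.config.modality}",
            f"  CV accuracy: {o['mean_accuracy']:.4f} ± {o['sd_accuracy']:.4f} "
            f"({len(self.cv['fold_metrics'])} folds)",
            "",
            summary_text(rep),
        ]
        return "\n".join(lines)

    def save(self, path):
        Path(path).write_text(
            json.dumps(self.to_report(), indent=1, sort_keys=True))
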
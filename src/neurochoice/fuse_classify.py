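"""Feature-level fusion, SMOTE balancing, and the stacking ensemble.

The classifier is a two-level stack: Random Forest (265 trees), Gradient
Boosting (89 stages) and XGBoost (300 rounds) as base learners, whose
out-of-fold predictions form a 3-column meta-feature matrix Z on which a
100-tree Random Forest meta-learner is trained. Meta features default to
positive-class probabilities; ``meta_input="label"`` uses hard labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

from .eval_report import compute_metrics

__all__ = ["SMOTEConfig", "FusedFeatureMatrix", "StackingModel",
           "align_windows", "fuse", "smote_balance", "default_base_learners",
           "fit_stacking", "predict_stacking", "crossvalidate"]

log = logging.getLogger(__name__)

#: fusion block order
BLOCK_ORDER = ("eeg_deep", "et_deep", "eeg_hand", "et_hand")
MODES = {
    "deep_only": ("eeg_deep", "et_deep"),
    "hand_only": ("eeg_hand", "et_hand"),
    "full": BLOCK_ORDER,
}


@dataclass(frozen=True)
class SMOTEConfig:
    k_neighbors: int = 3
    random_state: int = 42
    target_ratio: float = 1.0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must lie in (0, 1]")


@dataclass
class FusedFeatureMatrix:
    X: np.ndarray
    labels: np.ndarray
    subject_ids: list
    provenance: list  # [(block name, width)] covering all columns in order

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.labels):
            raise ValueError("feature matrix and labels are inconsistent")
        if not np.isfinite(self.X).all():
            raise ValueError("fused features contain NaN or Inf")
        if sum(w for _, w in self.provenance) != self.X.shape[1]:
            raise ValueError("column provenance does not cover all columns")

    @property
    def width(self) -> int:
        return self.X.shape[1]


def align_windows(eeg_trial_keys, et_trial_keys):
    """Pair EEG and ET windows by (trial, window ordinal).

    Arguments are per-window hashable trial keys (e.g. ``(subject, trial)``)
    in segmentation order. Within each trial, pairs are truncated to the
    shorter modality's window count; trials present in only one modality are
    dropped with a warning. Returns a list of (eeg index, et index) pairs.
    """
    def group(keys):
        d = {}
        for i, k in enumerate(keys):
            d.setdefault(k, []).append(i)
        return d

    eeg_g, et_g = group(eeg_trial_keys), group(et_trial_keys)
    pairs = []
    for k in eeg_g:
        if k not in et_g:
            log.warning("trial %r has EEG windows but no ET windows; dropped", k)
            continue
        a, b = eeg_g[k], et_g[k]
        if len(a) != len(b):
            log.warning("trial %r: %d EEG vs %d ET windows; truncating",
                        k, len(a), len(b))
        pairs.extend(zip(a, b))
    for k in et_g:
        if k not in eeg_g:
            log.warning("trial %r has ET windows but no EEG windows; dropped", k)
    return pairs


def fuse(blocks: dict, labels, subject_ids, mode: str = "full") -> FusedFeatureMatrix:
    """Column-wise concatenation of feature blocks in the documented order
    (EEG-deep, ET-deep, EEG-hand, ET-hand), restricted by ``mode``."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {sorted(MODES)}, got {mode!r}")
    use = [b for b in MODES[mode] if b in blocks]
    if not use:
        raise ValueError(f"no feature blocks available for mode {mode!r}")
    mats = []
    prov = []
    n = None
    for name in use:
        m = np.asarray(blocks[name], dtype=float)
        if n is None:
            n = len(m)
        elif len(m) != n:
            raise ValueError(
                f"block {name!r} has {len(m)} rows, expected {n} (misaligned)"
            )
        mats.append(m)
        prov.append((name, m.shape[1]))
    return FusedFeatureMatrix(
        X=np.concatenate(mats, axis=1),
        labels=labels, subject_ids=list(subject_ids), provenance=prov,
    )


def smote_balance(X, y, cfg: SMOTEConfig = SMOTEConfig()):
    """Oversample the minority class by interpolating between k-NN pairs.

    Each synthetic point is x + u·(neighbor − x) for a random minority sample
    x, one of its ``k_neighbors`` nearest minority neighbours (Euclidean) and
    u ~ U[0, 1]; generation continues until the class ratio reaches
    ``target_ratio``. Deterministic given ``random_state``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_balance expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= cfg.k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples, need more than "
            f"k={cfg.k_neighbors}; use a smaller k"
        )
    n_new = int(round(cfg.target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(cfg.random_state)
    base = rng.integers(0, len(Xm), size=n_new)
    pick = rng.integers(0, cfg.k_neighbors, size=n_new)
    u = rng.random(size=(n_new, 1))
    nb = Xm[neigh[base, pick]]
    synth = Xm[base] + u * (nb - Xm[base])
    return (np.vstack([X, synth]),
            np.concatenate([y, np.full(n_new, minority, dtype=int)]))


def default_base_learners(seed: int = 42):
    """The three base learners with the prescribed ensemble sizes."""
    return [
        ("rf", RandomForestClassifier(n_estimators=265, random_state=seed,
                                      n_jobs=1)),
        ("gb", GradientBoostingClassifier(n_estimators=89, random_state=seed)),
        ("xgb", XGBClassifier(n_estimators=300, random_state=seed, n_jobs=1,
                              tree_method="hist", eval_metric="logloss",
                              verbosity=0)),
    ]


@dataclass
class StackingModel:
    bases: list                 # [(name, fitted estimator)]
    meta: object                # fitted meta learner, or "identity"
    meta_input: str             # "proba" | "label"
    n_features: int
    oof_Z: np.ndarray = field(repr=False, default=None)


def _base_column(est, X, meta_input):
    if meta_input == "proba":
        return est.predict_proba(X)[:, 1]
    return est.predict(X).astype(float)


def fit_stacking(X, y, folds: int = 5, seed: int = 42,
                 meta_input: str = "proba", base_learners=None,
                 meta_learner=None) -> StackingModel:
    """Fit the stack: out-of-fold base predictions build Z, the bases are
    refitted on all data, and the meta Random Forest is fitted on Z.

    The internal split is stratified, shuffled and seeded, so base and meta
    learners never see predictions on data a base was trained on.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(y) < folds:
        raise ValueError(f"need at least {folds} samples for {folds} folds")
    if meta_input not in ("proba", "label"):
        raise ValueError("meta_input must be 'proba' or 'label'")
    templates = base_learners if base_learners is not None \
        else default_base_learners(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Z = np.zeros((len(y), len(templates)))
    for tr, va in skf.split(X, y):
        for j, (_, tmpl) in enumerate(templates):
            est = clone(tmpl)
            est.fit(X[tr], y[tr])
            Z[va, j] = _base_column(est, X[va], meta_input)
    bases = []
    for name, tmpl in templates:
        est = clone(tmpl)
        est.fit(X, y)
        bases.append((name, est))
    if meta_learner == "identity":
        if len(templates) != 1:
            raise ValueError("identity meta requires exactly one base learner")
        meta = "identity"
    else:
        meta = meta_learner if meta_learner is not None else \
            RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        meta.fit(Z, y)
    return StackingModel(bases=bases, meta=meta, meta_input=meta_input,
                         n_features=X.shape[1], oof_Z=Z)


def predict_stacking(model: StackingModel, X):
    """Labels and positive-class scores for new rows.

    Per row: base predictions → meta-feature vector Z_x → meta prediction.
    The score is the meta forest's positive-class vote fraction.
    """
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        return np.array([], dtype=int), np.array([])
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model was trained on "
            f"{model.n_features}"
        )
    Zx = np.column_stack(
        [_base_column(est, X, model.meta_input) for _, est in model.bases]
    )
    if model.meta == "identity":
        scores = Zx[:, 0]
        return (scores >= 0.5).astype(int), scores
    labels = model.meta.predict(Zx)
    scores = model.meta.predict_proba(Zx)[:, 1]
    return labels.astype(int), scores


def crossvalidate(X, y, folds: int = 10, seed: int = 42,
                  smote: SMOTEConfig | None = SMOTEConfig(),
                  smote_scope: str = "train_fold",
                  stacking_folds: int = 5, meta_input: str = "proba",
                  groups=None, base_learners=None):
    """Outer stratified k-fold evaluation of the stacking pipeline.

    SMOTE runs on the training portion of each fold by default
    (``smote_scope="train_fold"``); ``"global"`` applies it once to the whole
    matrix before splitting, reproducing the leakage-prone variant some
    pipelines use. With ``groups`` (e.g. subject ids) a stratified *grouped*
    split keeps each group in a single fold.

    Returns a dict with fold assignments, per-fold metric bundles and the
    pooled out-of-fold predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if smote_scope not in ("train_fold", "global"):
        raise ValueError("smote_scope must be 'train_fold' or 'global'")
    if smote is not None and smote_scope == "global":
        X, y = smote_balance(X, y, smote)
        groups = None  # synthetic rows belong to no group
    if groups is not None:
        skf = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                   random_state=seed)
        split = skf.split(X, y, groups)
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = skf.split(X, y)
    fold_metrics = []
    assignments = np.full(len(y), -1, dtype=int)
    oof_pred = np.full(len(y), -1, dtype=int)
    oof_score = np.full(len(y), np.nan)
    for fold, (tr, va) in enumerate(split):
        assignments[va] = fold
        Xtr, ytr = X[tr], y[tr]
        if smote is not None and smote_scope == "train_fold":
            Xtr, ytr = smote_balance(Xtr, ytr, smote)
        model = fit_stacking(Xtr, ytr, folds=stacking_folds, seed=seed,
                             meta_input=meta_input, base_learners=base_learners)
        pred, score = predict_stacking(model, X[va])
        oof_pred[va] = pred
        oof_score[va] = score
        fold_metrics.append(compute_metrics(y[va], pred, score))
    overall = compute_metrics(y[assignments >= 0], oof_pred[assignments >= 0],
                              oof_score[assignments >= 0])
    return {
        "fold_assignments": assignments,
        "fold_metrics": fold_metrics,
        "overall": overall,
        "oof_predictions": oof_pred,
        "oof_scores": oof_score,
    }
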
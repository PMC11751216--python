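"""Classification metrics and run reports.

Positive class is buy (label 1) throughout; precision/recall/F1 follow the
binary convention on that class. The ROC curve sweeps every unique score
threshold and the AUC is its trapezoidal integral.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["MetricsBundle", "compute_metrics", "report", "metrics_to_dict"]


@dataclass
class MetricsBundle:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    roc_points: list = field(default_factory=list)  # [(FPR, TPR)]
    auc: float | None = None
    auc_defined: bool = True

    @property
    def confusion(self):
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def _safe_div(a, b):
    return a / b if b else 0.0


def compute_metrics(y_true, y_pred, scores=None) -> MetricsBundle:
    """Confusion counts, derived rates, and (given scores) the empirical ROC.

    With a single-class ``y_true`` the ROC/AUC are undefined: ``auc`` is None
    and ``auc_defined`` is False.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not np.isin(y_true, (0, 1)).all() or not np.isin(y_pred, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    bundle = MetricsBundle(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_safe_div(tp + tn, tp + tn + fp + fn),
        precision=precision,
        recall=recall,
        specificity=_safe_div(tn, tn + fp),
        f1=_safe_div(2 * precision * recall, precision + recall),
    )
    if scores is not None:
        scores = np.asarray(scores, dtype=float).ravel()
        if len(np.unique(y_true)) < 2:
            bundle.auc = None
            bundle.auc_defined = False
        else:
            fpr, tpr, _ = roc_curve(y_true, scores)
            bundle.roc_points = list(zip(fpr.tolist(), tpr.tolist()))
            bundle.auc = float(np.trapezoid(tpr, fpr))
    return bundle


def metrics_to_dict(m: MetricsBundle) -> dict:
    return {
        "confusion": {"tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn},
        "accuracy": round(m.accuracy, 4),
        "precision": round(m.precision, 4),
        "recall": round(m.recall, 4),
        "specificity": round(m.specificity, 4),
        "f1": round(m.f1, 4),
        "auc": None if m.auc is None else round(m.auc, 4),
    }


def report(cv_results, config: dict, out_path=None) -> dict:
    """Assemble a JSON-serialisable run report with full provenance.

    ``cv_results`` is the dict from :func:`neurochoice.fuse_classify.crossvalidate`
    (or a list of (name, results) pairs for an ablation grid). Identical
    configs and seeds produce byte-identical metric blocks.
    """
    if isinstance(cv_results, dict):
        cv_results = [("run", cv_results)]
    rows = []
    for name, res in cv_results:
        folds = res.get("fold_metrics")
        if folds is None or any(f is None for f in folds):
            missing = [i for i, f in enumerate(folds or []) if f is None]
            raise ValueError(f"run {name!r}: missing fold result(s) {missing}")
        per_fold = [metrics_to_dict(f) for f in folds]
        acc = np.array([f.accuracy for f in folds])
        rows.append({
            "name": name,
            "per_fold": per_fold,
            "mean_accuracy": round(float(acc.mean()), 4),
            "sd_accuracy": round(float(acc.std(ddof=1)) if len(acc) > 1 else 0.0, 4),
            "overall": metrics_to_dict(res["overall"]),
        })
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    out = {
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "runs": rows,
    }
    if out_path is not None:
        from pathlib import Path
        Path(out_path).write_text(json.dumps(out, indent=1, sort_keys=True))
    return out


def summary_text(rep: dict) -> str:
    lines = [f"{'run':<24}{'acc':>8}{'prec':>8}{'rec':>8}{'f1':>8}{'auc':>8}"]
    for r in rep["runs"]:
        o = r["overall"]
        auc = "--" if o["auc"] is None else f"{o['auc']:.3f}"
        lines.append(
            f"{r['name']:<24}{o['accuracy']:>8.3f}{o['precision']:>8.3f}"
            f"{o['recall']:>8.3f}{o['f1']:>8.3f}{auc:>8}"
        )
    return "\n".join(lines)
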
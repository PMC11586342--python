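"""Multi-category agreement metrics and the leave-one-feature-out probe.

All scalar metrics are computed from the K-by-K confusion matrix
(rows = true, columns = predicted): micro precision pools TP/FP over
categories (equal to accuracy, and identically equal to micro F1, for
single-label prediction), macro precision averages per-category
precision unweighted, and Cohen's kappa chance-corrects the observed
agreement, kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginals.
One-vs-rest ROC curves / AUC come from the predicted probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .data import FeatureTable, LabelVector


@dataclass
class ConfusionMatrix:
    """K-by-K count matrix; rows are true categories, columns predicted."""

    counts: np.ndarray
    category_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.category_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K with K = len(category_names)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts).astype(float)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1).astype(float) - self.tp()

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.counts, index=self.category_names, columns=self.category_names).to_csv(
            path
        )


def confusion(y_true: LabelVector, y_pred: LabelVector | np.ndarray) -> ConfusionMatrix:
    """Tally counts[i][j] = #(true category i, predicted category j)."""
    pred = y_pred.codes if isinstance(y_pred, LabelVector) else np.asarray(y_pred, dtype=int)
    if pred.shape != y_true.codes.shape:
        raise ValueError(
            f"length mismatch: {y_true.codes.size} true vs {pred.size} predicted"
        )
    k = y_true.n_categories
    if pred.size and (pred.min() < 0 or pred.max() >= k):
        raise ValueError("predicted codes outside the true category space")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_true.codes, pred), 1)
    return ConfusionMatrix(counts=counts, category_names=list(y_true.category_names))


def micro_metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """(micro precision, micro F1): TP/FP/FN pooled over categories."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn = cm.tp().sum(), cm.fp().sum(), cm.fn().sum()
    micro_p = tp / (tp + fp)
    micro_f1 = 2 * tp / (2 * tp + fp + fn)
    return float(micro_p), float(micro_f1)


def macro_precision(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-category precision TP_i / (TP_i + FP_i).

    A category the predictor never emits has undefined precision; it
    contributes 0 with a warning so the average stays defined.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp = cm.tp(), cm.fp()
    denom = tp + fp
    never = denom == 0
    if never.any():
        names = [cm.category_names[i] for i in np.flatnonzero(never)]
        warnings.warn(
            f"category(ies) never predicted: {names}; precision counted as 0",
            UserWarning,
            stacklevel=2,
        )
    per = np.where(never, 0.0, tp / np.where(never, 1.0, denom))
    return float(per.mean())


def per_category_precision(cm: ConfusionMatrix) -> np.ndarray:
    tp, fp = cm.tp(), cm.fp()
    denom = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, 0.0, tp / np.where(denom == 0, 1.0, denom))
    return out


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = cm.tp().sum() / n
    pe = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / n**2
    if pe == 1.0:
        if po == 1.0:
            return 1.0
        raise ValueError("chance agreement p_e = 1 with imperfect observed agreement")
    return float((po - pe) / (1.0 - pe))


def roc_ovr(
    y_true: LabelVector, probs: np.ndarray
) -> dict[str, dict[str, np.ndarray | float]]:
    """One-vs-rest ROC sweep per category plus a micro-average curve.

    ``probs`` is (n, K) with rows summing to 1.  Categories absent from
    ``y_true`` are omitted with a warning.  Returns, per category name,
    ``{"fpr", "tpr", "thresholds", "auc"}``.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != len(y_true):
        raise ValueError("probs must be (n_subjects, K)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    k = y_true.n_categories
    out: dict[str, dict] = {}
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(y_true)), y_true.codes] = 1.0
    for i in range(k):
        name = y_true.category_names[i]
        pos = y_true.codes == i
        if pos.sum() == 0 or pos.sum() == len(y_true):
            warnings.warn(
                f"category {name!r} absent (or exhaustive) in y_true; ROC omitted",
                UserWarning,
                stacklevel=2,
            )
            continue
        fpr, tpr, thr = _roc_curve(pos.astype(int), probs[:, i])
        out[name] = {"fpr": fpr, "tpr": tpr, "thresholds": thr,
                     "auc": float(_trapezoid_auc(fpr, tpr))}
    fpr, tpr, thr = _roc_curve(onehot.ravel(), probs.ravel())
    out["micro"] = {"fpr": fpr, "tpr": tpr, "thresholds": thr,
                    "auc": float(_trapezoid_auc(fpr, tpr))}
    return out


@dataclass
class EvalReport:
    """All headline metrics for one prediction run."""

    confusion_matrix: ConfusionMatrix
    micro_precision: float
    micro_f1: float
    macro_precision: float
    kappa: float
    per_category_precision: np.ndarray
    roc: dict[str, dict] = field(default_factory=dict)

    @property
    def auc(self) -> dict[str, float]:
        return {name: curve["auc"] for name, curve in self.roc.items()}

    def to_dict(self) -> dict:
        return {
            "micro_precision": self.micro_precision,
            "micro_f1": self.micro_f1,
            "macro_precision": self.macro_precision,
            "kappa": self.kappa,
            "per_category_precision": self.per_category_precision.tolist(),
            "auc": self.auc,
            "confusion_matrix": self.confusion_matrix.counts.tolist(),
            "category_names": self.confusion_matrix.category_names,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        lines = [
            "Evaluation report",
            "=" * 40,
            f"{'micro precision':20s} {self.micro_precision:.4f}",
            f"{'micro F1':20s} {self.micro_f1:.4f}",
            f"{'macro precision':20s} {self.macro_precision:.4f}",
            f"{'Cohen kappa':20s} {self.kappa:.4f}",
        ]
        for name, a in self.auc.items():
            lines.append(f"{'AUC ' + name:20s} {a:.4f}")
        lines.append("=" * 40)
        return "\n".join(lines)


def evaluate_predictions(
    y_true: LabelVector,
    probs: np.ndarray,
    category_names: Sequence[str] | None = None,
) -> EvalReport:
    """Build the full report from true labels and predicted probabilities."""
    pred = np.asarray(probs).argmax(axis=1)
    cm = confusion(y_true, pred)
    micro_p, micro_f1 = micro_metrics(cm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        macro_p = macro_precision(cm)
        roc = roc_ovr(y_true, probs)
    return EvalReport(
        confusion_matrix=cm,
        micro_precision=micro_p,
        micro_f1=micro_f1,
        macro_precision=macro_p,
        kappa=cohens_kappa(cm),
        per_category_precision=per_category_precision(cm),
        roc=roc,
    )


def ablate_features(
    table: FeatureTable,
    labels: LabelVector,
    config,
    base_features: Sequence[str],
    seed: int = 0,
) -> list[dict]:
    """Leave-one-feature-out importance probe.

    Retrains the fusion classifier with each feature removed in turn and
    reports the four held-out metrics per removal, ranked by micro-F1
    drop relative to the all-features baseline (largest drop first).
    """
    from dataclasses import asdict

    from .fusion import FusionClassifier, FusionConfig

    base_features = list(base_features)
    missing = [f for f in base_features if f not in table.feature_names]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    if len(base_features) < 2:
        raise ValueError("removal would leave zero features")

    def run(features: Sequence[str], run_seed: int) -> EvalReport:
        cfg = FusionConfig(**{**asdict(config), "seed": run_seed})
        res = FusionClassifier(table.select(features), labels, cfg).fit()
        return res.evaluate()

    baseline = run(base_features, seed)
    rows = []
    for feat in base_features:
        rest = [f for f in base_features if f != feat]
        rep = run(rest, seed)
        rows.append(
            {
                "removed": feat,
                "micro_precision": rep.micro_precision,
                "micro_f1": rep.micro_f1,
                "macro_precision": rep.macro_precision,
                "kappa": rep.kappa,
                "micro_f1_drop": baseline.micro_f1 - rep.micro_f1,
            }
        )
    rows.sort(key=lambda r: -r["micro_f1_drop"])
    return [
        {
            "removed": None,
            "micro_precision": baseline.micro_precision,
            "micro_f1": baseline.micro_f1,
            "macro_precision": baseline.macro_precision,
            "kappa": baseline.kappa,
            "micro_f1_drop": 0.0,
        }
    ] + rows
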
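"""Confusion-matrix scoring: accuracy, per-class P/R/F1, Cohen's kappa.

Reports are computed per subject and then averaged with equal weight
(the reporting unit is the animal), with pooled scores over the summed
confusion matrix also available. Per-class F1 is defined as 0 when
both precision and recall are 0, so scores aggregate even when REM is
absent from a short evaluation stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .stages import Hypnogram, N_STAGES, STAGE_NAMES, as_codes

__all__ = [
    "ScoreReport",
    "confusion_matrix",
    "score_report",
    "aggregate_reports",
    "score_by_subject",
]


def confusion_matrix(truth, pred) -> np.ndarray:
    """3x3 count matrix, rows = true stage, columns = predicted stage."""
    t = as_codes(truth)
    p = as_codes(pred)
    if len(t) != len(p):
        raise ValueError(
            f"truth has {len(t)} epochs but prediction has {len(p)}"
        )
    return _sk_confusion(t, p, labels=list(range(N_STAGES))).astype(np.int64)


@dataclass
class ScoreReport:
    confusion: np.ndarray
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    kappa: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
        }

    def summary(self) -> str:
        lines = [
            "            " + "".join(f"{n:>8}" for n in STAGE_NAMES) + "   (pred)",
        ]
        for i, name in enumerate(STAGE_NAMES):
            lines.append(f"true {name:>6} " +
                         "".join(f"{int(c):>8}" for c in self.confusion[i]))
        lines.append("")
        lines.append(f"{'stage':>6} {'prec':>7} {'recall':>7} {'F1':>7}")
        for name in STAGE_NAMES:
            lines.append(f"{name:>6} {self.precision[name]:7.4f} "
                         f"{self.recall[name]:7.4f} {self.f1[name]:7.4f}")
        lines.append("")
        lines.append(f"accuracy {self.accuracy:.4f}   macro-F1 {self.macro_f1:.4f}   "
                     f"kappa {self.kappa:.4f}")
        return "\n".join(lines)


def score_report(cm: np.ndarray) -> ScoreReport:
    """All scalar scores from a 3x3 confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal
    products; defined as 1 when p_e = 1 with perfect agreement.
    """
    cm = np.asarray(cm)
    if cm.shape != (N_STAGES, N_STAGES):
        raise ValueError(f"confusion matrix must be 3x3, got {cm.shape}")
    if (cm < 0).any():
        raise ValueError("confusion counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    cm = cm.astype(np.int64)
    total = int(total)
    rowsum = cm.sum(axis=1)
    colsum = cm.sum(axis=0)
    accuracy = float(np.trace(cm)) / total

    precision, recall, f1 = {}, {}, {}
    for c, name in enumerate(STAGE_NAMES):
        p = cm[c, c] / colsum[c] if colsum[c] else 0.0
        r = cm[c, c] / rowsum[c] if rowsum[c] else 0.0
        precision[name] = float(p)
        recall[name] = float(r)
        f1[name] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
    macro_f1 = float(np.mean(list(f1.values())))

    p_o = accuracy
    p_e = float((rowsum * colsum).sum()) / total ** 2
    if abs(1.0 - p_e) < 1e-15:
        kappa = 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return ScoreReport(
        confusion=cm, accuracy=accuracy, precision=precision,
        recall=recall, f1=f1, macro_f1=macro_f1, kappa=float(kappa),
    )


def aggregate_reports(reports: list[ScoreReport]) -> dict:
    """Unweighted per-subject means of each scalar; confusions summed.

    Note the mean of per-subject kappas is generally not the kappa of
    the summed confusion matrix (marginals differ across subjects);
    both are therefore reported, as ``kappa`` (mean) and under
    ``pooled``.
    """
    if not reports:
        raise ValueError("need at least one report to aggregate")
    summed = np.sum([r.confusion for r in reports], axis=0)
    pooled = score_report(summed)
    out = {
        "n_subjects": len(reports),
        "accuracy": float(np.mean([r.accuracy for r in reports])),
        "macro_f1": float(np.mean([r.macro_f1 for r in reports])),
        "kappa": float(np.mean([r.kappa for r in reports])),
        "precision": {}, "recall": {}, "f1": {},
        "confusion_summed": summed,
        "pooled": pooled,
    }
    for name in STAGE_NAMES:
        out["precision"][name] = float(np.mean([r.precision[name] for r in reports]))
        out["recall"][name] = float(np.mean([r.recall[name] for r in reports]))
        out["f1"][name] = float(np.mean([r.f1[name] for r in reports]))
    return out


def score_by_subject(
    truth: Hypnogram,
    pred: Hypnogram,
    subjects: list[str] | np.ndarray,
) -> tuple[dict[str, ScoreReport], dict]:
    """Split epochs by subject tag, score each, and aggregate."""
    t = as_codes(truth)
    p = as_codes(pred)
    subjects = np.asarray(subjects)
    if not (len(t) == len(p) == len(subjects)):
        raise ValueError("truth, prediction and subject tags must be equal length")
    reports = {}
    for sid in sorted(set(subjects.tolist())):
        sel = subjects == sid
        reports[sid] = score_report(confusion_matrix(t[sel], p[sel]))
    return reports, aggregate_reports(list(reports.values()))
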
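"""Classification metrics, patient-level cross-validation, and the McNemar
paired-classifier test.

Metrics are the standard six: accuracy, AUC (rank-based with midrank ties),
precision, sensitivity, specificity and F1.  Ratios with empty denominators
are reported as ``nan`` with a warning rather than silently zeroed.

Cross-validation folds partition *patients* (never slices), stratified by
class, so no patient's slices leak across folds.

The McNemar test compares two classifiers on the same cases through the
discordant counts b (only A correct) and c (only B correct):
chi2 = (b - c)^2 / (b + c), p from the upper tail of chi-square with 1 df.
The continuity correction is off by default and available as a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionTable":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return ConfusionTable(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()))


@dataclass(frozen=True)
class PairedOutcomeTable:
    """2x2 paired-outcome counts for two classifiers on the same cases."""

    both_correct: int
    only_a_correct: int   # b
    only_b_correct: int   # c
    both_wrong: int

    def __post_init__(self):
        if min(self.both_correct, self.only_a_correct, self.only_b_correct,
               self.both_wrong) < 0:
            raise ValueError("counts must be non-negative")

    @staticmethod
    def from_predictions(y_true, pred_a, pred_b) -> "PairedOutcomeTable":
        y_true = np.asarray(y_true).astype(int)
        ok_a = np.asarray(pred_a).astype(int) == y_true
        ok_b = np.asarray(pred_b).astype(int) == y_true
        return PairedOutcomeTable(
            both_correct=int((ok_a & ok_b).sum()),
            only_a_correct=int((ok_a & ~ok_b).sum()),
            only_b_correct=int((~ok_a & ok_b).sum()),
            both_wrong=int((~ok_a & ~ok_b).sum()))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (empty denominator); reported as nan")
        return float("nan")
    return num / den


def metrics(ct: ConfusionTable) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity and F1 from counts."""
    acc = (ct.tp + ct.tn) / ct.total
    prec = _ratio(ct.tp, ct.tp + ct.fp, "precision")
    sens = _ratio(ct.tp, ct.tp + ct.fn, "sensitivity")
    spec = _ratio(ct.tn, ct.tn + ct.fp, "specificity")
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        warnings.warn("F1 undefined; reported as nan")
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {"accuracy": acc, "precision": prec, "sensitivity": sens,
            "specificity": spec, "f1": f1}


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def kfold_split(patient_ids, patient_labels, k: int = 5,
                seed: int = 0) -> dict[str, int]:
    """Stratified k-fold assignment at the patient level.

    Returns a mapping patient_id -> fold index in [0, k).  Deterministic for a
    given seed; every patient appears in exactly one fold.
    """
    patient_ids = np.asarray(patient_ids)
    patient_labels = np.asarray(patient_labels)
    uniq, first = np.unique(patient_ids, return_index=True)
    if uniq.size < k:
        raise ValueError(f"need at least k={k} patients, got {uniq.size}")
    labels = patient_labels[first]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(uniq, labels)):
        for i in test_idx:
            assignment[str(uniq[i])] = fold
    return assignment


def mcnemar(table: PairedOutcomeTable,
            continuity_correction: bool = False) -> tuple[float, float]:
    """McNemar chi-square statistic and 1-df upper-tail p-value."""
    b, c = table.only_a_correct, table.only_b_correct
    if b + c == 0:
        raise ValueError("McNemar test undefined: no discordant pairs")
    diff = abs(b - c) - 1 if continuity_correction else b - c
    diff = max(diff, 0) if continuity_correction else diff
    chi2 = diff ** 2 / (b + c)
    return float(chi2), float(_chi2_dist.sf(chi2, df=1))
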
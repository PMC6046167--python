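"""Scoring: per-class correct rates, confusion matrices, kappa, aggregation.

For the three shoulder actions the per-class correct rates are

    CRF = CNF / TNF * 100,   CRE = CNE / TNE * 100,   CRA = CNA / TNA * 100,

with CN* the correctly classified and TN* the total trials of flexion,
extension and abduction, and the total rate pools the counts:

    CR = (CNF + CNE + CNA) / (TNF + TNE + TNA) * 100.

With equal class totals CR is the arithmetic mean of the per-class rates.

Cross-subject summaries report mean +/- population standard deviation
(divisor n): only the population SD reproduces the printed +/-3.61 and
+/-5.61 spreads from the per-subject accuracies; the sample SD (divisor
n-1) would give 3.90 and 6.06 instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from afcsp.synth import CLASSES


@dataclass
class ConfusionMatrix3:
    """3x3 true-class x predicted-class table, order (flexion, extension,
    abduction).  ``normalized`` marks column-normalised percentage tables
    (each column sums to ~100) as opposed to raw counts."""

    table: np.ndarray
    classes: tuple[str, ...] = CLASSES
    normalized: bool = False

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(self.table < 0):
            raise ValueError("confusion matrix entries must be nonnegative")

    def column_normalized(self) -> "ConfusionMatrix3":
        col = self.table.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        return ConfusionMatrix3(self.table / col * 100.0,
                                self.classes, normalized=True)


def confusion_and_rates(y_true, y_pred) -> tuple[ConfusionMatrix3, float,
                                                 float, float, float]:
    """Counts plus (CRF, CRE, CRA, CR), each in [0, 100].

    A class absent from ``y_true`` gets rate 0 by convention (its count
    ratio is 0/0); CR always pools the raw counts.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    bad = (set(y_true) | set(y_pred)) - set(CLASSES)
    if bad:
        raise ValueError(f"labels outside the 3-class set: {sorted(bad)}")
    idx = {c: k for k, c in enumerate(CLASSES)}
    table = np.zeros((3, 3))
    for t, p in zip(y_true, y_pred):
        table[idx[t], idx[p]] += 1
    totals = table.sum(axis=1)
    corrects = np.diag(table)
    rates = [100.0 * c / t if t > 0 else 0.0
             for c, t in zip(corrects, totals)]
    cr = 100.0 * corrects.sum() / totals.sum() if totals.sum() > 0 else 0.0
    return ConfusionMatrix3(table), rates[0], rates[1], rates[2], cr


def pooled_cr(cms: list[ConfusionMatrix3]) -> tuple[float, float, float, float]:
    """(CRF, CRE, CRA, CR) pooled over several count matrices (e.g. folds)."""
    total = np.sum([cm.table for cm in cms], axis=0)
    totals = total.sum(axis=1)
    corrects = np.diag(total)
    rates = [100.0 * c / t if t > 0 else 0.0 for c, t in zip(corrects, totals)]
    cr = 100.0 * corrects.sum() / totals.sum() if totals.sum() > 0 else 0.0
    return rates[0], rates[1], rates[2], cr


def cohen_kappa(cm: ConfusionMatrix3 | np.ndarray) -> float:
    """Chance-corrected agreement kappa = (P_o - P_e) / (1 - P_e).

    P_o is the diagonal proportion and P_e the expected agreement from the
    row/column marginal products; percentage tables are treated as
    weights, so the statistic is scale invariant.
    """
    table = cm.table if isinstance(cm, ConfusionMatrix3) else np.asarray(
        cm, dtype=float)
    total = table.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(table) / total
    p_e = float(table.sum(axis=1) @ table.sum(axis=0)) / total ** 2
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("degenerate marginals: expected agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class SubjectSummary:
    accuracies: list[float]
    mean: float
    sd: float

    def __str__(self) -> str:
        return f"{self.mean:.2f}%±{self.sd:.2f}%"


def aggregate_subjects(accuracies: list[float]) -> SubjectSummary:
    """Mean and population SD (divisor n) over per-subject accuracies."""
    if not len(accuracies):
        raise ValueError("no subject accuracies to aggregate")
    a = np.asarray(accuracies, dtype=float)
    return SubjectSummary(accuracies=list(map(float, a)),
                          mean=round(float(a.mean()), 2),
                          sd=round(float(a.std(ddof=0)), 2))
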
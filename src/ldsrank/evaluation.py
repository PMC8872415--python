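"""Top-k enrichment counts and confusion-matrix metrics.

A ranking is evaluated against a set of known essential proteins by
declaring the top ``cutoff`` ranked proteins predicted-essential and
everything below predicted-non-essential.  Any ranked protein absent
from the essential set counts as a true non-essential (unknown proteins
are treated as non-essential).  Six standard ratios summarize the
resulting confusion matrix: sensitivity, specificity, positive and
negative predictive value, F-measure (harmonic mean of SN and PPV) and
accuracy.  Ratios with a zero denominator are defined as 0.0 and
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalReport:
    sn: float
    sp: float
    ppv: float
    npv: float
    f_measure: float
    acc: float


def topk_essential_count(
    ranking: Sequence[str], essentials: set[str], k: int
) -> int:
    """Number of true essential proteins among the top-k ranked."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k must lie in [1, {len(ranking)}], got {k}")
    return sum(1 for p in ranking[:k] if p in essentials)


def confusion_at_cutoff(
    ranking: Sequence[str], essentials: set[str], cutoff: int
) -> ConfusionMatrix:
    """Confusion matrix with the top ``cutoff`` proteins called essential."""
    if not 1 <= cutoff <= len(ranking):
        raise ValueError(
            f"cutoff must lie in [1, {len(ranking)}], got {cutoff}"
        )
    tp = fp = tn = fn = 0
    for i, p in enumerate(ranking):
        predicted = i < cutoff
        actual = p in essentials
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        log.warning("%s has a zero denominator; defining it as 0.0", name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """The six confusion-matrix ratios for one cutoff."""
    sn = _ratio(cm.tp, cm.tp + cm.fn, "SN")
    sp = _ratio(cm.tn, cm.tn + cm.fp, "SP")
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "PPV")
    npv = _ratio(cm.tn, cm.tn + cm.fn, "NPV")
    f = _ratio(2.0 * sn * ppv, sn + ppv, "F-measure")
    acc = _ratio(cm.tp + cm.tn, cm.total, "ACC")
    return EvalReport(sn=sn, sp=sp, ppv=ppv, npv=npv, f_measure=f, acc=acc)
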
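"""Binary classification metrics for the cough-positive task.

Five criteria are reported: sensitivity (cough recall), specificity
(noncough recall), the cough-class F1, the macro average (unweighted mean
of the two recalls) and the micro average (overall accuracy). The macro
and micro definitions are the ones consistent with both published baseline
rows this package reproduces in its worked example; they are documented as
inferred in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

POSITIVE = "cough"
NEGATIVE = "noncough"


@dataclass(frozen=True)
class ConfusionCounts:
    """Aggregated counts with cough as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class FiveMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    f1: float
    macro_avg: float
    micro_avg: float


def confusion(predictions: Sequence[str], truths: Sequence[str]) -> ConfusionCounts:
    """Count TP/FP/TN/FN over parallel label sequences."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    tp = fp = tn = fn = 0
    for pred, truth in zip(predictions, truths):
        if truth == POSITIVE:
            if pred == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if pred == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def five_metrics(c: ConfusionCounts) -> FiveMetrics:
    """Sensitivity, specificity, F1, macro and micro averages.

    F1 is the cough-class F1 and is defined as 0 when no cough is
    predicted or present (TP = 0). Both classes must be present.
    """
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError("both classes must be present in the truth")
    sens = c.tp / c.n_pos
    spec = c.tn / c.n_neg
    if c.tp == 0:
        f1 = 0.0
    else:
        prec = c.tp / (c.tp + c.fp)
        f1 = 2.0 * prec * sens / (prec + sens)
    macro = (sens + spec) / 2.0
    micro = (c.tp + c.tn) / c.total
    return FiveMetrics(sens, spec, f1, macro, micro)


def counts_from_recalls(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Rebuild integer counts from per-class recalls and class sizes.

    Used in the worked example, where published tables give class sizes
    and recalls but not the raw confusion matrix; counts are the nearest
    integers (half-up).
    """
    tp = int(Decimal(sensitivity * n_pos).quantize(0, rounding=ROUND_HALF_UP))
    tn = int(Decimal(specificity * n_neg).quantize(0, rounding=ROUND_HALF_UP))
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def round3(x: float) -> float:
    """Half-up rounding to 3 decimals, the reporting precision."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))
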
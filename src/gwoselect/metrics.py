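"""Confusion-matrix tallies and the six-metric binary-classification report.

With class 1 positive: Trp/Trn/Flp/Fln are the true/false positive/negative
counts.  The report holds

    ACC = (Trp+Trn) / (Trp+Trn+Flp+Fln)        accuracy
    SEN = Trp / (Trp+Fln)                      sensitivity (recall)
    SPE = Trn / (Trn+Flp)                      specificity
    PRE = Trp / (Trp+Flp)                      precision
    F1  = 2*PRE*SEN / (PRE+SEN)                harmonic mean
    MCC = (Trp*Trn - Flp*Fln) /
          sqrt((Trp+Flp)(Trp+Fln)(Trn+Flp)(Trn+Fln))

Any ratio with a zero denominator is defined as 0, which keeps reports
finite for degenerate (constant) predictors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "compute_metrics",
           "evaluate_predictions"]

#: Column order used for serialised reports (matches common table layout).
METRIC_ORDER = ("acc", "pre", "spe", "sen", "f1", "mcc")


@dataclass
class ConfusionCounts:
    Trp: int
    Trn: int
    Flp: int
    Fln: int

    @property
    def total(self) -> int:
        return self.Trp + self.Trn + self.Flp + self.Fln


@dataclass
class MetricReport:
    acc: float
    sen: float
    spe: float
    pre: float
    f1: float
    mcc: float

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_ORDER}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally a binary confusion matrix with class 1 as positive."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    return ConfusionCounts(
        Trp=int(np.sum((t == 1) & (p == 1))),
        Trn=int(np.sum((t == 0) & (p == 0))),
        Flp=int(np.sum((t == 0) & (p == 1))),
        Fln=int(np.sum((t == 1) & (p == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """The six-metric report from a confusion tally."""
    if c.total < 1:
        raise ValueError("empty confusion tally")
    acc = _ratio(c.Trp + c.Trn, c.total)
    sen = _ratio(c.Trp, c.Trp + c.Fln)
    spe = _ratio(c.Trn, c.Trn + c.Flp)
    pre = _ratio(c.Trp, c.Trp + c.Flp)
    f1 = _ratio(2.0 * pre * sen, pre + sen)
    mcc_den = np.sqrt(float(c.Trp + c.Flp) * (c.Trp + c.Fln)
                      * (c.Trn + c.Flp) * (c.Trn + c.Fln))
    mcc = _ratio(float(c.Trp) * c.Trn - float(c.Flp) * c.Fln, mcc_den)
    return MetricReport(acc=acc, sen=sen, spe=spe, pre=pre, f1=f1, mcc=mcc)


def evaluate_predictions(y_true, y_pred) -> MetricReport:
    """Convenience: tally then report."""
    return compute_metrics(confusion(y_true, y_pred))
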
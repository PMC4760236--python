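"""Precision / recall / F1 evaluation of a matching against ground truth.

Only feature pairs present in the ground truth are considered: a predicted
pair counts (as a true or false positive) only when both of its peaks occur
somewhere in the ground-truth covered sets; predicted pairs touching peaks
the truth never mentions are ignored entirely. False negatives are truth
pairs the prediction missed. Degenerate ratios (empty prediction or truth)
are defined as 0 so parameter sweeps never crash.
"""

from __future__ import annotations

from dataclasses import dataclass

from .peaks import GroundTruth, Matching


@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics_from_counts(tp: int, fp: int, fn: int) -> EvaluationResult:
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    return EvaluationResult(tp, fp, fn, precision, recall, f1)


def evaluate(predicted: Matching, truth: GroundTruth) -> EvaluationResult:
    """Score a predicted matching against one-to-one ground truth."""
    considered = {
        (a, b)
        for a, b in predicted.pairs
        if a in truth.covered_a and b in truth.covered_b
    }
    tp = len(considered & truth.pairs)
    fp = len(considered) - tp
    fn = len(truth.pairs) - tp
    return metrics_from_counts(tp, fp, fn)
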
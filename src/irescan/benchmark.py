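"""Evaluation of predictions against labelled positive/negative control sets.

Truth is per record: a positive-control sequence counts as detected when
it receives at least one qualifying prediction.  Metrics follow the
standard confusion-matrix definitions, reported as percentages;
balanced accuracy - the mean of sensitivity and specificity - is included
because control sets for this problem are strongly class-imbalanced.
Predictions can be pooled across confidence tiers ("overall") or
restricted to one pooled tier (high / medium / low).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = ["BenchmarkReport", "ReconciliationError", "evaluate"]

TIERS = ("overall", "high", "medium", "low")


class ReconciliationError(ValueError):
    """Label and prediction identifiers do not reconcile."""


@dataclass(frozen=True)
class BenchmarkReport:
    """Confusion counts and the four headline metrics for one tier.

    Metrics are percentages rounded to two decimals; a metric whose
    denominator is zero is ``None`` (undefined), never 0.
    """

    tier: str
    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _pct(num: int, den: int) -> float | None:
        return round(100.0 * num / den, 2) if den else None

    @property
    def sensitivity(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def balanced_accuracy(self) -> float | None:
        s, p = self.sensitivity, self.specificity
        if s is None or p is None:
            return None
        return round((s + p) / 2.0, 2)

    def as_dict(self) -> dict:
        return {
            "tier": self.tier,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _tier_of(prediction) -> str:
    """Accept ScoredIRE-like objects (``.pooled_tier``) or plain tier strings."""
    tier = getattr(prediction, "pooled_tier", prediction)
    if tier not in ("high", "medium", "low"):
        raise ValueError(f"unknown pooled tier {tier!r}")
    return tier


def evaluate(
    predictions: Mapping[str, Iterable],
    labels: Mapping[str, str],
    tier: str = "overall",
) -> BenchmarkReport:
    """Score one tier of a predictor against pos/neg record labels.

    ``predictions`` maps every labelled record id to its (possibly empty)
    prediction set; each prediction is a ScoredIRE or a pooled-tier
    string.  A record is called positive in a tier when it holds >= 1
    prediction of that tier ("overall" accepts any tier).  Raises
    :class:`ReconciliationError` listing orphan ids when the two maps
    disagree.
    """
    if tier not in TIERS:
        raise ValueError(f"tier must be one of {TIERS}")
    missing = sorted(set(labels) - set(predictions))
    extra = sorted(set(predictions) - set(labels))
    if missing or extra:
        raise ReconciliationError(
            f"unmatched ids - labelled without predictions: {missing}; "
            f"predicted without labels: {extra}"
        )
    bad = sorted(v for v in set(labels.values()) if v not in ("pos", "neg"))
    if bad:
        raise ValueError(f"labels must be 'pos'/'neg', got {bad}")
    tp = fp = tn = fn = 0
    for seq_id, label in labels.items():
        tiers = {_tier_of(p) for p in predictions[seq_id]}
        called = bool(tiers) if tier == "overall" else tier in tiers
        if label == "pos":
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    return BenchmarkReport(tier=tier, tp=tp, fp=fp, tn=tn, fn=fn)
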
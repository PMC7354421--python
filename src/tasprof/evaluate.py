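"""Scoring predicted sample compositions against known truth.

Congruency between a simulated sample's composition and the profiler's
output is measured with the Jaccard index JI = TP / (TP + FP + FN); the
false-positive rate is reported as the share of predicted taxa that are
wrong, FPR = 100 * FP / (TP + FP).  Both reduce the comparison to sets
of taxon labels at a chosen level (species or strain); predicted strain
*groups* ("a+b") count as true positives when they contain a truth
strain.  Per-sample results aggregate to means with standard errors of
the mean (sample sd with n-1, divided by sqrt(n)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .simulate import TruthSet

__all__ = ["EvalResult", "AggregateResult", "score_sample", "aggregate"]


@dataclass(frozen=True)
class EvalResult:
    sample_id: str
    tp: int
    fp: int
    fn: int
    ji: float
    fpr: float


@dataclass(frozen=True)
class AggregateResult:
    mean_ji: float
    sem_ji: float
    mean_fpr: float
    sem_fpr: float
    n_samples: int


def _expand(label: str) -> set[str]:
    return set(label.split("+"))


def score_sample(
    truth: TruthSet,
    predicted: Iterable[str],
    level: str = "species",
    strain_species: Mapping[str, str] | None = None,
    sample_id: str = "sample",
    fpr_denominator: str = "predicted",
) -> EvalResult:
    """Score one sample's predictions against its truth composition.

    At species level, predicted strain labels are mapped to species via
    ``strain_species`` when given (labels already at species level pass
    through).  At strain level a predicted group is a true positive iff
    it contains a truth strain; a truth strain counts as found when any
    predicted group contains it.  ``fpr_denominator`` selects FP/(TP+FP)
    (default) or FP/(FP+FN+TP) style alternatives ("union").
    """
    if level not in ("species", "strain"):
        raise ValueError(f"unknown level {level!r}")
    if level == "species":
        truth_set = set(truth.species)
        pred_set: set[str] = set()
        for label in predicted:
            for member in _expand(label):
                if strain_species and member in strain_species:
                    pred_set.add(strain_species[member])
                else:
                    pred_set.add(member)
        tp = len(truth_set & pred_set)
        fp = len(pred_set - truth_set)
        fn = len(truth_set - pred_set)
    else:
        truth_set = set(truth.strains)
        groups = [_expand(label) for label in set(predicted)]
        tp = sum(1 for g in groups if g & truth_set)
        fp = sum(1 for g in groups if not (g & truth_set))
        found = set().union(*groups) if groups else set()
        fn = len(truth_set - found)

    denom = tp + fp + fn
    ji = tp / denom if denom else 1.0
    if fpr_denominator == "predicted":
        fpr = 100.0 * fp / (tp + fp) if (tp + fp) else 0.0
    elif fpr_denominator == "union":
        fpr = 100.0 * fp / denom if denom else 0.0
    else:
        raise ValueError(f"unknown fpr_denominator {fpr_denominator!r}")
    return EvalResult(sample_id=sample_id, tp=tp, fp=fp, fn=fn, ji=ji, fpr=fpr)


def aggregate(results: Sequence[EvalResult] | Sequence[float]) -> AggregateResult:
    """Mean and SEM of JI and FPR over a sample panel.

    Accepts either :class:`EvalResult` objects or, for re-aggregating
    published per-sample tables, bare (ji, fpr) values via
    ``aggregate([EvalResult(...)...])``.  SEM uses the n-1 sample
    standard deviation over sqrt(n); a single sample has SEM 0.
    """
    if not results:
        raise ValueError("cannot aggregate an empty panel")
    jis = [r.ji for r in results]
    fprs = [r.fpr for r in results]
    n = len(results)

    def mean_sem(values: list[float]) -> tuple[float, float]:
        mean = sum(values) / n
        if n == 1:
            return mean, 0.0
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        return mean, math.sqrt(var) / math.sqrt(n)

    mean_ji, sem_ji = mean_sem(jis)
    mean_fpr, sem_fpr = mean_sem(fprs)
    return AggregateResult(
        mean_ji=mean_ji,
        sem_ji=sem_ji,
        mean_fpr=mean_fpr,
        sem_fpr=sem_fpr,
        n_samples=n,
    )
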
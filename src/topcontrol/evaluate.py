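"""Overlap statistics: hypergeometric tails, Benjamini–Hochberg adjustment,
and confusion-matrix evaluation of candidate sets against disease annotations.

The significance convention throughout is the inclusive upper tail
``P(X >= k)`` of the hypergeometric distribution — the standard
over-representation test — with the network node set as the finite background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import DiseaseAnnotation

__all__ = [
    "hypergeom_upper_tail",
    "bh_adjust",
    "ConfusionCounts",
    "EvaluationReport",
    "evaluate_candidates",
    "round_percent",
]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Inclusive upper-tail hypergeometric probability P(X >= k).

    Probability of at least ``k`` successes when drawing ``n`` items without
    replacement from a population of ``N`` containing ``K`` successes.
    Computed via scipy's log-space survival function for numerical stability.

    ``k`` above ``min(K, n)`` returns 0.0; ``k <= 0`` returns 1.0.
    """
    if N < 0 or K < 0 or n < 0 or K > N or n > N:
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k <= 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Adjusted values are clipped to 1 and monotone with respect to the raw
    ordering (cumulative-minimum enforcement of the step-up procedure).
    """
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if any(not (0.0 <= p <= 1.0) for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(pvalues, method="fdr_bh")[1])


def round_percent(fraction: float) -> int:
    """Round a fraction to the nearest integer percent, halves up
    (17/33 = 51.5% -> 52%)."""
    return int(math.floor(fraction * 100 + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 contingency of candidates vs annotated nodes over the universe.

    The identities ``tp + fn == disease_k``, ``tp + fp == candidate_n`` and
    ``tp + fp + fn + tn == universe_n`` hold by construction.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    universe_n: int
    disease_k: int
    candidate_n: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fn != self.disease_k:
            raise ValueError("tp + fn must equal the annotated count K")
        if self.tp + self.fp != self.candidate_n:
            raise ValueError("tp + fp must equal the candidate count n")
        if self.tp + self.fp + self.fn + self.tn != self.universe_n:
            raise ValueError("confusion cells must sum to the universe size N")


@dataclass(frozen=True)
class EvaluationReport:
    counts: ConfusionCounts
    sensitivity: Optional[float]  # tp / (tp + fn); None when no annotated node in universe
    specificity: Optional[float]  # tn / (tn + fp); None when every node is annotated
    accuracy: float               # (tp + tn) / N
    hyper_p: float                # P(X >= tp | N, K, n)

    def percentages(self) -> dict[str, Optional[int]]:
        """Metrics as rounded integer percent, as printed in study reports."""
        return {
            "sensitivity": None if self.sensitivity is None else round_percent(self.sensitivity),
            "specificity": None if self.specificity is None else round_percent(self.specificity),
            "accuracy": round_percent(self.accuracy),
        }

    def as_dict(self) -> dict:
        c = self.counts
        return {
            "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
            "universe_n": c.universe_n, "disease_k": c.disease_k,
            "candidate_n": c.candidate_n,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "hyper_p": self.hyper_p,
        }


def evaluate_candidates(
    candidates: Iterable[str],
    annotation: DiseaseAnnotation,
    universe: Iterable[str],
) -> EvaluationReport:
    """Score a candidate set against a disease annotation over a finite
    universe (all nodes of the constructed network as background).

    Annotated identifiers absent from the universe are ignored — the test is
    conditional on the network.  Significance is the inclusive upper-tail
    hypergeometric probability of the observed overlap.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("evaluation universe must be non-empty")
    candidates = set(candidates)
    if not candidates <= universe:
        raise ValueError("candidates must be a subset of the universe")
    annotated = set(annotation.members) & universe

    tp = len(candidates & annotated)
    fp = len(candidates - annotated)
    fn = len(annotated - candidates)
    tn = len(universe) - tp - fp - fn
    counts = ConfusionCounts(
        tp=tp, fp=fp, fn=fn, tn=tn,
        universe_n=len(universe), disease_k=len(annotated), candidate_n=len(candidates),
    )
    sensitivity = tp / (tp + fn) if (tp + fn) else None
    specificity = tn / (tn + fp) if (tn + fp) else None
    accuracy = (tp + tn) / len(universe)
    hyper_p = hypergeom_upper_tail(tp, len(universe), len(annotated), len(candidates))
    return EvaluationReport(counts, sensitivity, specificity, accuracy, hyper_p)
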
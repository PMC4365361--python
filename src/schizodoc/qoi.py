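"""Quality-of-Information calculus for logic-program argument values.

QoI scores how informative a single predicate argument is on [0,1]:
known (or known-false) arguments score 1; unknown arguments score 0 (the
limit 1/N as the set of admissible terms grows without bound); an argument
restricted to a finite abducible set of Card candidates scores 1/Card when
the candidates are mutually exclusive and 1/(2**Card - 1) when any
combination of them may hold (the sum over all non-empty card-combination
subsets).  A weighted per-predicate score V combines attribute QoIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

__all__ = [
    "AbducibleSet",
    "WeightVector",
    "qoi_known",
    "qoi_unknown",
    "qoi_set",
    "score_v",
    "clause_qoi",
]


@dataclass(frozen=True)
class AbducibleSet:
    """Finite candidate set for an unresolved argument.

    ``disjoint`` means exactly one candidate can be the true value; otherwise
    any non-empty combination of candidates is admissible.
    """

    cardinality: int
    disjoint: bool = True

    def __post_init__(self) -> None:
        if self.cardinality < 1:
            raise ValueError("abducible set must have cardinality >= 1")


@dataclass(frozen=True)
class WeightVector:
    """Non-negative attribute relevance weights, normalized to sum to 1."""

    weights: tuple[float, ...]

    def __init__(self, weights: Sequence[float]):
        w = tuple(float(x) for x in weights)
        if len(w) == 0:
            raise ValueError("weight vector must be non-empty")
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(w)}")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)

    @staticmethod
    def equal(n: int) -> "WeightVector":
        return WeightVector([1.0 / n] * n)


def qoi_known() -> float:
    """QoI of a known (positive or negative) argument: 1."""
    return 1.0


def qoi_unknown() -> float:
    """QoI of an unknown argument: lim 1/N = 0."""
    return 0.0


def qoi_set(s: AbducibleSet) -> float:
    """QoI of an abducible-set argument.

    Disjoint candidates: 1/Card.  Non-disjoint: one over the number of
    non-empty subsets, sum_{k=1..Card} C(Card, k) = 2**Card - 1.
    """
    if s.disjoint:
        return 1.0 / s.cardinality
    return 1.0 / sum(comb(s.cardinality, k) for k in range(1, s.cardinality + 1))


def score_v(w: WeightVector, qois: Sequence[float]) -> float:
    """Weighted predicate score V = sum_k w_k * QoI_k / n, in [0, 1/n]."""
    n = len(w)
    if len(qois) != n:
        raise ValueError(f"{n} weights but {len(qois)} QoI values")
    return sum(wk * q for wk, q in zip(w.weights, qois)) / n


def clause_qoi(qois: Sequence[float], policy: str = "one") -> float:
    """Clause-level QoI under a configurable aggregation policy.

    ``one`` (default) annotates every clause with QoI 1, the convention the
    worked records follow even when arguments are unknown; ``min`` takes the
    most pessimistic attribute QoI; ``mean`` averages.
    """
    if policy == "one":
        return 1.0
    if len(qois) == 0:
        raise ValueError("clause_qoi needs at least one attribute QoI")
    if policy == "min":
        return min(qois)
    if policy == "mean":
        return sum(qois) / len(qois)
    raise ValueError(f"unknown clause QoI policy {policy!r}")
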
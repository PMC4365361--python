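"""Synthetic labelled patient populations with a planted diagnostic rule.

No public case database exists for this screening task, so the classifier
is exercised on simulated populations.  A latent *complete* record is drawn
for every case from a two-profile mixture (healthy / affected symptom
distributions); the ground-truth risk is computed on that complete record by
a documented logistic rule in which first-order Kurt Schneider symptoms
dominate second-order ones, and a zero lucidity or differential factor
voids the diagnosis (label ``indeterminate``).  Only afterwards are cells
degraded — replaced by ``unknown`` or blurred into intervals at configurable
per-cell rates — so the label always reflects the latent truth, and rising
missingness lowers the record's Degree of Confidence without touching its
label.

The planted risk is

    risk = logistic(6*(Ks1/11) + 1.5*(Ks2/4) + (g/91.5) + 0.5*(as_mid/0.18) - 3)

with g the genetic-predisposition percentage and as_mid the midpoint of the
age/sex incidence interval.  The coefficients are artifact constants chosen
so that first-order symptoms dominate (weight 6 vs 1.5 on unit scales), the
predispositions act as mild priors, an all-zero symptom picture scores
risk < 0.1, a maximal one scores > 0.9, and an even mixture of the two
profiles yields a roughly balanced label split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .clinical import (
    RawPatientRecord,
    SUB_DOMAINS,
    age_sex_predisposition,
    build_clause,
    differential_value,
    genetic_predisposition,
    genetic_relations,
    lucidity_value,
)
from .intervals import AttrValue, widen_to_interval
from .pipeline import clause_to_doc, feature_vector

__all__ = [
    "GeneratorConfig",
    "LabelledCase",
    "planted_risk",
    "generate_population",
    "cases_to_training_data",
    "INDETERMINATE",
    "RISK_COEFFICIENTS",
]

#: sentinel returned by :func:`planted_risk` when the diagnosis is voided
INDETERMINATE = None

#: (alpha, beta, gamma, delta, theta) of the planted logistic rule
RISK_COEFFICIENTS = (6.0, 1.5, 1.0, 0.5, 3.0)

# cells the masking step may degrade; demographics stay observed
_MASKABLE = tuple(SUB_DOMAINS)


@dataclass(frozen=True)
class GeneratorConfig:
    """Population size, degradation rates, and seed.

    ``missing_rate`` and ``interval_rate`` are per-cell probabilities of
    replacing a latent value by ``unknown`` or by a blurred interval; they
    must sum to at most 1.  ``relation_missing_rate`` degrades the genetic
    relation separately (it is categorical, so it can only go missing).
    ``label_noise`` flips determinate labels at the given rate.
    """

    n: int
    missing_rate: float = 0.1
    interval_rate: float = 0.1
    label_noise: float = 0.0
    relation_missing_rate: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name in ("missing_rate", "interval_rate", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.missing_rate + self.interval_rate > 1.0 + 1e-12:
            raise ValueError("missing_rate + interval_rate must be <= 1")
        if self.relation_missing_rate is not None and not (
            0.0 <= self.relation_missing_rate <= 1.0
        ):
            raise ValueError("relation_missing_rate must lie in [0,1]")

    @property
    def effective_relation_missing_rate(self) -> float:
        return (
            self.missing_rate
            if self.relation_missing_rate is None
            else self.relation_missing_rate
        )


@dataclass(frozen=True)
class LabelledCase:
    """A degraded record, its label, and the latent risk that produced it."""

    record: RawPatientRecord
    label: str  # "schizophrenia" | "not_schizophrenia" | "indeterminate"
    true_risk: Optional[float]  # None when indeterminate
    latent_record: RawPatientRecord = field(repr=False)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def planted_risk(r: RawPatientRecord) -> Optional[float]:
    """Ground-truth schizophrenia risk of a complete record.

    Interval cells are reduced to their midpoints; unknown cells are not
    admissible here (the rule defines the latent truth, which is complete).
    Returns ``None`` (:data:`INDETERMINATE`) when the lucidity or
    differential product is exactly zero.
    """
    alpha, beta, gamma, delta, theta = RISK_COEFFICIENTS

    def mid(v: AttrValue, name: str) -> float:
        if v.is_unknown:
            raise ValueError(f"planted_risk needs a complete record; {name} is unknown")
        lo, hi = widen_to_interval(v, SUB_DOMAINS[name], attribute=name)
        return (lo + hi) / 2.0

    luc = lucidity_value(r.drugs, r.alcohol, r.somnolence, r.consciousness)
    dif = differential_value(r.neurological, r.infectious, r.toxic_metabolic)
    if (luc.is_point and luc.payload == 0.0) or (dif.is_point and dif.payload == 0.0):
        return INDETERMINATE

    ks1 = sum(
        mid(getattr(r, n), n)
        for n in ("thinking_alterations", "passivity", "hallucinations", "delusions")
    )
    ks2 = sum(
        mid(getattr(r, n), n)
        for n in ("delusional_intuition", "perplexity", "emotional_impoverishment", "dysthymias")
    )
    if r.relation is None:
        raise ValueError("planted_risk needs a complete record; relation is unknown")
    g = genetic_predisposition(r.relation)
    as_lo, as_hi = age_sex_predisposition(r.age, r.sex)
    as_mid = (as_lo + as_hi) / 2.0

    return _logistic(
        alpha * (ks1 / 11.0)
        + beta * (ks2 / 4.0)
        + gamma * (g / 91.5)
        + delta * (as_mid / 0.18)
        - theta
    )


# per-profile categorical distributions over the graded symptom scales
_PROFILES = {
    "healthy": {
        "thinking_alterations": [0.70, 0.20, 0.08, 0.02],
        "passivity": [0.80, 0.15, 0.05],
        "hallucinations": [0.75, 0.15, 0.05, 0.03, 0.02],
        "delusions": [0.80, 0.15, 0.05],
        "ks2_present": 0.15,
    },
    "affected": {
        "thinking_alterations": [0.05, 0.15, 0.30, 0.50],
        "passivity": [0.20, 0.40, 0.40],
        "hallucinations": [0.05, 0.10, 0.20, 0.25, 0.40],
        "delusions": [0.15, 0.35, 0.50],
        "ks2_present": 0.70,
    },
}
#: mixture weight of the affected profile
_AFFECTED_WEIGHT = 0.5

# lucidity / differential factors are usually unremarkable; occasional zeros
# exercise the diagnosis-voiding rule
_BINARY_OK = 0.98  # P(drugs/alcohol/somnolence/neurological/... = 1)
_CONSCIOUSNESS_P = [0.01, 0.09, 0.90]  # torpor / obnubilation / waking

# closest-relative category frequencies: mostly general population, the
# familial categories shared among the rest
_RELATIONS = genetic_relations()
_RELATION_P = np.array(
    [0.70 if rel == "general_population" else 0.30 / (len(_RELATIONS) - 1) for rel in _RELATIONS]
)


def _draw_latent(rng: np.random.Generator, record_id: str) -> RawPatientRecord:
    profile = _PROFILES["affected" if rng.random() < _AFFECTED_WEIGHT else "healthy"]
    point = AttrValue.point

    def cat(p: list[float]) -> AttrValue:
        return point(int(rng.choice(len(p), p=np.asarray(p) / np.sum(p))))

    def binary(p_one: float) -> AttrValue:
        return point(1.0 if rng.random() < p_one else 0.0)

    return RawPatientRecord(
        record_id=record_id,
        age=int(rng.integers(12, 70)),
        sex="male" if rng.random() < 0.5 else "female",
        relation=str(rng.choice(np.array(_RELATIONS), p=_RELATION_P)),
        drugs=binary(_BINARY_OK),
        alcohol=binary(_BINARY_OK),
        somnolence=binary(_BINARY_OK),
        consciousness=cat(_CONSCIOUSNESS_P),
        neurological=binary(_BINARY_OK),
        infectious=binary(_BINARY_OK),
        toxic_metabolic=binary(_BINARY_OK),
        thinking_alterations=cat(profile["thinking_alterations"]),
        passivity=cat(profile["passivity"]),
        hallucinations=cat(profile["hallucinations"]),
        delusions=cat(profile["delusions"]),
        delusional_intuition=binary(profile["ks2_present"]),
        perplexity=binary(profile["ks2_present"]),
        emotional_impoverishment=binary(profile["ks2_present"]),
        dysthymias=binary(profile["ks2_present"]),
    )


def _degrade(
    rng: np.random.Generator, latent: RawPatientRecord, cfg: GeneratorConfig
) -> RawPatientRecord:
    """Mask cells of the latent record: unknown, blurred interval, or intact."""
    updates: dict[str, object] = {}
    for name in _MASKABLE:
        u = rng.random()
        if u < cfg.missing_rate:
            updates[name] = AttrValue.unknown()
        elif u < cfg.missing_rate + cfg.interval_rate:
            d = SUB_DOMAINS[name]
            v: AttrValue = getattr(latent, name)
            lo, hi = widen_to_interval(v, d, attribute=name)
            half = 0.25 * d.width
            blurred = (max(d.lower, lo - half), min(d.upper, hi + half))
            updates[name] = AttrValue.interval(*blurred)
    if rng.random() < cfg.effective_relation_missing_rate:
        updates["relation"] = None
    return replace(latent, **updates) if updates else latent


def generate_population(cfg: GeneratorConfig) -> list[LabelledCase]:
    """Draw a reproducible labelled population.

    Labels are computed on the complete latent records *before* masking, so
    cell degradation changes a case's information content but never its
    label.  Identical configs (seed included) produce identical populations.
    """
    rng = np.random.default_rng(cfg.seed)
    cases: list[LabelledCase] = []
    for i in range(cfg.n):
        latent = _draw_latent(rng, record_id=f"case{i:05d}")
        risk = planted_risk(latent)
        if risk is INDETERMINATE:
            label = "indeterminate"
        else:
            positive = risk >= 0.5
            if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
                positive = not positive
            label = "schizophrenia" if positive else "not_schizophrenia"
        degraded = _degrade(rng, latent, cfg)
        cases.append(LabelledCase(degraded, label, risk, latent))
    return cases


def cases_to_training_data(
    cases: list[LabelledCase], include_indeterminate: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Features, binary labels and clause-DoC confidence targets.

    Indeterminate cases are dropped by default, since their diagnosis is not
    settled; with ``include_indeterminate`` they are kept as negatives.
    """
    feats, labels, confidences = [], [], []
    for case in cases:
        if case.label == "indeterminate" and not include_indeterminate:
            continue
        doc = clause_to_doc(build_clause(case.record))
        feats.append(feature_vector(doc))
        labels.append(1 if case.label == "schizophrenia" else 0)
        confidences.append(doc.clause_doc)
    if not feats:
        return np.empty((0, 18)), np.empty(0, dtype=int), np.empty(0)
    return np.vstack(feats), np.asarray(labels, dtype=int), np.asarray(confidences)
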
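"""Schizophrenia record schema: epidemiological lookups and derived scores.

A raw patient record holds the psychiatrist-entered sub-table cells; this
module derives from them the six attributes of the schizophrenia predicate:

* age/sex predisposition — an annual-incidence-rate interval (per 1000)
  looked up by age band and sex; inherently interval-valued.
* genetic predisposition — the percentage risk for the closest affected
  relative category; 0.9% for the general population.
* lucidity — the product of drugs x alcohol x somnolence x consciousness;
  any zero factor (intoxication, torpor) voids a reliable diagnosis.
* differential — the product of the neurological, infectious and
  toxic/metabolic absence indicators; same voiding rule.
* Ks_1 / Ks_2 — Kurt Schneider first- and second-order symptom sums, on
  [0,11] and [0,4]; first-order symptoms carry far more diagnostic weight.

Unknown sub-cells propagate through the products and sums by interval
arithmetic on non-negative ranges, so a derived attribute degrades gracefully
rather than collapsing to fully-unknown unless its hull truly covers the
whole domain.  The two lookup tables ship as CSV files under
``schizodoc/data`` so the clinical constants stay auditable and replaceable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .intervals import AttrValue, Domain, DomainViolation, widen_to_interval

__all__ = [
    "SUB_DOMAINS",
    "CLAUSE_ATTRIBUTES",
    "RawPatientRecord",
    "SchizophreniaClause",
    "age_sex_predisposition",
    "genetic_predisposition",
    "genetic_relations",
    "lucidity_value",
    "differential_value",
    "ks1_score",
    "ks2_score",
    "build_clause",
    "AS_DOMAIN_MALE",
    "AS_DOMAIN_FEMALE",
    "G_DOMAIN",
    "LUCIDITY_DOMAIN",
    "DIFFERENTIAL_DOMAIN",
    "KS1_DOMAIN",
    "KS2_DOMAIN",
]

AS_DOMAIN_MALE = Domain(0.0, 0.18)
AS_DOMAIN_FEMALE = Domain(0.0, 0.07)
G_DOMAIN = Domain(0.9, 91.5)
LUCIDITY_DOMAIN = Domain(0.0, 2.0)
DIFFERENTIAL_DOMAIN = Domain(0.0, 1.0)
KS1_DOMAIN = Domain(0.0, 11.0)
KS2_DOMAIN = Domain(0.0, 4.0)

# domains of the psychiatrist-entered sub-table cells
SUB_DOMAINS: dict[str, Domain] = {
    "drugs": Domain(0, 1),
    "alcohol": Domain(0, 1),
    "somnolence": Domain(0, 1),
    "consciousness": Domain(0, 2),
    "neurological": Domain(0, 1),
    "infectious": Domain(0, 1),
    "toxic_metabolic": Domain(0, 1),
    "thinking_alterations": Domain(0, 3),
    "passivity": Domain(0, 2),
    "hallucinations": Domain(0, 4),
    "delusions": Domain(0, 2),
    "delusional_intuition": Domain(0, 1),
    "perplexity": Domain(0, 1),
    "emotional_impoverishment": Domain(0, 1),
    "dysthymias": Domain(0, 1),
}

# fixed column order of the schizophrenia table
CLAUSE_ATTRIBUTES = (
    "as_predisposition",
    "g_predisposition",
    "lucidity",
    "differential",
    "ks1",
    "ks2",
)


def _load_age_sex_table() -> list[tuple[int, Optional[int], str, float, float]]:
    rows = []
    path = resources.files("schizodoc.data") / "age_sex_predisposition.csv"
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            hi = int(row["age_hi"]) if row["age_hi"] else None
            rows.append(
                (int(row["age_lo"]), hi, row["sex"], float(row["rate_lo"]), float(row["rate_hi"]))
            )
    return rows


def _load_genetic_table() -> dict[str, float]:
    path = resources.files("schizodoc.data") / "genetic_predisposition.csv"
    with path.open("r", encoding="utf-8") as fh:
        return {row["relation"]: float(row["percent"]) for row in csv.DictReader(fh)}


_AGE_SEX_TABLE = _load_age_sex_table()
_GENETIC_TABLE = _load_genetic_table()


def age_sex_predisposition(age: int, sex: str) -> tuple[float, float]:
    """Annual incidence-rate interval (per 1000) for the patient's age band and sex.

    Bands are inclusive integer-year ranges; the open-ended top band takes
    every age from 65 up.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    for lo, hi, s, rlo, rhi in _AGE_SEX_TABLE:
        if s == sex and age >= lo and (hi is None or age <= hi):
            return (rlo, rhi)
    raise ValueError(f"no age band covers age {age}")  # pragma: no cover


def genetic_relations() -> tuple[str, ...]:
    """Valid closest-relative category labels, in increasing risk order."""
    return tuple(sorted(_GENETIC_TABLE, key=_GENETIC_TABLE.get))


def genetic_predisposition(relation: str) -> float:
    """Risk percentage for the closest schizophrenic-relative category."""
    try:
        return _GENETIC_TABLE[relation]
    except KeyError:
        valid = ", ".join(genetic_relations())
        raise ValueError(f"unknown relation {relation!r}; valid labels: {valid}") from None


def _interval_product(
    factors: list[tuple[str, AttrValue]], out_domain: Domain
) -> AttrValue:
    """Endpoint product of non-negative factor intervals, unknowns widened first."""
    lo, hi = 1.0, 1.0
    for name, v in factors:
        flo, fhi = widen_to_interval(v, SUB_DOMAINS[name], attribute=name)
        lo *= flo
        hi *= fhi
    return _as_attrvalue(lo, hi, out_domain)


def _interval_sum(factors: list[tuple[str, AttrValue]], out_domain: Domain) -> AttrValue:
    lo, hi = 0.0, 0.0
    for name, v in factors:
        flo, fhi = widen_to_interval(v, SUB_DOMAINS[name], attribute=name)
        lo += flo
        hi += fhi
    return _as_attrvalue(lo, hi, out_domain)


def _as_attrvalue(lo: float, hi: float, domain: Domain) -> AttrValue:
    # a hull covering the whole domain is indistinguishable from unknown
    if lo <= domain.lower and hi >= domain.upper:
        return AttrValue.unknown()
    if lo == hi:
        return AttrValue.point(lo)
    return AttrValue.interval(lo, hi)


def lucidity_value(
    drugs: AttrValue, alcohol: AttrValue, somnolence: AttrValue, consciousness: AttrValue
) -> AttrValue:
    """Lucidity on [0,2]: drugs x alcohol x somnolence x consciousness level."""
    return _interval_product(
        [("drugs", drugs), ("alcohol", alcohol), ("somnolence", somnolence),
         ("consciousness", consciousness)],
        LUCIDITY_DOMAIN,
    )


def differential_value(
    neurological: AttrValue, infectious: AttrValue, toxic_metabolic: AttrValue
) -> AttrValue:
    """Differential-diagnosis status on [0,1]: product of the three absence flags."""
    return _interval_product(
        [("neurological", neurological), ("infectious", infectious),
         ("toxic_metabolic", toxic_metabolic)],
        DIFFERENTIAL_DOMAIN,
    )


def ks1_score(
    thinking_alterations: AttrValue, passivity: AttrValue,
    hallucinations: AttrValue, delusions: AttrValue,
) -> AttrValue:
    """First-order Kurt Schneider score on [0,11]: componentwise interval sum."""
    return _interval_sum(
        [("thinking_alterations", thinking_alterations), ("passivity", passivity),
         ("hallucinations", hallucinations), ("delusions", delusions)],
        KS1_DOMAIN,
    )


def ks2_score(
    delusional_intuition: AttrValue, perplexity: AttrValue,
    emotional_impoverishment: AttrValue, dysthymias: AttrValue,
) -> AttrValue:
    """Second-order Kurt Schneider score on [0,4]."""
    return _interval_sum(
        [("delusional_intuition", delusional_intuition), ("perplexity", perplexity),
         ("emotional_impoverishment", emotional_impoverishment), ("dysthymias", dysthymias)],
        KS2_DOMAIN,
    )


@dataclass(frozen=True)
class RawPatientRecord:
    """Psychiatrist-entered record: demographics plus the sub-table cells.

    ``relation`` is the closest affected relative's category label, or None
    when unknown.  Every other cell is an :class:`AttrValue` within the
    domain listed in :data:`SUB_DOMAINS`.
    """

    record_id: str
    age: int
    sex: str
    relation: Optional[str]
    drugs: AttrValue
    alcohol: AttrValue
    somnolence: AttrValue
    consciousness: AttrValue
    neurological: AttrValue
    infectious: AttrValue
    toxic_metabolic: AttrValue
    thinking_alterations: AttrValue
    passivity: AttrValue
    hallucinations: AttrValue
    delusions: AttrValue
    delusional_intuition: AttrValue
    perplexity: AttrValue
    emotional_impoverishment: AttrValue
    dysthymias: AttrValue

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.relation is not None and self.relation not in _GENETIC_TABLE:
            genetic_predisposition(self.relation)  # raises with valid labels
        for name in SUB_DOMAINS:
            v: AttrValue = getattr(self, name)
            widen_to_interval(v, SUB_DOMAINS[name], attribute=name)  # domain check


@dataclass(frozen=True)
class SchizophreniaClause:
    """The six-attribute schizophrenia record with attached domains."""

    record_id: str
    as_predisposition: AttrValue
    g_predisposition: AttrValue
    lucidity: AttrValue
    differential: AttrValue
    ks1: AttrValue
    ks2: AttrValue
    as_domain: Domain  # [0,0.18] male / [0,0.07] female
    g_domain: Domain = G_DOMAIN
    lucidity_domain: Domain = LUCIDITY_DOMAIN
    differential_domain: Domain = DIFFERENTIAL_DOMAIN
    ks1_domain: Domain = KS1_DOMAIN
    ks2_domain: Domain = KS2_DOMAIN

    def attributes(self) -> list[tuple[str, AttrValue, Domain]]:
        """(name, value, domain) triples in the fixed table column order."""
        return [
            ("as_predisposition", self.as_predisposition, self.as_domain),
            ("g_predisposition", self.g_predisposition, self.g_domain),
            ("lucidity", self.lucidity, self.lucidity_domain),
            ("differential", self.differential, self.differential_domain),
            ("ks1", self.ks1, self.ks1_domain),
            ("ks2", self.ks2, self.ks2_domain),
        ]

    def __post_init__(self) -> None:
        for name, value, domain in self.attributes():
            widen_to_interval(value, domain, attribute=name)


def build_clause(r: RawPatientRecord) -> SchizophreniaClause:
    """Assemble the schizophrenia clause from a raw record.

    Applies the Table-lookup and product/sum derivations; the age/sex
    predisposition domain depends on the patient's sex.
    """
    as_lo, as_hi = age_sex_predisposition(r.age, r.sex)
    g = (
        AttrValue.unknown()
        if r.relation is None
        else AttrValue.point(genetic_predisposition(r.relation))
    )
    return SchizophreniaClause(
        record_id=r.record_id,
        as_predisposition=AttrValue.interval(as_lo, as_hi),
        g_predisposition=g,
        lucidity=lucidity_value(r.drugs, r.alcohol, r.somnolence, r.consciousness),
        differential=differential_value(r.neurological, r.infectious, r.toxic_metabolic),
        ks1=ks1_score(r.thinking_alterations, r.passivity, r.hallucinations, r.delusions),
        ks2=ks2_score(
            r.delusional_intuition, r.perplexity, r.emotional_impoverishment, r.dysthymias
        ),
        as_domain=AS_DOMAIN_MALE if r.sex == "male" else AS_DOMAIN_FEMALE,
    )
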
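"""Record -> DoC representation -> classifier features.

Each schizophrenia clause is transformed attribute by attribute:
widen to a continuous interval, min-max normalize against the attribute's
domain, score the Degree of Confidence sqrt(1 - width**2).  The clause DoC
is the mean of the six attribute DoCs; the clause QoI follows the
configurable policy in :mod:`schizodoc.qoi`.  The classifier consumes the
normalized interval extremes plus the per-attribute DoC, a fixed-order
vector of 18 values in [0,1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import qoi
from .clinical import CLAUSE_ATTRIBUTES, RawPatientRecord, SchizophreniaClause, build_clause
from .intervals import (
    NormalizedInterval,
    aggregate_doc,
    attribute_doc,
    normalize,
    widen_to_interval,
)

__all__ = [
    "AttributeDoC",
    "DoCClause",
    "clause_to_doc",
    "feature_vector",
    "encode_batch",
    "BatchError",
    "write_doc_clauses",
    "read_doc_clauses",
]

FEATURE_NAMES = tuple(
    f"{attr}_{part}" for attr in CLAUSE_ATTRIBUTES for part in ("lo", "hi", "doc")
)


@dataclass(frozen=True)
class AttributeDoC:
    """One attribute's normalized interval and its Degree of Confidence."""

    name: str
    lo: float
    hi: float
    doc: float


@dataclass(frozen=True)
class DoCClause:
    """DoC representation of one schizophrenia clause.

    ``clause_doc`` is the arithmetic mean of the six attribute DoCs;
    ``clause_qoi`` is carried for the record annotation but is not a
    classifier input.
    """

    record_id: str
    attributes: tuple[AttributeDoC, ...]
    clause_qoi: float
    clause_doc: float

    def attribute(self, name: str) -> AttributeDoC:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)


def clause_to_doc(c: SchizophreniaClause, qoi_policy: str = "one") -> DoCClause:
    """Widen, normalize and score every attribute; aggregate by the mean."""
    attrs = []
    attr_qois = []
    for name, value, domain in c.attributes():
        ni = normalize(widen_to_interval(value, domain, attribute=name), domain)
        attrs.append(AttributeDoC(name, ni.lo, ni.hi, attribute_doc(ni)))
        attr_qois.append(qoi.qoi_unknown() if value.is_unknown else qoi.qoi_known())
    return DoCClause(
        record_id=c.record_id,
        attributes=tuple(attrs),
        clause_qoi=qoi.clause_qoi(attr_qois, policy=qoi_policy),
        clause_doc=aggregate_doc([a.doc for a in attrs]),
    )


def feature_vector(d: DoCClause) -> np.ndarray:
    """18-vector: (normalized lo, normalized hi, DoC) per attribute, fixed order."""
    out = np.empty(18)
    for i, a in enumerate(d.attributes):
        out[3 * i : 3 * i + 3] = (a.lo, a.hi, a.doc)
    return out


class BatchError(ValueError):
    """Aggregated per-record failures from a batch encode."""

    def __init__(self, failures: list[tuple[str, str]]):
        self.failures = failures
        lines = "; ".join(f"{rid}: {msg}" for rid, msg in failures)
        super().__init__(f"{len(failures)} record(s) failed to encode: {lines}")


def encode_batch(
    records: Iterable[RawPatientRecord], qoi_policy: str = "one", strict: bool = True
) -> tuple[list[tuple[DoCClause, np.ndarray]], list[tuple[str, str]]]:
    """Order-preserving encode of a record batch.

    Per-record failures are collected with the record identifier instead of
    aborting the batch; with ``strict`` they are raised as a single
    :class:`BatchError` at the end.
    """
    encoded: list[tuple[DoCClause, np.ndarray]] = []
    failures: list[tuple[str, str]] = []
    for r in records:
        try:
            d = clause_to_doc(build_clause(r), qoi_policy=qoi_policy)
            encoded.append((d, feature_vector(d)))
        except (ValueError, KeyError) as exc:
            failures.append((r.record_id, str(exc)))
    if strict and failures:
        raise BatchError(failures)
    return encoded, failures


# -- serialization: JSON-lines, one clause per line -------------------------

def _clause_to_obj(d: DoCClause) -> dict:
    return {
        "record_id": d.record_id,
        "attributes": {
            a.name: {"lo": a.lo, "hi": a.hi, "doc": a.doc} for a in d.attributes
        },
        "clause_qoi": d.clause_qoi,
        "clause_doc": d.clause_doc,
    }


def write_doc_clauses(clauses: Sequence[DoCClause], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in clauses:
            fh.write(json.dumps(_clause_to_obj(d)) + "\n")


def read_doc_clauses(path) -> list[DoCClause]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            attrs = tuple(
                AttributeDoC(name, v["lo"], v["hi"], v["doc"])
                for name, v in obj["attributes"].items()
            )
            out.append(
                DoCClause(obj["record_id"], attrs, obj["clause_qoi"], obj["clause_doc"])
            )
    return out
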
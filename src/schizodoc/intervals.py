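"""Interval algebra for incompletely known attribute values.

A clinical attribute may be recorded as an exact number, as an interval of
plausible values, as a finite set of candidate (abducible) values, or as
entirely unknown.  Every such value lives inside a declared closed *domain*.
The calculus here turns any of those four shapes into a continuous interval,
min-max normalizes it against its domain, and scores how much of the domain
the observation still leaves open: the Degree of Confidence

    DoC = sqrt(1 - dl**2),   dl = width of the normalized interval,

which is 1 for an exactly known value and 0 for a fully unknown one.  A
record-level DoC is the arithmetic mean of its attributes' DoCs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

__all__ = [
    "Domain",
    "AttrValue",
    "NormalizedInterval",
    "DomainViolation",
    "widen_to_interval",
    "normalize",
    "attribute_doc",
    "aggregate_doc",
    "round_report",
    "truncate_report",
    "doc_from_rounded_bounds",
]


class DomainViolation(ValueError):
    """An observed value falls outside its declared attribute domain."""


@dataclass(frozen=True)
class Domain:
    """Closed real interval bounding an attribute, in the attribute's units.

    Zero-width domains are rejected: a degenerate domain makes the
    normalization ill-defined, and clinical attribute ranges are never
    single points.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("domain bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError(
                f"domain must have lower < upper, got [{self.lower}, {self.upper}]"
            )

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class AttrValue:
    """Tagged attribute observation: point, interval, unknown, or finite set.

    ``unknown`` carries no payload and means the value may be anything in the
    owning domain.  A ``finite_set`` is a non-empty set of candidate values
    (the abducible values an unresolved argument may take).
    """

    tag: str  # "point" | "interval" | "unknown" | "finite_set"
    payload: object = None

    _TAGS = frozenset({"point", "interval", "unknown", "finite_set"})

    def __post_init__(self) -> None:
        if self.tag not in self._TAGS:
            raise ValueError(f"unknown AttrValue tag {self.tag!r}")
        if self.tag == "point":
            if not isinstance(self.payload, (int, float)):
                raise ValueError("point payload must be a number")
        elif self.tag == "interval":
            lo, hi = self.payload  # type: ignore[misc]
            if lo > hi:
                raise ValueError(f"interval payload has lo > hi: [{lo}, {hi}]")
        elif self.tag == "finite_set":
            vals = tuple(self.payload)  # type: ignore[arg-type]
            if len(vals) == 0:
                raise ValueError("finite_set payload must be non-empty")
        elif self.tag == "unknown" and self.payload is not None:
            raise ValueError("unknown carries no payload")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def point(x: float) -> "AttrValue":
        return AttrValue("point", float(x))

    @staticmethod
    def interval(lo: float, hi: float) -> "AttrValue":
        return AttrValue("interval", (float(lo), float(hi)))

    @staticmethod
    def unknown() -> "AttrValue":
        return AttrValue("unknown")

    @staticmethod
    def finite_set(values: Iterable[float]) -> "AttrValue":
        return AttrValue("finite_set", tuple(float(v) for v in values))

    @property
    def is_unknown(self) -> bool:
        return self.tag == "unknown"

    @property
    def is_point(self) -> bool:
        return self.tag == "point"


@dataclass(frozen=True)
class NormalizedInterval:
    """Dimensionless interval on the unit scale, 0 <= lo <= hi <= 1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        # tolerate tiny negative round-off at the boundaries
        eps = 1e-12
        if not (-eps <= self.lo <= self.hi <= 1 + eps):
            raise ValueError(f"not a unit-scale interval: [{self.lo}, {self.hi}]")
        object.__setattr__(self, "lo", min(max(self.lo, 0.0), 1.0))
        object.__setattr__(self, "hi", min(max(self.hi, 0.0), 1.0))

    @property
    def width(self) -> float:
        return self.hi - self.lo


def widen_to_interval(
    v: AttrValue, d: Domain, attribute: str = "attribute"
) -> tuple[float, float]:
    """Transition an attribute observation to a continuous interval.

    Points become degenerate intervals, unknowns widen to the full domain,
    finite sets are replaced by their hull.  Out-of-domain payloads raise
    :class:`DomainViolation` naming the attribute — clamping would silently
    hide data-entry faults.
    """
    if v.tag == "unknown":
        return (d.lower, d.upper)
    if v.tag == "point":
        x = float(v.payload)  # type: ignore[arg-type]
        _check_in_domain(x, x, d, attribute)
        return (x, x)
    if v.tag == "interval":
        lo, hi = v.payload  # type: ignore[misc]
        _check_in_domain(lo, hi, d, attribute)
        return (float(lo), float(hi))
    # finite_set -> hull; cardinality is only relevant to the QoI calculus
    vals = tuple(v.payload)  # type: ignore[arg-type]
    lo, hi = min(vals), max(vals)
    _check_in_domain(lo, hi, d, attribute)
    return (lo, hi)


def _check_in_domain(lo: float, hi: float, d: Domain, attribute: str) -> None:
    if lo < d.lower or hi > d.upper:
        raise DomainViolation(
            f"{attribute}: value [{lo}, {hi}] outside domain [{d.lower}, {d.upper}]"
        )


def normalize(i: tuple[float, float], d: Domain) -> NormalizedInterval:
    """Min-max normalize an interval against its domain: y -> (y - min)/(max - min)."""
    lo, hi = i
    _check_in_domain(lo, hi, d, "interval")
    return NormalizedInterval((lo - d.lower) / d.width, (hi - d.lower) / d.width)


def attribute_doc(ni: NormalizedInterval) -> float:
    """Degree of Confidence of one attribute: sqrt(1 - width**2).

    Geometrically the height of the unit circle over the chord of length
    ``width``: 1 for a point value, 0 for a full-domain unknown, strictly
    decreasing in interval width.
    """
    dl = ni.width
    return math.sqrt(max(0.0, 1.0 - dl * dl))


def aggregate_doc(docs: Sequence[float]) -> float:
    """Record-level DoC: arithmetic mean of the per-attribute DoCs."""
    if len(docs) == 0:
        raise ValueError("aggregate_doc needs at least one attribute DoC")
    for v in docs:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"DoC out of [0,1]: {v}")
    return sum(docs) / len(docs)


def round_report(x: float, places: int) -> float:
    """Half-up rounding for display; core computations keep full precision.

    Python's ``round`` is banker's rounding, which disagrees with the
    half-up convention of the reported values (e.g. 0.825 -> 0.83).
    """
    if places < 0:
        raise ValueError("places must be >= 0")
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate_report(x: float, places: int) -> float:
    """Truncate toward zero at ``places`` decimals (0.9165 -> 0.916)."""
    if places < 0:
        raise ValueError("places must be >= 0")
    scale = 10**places
    return math.trunc(x * scale) / scale


def doc_from_rounded_bounds(ni: NormalizedInterval, places: int = 2) -> float:
    """Attribute DoC computed on half-up-rounded normalized bounds.

    Reporting variant: the width is taken between the bounds as printed at
    ``places`` decimals, so e.g. [0.6667, 1] -> [0.67, 1.00] -> DoC 0.944
    instead of the full-precision 0.9428.
    """
    lo = round_report(ni.lo, places)
    hi = round_report(ni.hi, places)
    return attribute_doc(NormalizedInterval(lo, hi))
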
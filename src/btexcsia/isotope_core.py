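"""Core domain types and elementary isotope/concentration arithmetic.

Stable-isotope compositions are carried in delta notation,

    delta [permil] = (R_sample / R_standard - 1) * 1000,

where R is the heavy/light isotope abundance ratio (13C/12C against VPDB for
carbon, 2H/1H against VSMOW for hydrogen).  All downstream regression work is
expressed in standard-free ratio factors

    R_t / R_0 = (delta_t + 1000) / (delta_0 + 1000),

so the absolute standard ratios are needed only when exporting absolute
ratios; they never enter a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "ElementMismatchError",
    "IsotopeDomainError",
    "IsotopeStandard",
    "VPDB",
    "VSMOW",
    "STANDARDS",
    "DEFAULT_DELTA_SIGMA",
    "DeltaValue",
    "Measurement",
    "IsotopeSeries",
    "FractionRemaining",
    "delta_to_ratio",
    "ratio_to_delta",
    "ratio_factor",
    "fraction_remaining",
    "extent_of_degradation",
]


class ElementMismatchError(ValueError):
    """Raised when C and H quantities are combined."""


class IsotopeDomainError(ValueError):
    """Raised when a value leaves the physically meaningful domain."""


#: Default 1-sigma delta reproducibilities (permil) assumed when a measurement
#: carries no explicit uncertainty: 0.3 permil for carbon and 2.5 permil for
#: hydrogen, typical of replicate GC-IRMS analyses of monoaromatics.
DEFAULT_DELTA_SIGMA = {"C": 0.3, "H": 2.5}


@dataclass(frozen=True)
class IsotopeStandard:
    """An international isotope reference standard.

    The element <-> name pairing is fixed: carbon ratios are reported against
    VPDB and hydrogen ratios against VSMOW.
    """

    element: str
    name: str
    absolute_ratio: float

    def __post_init__(self) -> None:
        if self.absolute_ratio <= 0:
            raise IsotopeDomainError("standard ratio must be positive")
        expected = {"C": "VPDB", "H": "VSMOW"}
        if self.element not in expected:
            raise ValueError(f"unknown element {self.element!r}")
        if self.name != expected[self.element]:
            raise ValueError(
                f"element {self.element} must pair with {expected[self.element]}"
            )


#: VPDB 13C/12C absolute abundance ratio (standard reference value).
VPDB = IsotopeStandard("C", "VPDB", 0.0111802)
#: VSMOW 2H/1H absolute abundance ratio (standard reference value).
VSMOW = IsotopeStandard("H", "VSMOW", 0.00015576)

STANDARDS = {"C": VPDB, "H": VSMOW}


@dataclass(frozen=True)
class DeltaValue:
    """A delta value in permil, optionally with a 1-sigma half-width."""

    element: str
    value: float
    uncertainty: Optional[float] = None

    def __post_init__(self) -> None:
        if self.element not in ("C", "H"):
            raise ValueError(f"element must be 'C' or 'H', got {self.element!r}")
        if self.value <= -1000.0:
            raise IsotopeDomainError(
                f"delta = {self.value} permil implies a non-positive isotope ratio"
            )
        if self.uncertainty is not None and self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")

    @property
    def sigma(self) -> float:
        """Uncertainty if set, else the element's default reproducibility."""
        if self.uncertainty is not None:
            return self.uncertainty
        return DEFAULT_DELTA_SIGMA[self.element]


@dataclass
class Measurement:
    """One timepoint of one compound in one flask.

    Times are in days, concentrations in ppm (mass fraction).  The abiotic
    control concentration and the internal-standard (o-xylene) concentration
    travel with the measurement when available.
    """

    time: float
    compound: str
    conc: float
    conc_control: Optional[float] = None
    conc_internal_std: Optional[float] = None
    delta13C: Optional[DeltaValue] = None
    delta2H: Optional[DeltaValue] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0 days")
        for name in ("conc", "conc_control", "conc_internal_std"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def delta(self, element: str) -> Optional[DeltaValue]:
        if element == "C":
            return self.delta13C
        if element == "H":
            return self.delta2H
        raise ValueError(f"element must be 'C' or 'H', got {element!r}")


@dataclass
class IsotopeSeries:
    """Ordered measurements of one compound in one flask.

    ``t0_index`` marks the reference point (C_0, delta_0) of the Rayleigh
    bookkeeping; by default the first measurement.
    """

    compound: str
    measurements: list[Measurement] = field(default_factory=list)
    t0_index: int = 0

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("series needs at least one measurement")
        times = [m.time for m in self.measurements]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("measurement times must be strictly increasing")
        if not (0 <= self.t0_index < len(self.measurements)):
            raise ValueError("t0_index out of range")
        if self.t0.conc <= 0:
            raise IsotopeDomainError("the t0 measurement must have conc > 0")

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def t0(self) -> Measurement:
        return self.measurements[self.t0_index]

    def times(self) -> list[float]:
        return [m.time for m in self.measurements]

    def complete_for(self, element: str) -> list[Measurement]:
        """Measurements carrying both a concentration and the element's delta."""
        return [
            m
            for m in self.measurements
            if m.conc is not None and m.delta(element) is not None
        ]


def delta_to_ratio(delta: DeltaValue, std: IsotopeStandard) -> float:
    """Convert a delta value (permil) to an absolute isotope ratio.

    R = (delta/1000 + 1) * R_standard.  Exact inverse of :func:`ratio_to_delta`.
    """
    if delta.element != std.element:
        raise ElementMismatchError(
            f"delta is {delta.element} but standard is {std.element}"
        )
    if delta.value <= -1000.0:
        raise IsotopeDomainError("delta must exceed -1000 permil")
    return (delta.value / 1000.0 + 1.0) * std.absolute_ratio


def ratio_to_delta(ratio: float, std: IsotopeStandard) -> DeltaValue:
    """Convert an absolute isotope ratio back to delta notation (permil)."""
    if ratio <= 0:
        raise IsotopeDomainError("isotope ratio must be positive")
    return DeltaValue(std.element, (ratio / std.absolute_ratio - 1.0) * 1000.0)


def ratio_factor(delta_t: DeltaValue, delta_0: DeltaValue) -> float:
    """R_t/R_0 from two delta values of the same element.

    (delta_t + 1000)/(delta_0 + 1000); the standard ratio cancels, so the
    result is identical for any positive VPDB/VSMOW value.
    """
    if delta_t.element != delta_0.element:
        raise ElementMismatchError(
            f"cannot mix elements {delta_t.element} and {delta_0.element}"
        )
    return (delta_t.value + 1000.0) / (delta_0.value + 1000.0)


class FractionRemaining(NamedTuple):
    """f = C_t/C_0 plus a flag when f > 1 (evaporative/handling artifact).

    Values above one are reported as-is, never silently clipped; the flag lets
    callers decide whether to drop such points.
    """

    f: float
    exceeds_unity: bool


def fraction_remaining(series: IsotopeSeries, t_index: int) -> FractionRemaining:
    """Residual fraction f = C_t/C_0 at the given measurement index."""
    c0 = series.t0.conc
    if c0 <= 0:
        raise IsotopeDomainError("C_0 must be > 0")
    ct = series.measurements[t_index].conc
    f = ct / c0
    return FractionRemaining(f, f > 1.0)


def extent_of_degradation(f: float) -> float:
    """Extent of degradation B [%] = (1 - f) * 100."""
    if f < 0:
        raise IsotopeDomainError("f must be >= 0")
    return (1.0 - f) * 100.0
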
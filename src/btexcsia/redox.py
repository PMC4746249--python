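"""Literature reference library and redox-condition classification.

Ships a compilation of published carbon and hydrogen bulk enrichment factors
for anaerobic and aerobic benzene biodegradation (pure strains and mixed
enrichment cultures across oxic, chlorate-, nitrate-, iron-, sulfate-reducing
and methanogenic conditions).  The dual-isotope slope Lambda discriminates
redox regimes for benzene: values of 22-28 are characteristic of low-redox
(fermenting, methanogenic, sulfate-reducing) communities, values of 12-16 of
nitrate-reducing ones.  The gap between the two ranges has no published
interpretation, so values there are reported as unclassified rather than
snapped to the nearest interval.

Users may extend the database with additional literature rows in the same
tab-separated format (see ``data/benzene_reference.tsv`` for the header).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .rayleigh import BENZENE_POSITIONS, PositionParams, akie

__all__ = [
    "ReferenceEntry",
    "RedoxClassification",
    "LOW_REDOX_RANGE",
    "HIGH_REDOX_RANGE",
    "load_reference_table",
    "classify_redox",
    "nearest_reference",
    "akie_biplot_points",
]

#: Lambda interval of fermenting/methanogenic/sulfate-reducing benzene
#: degradation (boundaries inclusive).
LOW_REDOX_RANGE = (22.0, 28.0)
#: Lambda interval of nitrate-reducing benzene degradation.
HIGH_REDOX_RANGE = (12.0, 16.0)

#: Hydrogen enrichment factors are roughly 20x larger than carbon ones; the
#: nearest-neighbour distance divides eps_H by this factor so both axes
#: contribute comparably.
_H_SCALE = 20.0


@dataclass(frozen=True)
class ReferenceEntry:
    """One published (eps_C, eps_H) pair for benzene biodegradation."""

    culture_label: str
    culture_type: str  # pure | mixed
    condition: str
    initial_benzene_uM: float
    epsilon_C: float
    epsilon_C_ci95: float
    epsilon_C_r2: float
    epsilon_H: float
    epsilon_H_ci95: float
    epsilon_H_r2: float
    source: str

    def __post_init__(self) -> None:
        if self.epsilon_C > 0 or self.epsilon_H > 0:
            raise ValueError("enrichment factors must be <= 0")
        for r2 in (self.epsilon_C_r2, self.epsilon_H_r2):
            if not (0.0 <= r2 <= 1.0):
                raise ValueError("r2 must lie in [0, 1]")


@dataclass(frozen=True)
class RedoxClassification:
    """Outcome of the Lambda interval rule.

    ``category`` is ``low_redox`` (fermenting/methanogenic/sulfate-reducing),
    ``high_redox`` (nitrate-reducing) or ``unclassified``; ``ambiguous`` is
    set when a supplied CI straddles an interval boundary.
    """

    category: str
    rule_applied: str
    lambda_value: float
    ambiguous: bool = False
    nearest_entries: tuple = field(default_factory=tuple)


def _resource_df() -> pd.DataFrame:
    with resources.files("btexcsia.data").joinpath("benzene_reference.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_table(path=None) -> list[ReferenceEntry]:
    """Load the packaged reference database (or a user file, same format)."""
    df = pd.read_csv(path, sep="\t") if path is not None else _resource_df()
    return [
        ReferenceEntry(
            culture_label=row.culture_label,
            culture_type=row.culture_type,
            condition=row.condition,
            initial_benzene_uM=float(row.initial_benzene_uM),
            epsilon_C=float(row.epsilon_C_permil),
            epsilon_C_ci95=float(row.epsilon_C_ci95),
            epsilon_C_r2=float(row.epsilon_C_r2),
            epsilon_H=float(row.epsilon_H_permil),
            epsilon_H_ci95=float(row.epsilon_H_ci95),
            epsilon_H_r2=float(row.epsilon_H_r2),
            source=row.source,
        )
        for row in df.itertuples(index=False)
    ]


def classify_redox(
    lambda_value: float, ci95_half_width: Optional[float] = None
) -> RedoxClassification:
    """Classify a dual-isotope slope by the Lambda interval rule.

    Boundaries are inclusive; values in the gap (16, 22) or outside [12, 28]
    are unclassified.  When a CI half-width is given and the interval
    [Lambda - ci, Lambda + ci] straddles any range boundary, the result is
    flagged ambiguous.
    """
    if not math.isfinite(lambda_value):
        raise ValueError("lambda must be finite")
    lo_l, lo_u = LOW_REDOX_RANGE
    hi_l, hi_u = HIGH_REDOX_RANGE
    if lo_l <= lambda_value <= lo_u:
        category = "low_redox"
        rule = (
            f"Lambda in [{lo_l:g}, {lo_u:g}]: fermenting/methanogenic/"
            "sulfate-reducing conditions"
        )
    elif hi_l <= lambda_value <= hi_u:
        category = "high_redox"
        rule = f"Lambda in [{hi_l:g}, {hi_u:g}]: nitrate-reducing conditions"
    else:
        category = "unclassified"
        rule = (
            f"Lambda outside [{hi_l:g}, {hi_u:g}] and [{lo_l:g}, {lo_u:g}]: "
            "no published interval applies"
        )
    ambiguous = False
    if ci95_half_width is not None:
        lo, hi = lambda_value - ci95_half_width, lambda_value + ci95_half_width
        for bound in (lo_l, lo_u, hi_l, hi_u):
            if lo < bound < hi:
                ambiguous = True
    return RedoxClassification(
        category=category,
        rule_applied=rule,
        lambda_value=lambda_value,
        ambiguous=ambiguous,
    )


def nearest_reference(
    eps_C: float,
    eps_H: float,
    db: Optional[list[ReferenceEntry]] = None,
    k: int = 3,
) -> list[tuple[ReferenceEntry, float]]:
    """Rank reference entries by distance to a new (eps_C, eps_H) pair.

    Euclidean distance in (eps_C, eps_H / 20) space; ties broken by table
    order.  ``k`` larger than the database returns the full ranking.
    """
    if db is None:
        db = load_reference_table()
    if not db:
        raise ValueError("reference database is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [
        (
            entry,
            math.hypot(entry.epsilon_C - eps_C, (entry.epsilon_H - eps_H) / _H_SCALE),
        )
        for entry in db
    ]
    order = sorted(range(len(scored)), key=lambda i: (scored[i][1], i))
    return [scored[i] for i in order[:k]]


def akie_biplot_points(
    db: Optional[list[ReferenceEntry]] = None,
    pos: PositionParams = BENZENE_POSITIONS,
) -> list[dict]:
    """(AKIE_C, AKIE_H) for every database entry, for the redox biplot.

    Entries whose eps pair leaves the AKIE domain are flagged (``akie_C`` /
    ``akie_H`` set to None) rather than aborting the export.
    """
    if db is None:
        db = load_reference_table()
    points = []
    for entry in db:
        point = {"entry": entry, "akie_C": None, "akie_H": None, "flagged": False}
        for element, eps in (("C", entry.epsilon_C), ("H", entry.epsilon_H)):
            try:
                point[f"akie_{element}"] = akie(eps, pos).akie
            except ValueError:
                point["flagged"] = True
        points.append(point)
    return points
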
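"""Degradation-monitoring bookkeeping for microcosm time series.

Residual percentages are expressed against the abiotic control flask,
optionally double-normalized to a non-degraded internal standard (o-xylene)
so that shared physical losses — septa absorption, sampling withdrawal —
cancel:

    residual% = 100 * (C_t / IS_t) / (C_c,t / IS_c,t)

Lag detection, halt (inhibition) detection and biomass doubling time are
simple operational rules over those curves; anaerobic BTEX microcosms
typically show lag phases of tens to >100 days before first-order removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .isotope_core import IsotopeDomainError, IsotopeSeries

__all__ = [
    "ResidualCurve",
    "KineticsSummary",
    "residual_percentage",
    "detect_lag",
    "detect_halt",
    "doubling_time",
    "summarize_kinetics",
]


@dataclass(frozen=True)
class ResidualCurve:
    compound: str
    times: tuple[float, ...]
    residual_pct: tuple[float, ...]
    normalization: str  # control_only | control_and_internal_std

    def __post_init__(self) -> None:
        if len(self.times) != len(self.residual_pct):
            raise ValueError("times and residual_pct lengths differ")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(r < 0 for r in self.residual_pct):
            raise ValueError("residual_pct must be >= 0")


@dataclass(frozen=True)
class KineticsSummary:
    """Per-compound monitoring summary.

    ``out_of_range`` flags a removal extent that measurement noise pushed
    outside [0, 100]; the value itself is reported unclipped.
    """

    compound: str
    lag_days: Optional[float]
    removal_extent_pct: float
    halted: bool
    halt_time: Optional[float] = None
    halt_extent_pct: Optional[float] = None
    out_of_range: bool = False


def residual_percentage(
    series: IsotopeSeries,
    control: IsotopeSeries,
    internal_std_compound: Optional[str] = None,
) -> ResidualCurve:
    """Control-normalized residual percentage curve for one compound.

    Live and control flasks must be sampled on exactly matching times (no
    interpolation).  When ``internal_std_compound`` is given, both flasks must
    carry ``conc_internal_std`` at every time and the double normalization is
    applied; the argument records which compound anchors it.
    """
    ctrl_by_time = {m.time: m for m in control.measurements}
    times, residuals = [], []
    for m in series.measurements:
        if m.time not in ctrl_by_time:
            raise ValueError(
                f"{series.compound}: no control measurement at t = {m.time} days"
            )
        c = ctrl_by_time[m.time]
        if c.conc <= 0:
            raise IsotopeDomainError(
                f"{series.compound}: control concentration is 0 at t = {m.time}"
            )
        if internal_std_compound is None:
            r = 100.0 * m.conc / c.conc
        else:
            if m.conc_internal_std is None or c.conc_internal_std is None:
                raise ValueError(
                    f"{series.compound}: internal-standard concentration missing "
                    f"at t = {m.time} (did you call attach_internal_standard?)"
                )
            if m.conc_internal_std <= 0 or c.conc_internal_std <= 0:
                raise IsotopeDomainError(
                    f"{series.compound}: internal-standard concentration is 0 "
                    f"at t = {m.time}"
                )
            r = 100.0 * (m.conc / m.conc_internal_std) / (
                c.conc / c.conc_internal_std
            )
        times.append(m.time)
        residuals.append(r)
    return ResidualCurve(
        compound=series.compound,
        times=tuple(times),
        residual_pct=tuple(residuals),
        normalization=(
            "control_only"
            if internal_std_compound is None
            else "control_and_internal_std"
        ),
    )


def detect_lag(
    curve: ResidualCurve, threshold_pct: float = 5.0, sustain_points: int = 2
) -> Optional[float]:
    """First sampled time at which removal is under way and sustained.

    Returns the first time whose residual is below (100 - threshold) and
    stays below for ``sustain_points`` consecutive samples (including
    itself); None when degradation never starts.
    """
    if len(curve.times) < sustain_points + 1:
        raise ValueError(
            f"need at least {sustain_points + 1} points, got {len(curve.times)}"
        )
    cutoff = 100.0 - threshold_pct
    r = curve.residual_pct
    for i in range(len(r) - sustain_points + 1):
        window = r[i : i + sustain_points]
        if all(v < cutoff for v in window):
            return curve.times[i]
    return None


def detect_halt(
    curve: ResidualCurve,
    window_points: int = 3,
    slope_tol: float = 0.05,
    onset_threshold_pct: float = 5.0,
    residual_floor_pct: float = 5.0,
) -> tuple[bool, Optional[float], Optional[float]]:
    """Detect a halted (inhibited) removal as a flat trailing plateau.

    Scans trailing windows of ``window_points`` samples after removal has
    begun (extent > ``onset_threshold_pct``); a halt is the earliest window
    whose fitted slope magnitude is <= ``slope_tol`` %/day while the residual
    still exceeds ``residual_floor_pct`` (a curve flat at ~0% is complete
    removal, not a halt).  Returns (halted, halt_time, halt_extent_pct); with
    fewer than ``window_points`` post-onset samples, (False, None, None).
    """
    t = np.asarray(curve.times, dtype=float)
    r = np.asarray(curve.residual_pct, dtype=float)
    n = len(t)
    for i in range(n - window_points + 1):
        tw, rw = t[i : i + window_points], r[i : i + window_points]
        started = 100.0 - rw.mean() > onset_threshold_pct
        if not started:
            continue
        slope = np.polyfit(tw, rw, 1)[0]
        if abs(slope) <= slope_tol and rw.mean() > residual_floor_pct:
            return True, float(tw[0]), float(100.0 - rw.mean())
    return False, None, None


def doubling_time(n1: float, n2: float, dt: float) -> float:
    """Exponential-growth doubling time (days) between two cell counts."""
    if n1 <= 0 or n2 <= 0 or dt <= 0:
        raise IsotopeDomainError("counts and interval must be positive")
    if n2 <= n1:
        raise IsotopeDomainError("no growth: n2 must exceed n1")
    return dt * math.log(2.0) / math.log(n2 / n1)


def summarize_kinetics(
    curve: ResidualCurve,
    lag_threshold_pct: float = 5.0,
    sustain_points: int = 2,
    halt_window_points: int = 3,
    halt_slope_tol: float = 0.05,
) -> KineticsSummary:
    """Lag, removal extent and halt status for one residual curve."""
    lag = detect_lag(curve, lag_threshold_pct, sustain_points)
    extent = 100.0 - curve.residual_pct[-1]
    halted, halt_time, halt_extent = detect_halt(
        curve, halt_window_points, halt_slope_tol
    )
    return KineticsSummary(
        compound=curve.compound,
        lag_days=lag,
        removal_extent_pct=extent,
        halted=halted,
        halt_time=halt_time,
        halt_extent_pct=halt_extent,
        out_of_range=not (0.0 <= extent <= 100.0),
    )
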
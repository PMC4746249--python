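"""Rayleigh-model enrichment factors and apparent kinetic isotope effects.

In a closed system the isotope ratio of the residual substrate obeys the
Rayleigh distillation law R_t/R_0 = f**(eps/1000) with f = C_t/C_0.  Its
logarithmic form

    ln(R_t/R_0) = (eps/1000) * ln(C_t/C_0)

is linear and exact, so the bulk enrichment factor eps (permil) is estimated
as 1000 times the ordinary least-squares slope of ln(R_t/R_0) on ln f.  The
bulk factor is diluted by atoms that do not take part in the bond change;
scaling to the reactive position and correcting for intramolecular
competition among z equivalent positions gives the apparent kinetic isotope
effect

    AKIE = 1 / (1 + z * eps_reactive_position / 1000).

For benzene all six carbons (and six hydrogens) are equivalent potential
reaction sites, so z = n_total = x_reactive = 6 and the position correction
is the identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .isotope_core import IsotopeDomainError, IsotopeSeries, ratio_factor

__all__ = [
    "RayleighFit",
    "PositionParams",
    "BENZENE_POSITIONS",
    "AkieResult",
    "rayleigh_points",
    "fit_rayleigh",
    "epsilon_reactive_position",
    "akie",
]


@dataclass(frozen=True)
class RayleighFit:
    """Result of a linearized Rayleigh regression.

    ``epsilon_bulk`` is in permil (negative for a normal kinetic isotope
    effect); ``ci95_half_width`` is the two-sided 95% half-width from the
    t-distribution on the slope standard error; ``intercept`` is a diagnostic
    (0 when the origin is forced).
    """

    element: str
    epsilon_bulk: float
    ci95_half_width: float
    r_squared: float
    n_points: int
    intercept: float
    forced_origin: bool

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.ci95_half_width < 0:
            raise ValueError("ci95_half_width must be >= 0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class PositionParams:
    """Atom bookkeeping for the position-specific correction.

    z: atoms of the element in identical reactive positions (intramolecular
    competition); n_total: atoms of the element in the molecule; x_reactive:
    atoms at the reactive site.  Benzene defaults: all six equivalent.
    """

    z: int = 6
    n_total: int = 6
    x_reactive: int = 6

    def __post_init__(self) -> None:
        if not (1 <= self.x_reactive <= self.n_total):
            raise ValueError("need 1 <= x_reactive <= n_total")
        if not (1 <= self.z <= self.x_reactive):
            raise ValueError("need 1 <= z <= x_reactive")


BENZENE_POSITIONS = PositionParams(z=6, n_total=6, x_reactive=6)


@dataclass(frozen=True)
class AkieResult:
    """Apparent kinetic isotope effect with a transformed 95% half-width."""

    akie: float
    ci95_half_width: float
    epsilon_reactive_position: float

    def __post_init__(self) -> None:
        if self.akie <= 0:
            raise ValueError("AKIE must be positive")


def rayleigh_points(
    series: IsotopeSeries, element: str
) -> tuple[np.ndarray, np.ndarray]:
    """(ln f, ln R_t/R_0) pairs for the double-log Rayleigh plot.

    Uses every measurement carrying both a concentration and the element's
    delta; the t0 point contributes exactly (0, 0).
    """
    t0 = series.t0
    d0 = t0.delta(element)
    if d0 is None:
        raise IsotopeDomainError(f"t0 measurement lacks a {element} delta")
    ms = series.complete_for(element)
    if any(m.conc <= 0 for m in ms):
        raise IsotopeDomainError("all concentrations must be > 0 (log undefined)")
    ln_f = np.array([math.log(m.conc / t0.conc) for m in ms])
    ln_r = np.array([math.log(ratio_factor(m.delta(element), d0)) for m in ms])
    return ln_f, ln_r


def _slope_fit(x: np.ndarray, y: np.ndarray, forced_origin: bool):
    """OLS of y on x; returns (slope, slope 95% half-width, R^2, intercept)."""
    if forced_origin:
        model = sm.OLS(y, x[:, None]).fit()
        slope = float(model.params[0])
        intercept = 0.0
    else:
        model = sm.OLS(y, sm.add_constant(x)).fit()
        intercept = float(model.params[0])
        slope = float(model.params[1])
    lo, hi = model.conf_int(alpha=0.05)[-1]
    half = float((hi - lo) / 2.0)
    if not math.isfinite(half):
        half = float("inf")
    r2 = float(model.rsquared)  # uncentered when origin is forced
    if not math.isfinite(r2):
        # constant response: R^2 undefined; a zero-residual fit is perfect
        r2 = 1.0 if model.ssr < 1e-24 else 0.0
    return slope, half, min(max(r2, 0.0), 1.0), intercept


def fit_rayleigh(
    series: IsotopeSeries, element: str, forced_origin: bool = False
) -> RayleighFit:
    """Fit the linearized Rayleigh model for one element.

    Free-intercept OLS by default (the intercept is reported as a
    diagnostic); with ``forced_origin`` the regression is constrained through
    (0, 0).  Requires >= 3 complete points (>= 2 when the origin is forced).
    """
    x, y = rayleigh_points(series, element)
    n_min = 2 if forced_origin else 3
    if len(x) < n_min:
        raise ValueError(
            f"fit_rayleigh needs >= {n_min} points with conc and "
            f"delta {element}; got {len(x)}"
        )
    if np.ptp(x) == 0:
        raise IsotopeDomainError("zero variance in ln f; slope undefined")
    slope, half, r2, intercept = _slope_fit(x, y, forced_origin)
    return RayleighFit(
        element=element,
        epsilon_bulk=slope * 1000.0,
        ci95_half_width=half * 1000.0,
        r_squared=r2,
        n_points=len(x),
        intercept=intercept,
        forced_origin=forced_origin,
    )


def epsilon_reactive_position(fit: RayleighFit | float, pos: PositionParams) -> float:
    """Scale a bulk enrichment factor to the reactive position.

    eps_rp = (n_total / x_reactive) * eps_bulk.  Accepts a
    :class:`RayleighFit` or a bare eps_bulk in permil.  With benzene defaults
    (n = x = 6) this is the identity.
    """
    eps_bulk = fit.epsilon_bulk if isinstance(fit, RayleighFit) else float(fit)
    return (pos.n_total / pos.x_reactive) * eps_bulk


def akie(
    epsilon_rp: float,
    pos: PositionParams = BENZENE_POSITIONS,
    ci95_half_width: float = 0.0,
) -> AkieResult:
    """AKIE = 1/(1 + z*eps_rp/1000) with a transformed confidence interval.

    The CI is obtained by pushing eps_rp +/- ci95_half_width through the same
    transform and taking the larger of the two (asymmetric) half-widths.
    """
    denom = 1.0 + pos.z * epsilon_rp / 1000.0
    if denom <= 0:
        raise IsotopeDomainError(
            f"AKIE undefined: 1 + z*eps_rp/1000 = {denom:.6g} <= 0"
        )
    value = 1.0 / denom
    half = 0.0
    if ci95_half_width:
        halves = []
        for eps in (epsilon_rp - ci95_half_width, epsilon_rp + ci95_half_width):
            d = 1.0 + pos.z * eps / 1000.0
            if d > 0:
                halves.append(abs(1.0 / d - value))
            else:
                halves.append(float("inf"))
        half = max(halves)
    return AkieResult(
        akie=value, ci95_half_width=half, epsilon_reactive_position=epsilon_rp
    )
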
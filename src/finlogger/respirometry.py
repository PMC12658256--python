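"""Swim-tunnel respirometry: MO2, cost of transport, and optimal speed.

Oxygen consumption is computed from the percent-saturation decline while
the tunnel valves are closed,

    MO2 = dO2% * (DOmax * L / 100) / t        [mg O2 / h]

with DOmax the dissolved-oxygen ceiling (mg O2/L), L the tunnel volume
(L) and t the elapsed time in hours.  dO2% is estimated as the fitted
linear decline over the measurement window (more noise-resistant than
an endpoint difference) and corrected for background (bacterial)
consumption measured without fish.  The cost of transport is
COT = MO2 / dd with dd the distance covered in km, i.e. the
mass-specific MO2 divided by the speed in km/h.  Per individual, a
quadratic fit of COT against flow speed yields the optimal swimming
speed U_opt (derivative zero) and the minimum cost COT_min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NoMinimum
from .synthetic import O2Trace

SPEED_RANGE_MPS = (0.2, 1.0)  # ladder of tested flow speeds


@dataclass
class RespirometryResult:
    """MO2 and COT for one individual at one flow speed."""

    mo2_abs: float  # mg O2 / h, background-corrected
    mo2_mass_specific: float  # mg O2 / kg / h
    mo2_se: float  # standard error propagated from the slope fit
    cot: float | None  # mg O2 / kg / km, None until a speed is applied
    flow_speed: float | None  # m/s
    body_mass: float  # kg
    flagged_negative: bool = False


@dataclass
class EnduranceEstimate:
    """Optimal swimming speed and minimum cost of transport."""

    uopt_mps: float
    cot_min: float
    poly_coeffs: np.ndarray  # highest degree first
    r_squared: float | None = None
    uopt_bls: float | None = None
    extrapolated: bool = False


def compute_mo2(
    trace: O2Trace,
    background_rate: float = 0.0,
    body_mass: float = 0.391,
    window_h: tuple[float, float] | None = None,
) -> RespirometryResult:
    """Oxygen consumption from a closed-tunnel %-saturation decline.

    ``background_rate`` (mg O2/h) is subtracted from the raw rate;
    ``body_mass`` is in kg.  ``window_h`` optionally restricts the fit
    to a sub-window of the trace (hours).  A corrected rate below zero
    is clamped-free but flagged; a rising trace triggers a warning.
    """
    t = np.asarray(trace.time_h, dtype=float)
    o2 = np.asarray(trace.o2_percent, dtype=float)
    if window_h is not None:
        sel = (t >= window_h[0]) & (t <= window_h[1])
        t, o2 = t[sel], o2[sel]
    if t.size < 2 or t[-1] - t[0] <= 0:
        raise ValueError("need at least 2 samples spanning a positive duration")
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    # least-squares slope in %/h
    coeffs, cov = np.polyfit(t, o2, 1, cov=(t.size > 2))if t.size > 2 else \
        (np.polyfit(t, o2, 1), None)
    slope = coeffs[0]
    slope_se = float(np.sqrt(cov[0, 0])) if cov is not None else 0.0
    decline = -slope  # %/h consumed
    if decline < -1e-9:
        warnings.warn("oxygen trace rises over the window; MO2 set from "
                      "the (negative) decline", stacklevel=2)
    factor = trace.do_max * trace.volume / 100.0  # mg O2 per %-saturation
    mo2_abs = decline * factor - background_rate
    flagged = mo2_abs < -1e-9
    if flagged:
        warnings.warn("background-corrected MO2 is negative; result flagged",
                      stacklevel=2)
    return RespirometryResult(
        mo2_abs=mo2_abs,
        mo2_mass_specific=mo2_abs / body_mass,
        mo2_se=slope_se * factor,
        cot=None,
        flow_speed=None,
        body_mass=body_mass,
        flagged_negative=flagged,
    )


def compute_cot(result: RespirometryResult, flow_speed: float) -> RespirometryResult:
    """Cost of transport at a given flow speed (m/s).

    COT = mass-specific MO2 / speed-in-km/h, i.e. oxygen per kg per km
    covered.  Undefined at zero or negative speed.
    """
    if flow_speed <= 0:
        raise ValueError("COT is undefined at non-positive flow speed")
    speed_kmh = flow_speed * 3.6
    result.cot = result.mo2_mass_specific / speed_kmh
    result.flow_speed = flow_speed
    return result


def fit_cot_curve(speeds, cots, degree: int = 2):
    """Least-squares polynomial of COT against flow speed, plus R^2."""
    speeds = np.asarray(speeds, dtype=float)
    cots = np.asarray(cots, dtype=float)
    if np.unique(speeds).size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct speeds for degree {degree}"
        )
    coeffs = np.polyfit(speeds, cots, degree)
    fitted = np.polyval(coeffs, speeds)
    ss_res = float(np.sum((cots - fitted) ** 2))
    ss_tot = float(np.sum((cots - cots.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coeffs, r2


def optimal_speed(coeffs, r_squared: float | None = None,
                  speed_range: tuple[float, float] = SPEED_RANGE_MPS
                  ) -> EnduranceEstimate:
    """U_opt and COT_min from a fitted quadratic (derivative = 0).

    Requires a convex quadratic (positive leading coefficient); raises
    :class:`NoMinimum` otherwise.  Estimates outside the tested speed
    range are flagged as extrapolated.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size != 3:
        raise ValueError("optimal_speed expects quadratic coefficients (a, b, c)")
    a, b, c = coeffs
    if a <= 0:
        raise NoMinimum("COT curve is not convex: no interior minimum")
    uopt = -b / (2 * a)
    cot_min = c - b * b / (4 * a)
    return EnduranceEstimate(
        uopt_mps=uopt,
        cot_min=cot_min,
        poly_coeffs=coeffs,
        r_squared=r_squared,
        extrapolated=not (speed_range[0] <= uopt <= speed_range[1]),
    )


def to_body_lengths(speed_mps: float, standard_length_cm: float) -> float:
    """Convert m/s to body lengths per second given SL in cm."""
    if standard_length_cm <= 0:
        raise ValueError("standard_length_cm must be > 0")
    return speed_mps * 100.0 / standard_length_cm
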
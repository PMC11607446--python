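"""Water-vapor equilibration kinetics.

During the 48 h incubation, isotopically enriched source water at the bottom
of the headspace vial equilibrates with soil water through the vapor phase.
The soil-water enrichment follows a saturating exponential

    X(t) = X_end + (X_start - X_end) * exp(-b t)

with a soil-specific rate constant b (h^-1). Because the flux equations need
the enrichment the organisms actually experienced over the whole incubation,
the tracer denominator is the time average of X over [0, window].

Soil-water enrichment is not measured directly: it is derived from the label
lost by the source-water pool via two-pool mass balance (label is conserved;
fractionation over 48 h is neglected).
"""
from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
from scipy import optimize

from .errors import DataError, FitError, MassBalanceError
from .types import EquilibrationFit, WaterObservation

__all__ = [
    "source_loss_to_soil_atpct",
    "fit_equilibration",
    "average_enrichment",
    "exponential_curve",
]

B_MIN = 1e-6   # h^-1, lower bound for the rate constant
B_MAX = 1e3    # h^-1, upper bound
FLAT_ATPCT_TOL = 1e-9  # at% spread below which a series is treated as flat


def exponential_curve(t, at_start: float, at_end: float, b: float):
    """Evaluate X(t) = at_end + (at_start - at_end) exp(-b t)."""
    return at_end + (at_start - at_end) * np.exp(-b * np.asarray(t, dtype=float))


def source_loss_to_soil_atpct(
    source_series: Sequence[WaterObservation],
    source_mass: float,
    soil_water_mass: float,
    soil_nat_atpct: float,
) -> list[WaterObservation]:
    """Derive the soil-water enrichment series from source-water label loss.

    Two-pool conservation: every at%-gram of heavy isotope leaving the source
    reservoir appears in soil water, so

        soil at%(t) = soil_nat + (source_mass / soil_water_mass)
                      * (source at%(0) - source at%(t)).

    Raises
    ------
    MassBalanceError
        A computed soil at% below natural abundance or outside (0, 100),
        signalling inconsistent pool masses.
    DataError
        Empty series or series not starting at t = 0.
    """
    if source_mass <= 0 or soil_water_mass <= 0:
        raise MassBalanceError("pool masses must be > 0")
    series = sorted(source_series, key=lambda o: o.time)
    if not series:
        raise DataError("empty source series")
    if series[0].time != 0:
        raise DataError("source series must start at t = 0")
    at0 = series[0].atom_percent
    ratio = source_mass / soil_water_mass
    out = []
    for obs in series:
        soil_at = soil_nat_atpct + ratio * (at0 - obs.atom_percent)
        if soil_at < soil_nat_atpct - 1e-12 or not 0 < soil_at < 100:
            raise MassBalanceError(
                f"soil at% {soil_at:.6g} at t={obs.time} h is unphysical; "
                "check source/soil water masses"
            )
        out.append(WaterObservation(time=obs.time, atom_percent=soil_at))
    return out


def _initial_b(t: np.ndarray, x: np.ndarray, x0: float, xinf: float) -> float:
    """Log-linearized starting value for the rate constant."""
    span = x0 - xinf
    if span == 0:
        return 0.1
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - xinf) / span
        mask = (z > 1e-12) & (t > 0)
        if mask.sum() >= 1:
            slopes = -np.log(z[mask]) / t[mask]
            b0 = float(np.median(slopes))
            if math.isfinite(b0) and b0 > 0:
                return min(max(b0, B_MIN), B_MAX)
    return 0.1


def fit_equilibration(
    series: Sequence[WaterObservation], window: float = 48.0
) -> EquilibrationFit:
    """Least-squares fit of the saturating exponential to a water series.

    Requires at least three observations spanning t = 0 to t = window. A flat
    series (no identifiable rate) returns at_start == at_end flagged
    ``degenerate`` instead of failing.

    Raises
    ------
    DataError
        Fewer than 3 points, or anchors at 0 / window missing.
    FitError
        Optimizer failure; carries the initial guess and residuals.
    """
    obs = sorted(series, key=lambda o: o.time)
    if len(obs) < 3:
        raise DataError(f"need >= 3 observations, got {len(obs)}")
    t = np.array([o.time for o in obs])
    x = np.array([o.atom_percent for o in obs])
    if t[0] > 1e-9 or t[-1] < window - 1e-9:
        raise DataError("series must include observations at t = 0 and t = window")

    if np.ptp(x) < FLAT_ATPCT_TOL:
        val = float(np.mean(x))
        return EquilibrationFit(
            at_start=val, at_end=val, b=0.0, window=window,
            average_atpct=val, degenerate=True,
        )

    x0_guess, xinf_guess = float(x[0]), float(x[-1])
    b0 = _initial_b(t, x, x0_guess, xinf_guess)
    p0 = (x0_guess, xinf_guess, b0)
    lo_x, hi_x = min(x.min(), 0.0), x.max() * 2 + 1
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a0, ainf, b: exponential_curve(tt, a0, ainf, b),
            t, x, p0=p0,
            bounds=([lo_x, lo_x, B_MIN], [hi_x, hi_x, B_MAX]),
            xtol=1e-12, ftol=1e-14, gtol=1e-12, maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        resid = x - exponential_curve(t, *p0)
        raise FitError(f"equilibration fit failed: {exc}", initial_guess=p0,
                       residuals=resid) from exc
    at_start, at_end, b = (float(v) for v in popt)
    resid = x - exponential_curve(t, at_start, at_end, b)
    dof = max(len(obs) - 3, 1)
    fit = EquilibrationFit(
        at_start=at_start, at_end=at_end, b=b, window=window,
        average_atpct=_closed_form_average(at_start, at_end, b, window),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )
    return fit


def _closed_form_average(at_start: float, at_end: float, b: float, window: float) -> float:
    """Time average of the exponential over [0, window], closed form.

    integral X dt / W = at_end + (at_start - at_end) (1 - e^(-bW)) / (bW);
    the b -> 0 limit is the midpoint-free limit at_start.
    """
    bw = b * window
    if bw < 1e-12:
        return at_start
    if bw > 700:  # exp underflow; plateau reached immediately
        factor = 1.0 / bw
    else:
        factor = (1.0 - math.exp(-bw)) / bw
    return at_end + (at_start - at_end) * factor


def average_enrichment(fit: EquilibrationFit) -> float:
    """Time-averaged soil-water at% over [0, window] (the tracer denominator)."""
    return _closed_form_average(fit.at_start, fit.at_end, fit.b, fit.window)
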
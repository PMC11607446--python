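"""Community physiology: respiration, carbon uptake, CUE and turnover.

Respiration comes from the headspace CO2 increase over the incubation via the
ideal gas law. Carbon use efficiency partitions uptake between anabolism and
catabolism, CUE = growth / (growth + respiration), and turnover time is the
reciprocal of the daily mass-specific growth rate:

    T (days) = Microbial BM C / (growth * 24)

with growth as an hourly rate, so biomass C divided by daily biomass C
production.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import UndefinedRatioError
from .types import HeadspaceReading, PhysioResult, SampleMeta, Tracer

logger = logging.getLogger(__name__)

__all__ = [
    "respiration_rate",
    "cue",
    "turnover_days",
    "assemble_physiology",
    "RespirationResult",
]

R_GAS = 8.314462618   # J mol^-1 K^-1
C_MOLAR_NG = 12.011e9  # ng C per mol
UG_TO_NG = 1000.0
# Negative headspace CO2 change larger than this (ppm) is flagged as a
# suspected leak; the rate is still returned.
LEAK_TOLERANCE_PPM = 5.0


@dataclass(frozen=True)
class RespirationResult:
    rate: float  # ng C g^-1 dry soil h^-1
    leak_suspected: bool


def respiration_rate(r: HeadspaceReading, meta: SampleMeta) -> RespirationResult:
    """Soil respiration from the headspace CO2 change (ng C g^-1 dry soil h^-1).

    ppm is treated as umol CO2 per mol of headspace gas at vial pressure:
    mol CO2 = P V dppm 1e-6 / (R T); carbon mass via 12.011 g mol^-1.
    """
    delta_ppm = r.co2_t1 - r.co2_t0
    leak = delta_ppm < -LEAK_TOLERANCE_PPM
    if leak:
        logger.warning(
            "sample %s: headspace CO2 decreased by %.1f ppm; leak suspected",
            r.sample_id, -delta_ppm,
        )
    t_kelvin = r.temperature + 273.15
    mol_co2 = r.pressure * (r.headspace_volume * 1e-6) * (delta_ppm * 1e-6) / (
        R_GAS * t_kelvin
    )
    rate = mol_co2 * C_MOLAR_NG / meta.soil_dry_mass / r.elapsed
    return RespirationResult(rate=rate, leak_suspected=leak)


def cue(growth: float, respiration: float) -> float:
    """Carbon use efficiency: growth / (growth + respiration).

    Invariant to simultaneous rescaling of both rates.

    Raises
    ------
    UndefinedRatioError
        growth + respiration == 0.
    """
    total = growth + respiration
    if total == 0:
        raise UndefinedRatioError("CUE undefined: growth + respiration is zero")
    return growth / total


def turnover_days(biomass_c: float, growth: float) -> float:
    """Community turnover time in days: biomass C / daily biomass C production.

    ``biomass_c`` in ug C g^-1; ``growth`` in ng C g^-1 h^-1. Equivalently the
    reciprocal of the daily mass-specific growth rate.

    Raises
    ------
    UndefinedRatioError
        growth <= 0 (turnover undefined for a non-growing community).
    """
    if growth <= 0:
        raise UndefinedRatioError("turnover undefined for growth <= 0")
    return biomass_c * UG_TO_NG / (growth * 24.0)


def assemble_physiology(
    sample_id: str,
    tracer: Tracer,
    growth: float,
    respiration: float,
    meta: SampleMeta,
) -> PhysioResult:
    """Combine a growth rate and a respiration rate into one physiology record."""
    mass_specific_day = (
        growth / (meta.microbial_biomass_c * UG_TO_NG) * 24.0
        if meta.microbial_biomass_c > 0
        else float("nan")
    )
    turnover = (
        turnover_days(meta.microbial_biomass_c, growth) if growth > 0 else float("nan")
    )
    return PhysioResult(
        sample_id=sample_id,
        tracer=tracer,
        growth=growth,
        respiration=respiration,
        uptake=growth + respiration,
        cue=cue(growth, respiration),
        turnover_days=turnover,
        mass_specific_growth=mass_specific_day,
    )
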
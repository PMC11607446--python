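"""18O-into-DNA tracer calculus.

DNA production follows the same excess-enrichment kernel as the lipid path,
scaled by the average oxygen mass fraction of DNA (31.21%):

    DNA_produced = O_DNA_extract * (at%_labelled - at%_natural) / at%_soil_water
                   * 100 / oxygen_fraction_pct            [ug DNA g^-1 dry soil]

No assimilation constant is applied on the DNA path: all DNA oxygen is assumed
to derive from soil water. DNA-based growth scales the produced fraction of
the DNA pool to microbial biomass carbon per hour:

    Growth_DNA = (DNA_produced / Total DNA) * Microbial BM C / time.

Division by the incubation time makes Growth_DNA an hourly rate, so it
combines with hourly respiration into CUE; see docs/methods.md for why the
rate form is used.
"""
from __future__ import annotations

from .errors import DegenerateSampleError, DomainError
from .flux_kernel import KernelResult, excess_fraction_production
from .types import DnaSample, SampleMeta

__all__ = ["dna_produced", "growth_dna"]

UG_TO_NG = 1000.0


def dna_produced(
    s: DnaSample,
    oxygen_fraction_pct: float = 31.21,
    clamp_negative: bool = True,
) -> KernelResult:
    """DNA newly produced over the incubation (ug DNA g^-1 dry soil).

    Raises
    ------
    DomainError
        Zero/negative soil-water enrichment or oxygen fraction outside (0, 100).
    """
    if not 0 < oxygen_fraction_pct < 100:
        raise DomainError("oxygen_fraction_pct must be in (0, 100)")
    if s.soil_water_atpct <= 0:
        raise DomainError("soil-water 18O enrichment must be > 0 at%")
    res = excess_fraction_production(
        s.atpct_labelled,
        s.atpct_natural,
        s.soil_water_atpct,
        s.o_dna_extract,
        clamp_negative=clamp_negative,
    )
    scale = 100.0 / oxygen_fraction_pct
    return KernelResult(
        produced=res.produced * scale,
        fraction_new=res.fraction_new,
        clamped=res.clamped,
    )


def growth_dna(s: DnaSample, produced: float, meta: SampleMeta) -> float:
    """DNA-based community growth rate (ng C g^-1 dry soil h^-1).

    Raises
    ------
    DegenerateSampleError
        total_dna == 0.
    """
    if s.total_dna <= 0:
        raise DegenerateSampleError(f"sample {s.sample_id}: total DNA is zero")
    return (
        produced / s.total_dna * meta.microbial_biomass_c * UG_TO_NG / meta.incubation_time
    )
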
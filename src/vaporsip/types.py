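"""Domain types shared by all pipeline stages.

Validation happens at construction: a type instance is always internally
consistent, so downstream numeric code carries no defensive checks.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import ConfigError, DataError, DomainError


class Treatment(str, enum.Enum):
    AMBIENT = "ambient"
    DROUGHT = "drought"
    FUTURE = "future"
    FUTURE_DROUGHT = "future_drought"

    @property
    def is_drought(self) -> bool:
        return self in (Treatment.DROUGHT, Treatment.FUTURE_DROUGHT)

    @property
    def control(self) -> "Treatment":
        """The matching non-drought climate (ambient<->drought, future<->future_drought)."""
        if self in (Treatment.AMBIENT, Treatment.DROUGHT):
            return Treatment.AMBIENT
        return Treatment.FUTURE


class Phase(str, enum.Enum):
    DROUGHT = "drought"
    RECOVERY = "recovery"


class Fraction(str, enum.Enum):
    PLFA = "plfa"
    NLFA = "nlfa"


class Group(str, enum.Enum):
    FUNGI = "fungi"
    AMF = "amf"
    GRAM_POSITIVE = "gram_positive"
    GRAM_NEGATIVE = "gram_negative"
    ACTINOBACTERIA = "actinobacteria"
    GENERAL = "general"


class Tracer(str, enum.Enum):
    PLFA_2H = "plfa_2h"
    DNA_18O = "dna_18o"


class Isotope(str, enum.Enum):
    H2 = "2h"
    O18 = "18o"


class Pool(str, enum.Enum):
    SOURCE = "source"
    SOIL = "soil"


@dataclass(frozen=True)
class SampleMeta:
    """Incubation metadata for one soil sample.

    Masses are per gram of dry soil; ``microbial_biomass_c`` is the
    chloroform-fumigation biomass estimate in ug C g^-1 dry soil.
    """

    sample_id: str
    plot_id: str
    treatment: Treatment
    phase: Phase
    soil_dry_mass: float          # g
    microbial_biomass_c: float    # ug C g^-1 dry soil
    incubation_time: float = 48.0  # h
    temperature: float = 20.0      # degC

    def __post_init__(self):
        # accept plain strings for the closed enums
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        object.__setattr__(self, "phase", Phase(self.phase))
        if self.soil_dry_mass <= 0:
            raise DomainError(f"soil_dry_mass must be > 0, got {self.soil_dry_mass}")
        if self.incubation_time <= 0:
            raise DomainError(f"incubation_time must be > 0, got {self.incubation_time}")
        if self.microbial_biomass_c < 0:
            raise DomainError("microbial_biomass_c must be >= 0")


# Two-isotope VSMOW ratios: 2H/1H and 18O/16O.
R_VSMOW_2H = 0.00015576
R_VSMOW_18O = 0.0020052
# Average oxygen mass fraction of DNA, percent.
DNA_OXYGEN_FRACTION_PCT = 31.21
# Water-hydrogen assimilation constant for heterotrophs.
A_W_DEFAULT = 0.71


@dataclass(frozen=True)
class RunConfig:
    """Constants and toggles for one analysis run.

    ``a_w`` is the water hydrogen assimilation constant: the fraction of
    fatty-acid hydrogen drawn from ambient water during biosynthesis,
    including net fractionation. ``headspace_volume`` is the free gas volume
    of the incubation vial (27 mL glass vial minus inner-vial/soil
    displacement).
    """

    a_w: float = A_W_DEFAULT
    dna_oxygen_fraction: float = DNA_OXYGEN_FRACTION_PCT  # percent
    r_vsmow_2h: float = R_VSMOW_2H
    r_vsmow_18o: float = R_VSMOW_18O
    headspace_volume: float = 27.0 - 1.2   # mL
    internal_standard: str = "19:0"
    clamp_negative_enrichment: bool = True
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.a_w <= 1:
            raise ConfigError(f"a_w must be in (0, 1], got {self.a_w}")
        if not 0 < self.dna_oxygen_fraction < 100:
            raise ConfigError(
                f"dna_oxygen_fraction must be in (0, 100) percent, got {self.dna_oxygen_fraction}"
            )
        if self.headspace_volume <= 0:
            raise ConfigError("headspace_volume must be > 0 mL")


@dataclass(frozen=True)
class DeltaMeasurement:
    """One GC-IRMS peak: a sample compound or a bracketing standard."""

    compound: str
    delta_raw: float              # per-mil vs working reference
    peak_area: float = 1.0        # arbitrary units
    run_index: int = 0            # position in the measurement sequence
    is_standard: bool = False
    known_delta: float | None = None  # per-mil, standards only

    def __post_init__(self):
        if self.peak_area < 0:
            raise DomainError("peak_area must be >= 0")
        if self.is_standard != (self.known_delta is not None):
            raise DomainError("known_delta must be present iff is_standard")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear VSMOW normalization with an optional per-position drift term."""

    slope: float                  # dimensionless
    intercept: float              # per-mil
    drift_per_index: float = 0.0  # per-mil per run position
    residual_sd: float = 0.0      # per-mil

    def __post_init__(self):
        if not math.isfinite(self.slope) or self.slope == 0:
            raise DomainError("calibration slope must be finite and nonzero")


@dataclass(frozen=True)
class WaterObservation:
    """One water-isotope measurement in the equilibration time course."""

    time: float          # h
    atom_percent: float  # at%

    def __post_init__(self):
        if self.time < 0:
            raise DomainError("time must be >= 0 h")
        if not 0 < self.atom_percent < 100:
            raise DomainError("atom_percent must lie in (0, 100)")


@dataclass(frozen=True)
class EquilibrationFit:
    """Fitted water-vapor equilibration curve X(t) = X_inf + (X_0 - X_inf) e^(-b t).

    ``average_atpct`` is the time average of the curve over [0, window]; it is
    the tracer denominator (at% soil water) of the flux equations.
    """

    at_start: float       # at% at t = 0
    at_end: float         # at% plateau (t -> window)
    b: float              # h^-1
    window: float = 48.0  # h
    average_atpct: float = float("nan")
    degenerate: bool = False
    residual_sd: float = 0.0

    def __post_init__(self):
        if self.b < 0:
            raise DomainError("rate constant b must be >= 0")
        if self.window <= 0:
            raise DomainError("window must be > 0 h")
        lo, hi = sorted((self.at_start, self.at_end))
        if math.isfinite(self.average_atpct) and not (
            lo - 1e-9 <= self.average_atpct <= hi + 1e-9
        ):
            raise DomainError("average_atpct must lie between at_start and at_end")


@dataclass(frozen=True)
class FattyAcidRecord:
    """One fatty-acid compound in one sample and lipid fraction.

    Isotopic composition is stored in atom percent ``2H``; ``fa_c`` is the
    carbon amount of the compound in ng C g^-1 dry soil (mean of labelled and
    natural-abundance incubations).
    """

    sample_id: str
    marker: str
    fraction: Fraction
    atpct_labelled: float  # at% 2H, labelled incubation
    atpct_natural: float   # at% 2H, paired natural-abundance incubation
    fa_c: float            # ng C g^-1 dry soil

    def __post_init__(self):
        if self.fa_c < 0:
            raise DomainError("fa_c must be >= 0")
        for v in (self.atpct_labelled, self.atpct_natural):
            if not 0 < v < 100:
                raise DomainError(f"atom percent must lie in (0, 100), got {v}")


@dataclass(frozen=True)
class DnaSample:
    """Bulk-DNA 18O record for one sample."""

    sample_id: str
    o_dna_extract: float    # ug O g^-1 dry soil
    atpct_labelled: float   # at% 18O, labelled
    atpct_natural: float    # at% 18O, natural abundance
    total_dna: float        # ug DNA g^-1 dry soil
    soil_water_atpct: float  # average at% 18O of soil water over the window

    def __post_init__(self):
        if self.o_dna_extract < 0 or self.total_dna < 0:
            raise DomainError("DNA pools must be >= 0")
        if self.o_dna_extract > self.total_dna + 1e-9:
            raise DomainError("oxygen in extract cannot exceed total DNA mass")
        for v in (self.atpct_labelled, self.atpct_natural):
            if not 0 < v < 100:
                raise DomainError(f"atom percent must lie in (0, 100), got {v}")


@dataclass(frozen=True)
class HeadspaceReading:
    """Headspace CO2 concentrations at the start and end of the incubation."""

    sample_id: str
    co2_t0: float             # ppm (umol mol^-1)
    co2_t1: float             # ppm
    headspace_volume: float   # mL
    temperature: float        # degC
    elapsed: float            # h
    pressure: float = 101325.0  # Pa

    def __post_init__(self):
        if self.headspace_volume <= 0 or self.elapsed <= 0:
            raise DomainError("headspace_volume and elapsed must be > 0")
        if self.co2_t0 < 0 or self.co2_t1 < 0:
            raise DomainError("CO2 concentrations must be >= 0")


@dataclass(frozen=True)
class PhysioResult:
    """Community physiology for one sample under one tracer."""

    sample_id: str
    tracer: Tracer
    growth: float              # ng C g^-1 h^-1
    respiration: float         # ng C g^-1 h^-1
    uptake: float              # ng C g^-1 h^-1
    cue: float                 # fraction
    turnover_days: float       # d
    mass_specific_growth: float  # day^-1

    def __post_init__(self):
        if self.growth >= 0 and self.respiration >= 0 and (self.growth + self.respiration) > 0:
            if not -1e-12 <= self.cue <= 1 + 1e-12:
                raise DomainError("CUE must lie in [0, 1] for non-negative rates")
        if abs(self.uptake - (self.growth + self.respiration)) > 1e-9 * max(
            1.0, abs(self.uptake)
        ):
            raise DomainError("uptake must equal growth + respiration")


@dataclass
class PairedSample:
    """Two paired measurement vectors (e.g. labelled vs natural-abundance vials)."""

    ids: list = field(default_factory=list)
    x: list = field(default_factory=list)
    y: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.x) != len(self.y):
            raise DataError("paired vectors must have equal length")
        if len(self.x) < 2:
            raise DataError("paired t-test needs n >= 2")
        if not self.ids:
            self.ids = list(range(len(self.x)))
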
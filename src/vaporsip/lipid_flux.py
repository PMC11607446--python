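"""2H-into-fatty-acid tracer calculus.

Per-marker newly produced carbon, community PLFA-based growth, mass-specific
and group-specific rates, fungi:bacteria ratios, and NLFA storage-investment
percentages.

The central relation converts the excess 2H enrichment of a fatty acid into
the fraction of its carbon synthesized during the incubation:

    FA C_produced = (at%_labelled - at%_natural) / (a_w * at%_soil_water) * FA C

where a_w is the water-hydrogen assimilation constant (fraction of fatty-acid
H drawn from ambient water, including net fractionation; 0.71 for
heterotrophic communities) and at%_soil_water the time-averaged soil-water
enrichment from the equilibration fit. Community growth scales the produced
fraction of the total PLFA pool to microbial biomass carbon:

    Growth_PLFA = (PLFA C_produced / Total PLFA C) * Microbial BM C / time.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import DegenerateSampleError, DomainError, UndefinedRatioError
from .flux_kernel import KernelResult, excess_fraction_production
from .registry import MarkerRegistry, default_registry, normalize_marker
from .types import FattyAcidRecord, Fraction, Group, RunConfig, SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "LipidFluxResult",
    "fa_c_produced",
    "community_growth",
    "mass_specific_rates",
    "fungi_to_bacteria",
    "nlfa_storage_pct",
    "compute_lipid_fluxes",
]

UG_TO_NG = 1000.0


def fa_c_produced(
    rec: FattyAcidRecord,
    soil_water_atpct: float,
    a_w: float,
    clamp_negative: bool = True,
) -> KernelResult:
    """Newly produced C of one fatty acid over the incubation (ng C g^-1).

    Linear in 1/a_w: halving a_w exactly doubles the estimate.

    Raises
    ------
    DomainError
        soil_water_atpct <= 0 or a_w outside (0, 1].
    """
    if not 0 < a_w <= 1:
        raise DomainError(f"a_w must be in (0, 1], got {a_w}")
    return excess_fraction_production(
        rec.atpct_labelled,
        rec.atpct_natural,
        a_w * soil_water_atpct,
        rec.fa_c,
        clamp_negative=clamp_negative,
    )


@dataclass
class LipidFluxResult:
    """Lipid tracer fluxes for one sample.

    ``marker_table`` holds one row per marker x fraction with columns
    ``marker, fraction, group, fa_c, fa_c_produced, fraction_new, clamped``.
    Group rates are mass-specific PLFA production (h^-1). The community
    invariant plfa_c_produced == sum of member markers' fa_c_produced holds by
    construction.
    """

    sample_id: str
    marker_table: pd.DataFrame
    total_plfa_c: float
    plfa_c_produced: float
    total_nlfa_c: float = 0.0
    nlfa_c_produced: float = 0.0
    group_plfa_c: dict[Group, float] = field(default_factory=dict)
    group_plfa_produced: dict[Group, float] = field(default_factory=dict)
    n_clamped: int = 0

    @property
    def fraction_new(self) -> float:
        """Fraction of the PLFA pool produced during the incubation."""
        if self.total_plfa_c == 0:
            raise DegenerateSampleError(f"sample {self.sample_id}: total PLFA C is zero")
        return self.plfa_c_produced / self.total_plfa_c


def community_growth(fluxes: LipidFluxResult, meta: SampleMeta) -> float:
    """PLFA-based community growth rate (ng C g^-1 dry soil h^-1).

    The produced fraction of the PLFA pool is taken as the produced fraction
    of total microbial biomass C (ug g^-1, converted to ng) per hour.
    """
    return fluxes.fraction_new * meta.microbial_biomass_c * UG_TO_NG / meta.incubation_time


def mass_specific_rates(fluxes: LipidFluxResult, meta: SampleMeta) -> dict:
    """Community and group mass-specific growth rates.

    Returns a dict with:

    * ``community_per_hour`` — growth / biomass (mg C g^-1 microbial C h^-1,
      numerically equal to the hourly fraction-new)
    * ``community_per_day`` — the same x 24 (day^-1)
    * ``group_per_hour`` — {Group: (sum produced_g / sum FA C_g) / time}, PLFA
      markers only; a group with zero FA C is omitted with a notice, never
      reported as 0.
    """
    community_h = fluxes.fraction_new / meta.incubation_time
    group_h: dict[Group, float] = {}
    for group, fa_c in fluxes.group_plfa_c.items():
        if fa_c <= 0:
            logger.info(
                "sample %s: group %s has zero PLFA C; rate omitted",
                fluxes.sample_id, group.value,
            )
            continue
        group_h[group] = (
            fluxes.group_plfa_produced.get(group, 0.0) / fa_c / meta.incubation_time
        )
    return {
        "community_per_hour": community_h,
        "community_per_day": community_h * 24.0,
        "group_per_hour": group_h,
        "group_per_day": {g: r * 24.0 for g, r in group_h.items()},
    }


def fungi_to_bacteria(values: Mapping[Group, float]) -> float:
    """Fungi / (gram-positive sum + gram-negative) on any per-group quantity.

    The gram-positive sum includes actinobacteria; AMF and general markers are
    excluded from both numerator and denominator.

    Raises
    ------
    UndefinedRatioError
        Bacterial denominator is zero.
    """
    bacteria = (
        values.get(Group.GRAM_POSITIVE, 0.0)
        + values.get(Group.ACTINOBACTERIA, 0.0)
        + values.get(Group.GRAM_NEGATIVE, 0.0)
    )
    if bacteria <= 0:
        raise UndefinedRatioError("bacterial denominator is zero")
    return values.get(Group.FUNGI, 0.0) / bacteria


def nlfa_storage_pct(fluxes: LipidFluxResult) -> dict[Group, float]:
    """Storage investment: newly produced NLFA as a percentage of newly
    produced PLFA, per group, over markers present in *both* fractions.

    Groups whose matched PLFA production is zero are omitted with a notice
    (the percentage is undefined there).
    """
    tbl = fluxes.marker_table
    plfa = tbl[tbl["fraction"] == Fraction.PLFA.value].set_index("marker")
    nlfa = tbl[tbl["fraction"] == Fraction.NLFA.value].set_index("marker")
    shared = plfa.index.intersection(nlfa.index)
    out: dict[Group, float] = {}
    for group in Group:
        members = [m for m in shared if plfa.loc[m, "group"] == group.value]
        if not members:
            continue
        p = float(plfa.loc[members, "fa_c_produced"].sum())
        n = float(nlfa.loc[members, "fa_c_produced"].sum())
        if p <= 0:
            logger.info(
                "sample %s: group %s has zero matched PLFA production; "
                "storage percentage undefined", fluxes.sample_id, group.value,
            )
            continue
        out[group] = 100.0 * n / p
    return out


def compute_lipid_fluxes(
    records: Iterable[FattyAcidRecord],
    soil_water_atpct: float,
    config: RunConfig | None = None,
    registry: MarkerRegistry | None = None,
) -> LipidFluxResult:
    """Per-marker production and group/community sums for one sample.

    The internal standard is excluded from all sums. All records must belong
    to one sample.
    """
    config = config or RunConfig()
    registry = registry or default_registry()
    is_name = normalize_marker(config.internal_standard)

    rows = []
    sample_ids = set()
    n_clamped = 0
    for rec in records:
        marker = normalize_marker(rec.marker)
        if marker == is_name:
            continue
        sample_ids.add(rec.sample_id)
        res = fa_c_produced(
            rec, soil_water_atpct, config.a_w,
            clamp_negative=config.clamp_negative_enrichment,
        )
        n_clamped += res.clamped
        rows.append({
            "marker": marker,
            "fraction": rec.fraction.value,
            "group": registry.assign(marker).group.value,
            "fa_c": rec.fa_c,
            "fa_c_produced": res.produced,
            "fraction_new": res.fraction_new,
            "clamped": res.clamped,
        })
    if len(sample_ids) > 1:
        raise DomainError(f"records span multiple samples: {sorted(sample_ids)}")
    if not rows:
        raise DegenerateSampleError("no fatty-acid records after internal-standard exclusion")
    sample_id = sample_ids.pop()
    tbl = pd.DataFrame(rows)

    plfa = tbl[tbl["fraction"] == Fraction.PLFA.value]
    nlfa = tbl[tbl["fraction"] == Fraction.NLFA.value]
    group_c = {
        Group(g): float(s) for g, s in plfa.groupby("group")["fa_c"].sum().items()
    }
    group_prod = {
        Group(g): float(s) for g, s in plfa.groupby("group")["fa_c_produced"].sum().items()
    }
    return LipidFluxResult(
        sample_id=sample_id,
        marker_table=tbl,
        total_plfa_c=float(plfa["fa_c"].sum()),
        plfa_c_produced=float(plfa["fa_c_produced"].sum()),
        total_nlfa_c=float(nlfa["fa_c"].sum()),
        nlfa_c_produced=float(nlfa["fa_c_produced"].sum()),
        group_plfa_c=group_c,
        group_plfa_produced=group_prod,
        n_clamped=int(n_clamped),
    )
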
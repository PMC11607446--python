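"""Forward simulation of complete vapor-SIP incubation datasets.

Every pipeline stage has an exact inverse here, so the whole analysis is
testable by parameter recovery without any external data. The generator
emulates the study conditions: a two-climate x drought factorial (ambient,
drought, future, future + drought) in two phases, four plots per treatment,
48 h incubations at field temperature, soil water enriched to ~13-21 at%
through vapor-phase equilibration, drought halving bacterial mass-specific
growth while fungal growth is unchanged, and fungal storage (NLFA) synthesis
rising from ~22% of membrane-lipid (PLFA) synthesis to several hundred
percent under drought.

Noise is applied where the instruments see it: delta-space for 2H in fatty
acids (sd 4 per-mil, the bracketing-standard reproducibility), atom-percent
space for bulk-DNA 18O, ppm for headspace CO2. A log-normal plot-level
multiplier, shared by all rates of a sample, emulates plot-to-plot
variability; the same multiplier drives the lipid, DNA and respiration
responses of a sample, so tracer comparisons are exact pre-noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import atom_percent_to_delta, delta_to_atom_percent
from .equilibration import _closed_form_average, exponential_curve
from .errors import TruthError
from .io import UNIT_ATPCT
from .physiology import C_MOLAR_NG, R_GAS
from .types import (
    A_W_DEFAULT,
    DNA_OXYGEN_FRACTION_PCT,
    Group,
    Isotope,
    Phase,
    R_VSMOW_2H,
    Treatment,
)

__all__ = ["WaterCurve", "TruthParams", "SyntheticDataset", "default_truth",
           "simulate_water_series", "simulate_fame_table", "simulate_dna_table",
           "simulate_headspace", "simulate_dataset"]

SAMPLING_TIMES_H = (0.0, 3.0, 6.0, 16.0, 48.0)

# Natural-abundance atom percents of the measured pools.
NAT_2H_WATER = 0.0155
NAT_2H_PLFA = 0.0136
NAT_2H_NLFA = 0.014
NAT_18O_WATER = 0.1995
NAT_18O_DNA = 0.203

PLFA_COMPOSITION = {
    # fractional FA C per marker, summing to 1 within the PLFA fraction
    "16:0": 0.16, "17:0": 0.02, "18:0": 0.05, "18:1w9t": 0.04,
    "18:1w9c": 0.09, "18:2w6,9": 0.07, "16:1w5": 0.04,
    "i15:0": 0.06, "a15:0": 0.06, "i16:0": 0.04, "i17:0": 0.03, "a17:0": 0.03,
    "10Me16:0": 0.05, "10Me17:0": 0.02, "10Me18:0": 0.03,
    "16:1w7": 0.11, "cy17:0": 0.05, "cy19:0": 0.05,
}
# NLFAs are detectable only in fungal, AMF, one gram-negative and the
# general markers.
NLFA_COMPOSITION = {
    "18:1w9c": 0.22, "18:2w6,9": 0.18, "16:1w5": 0.14, "16:1w7": 0.10,
    "16:0": 0.20, "18:0": 0.10, "18:1w9t": 0.06,
}


@dataclass(frozen=True)
class WaterCurve:
    """Ground-truth soil-water equilibration parameters."""

    at_start: float  # at% at t = 0 (natural abundance of soil water)
    at_end: float    # at% plateau at the end of the window
    b: float         # h^-1

    def average(self, window: float = 48.0) -> float:
        return _closed_form_average(self.at_start, self.at_end, self.b, window)


def _cell(amb, drt, fut, fdr) -> dict[Treatment, float]:
    return {Treatment.AMBIENT: amb, Treatment.DROUGHT: drt,
            Treatment.FUTURE: fut, Treatment.FUTURE_DROUGHT: fdr}


@dataclass(frozen=True)
class TruthParams:
    """Ground truth for one simulated campaign (both phases).

    Mass-specific growth rates are day^-1 per microbial group; drought halves
    the bacterial groups while fungi (and AMF) are unchanged. NLFA investment
    is the ratio of group NLFA synthesis to PLFA synthesis. Respiration is the
    community rate in ng C g^-1 dry soil h^-1.
    """

    growth_per_day: dict = field(default_factory=dict)      # (Phase, Treatment) -> {Group: d^-1}
    nlfa_investment: dict = field(default_factory=dict)     # (Phase, Treatment) -> {Group: ratio}
    respiration: dict = field(default_factory=dict)         # (Phase, Treatment) -> ng C g^-1 h^-1
    water_2h: dict = field(default_factory=dict)            # (Phase, Treatment) -> WaterCurve
    water_18o: dict = field(default_factory=dict)           # (Phase, Treatment) -> WaterCurve
    biomass_c: float = 1000.0        # ug C g^-1 dry soil
    total_plfa_c: float = 40000.0    # ng C g^-1 dry soil
    total_nlfa_c: float = 12000.0    # ng C g^-1 dry soil
    total_dna: float = 10.0          # ug g^-1 dry soil
    plfa_composition: dict = field(default_factory=lambda: dict(PLFA_COMPOSITION))
    nlfa_composition: dict = field(default_factory=lambda: dict(NLFA_COMPOSITION))
    a_w_true: float = A_W_DEFAULT
    n_plots: int = 4
    soil_dry_mass: float = 0.8       # g
    incubation_time: float = 48.0    # h
    headspace_volume: float = 25.8   # mL
    co2_baseline_ppm: float = 420.0
    temperature: dict = field(
        default_factory=lambda: _cell(20.0, 20.0, 23.0, 23.0)
    )
    # noise levels
    delta_sd_permil: float = 4.0     # IRMS reproducibility for delta-2H
    atpct_18o_sd: float = 0.0005     # at% on bulk-DNA 18O
    co2_ppm_sd: float = 3.0
    water_atpct_sd: float = 0.0
    plot_sd: float = 0.12            # sd of the log-normal plot multiplier

    def __post_init__(self):
        for name, comp in (("plfa", self.plfa_composition), ("nlfa", self.nlfa_composition)):
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-12:
                raise TruthError(f"{name} marker fractions sum to {total}, not 1")
        for rates in self.growth_per_day.values():
            if any(r < 0 for r in rates.values()):
                raise TruthError("growth rates must be >= 0")

    def community_rate(self, phase: Phase, treatment: Treatment, registry) -> float:
        """PLFA-C-weighted community mass-specific growth (day^-1)."""
        rates = self.growth_per_day[(phase, treatment)]
        return sum(
            frac * rates[registry.assign(m).group]
            for m, frac in self.plfa_composition.items()
        )


def default_truth(**overrides) -> TruthParams:
    """Study-condition defaults: drought halves bacterial growth, fungal
    growth is unchanged, and fungal NLFA investment rises ~10-fold."""
    base = 1.0 / 96.0  # day^-1; ambient community turns over in ~96 days
    ambient = {g: base for g in Group}
    drought = {
        Group.FUNGI: base, Group.AMF: base,
        Group.GRAM_POSITIVE: base * 0.51, Group.GRAM_NEGATIVE: base * 0.46,
        Group.ACTINOBACTERIA: base * 0.78, Group.GENERAL: base * 0.52,
    }
    fut_drought = {
        Group.FUNGI: base, Group.AMF: base,
        Group.GRAM_POSITIVE: base * 0.47, Group.GRAM_NEGATIVE: base * 0.51,
        Group.ACTINOBACTERIA: base * 0.56, Group.GENERAL: base * 0.52,
    }
    recovery = {g: 1.0 / 91.0 for g in Group}
    growth = {
        (Phase.DROUGHT, Treatment.AMBIENT): ambient,
        (Phase.DROUGHT, Treatment.DROUGHT): drought,
        (Phase.DROUGHT, Treatment.FUTURE): dict(ambient),
        (Phase.DROUGHT, Treatment.FUTURE_DROUGHT): fut_drought,
        (Phase.RECOVERY, Treatment.AMBIENT): recovery,
        (Phase.RECOVERY, Treatment.DROUGHT): {g: 1.0 / 100.0 for g in Group},
        (Phase.RECOVERY, Treatment.FUTURE): {g: 1.0 / 87.0 for g in Group},
        (Phase.RECOVERY, Treatment.FUTURE_DROUGHT): {g: 1.0 / 92.0 for g in Group},
    }
    invest_ctrl = {Group.FUNGI: 0.22, Group.AMF: 0.20, Group.GRAM_NEGATIVE: 0.01,
                   Group.GENERAL: 0.05}
    nlfa = {
        (Phase.DROUGHT, Treatment.AMBIENT): dict(invest_ctrl),
        (Phase.DROUGHT, Treatment.DROUGHT): {
            Group.FUNGI: 2.28, Group.AMF: 1.5, Group.GRAM_NEGATIVE: 0.063,
            Group.GENERAL: 0.1,
        },
        (Phase.DROUGHT, Treatment.FUTURE): dict(invest_ctrl),
        (Phase.DROUGHT, Treatment.FUTURE_DROUGHT): {
            Group.FUNGI: 3.05, Group.AMF: 1.5, Group.GRAM_NEGATIVE: 0.05,
            Group.GENERAL: 0.1,
        },
        (Phase.RECOVERY, Treatment.AMBIENT): dict(invest_ctrl),
        (Phase.RECOVERY, Treatment.DROUGHT): dict(invest_ctrl),
        (Phase.RECOVERY, Treatment.FUTURE): dict(invest_ctrl),
        (Phase.RECOVERY, Treatment.FUTURE_DROUGHT): dict(invest_ctrl),
    }
    resp = {
        (Phase.DROUGHT, Treatment.AMBIENT): 650.0,
        (Phase.DROUGHT, Treatment.DROUGHT): 320.0,
        (Phase.DROUGHT, Treatment.FUTURE): 700.0,
        (Phase.DROUGHT, Treatment.FUTURE_DROUGHT): 340.0,
        (Phase.RECOVERY, Treatment.AMBIENT): 620.0,
        (Phase.RECOVERY, Treatment.DROUGHT): 600.0,
        (Phase.RECOVERY, Treatment.FUTURE): 900.0,
        (Phase.RECOVERY, Treatment.FUTURE_DROUGHT): 880.0,
    }
    # Plateaus chosen so the 48 h time averages land near the enrichments the
    # vapor method reaches in the field campaign (2H ~13-19 at%, 18O ~19-22).
    w2h = {
        (Phase.DROUGHT, Treatment.AMBIENT): WaterCurve(NAT_2H_WATER, 16.1, 0.12),
        (Phase.DROUGHT, Treatment.DROUGHT): WaterCurve(NAT_2H_WATER, 12.6, 0.10),
        (Phase.DROUGHT, Treatment.FUTURE): WaterCurve(NAT_2H_WATER, 18.9, 0.12),
        (Phase.DROUGHT, Treatment.FUTURE_DROUGHT): WaterCurve(NAT_2H_WATER, 15.5, 0.10),
        (Phase.RECOVERY, Treatment.AMBIENT): WaterCurve(NAT_2H_WATER, 16.1, 0.12),
        (Phase.RECOVERY, Treatment.DROUGHT): WaterCurve(NAT_2H_WATER, 16.1, 0.12),
        (Phase.RECOVERY, Treatment.FUTURE): WaterCurve(NAT_2H_WATER, 18.9, 0.12),
        (Phase.RECOVERY, Treatment.FUTURE_DROUGHT): WaterCurve(NAT_2H_WATER, 18.9, 0.12),
    }
    w18o = {
        (Phase.DROUGHT, Treatment.AMBIENT): WaterCurve(NAT_18O_WATER, 20.3, 0.25),
        (Phase.DROUGHT, Treatment.DROUGHT): WaterCurve(NAT_18O_WATER, 18.9, 0.22),
        (Phase.DROUGHT, Treatment.FUTURE): WaterCurve(NAT_18O_WATER, 21.5, 0.25),
        (Phase.DROUGHT, Treatment.FUTURE_DROUGHT): WaterCurve(NAT_18O_WATER, 19.9, 0.22),
        (Phase.RECOVERY, Treatment.AMBIENT): WaterCurve(NAT_18O_WATER, 21.9, 0.25),
        (Phase.RECOVERY, Treatment.DROUGHT): WaterCurve(NAT_18O_WATER, 20.6, 0.25),
        (Phase.RECOVERY, Treatment.FUTURE): WaterCurve(NAT_18O_WATER, 22.7, 0.25),
        (Phase.RECOVERY, Treatment.FUTURE_DROUGHT): WaterCurve(NAT_18O_WATER, 21.3, 0.25),
    }
    params = TruthParams(
        growth_per_day=growth, nlfa_investment=nlfa, respiration=resp,
        water_2h=w2h, water_18o=w18o,
    )
    return replace(params, **overrides) if overrides else params


@dataclass
class SyntheticDataset:
    """The five input tables plus the ground-truth sidecar."""

    fame: pd.DataFrame
    water: pd.DataFrame
    dna: pd.DataFrame
    headspace: pd.DataFrame
    metadata: pd.DataFrame
    truth_table: pd.DataFrame
    truth: TruthParams

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "fame": self.fame, "water": self.water, "dna": self.dna,
            "headspace": self.headspace, "metadata": self.metadata,
            "truth": self.truth_table,
        }

    def fame_records(self):
        """The fatty-acid table as validated records (at% units)."""
        from .types import FattyAcidRecord, Fraction

        return [
            FattyAcidRecord(
                sample_id=r.sample_id, marker=r.marker, fraction=Fraction(r.fraction),
                atpct_labelled=r.labelled, atpct_natural=r.natural, fa_c=r.fa_c,
            )
            for r in self.fame.itertuples()
        ]

    def sample_meta(self):
        """The metadata table as validated SampleMeta objects, keyed by id."""
        from .types import SampleMeta

        return {
            r.sample_id: SampleMeta(
                sample_id=r.sample_id, plot_id=r.plot_id, treatment=r.treatment,
                phase=r.phase, soil_dry_mass=r.soil_dry_mass,
                microbial_biomass_c=r.microbial_biomass_c,
                incubation_time=r.incubation_time, temperature=r.temperature,
            )
            for r in self.metadata.itertuples()
        }


def _phases(truth: TruthParams):
    return sorted({p for p, _ in truth.growth_per_day}, key=lambda p: p.value)


def _samples(truth: TruthParams):
    for phase in _phases(truth):
        for treatment in Treatment:
            for plot in range(1, truth.n_plots + 1):
                sid = f"{phase.value[:3]}_{treatment.value}_p{plot}"
                yield phase, treatment, plot, sid


def simulate_water_series(
    truth: TruthParams,
    seed: int,
    source_mass: float = 1.0,
    soil_water_mass: float = 0.25,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Exact exponential soil-water trajectories at the campaign's sampling
    times (0, 3, 6, 16, 48 h), with the source pool derived by two-pool mass
    balance so label is conserved exactly pre-noise."""
    rng = np.random.default_rng(seed)
    rows = []
    curves = {Isotope.H2: truth.water_2h, Isotope.O18: truth.water_18o}
    times = np.array(SAMPLING_TIMES_H)
    for isotope, by_cell in curves.items():
        for (phase, treatment), curve in by_cell.items():
            soil = exponential_curve(times, curve.at_start, curve.at_end, curve.b)
            # mass balance: label gained by soil water came out of the source
            gained = (soil - curve.at_start) * soil_water_mass / source_mass
            source0 = gained[-1] + curve.at_end * 1.2  # comfortably above the loss
            source = source0 - gained
            for rep in range(1, n_replicates + 1):
                for pool, series in (("soil", soil), ("source", source)):
                    noisy = series + rng.normal(0.0, truth.water_atpct_sd, len(series)) \
                        if truth.water_atpct_sd > 0 else series
                    for t, at in zip(times, noisy):
                        rows.append({
                            "isotope": isotope.value, "phase": phase.value,
                            "treatment": treatment.value, "replicate": f"r{rep}",
                            "pool": pool, "time_h": t, "atom_percent": at,
                        })
    return pd.DataFrame(rows)


def _plot_multipliers(truth: TruthParams, seed: int) -> dict[str, float]:
    """Log-normal plot-level effect, one multiplier per sample, mean 1."""
    rng = np.random.default_rng(seed)
    out = {}
    for *_, sid in _samples(truth):
        if truth.plot_sd > 0:
            out[sid] = float(rng.lognormal(-0.5 * truth.plot_sd**2, truth.plot_sd))
        else:
            out[sid] = 1.0
    return out


def simulate_fame_table(
    truth: TruthParams, seed: int, registry=None,
    multipliers: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Fatty-acid records with labelled and natural-abundance atom percents.

    The labelled at% is the exact inverse of the production equation:
    at%_labelled = at%_nat + f * a_w_true * mean soil-water at%, with f the
    marker's fraction-new over the incubation. Instrument noise is drawn in
    delta space (sd ``delta_sd_permil``) and converted back.
    """
    from .registry import default_registry

    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    multipliers = multipliers or _plot_multipliers(truth, seed + 1)
    rows = []
    for phase, treatment, plot, sid in _samples(truth):
        rates = truth.growth_per_day[(phase, treatment)]
        invest = truth.nlfa_investment[(phase, treatment)]
        avg_sw = truth.water_2h[(phase, treatment)].average(truth.incubation_time)
        m = multipliers[sid]
        for marker, frac_c in truth.plfa_composition.items():
            group = registry.assign(marker).group
            f_new = rates[group] / 24.0 * truth.incubation_time * m
            if f_new > 1:
                raise TruthError(
                    f"fraction-new {f_new:.3f} > 1 for {marker}: more than one "
                    "pool turnover in one incubation is unphysical here"
                )
            plfa_c = truth.total_plfa_c * frac_c
            rows.append(_fame_row(
                sid, marker, "plfa", NAT_2H_PLFA, f_new, avg_sw,
                truth, plfa_c, rng,
            ))
            if marker in truth.nlfa_composition:
                nlfa_c = truth.total_nlfa_c * truth.nlfa_composition[marker]
                produced_nlfa = f_new * plfa_c * invest.get(group, 0.0)
                f_new_nlfa = produced_nlfa / nlfa_c
                if f_new_nlfa > 1:
                    raise TruthError(f"NLFA fraction-new > 1 for {marker}")
                rows.append(_fame_row(
                    sid, marker, "nlfa", NAT_2H_NLFA, f_new_nlfa, avg_sw,
                    truth, nlfa_c, rng,
                ))
    return pd.DataFrame(rows)


def _fame_row(sid, marker, fraction, nat_at, f_new, avg_sw, truth, fa_c, rng):
    at_l = nat_at + f_new * truth.a_w_true * avg_sw
    if truth.delta_sd_permil > 0:
        d_l = atom_percent_to_delta(at_l, R_VSMOW_2H) + rng.normal(0, truth.delta_sd_permil)
        d_n = atom_percent_to_delta(nat_at, R_VSMOW_2H) + rng.normal(0, truth.delta_sd_permil)
        at_l = delta_to_atom_percent(d_l, R_VSMOW_2H)
        nat_at = delta_to_atom_percent(d_n, R_VSMOW_2H)
    return {
        "sample_id": sid, "marker": marker, "fraction": fraction,
        "units": UNIT_ATPCT, "labelled": at_l, "natural": nat_at, "fa_c": fa_c,
    }


def simulate_dna_table(
    truth: TruthParams, seed: int, registry=None,
    multipliers: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Bulk-DNA 18O records whose inversion recovers the same community
    mass-specific rate as the lipid truth (no assimilation constant on the
    DNA path). Oxygen content of the extract is exactly 31.21% of total DNA."""
    from .registry import default_registry

    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    multipliers = multipliers or _plot_multipliers(truth, seed + 1)
    rows = []
    for phase, treatment, plot, sid in _samples(truth):
        rate_day = truth.community_rate(phase, treatment, registry)
        avg_sw = truth.water_18o[(phase, treatment)].average(truth.incubation_time)
        f_new = rate_day / 24.0 * truth.incubation_time * multipliers[sid]
        at_l = NAT_18O_DNA + f_new * avg_sw
        at_n = NAT_18O_DNA
        if truth.atpct_18o_sd > 0:
            at_l += rng.normal(0, truth.atpct_18o_sd)
            at_n += rng.normal(0, truth.atpct_18o_sd)
        rows.append({
            "sample_id": sid,
            "o_dna_extract": truth.total_dna * DNA_OXYGEN_FRACTION_PCT / 100.0,
            "atpct_labelled": at_l, "atpct_natural": at_n,
            "total_dna": truth.total_dna,
        })
    return pd.DataFrame(rows)


def simulate_headspace(
    truth: TruthParams, seed: int,
    multipliers: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Headspace CO2 pairs consistent with the respiration truth through the
    ideal gas law; labelled and natural-abundance vials share the same truth
    (the label does not alter activity), so the paired label-toxicity test is
    null by construction."""
    rng = np.random.default_rng(seed)
    multipliers = multipliers or _plot_multipliers(truth, seed + 1)
    rows = []
    for phase, treatment, plot, sid in _samples(truth):
        resp = truth.respiration[(phase, treatment)] * multipliers[sid]
        t_kelvin = truth.temperature[treatment] + 273.15
        total_c_ng = resp * truth.soil_dry_mass * truth.incubation_time
        mol = total_c_ng / C_MOLAR_NG
        delta_ppm = mol * R_GAS * t_kelvin / (
            101325.0 * truth.headspace_volume * 1e-6
        ) * 1e6
        for vial in ("labelled", "natural"):
            t0 = truth.co2_baseline_ppm
            t1 = t0 + delta_ppm
            if truth.co2_ppm_sd > 0:
                t0 += rng.normal(0, truth.co2_ppm_sd)
                t1 += rng.normal(0, truth.co2_ppm_sd)
            rows.append({
                "sample_id": sid, "vial": vial, "co2_t0": t0, "co2_t1": t1,
                "headspace_volume": truth.headspace_volume,
                "temperature": truth.temperature[treatment],
                "elapsed": truth.incubation_time,
            })
    return pd.DataFrame(rows)


def simulate_dataset(truth: TruthParams | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate the five input tables plus the ground-truth sidecar.

    Child seeds for the independent noise streams are derived from ``seed``
    via :class:`numpy.random.SeedSequence`; the same seed yields a
    byte-identical dataset.
    """
    from .registry import default_registry

    truth = truth or default_truth()
    registry = default_registry()
    children = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]
    multipliers = _plot_multipliers(truth, seeds[0])

    water = simulate_water_series(truth, seeds[1])
    fame = simulate_fame_table(truth, seeds[2], registry, multipliers)
    dna = simulate_dna_table(truth, seeds[3], registry, multipliers)
    headspace = simulate_headspace(truth, seeds[4], multipliers)

    meta_rows, truth_rows = [], []
    for phase, treatment, plot, sid in _samples(truth):
        meta_rows.append({
            "sample_id": sid, "plot_id": f"{treatment.value}_p{plot}",
            "treatment": treatment.value, "phase": phase.value,
            "soil_dry_mass": truth.soil_dry_mass,
            "microbial_biomass_c": truth.biomass_c,
            "incubation_time": truth.incubation_time,
            "temperature": truth.temperature[treatment],
        })
        m = multipliers[sid]
        rate_day = truth.community_rate(phase, treatment, registry) * m
        growth = rate_day / 24.0 * truth.biomass_c * 1000.0
        resp = truth.respiration[(phase, treatment)] * m
        row = {
            "sample_id": sid, "phase": phase.value, "treatment": treatment.value,
            "plot_multiplier": m,
            "community_mass_specific_per_day": rate_day,
            "growth_ng_per_g_h": growth,
            "respiration_ng_per_g_h": resp,
            "cue": growth / (growth + resp),
            "turnover_days": 1.0 / rate_day,
        }
        for g, r in truth.growth_per_day[(phase, treatment)].items():
            row[f"rate_{g.value}_per_day"] = r * m
        for g, v in truth.nlfa_investment[(phase, treatment)].items():
            row[f"nlfa_pct_{g.value}"] = v * 100.0
        truth_rows.append(row)

    return SyntheticDataset(
        fame=fame, water=water, dna=dna, headspace=headspace,
        metadata=pd.DataFrame(meta_rows), truth_table=pd.DataFrame(truth_rows),
        truth=truth,
    )
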
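"""End-to-end orchestration: calibration -> equilibration -> fluxes ->
physiology -> summaries.

The soil-water tracer denominator is resolved per treatment: the replicate
equilibration series of a treatment are fitted individually and their time
averages averaged, and that treatment mean is applied to every sample of the
treatment. Where a phase x treatment cell has no measured series (the
recovery-phase 2H case in the field campaign), the value falls back to the
matching non-drought cell and then to the peak-drought cell, logged.

Stages log record counts to stderr with stage-tagged lines; given identical
inputs and seed the pipeline is deterministic.
"""
from __future__ import annotations

import logging
import sys
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .dna_flux import dna_produced, growth_dna
from .equilibration import fit_equilibration
from .errors import DataError, VaporSipError
from .lipid_flux import (
    community_growth,
    compute_lipid_fluxes,
    fungi_to_bacteria,
    mass_specific_rates,
    nlfa_storage_pct,
)
from .physiology import assemble_physiology, respiration_rate
from .registry import MarkerRegistry, default_registry
from .stats_summary import paired_t, treatment_contrasts, turnover_table
from .types import (
    DnaSample,
    FattyAcidRecord,
    Group,
    HeadspaceReading,
    Isotope,
    PairedSample,
    Phase,
    RunConfig,
    SampleMeta,
    Tracer,
    Treatment,
    WaterObservation,
)

logger = logging.getLogger(__name__)

__all__ = ["fit_water_table", "analyze", "run_pipeline", "load_config"]


def fit_water_table(water: pd.DataFrame, window: float = 48.0) -> pd.DataFrame:
    """Fit every (isotope, phase, treatment, replicate) soil-pool series and
    average the time-averaged enrichment per treatment cell.

    Returns one row per cell with fitted parameters of each replicate folded
    into mean values and the cell-level ``average_atpct``.
    """
    soil = water[water["pool"] == "soil"]
    if soil.empty:
        raise DataError("water table contains no soil-pool series")
    rows = []
    for (isotope, phase, treatment), cell in soil.groupby(
        ["isotope", "phase", "treatment"], sort=False
    ):
        fits = []
        for _, series in cell.groupby("replicate", sort=False):
            obs = [
                WaterObservation(time=r.time_h, atom_percent=r.atom_percent)
                for r in series.itertuples()
            ]
            fits.append(fit_equilibration(obs, window=window))
        rows.append({
            "isotope": isotope, "phase": phase, "treatment": treatment,
            "n_replicates": len(fits),
            "at_start": float(np.mean([f.at_start for f in fits])),
            "at_end": float(np.mean([f.at_end for f in fits])),
            "b": float(np.mean([f.b for f in fits])),
            "average_atpct": float(np.mean([f.average_atpct for f in fits])),
        })
    logger.info("[equilibration] fitted %d treatment cells", len(rows))
    return pd.DataFrame(rows)


def _water_lookup(fits: pd.DataFrame, isotope: Isotope):
    table = {
        (r.phase, r.treatment): r.average_atpct
        for r in fits[fits["isotope"] == isotope.value].itertuples()
    }

    def lookup(phase: Phase, treatment: Treatment) -> float:
        chain = [
            (phase.value, treatment.value),
            (phase.value, treatment.control.value),
            (Phase.DROUGHT.value, treatment.value),
            (Phase.DROUGHT.value, treatment.control.value),
        ]
        for key in chain:
            if key in table:
                if key != chain[0]:
                    logger.info(
                        "[equilibration] no %s series for %s/%s; using %s/%s",
                        isotope.value, phase.value, treatment.value, *key,
                    )
                return table[key]
        raise DataError(
            f"no {isotope.value} soil-water series resolvable for "
            f"{phase.value}/{treatment.value}"
        )

    return lookup


def analyze(
    meta: dict[str, SampleMeta],
    water: pd.DataFrame,
    fame_records: list[FattyAcidRecord] | None = None,
    dna: pd.DataFrame | None = None,
    headspace: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    registry: MarkerRegistry | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full calculus on validated inputs; returns tidy result tables.

    Lipid outputs require ``fame_records``; DNA outputs require ``dna``;
    physiology (CUE, uptake, turnover) additionally requires ``headspace``.
    Absent inputs simply omit the corresponding tables.
    """
    config = config or RunConfig()
    registry = registry or default_registry()
    results: dict[str, pd.DataFrame] = {}

    fits = fit_water_table(water)
    results["water_fits"] = fits

    respiration: dict[str, float] = {}
    if headspace is not None and len(headspace):
        resp_rows = []
        hs = headspace
        vials = hs["vial"] if "vial" in hs.columns else pd.Series("labelled", index=hs.index)
        for i, row in hs.iterrows():
            sid = str(row["sample_id"])
            m = meta[sid]
            reading = HeadspaceReading(
                sample_id=sid,
                co2_t0=float(row["co2_t0"]), co2_t1=float(row["co2_t1"]),
                headspace_volume=float(row.get("headspace_volume", config.headspace_volume)),
                temperature=float(row.get("temperature", m.temperature)),
                elapsed=float(row.get("elapsed", m.incubation_time)),
            )
            res = respiration_rate(reading, m)
            resp_rows.append({
                "sample_id": sid, "vial": vials.loc[i],
                "respiration": res.rate, "leak_suspected": res.leak_suspected,
            })
            if vials.loc[i] == "labelled":
                respiration[sid] = res.rate
        results["respiration"] = pd.DataFrame(resp_rows)
        logger.info("[physiology] %d respiration rates", len(resp_rows))

        # label-toxicity check: paired t-test of labelled vs natural vials
        rt = results["respiration"]
        if set(rt["vial"]) >= {"labelled", "natural"}:
            lab = rt[rt["vial"] == "labelled"].set_index("sample_id")["respiration"]
            nat = rt[rt["vial"] == "natural"].set_index("sample_id")["respiration"]
            shared = lab.index.intersection(nat.index)
            if len(shared) >= 2:
                try:
                    tt = paired_t(PairedSample(
                        ids=list(shared), x=list(lab.loc[shared]), y=list(nat.loc[shared]),
                    ))
                    results["label_toxicity_ttest"] = pd.DataFrame(
                        [{"t": tt.t, "df": tt.df, "p": tt.p, "n": len(shared)}]
                    )
                except VaporSipError as exc:
                    logger.info("[stats] label-toxicity t-test skipped: %s", exc)

    physio_rows = []
    response_rows = []  # long table feeding treatment contrasts

    if fame_records:
        lookup_2h = _water_lookup(fits, Isotope.H2)
        by_sample: dict[str, list[FattyAcidRecord]] = defaultdict(list)
        for rec in fame_records:
            by_sample[rec.sample_id].append(rec)
        marker_rows, group_rows, community_rows = [], [], []
        for sid, recs in by_sample.items():
            m = meta[sid]
            sw = lookup_2h(m.phase, m.treatment)
            flux = compute_lipid_fluxes(recs, sw, config, registry)
            mt = flux.marker_table.copy()
            mt.insert(0, "sample_id", sid)
            marker_rows.append(mt)
            growth = community_growth(flux, m)
            ms = mass_specific_rates(flux, m)
            for g, r in ms["group_per_day"].items():
                group_rows.append({
                    "sample_id": sid, "phase": m.phase.value,
                    "treatment": m.treatment.value, "group": g.value,
                    "mass_specific_per_day": r,
                })
                response_rows.append({
                    "phase": m.phase.value, "treatment": m.treatment.value,
                    "response": f"rate_{g.value}", "value": r,
                })
            try:
                fb = fungi_to_bacteria(ms["group_per_day"])
            except VaporSipError:
                fb = np.nan
            storage = nlfa_storage_pct(flux)
            community_rows.append({
                "sample_id": sid, "phase": m.phase.value, "treatment": m.treatment.value,
                "soil_water_atpct_2h": sw,
                "total_plfa_c": flux.total_plfa_c,
                "plfa_c_produced": flux.plfa_c_produced,
                "nlfa_c_produced": flux.nlfa_c_produced,
                "growth": growth,
                "mass_specific_per_day": ms["community_per_day"],
                "fungi_to_bacteria_rate": fb,
                "nlfa_pct_fungi": storage.get(Group.FUNGI, np.nan),
                "n_clamped": flux.n_clamped,
            })
            response_rows.append({
                "phase": m.phase.value, "treatment": m.treatment.value,
                "response": "mass_specific_growth_plfa",
                "value": ms["community_per_day"],
            })
            if not np.isnan(fb):
                response_rows.append({
                    "phase": m.phase.value, "treatment": m.treatment.value,
                    "response": "fungi_to_bacteria_rate", "value": fb,
                })
            for g, pct in storage.items():
                response_rows.append({
                    "phase": m.phase.value, "treatment": m.treatment.value,
                    "response": f"nlfa_pct_{g.value}", "value": pct,
                })
            response_rows.append({
                "phase": m.phase.value, "treatment": m.treatment.value,
                "response": "nlfa_c_produced", "value": flux.nlfa_c_produced,
            })
            if sid in respiration:
                p = assemble_physiology(sid, Tracer.PLFA_2H, growth, respiration[sid], m)
                physio_rows.append(_physio_row(p, m))
                response_rows.append({
                    "phase": m.phase.value, "treatment": m.treatment.value,
                    "response": "cue_plfa", "value": p.cue,
                })
        results["marker_fluxes"] = pd.concat(marker_rows, ignore_index=True)
        results["group_rates"] = pd.DataFrame(group_rows)
        results["lipid_community"] = pd.DataFrame(community_rows)
        logger.info("[lipid_flux] %d samples, %d marker rows",
                    len(community_rows), len(results["marker_fluxes"]))

    if dna is not None and len(dna):
        lookup_18o = _water_lookup(fits, Isotope.O18)
        dna_rows = []
        for row in dna.itertuples():
            sid = str(row.sample_id)
            m = meta[sid]
            sw = lookup_18o(m.phase, m.treatment)
            sample = DnaSample(
                sample_id=sid,
                o_dna_extract=row.o_dna_extract,
                atpct_labelled=row.atpct_labelled,
                atpct_natural=row.atpct_natural,
                total_dna=row.total_dna,
                soil_water_atpct=sw,
            )
            res = dna_produced(
                sample, config.dna_oxygen_fraction,
                clamp_negative=config.clamp_negative_enrichment,
            )
            growth = growth_dna(sample, res.produced, m)
            dna_rows.append({
                "sample_id": sid, "phase": m.phase.value, "treatment": m.treatment.value,
                "soil_water_atpct_18o": sw,
                "dna_produced": res.produced,
                "total_dna": row.total_dna,
                "growth": growth,
                "mass_specific_per_day": growth / (m.microbial_biomass_c * 1000.0) * 24.0,
                "clamped": res.clamped,
            })
            response_rows.append({
                "phase": m.phase.value, "treatment": m.treatment.value,
                "response": "mass_specific_growth_dna",
                "value": growth / (m.microbial_biomass_c * 1000.0) * 24.0,
            })
            if sid in respiration:
                p = assemble_physiology(sid, Tracer.DNA_18O, growth, respiration[sid], m)
                physio_rows.append(_physio_row(p, m))
                response_rows.append({
                    "phase": m.phase.value, "treatment": m.treatment.value,
                    "response": "cue_dna", "value": p.cue,
                })
        results["dna_fluxes"] = pd.DataFrame(dna_rows)
        logger.info("[dna_flux] %d samples", len(dna_rows))

    if physio_rows:
        physio = pd.DataFrame(physio_rows)
        results["physiology"] = physio
        results["turnover"] = turnover_table(physio)

    if response_rows:
        responses = pd.DataFrame(response_rows)
        results["responses"] = responses
        results["treatment_summary"] = treatment_contrasts(responses)

    return results


def _physio_row(p, m: SampleMeta) -> dict:
    return {
        "sample_id": p.sample_id, "tracer": p.tracer.value,
        "phase": m.phase.value, "treatment": m.treatment.value,
        "growth": p.growth, "respiration": p.respiration, "uptake": p.uptake,
        "cue": p.cue, "turnover_days": p.turnover_days,
        "mass_specific_growth": p.mass_specific_growth,
        "microbial_biomass_c": m.microbial_biomass_c,
    }


def load_config(config_path) -> tuple[dict, RunConfig]:
    """Parse the YAML run configuration into (paths/settings, RunConfig)."""
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg_fields = {f for f in RunConfig.__dataclass_fields__}
    constants = {k: v for k, v in (raw.get("constants") or {}).items() if k in cfg_fields}
    return raw, RunConfig(**constants)


def run_pipeline(config_path) -> dict[str, str]:
    """Execute the whole pipeline from a YAML config; returns the manifest.

    Config keys: ``inputs`` (metadata, water, and any of fame/dna/headspace
    CSV paths), ``output_dir``, optional ``constants`` (RunConfig fields) and
    ``registry`` (CSV path overriding the shipped marker registry). Stage
    errors propagate with the stage name attached.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(message)s")
    raw, config = load_config(config_path)
    inputs = raw.get("inputs") or {}
    if "metadata" not in inputs or "water" not in inputs:
        raise DataError("config must name 'metadata' and 'water' input tables")
    outdir = raw.get("output_dir", "vaporsip_out")
    registry = (
        MarkerRegistry.from_csv(raw["registry"]) if raw.get("registry") else default_registry()
    )

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except VaporSipError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    meta = _stage("io", vio.read_metadata_table, inputs["metadata"])
    logger.info("[io] %d samples in metadata", len(meta))
    water = _stage("io", vio.read_water_table, inputs["water"])
    fame = (
        _stage("io", vio.read_fame_table, inputs["fame"], config)
        if inputs.get("fame") else None
    )
    dna = _stage("io", vio.read_dna_table, inputs["dna"]) if inputs.get("dna") else None
    headspace = (
        _stage("io", vio.read_headspace_table, inputs["headspace"])
        if inputs.get("headspace") else None
    )
    results = _stage(
        "analyze", analyze, meta, water,
        fame_records=fame, dna=dna, headspace=headspace,
        config=config, registry=registry,
    )
    manifest = _stage("io", vio.write_results, results, outdir)
    logger.info("[io] wrote %d tables to %s", len(manifest), Path(outdir))
    return manifest
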
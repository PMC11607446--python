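"""Reading, validation and writing of the pipeline's tabular formats.

All tables are RFC-4180 CSV with lower_snake_case canonical headers; a
documented alias map absorbs the common spreadsheet variants (``at%``,
``atom%``, ``time (h)`` ...). Units are explicit — every isotopic value column
is accompanied by a ``units`` column (``delta_permil`` or ``atom_percent``),
never inferred from magnitudes. Masses are per g dry soil; if metadata
supplies fresh mass plus gravimetric water content instead of dry mass, the
dry mass is derived at read time.

Validation is total: a missing column raises :class:`SchemaError` naming the
column, an unparseable number raises :class:`RowError` with its line number,
and unknown enum labels raise :class:`SchemaError`. No silent NaN ever enters
the pipeline.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import delta_to_atom_percent
from .errors import DataError, RowError, SchemaError
from .registry import normalize_marker
from .types import (
    Fraction,
    Isotope,
    Phase,
    Pool,
    RunConfig,
    SampleMeta,
    Treatment,
    FattyAcidRecord,
)

__all__ = [
    "read_fame_table",
    "read_water_table",
    "read_dna_table",
    "read_headspace_table",
    "read_metadata_table",
    "write_results",
    "UNIT_DELTA",
    "UNIT_ATPCT",
]

UNIT_DELTA = "delta_permil"
UNIT_ATPCT = "atom_percent"

# alias -> canonical column name, lower-cased comparison
COLUMN_ALIASES = {
    "sample": "sample_id",
    "sampleid": "sample_id",
    "plot": "plot_id",
    "plotid": "plot_id",
    "compound": "marker",
    "lipid_fraction": "fraction",
    "unit": "units",
    "time": "time_h",
    "time_(h)": "time_h",
    "time_hours": "time_h",
    "at%": "atom_percent",
    "atom%": "atom_percent",
    "atpct": "atom_percent",
    "labelled_value": "labelled",
    "labeled": "labelled",
    "natural_value": "natural",
    "nat_ab": "natural",
    "temp": "temperature",
    "mbc": "microbial_biomass_c",
    "co2_t0_ppm": "co2_t0",
    "co2_t48_ppm": "co2_t1",
    "co2_t1_ppm": "co2_t1",
    "elapsed_h": "elapsed",
}

UNIT_ALIASES = {
    "delta_permil": UNIT_DELTA, "delta": UNIT_DELTA, "permil": UNIT_DELTA,
    "d2h": UNIT_DELTA, "δ‰": UNIT_DELTA, "‰": UNIT_DELTA,
    "atom_percent": UNIT_ATPCT, "at%": UNIT_ATPCT, "atom%": UNIT_ATPCT,
    "atpct": UNIT_ATPCT,
}


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    cols = []
    for c in df.columns:
        key = str(c).strip().lower().replace(" ", "_")
        cols.append(COLUMN_ALIASES.get(key, key))
    out = df.copy()
    out.columns = cols
    return out


def _require_columns(df: pd.DataFrame, required: set[str], table: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{table} table missing column(s): {sorted(missing)}")


def _numeric(df: pd.DataFrame, col: str, table: str) -> pd.Series:
    """Strict numeric conversion; a bad cell names its 1-based CSV line."""
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        i = int(np.flatnonzero(bad.values)[0])
        raise RowError(
            f"{table} table, column '{col}': cannot parse {df[col].iloc[i]!r}",
            line=i + 2,  # header is line 1
        )
    if converted.isna().any():
        i = int(np.flatnonzero(converted.isna().values)[0])
        raise RowError(f"{table} table, column '{col}': empty value", line=i + 2)
    return converted.astype(float)


def _enum_series(df: pd.DataFrame, col: str, enum_cls, table: str) -> pd.Series:
    values = df[col].astype(str).str.strip().str.lower()
    values = values.str.replace(r"[\s+]+", "_", regex=True).str.replace(
        r"_+", "_", regex=True
    ).str.strip("_")
    allowed = {e.value for e in enum_cls}
    bad = ~values.isin(allowed)
    if bad.any():
        raise SchemaError(
            f"{table} table, column '{col}': unknown label(s) "
            f"{sorted(set(values[bad]))}; allowed: {sorted(allowed)}"
        )
    return values


def read_fame_table(path, config: RunConfig | None = None) -> list[FattyAcidRecord]:
    """Read per-sample per-compound fatty-acid records.

    Canonical columns: ``sample_id, marker, fraction, units, labelled,
    natural, fa_c``; ``units`` is ``delta_permil`` (converted to atom percent
    via the 2H VSMOW ratio) or ``atom_percent`` (passed through). Row count is
    preserved: one record per row.
    """
    config = config or RunConfig()
    df = _canonicalize_columns(pd.read_csv(path))
    _require_columns(
        df, {"sample_id", "marker", "fraction", "units", "labelled", "natural", "fa_c"},
        "fame",
    )
    fraction = _enum_series(df, "fraction", Fraction, "fame")
    labelled = _numeric(df, "labelled", "fame")
    natural = _numeric(df, "natural", "fame")
    fa_c = _numeric(df, "fa_c", "fame")
    units = df["units"].astype(str).str.strip().str.lower().map(UNIT_ALIASES)
    if units.isna().any():
        bad = sorted(set(df["units"][units.isna()].astype(str)))
        raise SchemaError(f"fame table: unknown units label(s) {bad}")

    records = []
    for i in range(len(df)):
        if units.iloc[i] == UNIT_DELTA:
            at_l = delta_to_atom_percent(labelled.iloc[i], config.r_vsmow_2h)
            at_n = delta_to_atom_percent(natural.iloc[i], config.r_vsmow_2h)
        else:
            at_l, at_n = labelled.iloc[i], natural.iloc[i]
        records.append(
            FattyAcidRecord(
                sample_id=str(df["sample_id"].iloc[i]),
                marker=normalize_marker(str(df["marker"].iloc[i])),
                fraction=Fraction(fraction.iloc[i]),
                atpct_labelled=float(at_l),
                atpct_natural=float(at_n),
                fa_c=float(fa_c.iloc[i]),
            )
        )
    return records


def read_water_table(path) -> pd.DataFrame:
    """Read the water-equilibration time series.

    Canonical columns: ``isotope (2h|18o), phase, treatment, replicate, pool
    (source|soil), time_h, atom_percent``.
    """
    df = _canonicalize_columns(pd.read_csv(path))
    _require_columns(
        df,
        {"isotope", "phase", "treatment", "replicate", "pool", "time_h", "atom_percent"},
        "water",
    )
    out = pd.DataFrame({
        "isotope": _enum_series(df, "isotope", Isotope, "water"),
        "phase": _enum_series(df, "phase", Phase, "water"),
        "treatment": _enum_series(df, "treatment", Treatment, "water"),
        "replicate": df["replicate"].astype(str),
        "pool": _enum_series(df, "pool", Pool, "water"),
        "time_h": _numeric(df, "time_h", "water"),
        "atom_percent": _numeric(df, "atom_percent", "water"),
    })
    if (out["time_h"] < 0).any():
        raise DataError("water table: negative time")
    return out


def read_dna_table(path) -> pd.DataFrame:
    """Read per-sample bulk-DNA 18O records.

    Canonical columns: ``sample_id, o_dna_extract, atpct_labelled,
    atpct_natural, total_dna`` (at% 18O; masses in ug g^-1 dry soil). The
    soil-water 18O denominator is attached later from the equilibration fits.
    """
    df = _canonicalize_columns(pd.read_csv(path))
    _require_columns(
        df,
        {"sample_id", "o_dna_extract", "atpct_labelled", "atpct_natural", "total_dna"},
        "dna",
    )
    return pd.DataFrame({
        "sample_id": df["sample_id"].astype(str),
        "o_dna_extract": _numeric(df, "o_dna_extract", "dna"),
        "atpct_labelled": _numeric(df, "atpct_labelled", "dna"),
        "atpct_natural": _numeric(df, "atpct_natural", "dna"),
        "total_dna": _numeric(df, "total_dna", "dna"),
    })


def read_headspace_table(path) -> pd.DataFrame:
    """Read headspace CO2 readings.

    Canonical columns: ``sample_id, co2_t0, co2_t1`` (ppm); optional
    ``headspace_volume`` (mL), ``temperature`` (degC), ``elapsed`` (h) —
    missing optional columns are filled from run config / sample metadata.
    An optional ``vial`` column (``labelled`` | ``natural``) distinguishes the
    tracer vial from its natural-abundance pair for the label-toxicity test.
    """
    df = _canonicalize_columns(pd.read_csv(path))
    _require_columns(df, {"sample_id", "co2_t0", "co2_t1"}, "headspace")
    out = pd.DataFrame({
        "sample_id": df["sample_id"].astype(str),
        "co2_t0": _numeric(df, "co2_t0", "headspace"),
        "co2_t1": _numeric(df, "co2_t1", "headspace"),
    })
    for opt in ("headspace_volume", "temperature", "elapsed"):
        if opt in df.columns:
            out[opt] = _numeric(df, opt, "headspace")
    if "vial" in df.columns:
        vial = df["vial"].astype(str).str.strip().str.lower()
        bad = ~vial.isin({"labelled", "natural"})
        if bad.any():
            raise SchemaError(
                f"headspace table: unknown vial label(s) {sorted(set(vial[bad]))}"
            )
        out["vial"] = vial
    return out


def read_metadata_table(path) -> dict[str, SampleMeta]:
    """Read per-sample metadata into validated :class:`SampleMeta` objects.

    Canonical columns: ``sample_id, plot_id, treatment, phase, soil_dry_mass,
    microbial_biomass_c``; optional ``incubation_time`` (default 48 h) and
    ``temperature`` (default 20 degC). If ``soil_dry_mass`` is absent but
    ``soil_fresh_mass`` and ``water_content`` (gravimetric, g water per g dry
    soil) are present, dry mass = fresh / (1 + water_content).
    """
    df = _canonicalize_columns(pd.read_csv(path))
    base = {"sample_id", "plot_id", "treatment", "phase", "microbial_biomass_c"}
    _require_columns(df, base, "metadata")
    if "soil_dry_mass" in df.columns:
        dry = _numeric(df, "soil_dry_mass", "metadata")
    elif {"soil_fresh_mass", "water_content"} <= set(df.columns):
        fresh = _numeric(df, "soil_fresh_mass", "metadata")
        gwc = _numeric(df, "water_content", "metadata")
        dry = fresh / (1.0 + gwc)
    else:
        raise SchemaError(
            "metadata table needs soil_dry_mass, or soil_fresh_mass + water_content"
        )
    treatment = _enum_series(df, "treatment", Treatment, "metadata")
    phase = _enum_series(df, "phase", Phase, "metadata")
    bmc = _numeric(df, "microbial_biomass_c", "metadata")
    inc = (
        _numeric(df, "incubation_time", "metadata")
        if "incubation_time" in df.columns
        else pd.Series(48.0, index=df.index)
    )
    temp = (
        _numeric(df, "temperature", "metadata")
        if "temperature" in df.columns
        else pd.Series(20.0, index=df.index)
    )
    out: dict[str, SampleMeta] = {}
    for i in range(len(df)):
        sid = str(df["sample_id"].iloc[i])
        if sid in out:
            raise SchemaError(f"metadata table: duplicate sample_id {sid!r}")
        out[sid] = SampleMeta(
            sample_id=sid,
            plot_id=str(df["plot_id"].iloc[i]),
            treatment=Treatment(treatment.iloc[i]),
            phase=Phase(phase.iloc[i]),
            soil_dry_mass=float(dry.iloc[i]),
            microbial_biomass_c=float(bmc.iloc[i]),
            incubation_time=float(inc.iloc[i]),
            temperature=float(temp.iloc[i]),
        )
    return out


def write_results(results: dict[str, pd.DataFrame], path) -> dict[str, str]:
    """Write result tables as CSV plus a JSON manifest; returns the manifest.

    Floats are written at full round-trip precision so re-reading reproduces
    every value exactly.

    Raises
    ------
    DataError
        Empty results collection.
    """
    if not results:
        raise DataError("no result tables to write")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, table in results.items():
        fname = f"{name}.csv"
        table.to_csv(outdir / fname, index=False, float_format="%.17g")
        manifest[name] = fname
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
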
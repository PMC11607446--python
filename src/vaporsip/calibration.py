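"""GC-IRMS delta-value calibration and internal-standard quantification.

Raw per-mil values measured against the working reference gas are normalized
to the VSMOW scale with bracketing isotopic standards (ordinary least squares
of known on measured delta), with an optional linear drift term over the run
sequence estimated from repeated standards. Atom-percent conversion uses the
two-isotope relation R = (delta/1000 + 1) * R_std, at% = 100 R / (1 + R);
adequate at tracer enrichments where the third isotope is negligible.

Fatty-acid carbon amounts are quantified against a co-injected internal
standard (19:0 by default) added as FAME at known mass.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np

from .errors import DegenerateFitError, DomainError, QuantificationError
from .types import CalibrationModel, DeltaMeasurement

__all__ = [
    "fit_calibration",
    "apply_calibration",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "correct_fame_methyl_h",
    "quantify_fa_carbon",
]


def fit_calibration(standards: Iterable[DeltaMeasurement]) -> CalibrationModel:
    """Fit the VSMOW normalization line from bracketing standards.

    Ordinary least squares of known delta on measured delta. If any standard
    compound appears at two or more run positions, a shared linear drift in
    run_index is estimated jointly; otherwise drift is fixed at 0.

    Raises
    ------
    DegenerateFitError
        Fewer than two distinct known deltas, or all measured deltas equal.
    """
    stds = [s for s in standards if s.is_standard]
    if len({s.known_delta for s in stds}) < 2:
        raise DegenerateFitError("need >= 2 standards with distinct known deltas")
    measured = np.array([s.delta_raw for s in stds], dtype=float)
    known = np.array([s.known_delta for s in stds], dtype=float)
    idx = np.array([s.run_index for s in stds], dtype=float)
    if np.ptp(measured) == 0:
        raise DegenerateFitError("all standards identical in measured delta")

    names = [s.compound for s in stds]
    has_repeats = len(set(names)) < len(names) and np.ptp(idx) > 0
    # known = slope * measured + intercept + drift * run_index
    cols = [measured, np.ones_like(measured)]
    if has_repeats:
        cols.append(idx)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, known, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    drift = float(coef[2]) if has_repeats else 0.0
    # Sign convention: apply_calibration subtracts drift * run_index, so the
    # fitted coefficient (an additive correction) is negated.
    resid = known - design @ coef
    dof = max(len(stds) - design.shape[1], 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return CalibrationModel(
        slope=slope, intercept=intercept, drift_per_index=-drift, residual_sd=residual_sd
    )


def apply_calibration(m: DeltaMeasurement, cal: CalibrationModel) -> float:
    """Return the measurement's delta on the VSMOW scale (per-mil).

    delta_vsmow = slope * delta_raw + intercept - drift_per_index * run_index.
    Order-preserving in delta_raw for fixed run_index.
    """
    return cal.slope * m.delta_raw + cal.intercept - cal.drift_per_index * m.run_index


def delta_to_atom_percent(delta, r_std: float):
    """Convert per-mil delta (VSMOW scale) to atom percent.

    Accepts scalars or arrays. Strictly increasing in delta; output in (0, 100).

    Raises
    ------
    DomainError
        delta <= -1000 per-mil (a negative isotope ratio).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000):
        raise DomainError("delta must be > -1000 per-mil")
    ratio = (delta / 1000.0 + 1.0) * r_std
    atpct = 100.0 * ratio / (1.0 + ratio)
    return float(atpct) if atpct.ndim == 0 else atpct


def atom_percent_to_delta(atpct, r_std: float):
    """Inverse of :func:`delta_to_atom_percent`; round-trips to ~1e-10 relative."""
    atpct = np.asarray(atpct, dtype=float)
    if np.any((atpct <= 0) | (atpct >= 100)):
        raise DomainError("atom percent must lie in (0, 100)")
    frac = atpct / 100.0
    ratio = frac / (1.0 - frac)
    delta = (ratio / r_std - 1.0) * 1000.0
    return float(delta) if delta.ndim == 0 else delta


def correct_fame_methyl_h(
    atpct_fame: float,
    atpct_methanol: float,
    n_h_fatty_acid: int,
    n_h_methyl: int = 3,
) -> float:
    """Remove the derivatization methyl's hydrogen from a FAME atom percent.

    Transesterification adds a methyl group (3 H from methanol) to each fatty
    acid; the measured FAME enrichment is the H-weighted mixture of the fatty
    acid and that methyl. Solving the mass balance for the fatty acid:

        at%_FA = (at%_FAME * (n_FA + n_Me) - at%_MeOH * n_Me) / n_FA

    Optional — off by default throughout the pipeline, since the methyl
    contribution is identical in the labelled and natural-abundance vials and
    largely cancels in the excess.

    Raises
    ------
    DomainError
        Non-positive hydrogen counts or a corrected value outside (0, 100).
    """
    if n_h_fatty_acid <= 0 or n_h_methyl < 0:
        raise DomainError("hydrogen counts must be positive")
    total = n_h_fatty_acid + n_h_methyl
    at_fa = (atpct_fame * total - atpct_methanol * n_h_methyl) / n_h_fatty_acid
    if not 0 < at_fa < 100:
        raise DomainError(
            f"corrected fatty-acid at% {at_fa:.6g} outside (0, 100); "
            "check methanol enrichment and hydrogen counts"
        )
    return at_fa


def quantify_fa_carbon(
    areas: Mapping[str, float],
    is_amount: float,
    soil_dry_mass: float,
    internal_standard: str = "19:0",
    response_factors: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Convert per-compound peak areas to fatty-acid C (ng C g^-1 dry soil).

    FA C_i = (area_i / area_IS) * C_IS / soil_dry_mass, optionally scaled by a
    per-compound response factor (default: none). The internal standard itself
    is excluded from the result so it never enters community sums.

    Parameters
    ----------
    areas : mapping of marker name -> peak area for one sample
    is_amount : ng C of internal standard added to the sample
    soil_dry_mass : g dry soil in the extraction

    Raises
    ------
    QuantificationError
        Internal-standard peak missing or with zero area.
    """
    if internal_standard not in areas or areas[internal_standard] <= 0:
        raise QuantificationError(
            f"internal standard '{internal_standard}' missing or zero-area"
        )
    if soil_dry_mass <= 0:
        raise DomainError("soil_dry_mass must be > 0")
    area_is = areas[internal_standard]
    out: dict[str, float] = {}
    for marker, area in areas.items():
        if marker == internal_standard:
            continue
        if area < 0:
            raise QuantificationError(f"negative peak area for '{marker}'")
        rf = 1.0 if response_factors is None else response_factors.get(marker, 1.0)
        out[marker] = (area / area_is) * is_amount * rf / soil_dry_mass
    return out
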
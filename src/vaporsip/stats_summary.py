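"""Treatment-level summaries and the label-toxicity paired t-test.

The experimental design crosses two climates (ambient, future) with drought
(absent, present) in two phases (peak drought, recovery). Drought effects are
reported as percent change of the drought cell relative to its matching
non-drought climate (ambient vs drought; future vs future + drought), per
climate and pooled (mean of the two climate-specific percent changes), plus
fold changes for storage-synthesis responses.

The paired t-test checks whether the heavy-isotope label itself altered
respiration: labelled vs natural-abundance vials from the same plots.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegenerateFitError
from .types import PairedSample, Phase, Treatment

logger = logging.getLogger(__name__)

__all__ = ["TTestResult", "paired_t", "treatment_contrasts", "turnover_table"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def paired_t(p: PairedSample) -> TTestResult:
    """Two-sided paired t-test on the differences x - y.

    t = mean(d) / (sd(d) / sqrt(n)), df = n - 1, p from the central t
    distribution.

    Raises
    ------
    DegenerateFitError
        All differences identical (sd = 0), where t is undefined.
    """
    d = np.asarray(p.x, dtype=float) - np.asarray(p.y, dtype=float)
    n = d.size
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateFitError("zero-variance differences: t undefined")
    t = mean / (sd / np.sqrt(n))
    pval = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return TTestResult(t=float(t), df=n - 1, p=pval)


def _percent_change(control_mean: float, drought_mean: float) -> float:
    """Drought reduction as percent of the matching non-drought mean."""
    return 100.0 * (control_mean - drought_mean) / control_mean


def treatment_contrasts(
    table: pd.DataFrame,
    value_col: str = "value",
    response_col: str = "response",
) -> pd.DataFrame:
    """Per-phase, per-response drought contrasts from a tidy long table.

    Parameters
    ----------
    table : DataFrame with columns ``phase, treatment, {response_col}, {value_col}``
        One row per sample per response.

    Returns
    -------
    DataFrame with one row per (phase, response, climate) plus a pooled row,
    holding cell means/sds/ns, ``percent_change_drought`` (reduction relative
    to the matching non-drought climate) and ``fold_change``
    (drought / non-drought). Pooled values are means of the two climate-specific
    contrasts. Cells with no samples are omitted with a notice.
    """
    required = {"phase", "treatment", response_col, value_col}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"contrast table missing columns: {sorted(missing)}")

    rows = []
    for (phase, response), sub in table.groupby(["phase", response_col], sort=False):
        cells = sub.groupby("treatment")[value_col].agg(["mean", "std", "count"])
        pairs = {
            "ambient": (Treatment.AMBIENT.value, Treatment.DROUGHT.value),
            "future": (Treatment.FUTURE.value, Treatment.FUTURE_DROUGHT.value),
        }
        climate_pcts, climate_folds = [], []
        for climate, (ctrl, drt) in pairs.items():
            if ctrl not in cells.index or drt not in cells.index:
                logger.info(
                    "phase %s response %s: missing cell for %s pair; contrast omitted",
                    phase, response, climate,
                )
                continue
            cm, dm = cells.loc[ctrl, "mean"], cells.loc[drt, "mean"]
            pct = _percent_change(cm, dm) if cm != 0 else np.nan
            fold = dm / cm if cm != 0 else np.nan
            climate_pcts.append(pct)
            climate_folds.append(fold)
            rows.append({
                "phase": phase, "response": response, "climate": climate,
                "mean_control": cm, "sd_control": cells.loc[ctrl, "std"],
                "n_control": int(cells.loc[ctrl, "count"]),
                "mean_drought": dm, "sd_drought": cells.loc[drt, "std"],
                "n_drought": int(cells.loc[drt, "count"]),
                "percent_change_drought": pct, "fold_change": fold,
            })
        if climate_pcts:
            rows.append({
                "phase": phase, "response": response, "climate": "pooled",
                "mean_control": np.nan, "sd_control": np.nan, "n_control": 0,
                "mean_drought": np.nan, "sd_drought": np.nan, "n_drought": 0,
                "percent_change_drought": float(np.mean(climate_pcts)),
                "fold_change": float(np.mean(climate_folds)),
            })
    return pd.DataFrame(rows)


def turnover_table(physio: pd.DataFrame) -> pd.DataFrame:
    """Treatment-mean turnover times, raw and rounded to whole days.

    Canonical turnover per treatment cell is biomass over daily production at
    the *treatment means* (mean biomass / (mean hourly growth * 24)); the mean
    of per-sample turnovers is emitted alongside for comparison.

    Expects columns ``phase, treatment, tracer, growth, microbial_biomass_c``
    (growth in ng C g^-1 h^-1, biomass in ug C g^-1).
    """
    rows = []
    for (phase, treatment, tracer), sub in physio.groupby(
        ["phase", "treatment", "tracer"], sort=False
    ):
        mean_growth = sub["growth"].mean()
        mean_bm = sub["microbial_biomass_c"].mean()
        if mean_growth <= 0:
            logger.info("cell %s/%s/%s: non-positive mean growth; turnover omitted",
                        phase, treatment, tracer)
            continue
        t_mean = mean_bm * 1000.0 / (mean_growth * 24.0)
        per_sample = (
            sub["microbial_biomass_c"] * 1000.0 / (sub["growth"] * 24.0)
        ).replace([np.inf, -np.inf], np.nan)
        rows.append({
            "phase": phase, "treatment": treatment, "tracer": tracer,
            "turnover_days": t_mean,
            "turnover_days_rounded": round(t_mean),
            "turnover_days_sample_mean": float(per_sample.mean()),
            "n": len(sub),
        })
    return pd.DataFrame(rows)


def _validate_enums(table: pd.DataFrame) -> None:
    bad_t = set(table["treatment"]) - {t.value for t in Treatment}
    bad_p = set(table["phase"]) - {p.value for p in Phase}
    if bad_t or bad_p:
        raise DataError(f"unknown treatment/phase labels: {bad_t | bad_p}")
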
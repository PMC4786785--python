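"""Gel densitometry: per-gel calibration curves and CFE concentrations.

Each SDS-PAGE gel carries four calibration lanes (0.5, 1, 2.5 and 5 μg of
purified wild-type protein) next to the sample lanes.  An ordinary
least-squares line through (load, intensity) of the calibration lanes is
inverted to read back the protein amount in each sample lane, which is then
scaled to a soluble-protein concentration in the cell-free extract (CFE).
Calibration from one gel is never applied to lanes of another gel.

Concentrations below the 0.5 mg ml^-1 detection limit are flagged rather
than dropped, and negative regression inversions are clipped to zero with
the same flag: those wells stay in the landscape as an explicit state.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LOD_MG_ML = 0.5


@dataclasses.dataclass
class CalibrationCurve:
    slope: float          # intensity per μg
    intercept: float      # intensity
    r_squared: float
    gel_id: str

    def invert(self, intensity: float) -> float:
        """Band intensity -> loaded protein (μg)."""
        return (intensity - self.intercept) / self.slope


@dataclasses.dataclass
class ExpressionRecord:
    variant_id: str
    conc_mg_ml: float
    below_lod: bool
    gel_id: str = ""
    r_squared: float | None = None
    clipped: bool = False


def fit_calibration(loads_ug: Sequence[float], intensities: Sequence[float],
                    gel_id: str = "") -> CalibrationCurve:
    """OLS line (free intercept) through the calibration lanes of one gel."""
    loads = np.asarray(loads_ug, dtype=float)
    intens = np.asarray(intensities, dtype=float)
    if loads.size < 3:
        raise ValueError(f"need at least 3 calibration points, got {loads.size}")
    if np.unique(loads).size < 2:
        raise ValueError("calibration loads are degenerate (zero variance)")
    fit = stats.linregress(loads, intens)
    return CalibrationCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue) ** 2, gel_id=gel_id)


def quantify_lane(intensity: float, curve: CalibrationCurve, variant_id: str = "",
                  loaded_cfe_volume_ul: float = 1.0, dilution: float = 1.0,
                  lod_mg_ml: float = LOD_MG_ML) -> ExpressionRecord:
    """CFE soluble-protein concentration from one sample lane.

    The inverted lane load (μg) divided by the CFE volume equivalent loaded
    (μl) gives μg μl^-1 == mg ml^-1; ``dilution`` undoes any upstream
    dilution of the CFE.  Negative inversions clip to 0 and are flagged.
    """
    load_ug = curve.invert(intensity)
    conc = load_ug / loaded_cfe_volume_ul * dilution
    clipped = conc < 0
    conc = max(conc, 0.0)
    return ExpressionRecord(
        variant_id=variant_id, conc_mg_ml=conc, below_lod=conc < lod_mg_ml,
        gel_id=curve.gel_id, r_squared=curve.r_squared, clipped=clipped,
    )


def quantify_gels(gel_table: pd.DataFrame, loaded_cfe_volume_ul: float = 1.0,
                  dilution: float = 1.0,
                  lod_mg_ml: float = LOD_MG_ML) -> dict[str, ExpressionRecord]:
    """Calibrate and quantify every gel of a band-intensity table.

    ``gel_table`` follows the generator dialect (gel_id, lane, role,
    variant_id, load_ug, intensity).  Per-gel isolation is enforced by
    grouping on ``gel_id`` before fitting.
    """
    records: dict[str, ExpressionRecord] = {}
    for gel_id, gel in gel_table.groupby("gel_id", sort=False):
        cal = gel[gel["role"] == "calibration"]
        curve = fit_calibration(cal["load_ug"], cal["intensity"], gel_id=str(gel_id))
        for _, row in gel[gel["role"] == "sample"].iterrows():
            rec = quantify_lane(row["intensity"], curve, variant_id=row["variant_id"],
                                loaded_cfe_volume_ul=loaded_cfe_volume_ul,
                                dilution=dilution, lod_mg_ml=lod_mg_ml)
            records[rec.variant_id] = rec
    return records


def expression_frame(records: Mapping[str, ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records.values()],
            "conc_mg_ml": [r.conc_mg_ml for r in records.values()],
            "below_lod": [r.below_lod for r in records.values()],
            "gel_id": [r.gel_id for r in records.values()],
            "r_squared": [r.r_squared for r in records.values()],
        }
    )


def substitution_averages(landscape) -> pd.Series:
    """Mean effect of each substitution identity across all positions.

    Valued cells enter the mean at their value; below-detection-limit cells
    enter as 0 (they are a floor category, not missing data); wild-type and
    absent cells are excluded.  Returns a 20-element Series indexed by
    amino acid.
    """
    frame = landscape.to_long()
    means = {}
    for aa in landscape.amino_acids:
        rows = frame[(frame["mut_aa"] == aa) &
                     (frame["state"].isin(["value", "below_lod"]))]
        if len(rows):
            vals = np.where(rows["state"] == "value", rows["value"], 0.0)
            means[aa] = float(np.mean(vals.astype(float)))
        else:
            means[aa] = np.nan
    return pd.Series(means, name="mean_effect")
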
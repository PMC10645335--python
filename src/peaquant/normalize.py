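"""Ct -> NPX normalization.

Two nested corrections turn raw qPCR Ct values into Normalized Protein
eXpression (NPX):

1. *Within-run*: the Ct of each well's internal extension control is
   subtracted from every assay Ct of that well, ``dCt = Ct - Ct_ext``.
   This cancels per-well technical variation (pipetting, amplification
   efficiency) because it shifts all assays of a well equally.
2. *Between-run*: per plate and assay, the median of each non-blank
   calibrator triplicate is taken and the three medians averaged,
   ``dCt_cal = mean(median(High), median(Middle), median(Low))``; then
   ``ddCt = dCt - dCt_cal``.  Any plate-wide additive Ct shift cancels
   exactly here, making NPX comparable across runs.

Finally ``NPX = correction_factor - ddCt``.  The sign flip makes NPX
increase with protein amount (more template -> lower Ct), and the
correction factor (a per-assay log2-scale constant) places the blank
background near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_model import (
    CALIBRATOR_ROLES,
    ROLE_CAL_BLANK,
    ROLE_CAL_HIGH,
    ROLE_CAL_LOW,
    ROLE_CAL_MIDDLE,
    ConfigurationError,
    NPXMatrix,
    PanelConfig,
    PlateTable,
    ValidationError,
)


@dataclass(frozen=True)
class CalibratorSummary:
    """Per-(plate, assay) calibrator statistics anchoring between-run scale."""

    plate_id: str
    assay_id: str
    dct_high: float
    dct_middle: float
    dct_low: float

    @property
    def dct_cal(self) -> float:
        return (self.dct_high + self.dct_middle + self.dct_low) / 3.0

    def to_row(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "assay_id": self.assay_id,
            "dct_high": self.dct_high,
            "dct_middle": self.dct_middle,
            "dct_low": self.dct_low,
            "dct_cal": self.dct_cal,
        }


def compute_dct(table: PlateTable) -> pd.DataFrame:
    """Extension-control subtraction: ``dCt = Ct - ext_ctrl_ct`` per well/assay.

    Returns a long DataFrame ``plate_id, well_id, sample_id, role, assay_id,
    ct, dct``.  Missing Ct propagates to missing dCt.
    """
    rows = []
    for w in table.wells:
        for aid in table.panel.assay_ids:
            ct = w.ct.get(aid, math.nan)
            rows.append(
                {
                    "plate_id": w.plate_id,
                    "well_id": w.well_id,
                    "sample_id": w.sample_id,
                    "role": w.role,
                    "assay_id": aid,
                    "ct": ct,
                    "dct": ct - w.ext_ctrl_ct,
                }
            )
    return pd.DataFrame(rows)


def summarize_calibrators(dct: pd.DataFrame, plate_id: str) -> dict[str, CalibratorSummary]:
    """Median of each non-blank calibrator triplicate, then mean of the three.

    The median makes the anchor robust to a single aberrant calibrator well;
    an even replicate count yields the midpoint of the two central values.
    """
    plate = dct[dct["plate_id"] == plate_id]
    out: dict[str, CalibratorSummary] = {}
    levels = {
        ROLE_CAL_HIGH: "dct_high",
        ROLE_CAL_MIDDLE: "dct_middle",
        ROLE_CAL_LOW: "dct_low",
    }
    for assay_id, grp in plate.groupby("assay_id"):
        meds = {}
        for role, key in levels.items():
            vals = grp.loc[grp["role"] == role, "dct"].dropna().to_numpy()
            if vals.size == 0:
                raise ValidationError(
                    f"plate {plate_id}: calibrator level {role} absent for assay "
                    f"{assay_id} (run validate_layout for a full report)"
                )
            meds[key] = float(np.median(vals))
        out[str(assay_id)] = CalibratorSummary(plate_id=plate_id, assay_id=str(assay_id), **meds)
    return out


def to_npx(
    dct: pd.DataFrame,
    calibrators: dict[str, CalibratorSummary],
    correction_factors: dict[str, float],
) -> pd.DataFrame:
    """Apply calibrator normalization and correction factor for one plate.

    ``ddCt = dCt - dCt_cal``; ``NPX = cf - ddCt``.
    """
    plate_ids = dct["plate_id"].unique()
    if len(plate_ids) != 1:
        raise ValidationError("to_npx operates on one plate at a time")
    assays = dct["assay_id"].unique()
    for aid in assays:
        if aid not in calibrators:
            raise ValidationError(f"no calibrator summary for assay {aid}")
        if aid not in correction_factors:
            raise ConfigurationError(f"assay {aid} lacks a correction factor")
    dct_cal = dct["assay_id"].map({a: calibrators[a].dct_cal for a in assays})
    cf = dct["assay_id"].map(correction_factors)
    out = dct.copy()
    out["ddct"] = dct["dct"] - dct_cal
    out["npx"] = cf - out["ddct"]
    return out


def normalize_plates(table: PlateTable) -> NPXMatrix:
    """Full normalization of a plate table: dCt, calibrator ddCt, NPX.

    Wells whose extension control is missing but that carry finite assay Ct
    are rejected; the correction factor of each assay comes from the panel
    (0 when unspecified, leaving NPX on a relative scale with blank
    background near zero).
    """
    cf = {a.assay_id: a.correction_factor for a in table.panel.assays}
    dct = compute_dct(table)
    parts = []
    for plate_id in table.plates():
        plate_dct = dct[dct["plate_id"] == plate_id]
        cal = summarize_calibrators(dct, plate_id)
        parts.append(to_npx(plate_dct, cal, cf))
    values = pd.concat(parts, ignore_index=True)
    return NPXMatrix(values=values[list(NPXMatrix.REQUIRED) + ["ct"]])
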
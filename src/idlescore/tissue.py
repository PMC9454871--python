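"""Per-patient tissue features from pathologist ROI readings.

Aggregates the reading table (one row per annotated region of interest) into
the per-patient tissue block used by the risk model: five histologic subtype
flags, highest numeric tumor grade (GX, undetermined, is tracked separately
and never enters the numeric maximum), the largest invasive dimension over
all ROIs, ROI count, and a pre-malignant-region flag.  Aggregation is
invariant to ROI order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SUBTYPE_FLAGS = {
    "AIS": "subtype_ais",
    "invasive adenocarcinoma": "subtype_invasive_adeno",
    "carcinoid": "subtype_carcinoid",
    "large-cell": "subtype_largecell",
    "squamous": "subtype_squamous",
}

TISSUE_COLUMNS = (
    "subtype_ais", "subtype_invasive_adeno", "subtype_carcinoid",
    "subtype_largecell", "subtype_squamous", "highest_grade", "grade_gx",
    "grade_missing", "largest_invasive_dimension", "n_rois", "any_premalignant",
)

#: model-input column order (clinical block + tissue block); CT features are
#: appended after these by the pipeline.
CLINICAL_COLUMNS = (
    "age_at_surgery", "sex_f", "smoke_pack_years", "surgery_type_lobectomy",
    "residual_r0", "lymphadenectomy", "days_ldct_to_surgery",
)


def derive_tissue_features(roi_readings: pd.DataFrame,
                           patient_ids=None) -> pd.DataFrame:
    """One tissue-feature row per patient from the ROI reading table.

    ``patient_ids`` optionally lists the patients that must be covered; a
    listed patient with zero ROIs raises a ValueError.
    """
    req = {"patient_id", "region_class", "diagnosis", "grade", "invasive_dimension_mm"}
    missing = req - set(roi_readings.columns)
    if missing:
        raise KeyError(f"roi_readings is missing columns: {sorted(missing)}")
    if patient_ids is not None:
        absent = set(patient_ids) - set(roi_readings["patient_id"])
        if absent:
            raise ValueError(f"patients with zero ROIs: {sorted(absent)[:5]}")

    rows = []
    for pid, grp in roi_readings.groupby("patient_id", sort=True):
        row = {"patient_id": pid}
        diags = set(grp["diagnosis"].dropna()) - {""}
        for diag, col in SUBTYPE_FLAGS.items():
            row[col] = float(diag in diags)
        grades = grp["grade"].astype(str)
        numeric = pd.to_numeric(grades[grades.isin(list("1234"))], errors="coerce")
        row["grade_gx"] = float((grades == "GX").any())
        row["grade_missing"] = float(numeric.empty)
        row["highest_grade"] = float(numeric.max()) if not numeric.empty else 0.0
        row["largest_invasive_dimension"] = float(grp["invasive_dimension_mm"].max())
        row["n_rois"] = float(len(grp))
        row["any_premalignant"] = float((grp["region_class"] == "pre-malignant").any())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("patient_id")
    return out[list(TISSUE_COLUMNS)]


def encode_clinical(patients: pd.DataFrame) -> pd.DataFrame:
    """One-hot / numeric encoding of the clinical and surgical variables."""
    p = patients.set_index("patient_id")
    out = pd.DataFrame(index=p.index)
    out["age_at_surgery"] = p["age_at_surgery"].astype(float)
    out["sex_f"] = (p["sex"] == "F").astype(float)
    out["smoke_pack_years"] = p["smoke_pack_years"].astype(float)
    out["surgery_type_lobectomy"] = (p["surgery_type"] == "lobectomy").astype(float)
    out["residual_r0"] = (p["residual_disease"] == "R0").astype(float)
    out["lymphadenectomy"] = p["lymphadenectomy"].astype(float)
    out["days_ldct_to_surgery"] = p["days_ldct_to_surgery"].astype(float)
    return out


def assemble_model_inputs(tissue: pd.DataFrame, patients: pd.DataFrame,
                          ct_features: pd.DataFrame | None = None,
                          train_ids=None, standardize: bool = True) -> pd.DataFrame:
    """Per-patient model input block in a fixed, documented column order.

    Clinical block, then tissue block, then (optionally) the CT feature
    block.  Continuous columns are standardized using statistics computed on
    ``train_ids`` only (all patients when ``None``); binary flags are left
    as 0/1.  Constant columns standardize to zero.
    """
    clin = encode_clinical(patients)
    blocks = [clin, tissue]
    if ct_features is not None:
        blocks.append(ct_features)
    X = pd.concat(blocks, axis=1, join="inner")
    if X.isna().any().any():
        raise ValueError("model inputs contain missing values")
    missing = set(patients["patient_id"]) - set(X.index)
    if missing:
        raise KeyError(f"patients without a complete input row: {sorted(missing)[:5]}")
    X = X.loc[patients["patient_id"]]
    if not standardize:
        return X
    train = X.loc[train_ids] if train_ids is not None else X
    binary = [c for c in X.columns if set(np.unique(train[c])) <= {0.0, 1.0}]
    out = X.copy()
    for c in X.columns:
        if c in binary:
            continue
        mu = float(train[c].mean())
        sd = float(train[c].std(ddof=0))
        out[c] = (X[c] - mu) / sd if sd > 0 else 0.0
    return out
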
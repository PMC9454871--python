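"""End-to-end glue: phantom volumes -> CT features -> model inputs.

The per-image chain is: resample to 0.5 mm isotropic, segment the lung,
segment the lesion inside its gross cube, check eligibility (>= 4 mm,
non-calcified) on the raw intensities, build the peri/extra/adjacent VOIs,
normalise intensities, and extract the 173-feature registry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import SyntheticCohort
from .ct.registry import extract_all, lesion_eligibility
from .ct.volume import (Volume3D, build_voi_set, normalize_intensities,
                        resample_isotropic, segment_lesion, segment_lung)
from .tissue import assemble_model_inputs, derive_tissue_features


def extract_image_features(raw: Volume3D, gross_box, lesion_table=None,
                           enforce_eligibility: bool = True) -> pd.Series:
    """Full feature vector (length 173) for one lesion in one CT volume."""
    vol = resample_isotropic(raw)
    lung = segment_lung(vol)
    tumor = segment_lesion(vol, gross_box, lung_mask=lung)
    elig = lesion_eligibility(vol, tumor)
    if enforce_eligibility and not elig.eligible:
        raise ValueError(f"lesion not eligible for analysis: {'; '.join(elig.reasons)}")
    vois = build_voi_set(tumor, lung | tumor, vol, gross_box=gross_box)
    norm = normalize_intensities(vol, vois)
    return extract_all(norm, vois, lesion_table)


def cohort_ct_features(cohort: SyntheticCohort,
                       enforce_eligibility: bool = False) -> pd.DataFrame:
    """CT feature table (patients x 173) for a generated cohort."""
    if not cohort.volumes:
        raise ValueError("cohort was generated without volumes")
    rows = {}
    for pid, bundle in cohort.volumes.items():
        rows[pid] = extract_image_features(bundle.volume, bundle.gross_box,
                                           bundle.lesion_table,
                                           enforce_eligibility=enforce_eligibility)
    out = pd.DataFrame(rows).T
    out.index.name = "patient_id"
    return out.loc[list(cohort.volumes)]


def build_model_inputs(cohort: SyntheticCohort,
                       ct_features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Raw (unstandardized) model input block for a cohort.

    Clinical + tissue blocks from the generated tables, plus the CT feature
    block when provided (or extractable).  Standardization is left to the
    model so it can be redone per LOOCV fold.
    """
    if ct_features is None:
        ct_features = cohort_ct_features(cohort)
    tissue = derive_tissue_features(cohort.roi_readings,
                                    cohort.patients["patient_id"])
    return assemble_model_inputs(tissue, cohort.patients, ct_features,
                                 standardize=False)
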
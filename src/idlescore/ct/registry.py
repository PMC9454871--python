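"""The named, ordered CT feature registry (173 features per image).

Composition:

* 48 texture features (15 first-order + 22 GLCM + 11 GLRLM) for each of the
  intra-tumor, peri-tumor, and extra-tumor VOIs = 144;
* 9 nested spatial features (tumor volume, LocSd100/50/20 and their
  volume-normalised versions, center shifts d50/d20);
* 3 tumor/peritumor intensity-ratio features (mean ratio, R50, R90);
* 17 lung-level features: per-lobe lesion count, any-solid and
  any-part-solid flags for the five lobes, plus total lesion count and total
  lesion volume.

Feature names and order are stable across runs; ``extract_all`` always emits
exactly this registry or raises an error naming the failing family.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import spatial, texture
from .volume import LesionVOISet, Volume3D

VOI_NAMES = ("tumor", "peritumor", "extratumor")
LOBES = ("rul", "rml", "rll", "lul", "lll")

#: Lesions must be non-calcified and at least this large to be analysed.
MIN_LESION_DIAMETER_MM = 4.0
#: Raw-HU threshold and voxel fraction defining a calcified lesion.
CALCIFICATION_HU = 130.0
CALCIFICATION_FRACTION = 0.10

#: Mean raw HU above which a lesion counts as solid, and the band that
#: counts as part-solid.
SOLID_HU = -300.0
PART_SOLID_HU = -600.0

SPATIAL_NAMES = ("volume_mm3", "locsd100", "locsd100v", "locsd50", "locsd50v",
                 "locsd20", "locsd20v", "d50", "d20")
RATIO_NAMES = ("mean_intensity_ratio", "r50", "r90")


def feature_registry() -> pd.DataFrame:
    """Ordered catalog of all 173 feature names with family and VOI tags."""
    rows = []
    for voi in VOI_NAMES:
        for n in texture.FIRST_ORDER_NAMES:
            rows.append((f"{voi}_fo_{n}", "first_order", voi))
        for n in texture.GLCM_FEATURE_NAMES:
            rows.append((f"{voi}_glcm_{n}", "glcm", voi))
        for n in texture.GLRLM_FEATURE_NAMES:
            rows.append((f"{voi}_glrlm_{n}", "glrlm", voi))
    for n in SPATIAL_NAMES:
        rows.append((f"tumor_{n}", "nested_spatial", "tumor"))
    for n in RATIO_NAMES:
        rows.append((n, "intensity_ratio", "tumor_vs_peritumor"))
    for lobe in LOBES:
        rows.append((f"{lobe}_lesion_count", "lung_level", "lung"))
        rows.append((f"{lobe}_any_solid", "lung_level", "lung"))
        rows.append((f"{lobe}_any_part_solid", "lung_level", "lung"))
    rows.append(("total_lesion_count", "lung_level", "lung"))
    rows.append(("total_lesion_volume_mm3", "lung_level", "lung"))
    reg = pd.DataFrame(rows, columns=["name", "family", "voi"])
    assert len(reg) == 173 and reg["name"].is_unique
    return reg


FEATURE_NAMES = tuple(feature_registry()["name"])


def registry_to_json(path) -> None:
    reg = feature_registry()
    with open(path, "w") as fh:
        json.dump(reg.to_dict(orient="records"), fh, indent=1)


@dataclass(frozen=True)
class LesionEligibility:
    eligible: bool
    diameter_mm: float
    calcified_fraction: float
    reasons: tuple[str, ...]


def lesion_eligibility(raw_volume: Volume3D, tumor_mask: np.ndarray) -> LesionEligibility:
    """Inclusion check: equivalent diameter >= 4 mm and non-calcified.

    Calcification is flagged when more than 10% of tumor voxels in the raw
    (unnormalised) volume exceed +130 HU.
    """
    n = int(np.asarray(tumor_mask, dtype=bool).sum())
    if n == 0:
        raise ValueError("empty tumor mask")
    vol_mm3 = n * float(np.prod(raw_volume.spacing))
    diameter = (6.0 * vol_mm3 / np.pi) ** (1.0 / 3.0)
    calc = float(np.mean(raw_volume.data[tumor_mask.astype(bool)] > CALCIFICATION_HU))
    reasons = []
    if diameter < MIN_LESION_DIAMETER_MM:
        reasons.append(f"diameter {diameter:.1f} mm < {MIN_LESION_DIAMETER_MM} mm")
    if calc > CALCIFICATION_FRACTION:
        reasons.append(f"calcified ({calc:.0%} voxels > {CALCIFICATION_HU:+.0f} HU)")
    return LesionEligibility(not reasons, diameter, calc, tuple(reasons))


def intensity_ratios(tumor_voxels, peritumor_voxels) -> "OrderedDict[str, float]":
    """Tumor/peritumor ratios of mean intensity and of the 50th/90th
    percentiles, on normalised (non-negative) intensities."""
    t = np.asarray(tumor_voxels, dtype=float)
    p = np.asarray(peritumor_voxels, dtype=float)
    if t.size == 0 or p.size == 0:
        raise ValueError("both tumor and peritumor voxel sets must be non-empty")
    out = OrderedDict()
    denom_mean = p.mean()
    if denom_mean == 0:
        raise ZeroDivisionError("peritumoral mean intensity is zero")
    out["mean_intensity_ratio"] = float(t.mean() / denom_mean)
    for q, name in ((50, "r50"), (90, "r90")):
        denom = np.percentile(p, q)
        if denom == 0:
            raise ZeroDivisionError(f"peritumoral {q}th percentile is zero")
        out[name] = float(np.percentile(t, q) / denom)
    return out


def lung_level_features(lesion_table: pd.DataFrame | None) -> "OrderedDict[str, float]":
    """Per-lobe lesion counts and solidity flags plus totals.

    ``lesion_table`` has one row per detected lung lesion with columns
    ``lobe`` (rul/rml/rll/lul/lll), ``volume_mm3`` and ``mean_hu`` (raw
    scale).  A lesion is solid when its mean HU exceeds -300 and part-solid
    in (-600, -300].  ``None`` or an empty table yields all-zero features.
    """
    out = OrderedDict()
    if lesion_table is None:
        lesion_table = pd.DataFrame(columns=["lobe", "volume_mm3", "mean_hu"])
    solid = lesion_table["mean_hu"] > SOLID_HU if len(lesion_table) else pd.Series(dtype=bool)
    part = ((lesion_table["mean_hu"] > PART_SOLID_HU)
            & (lesion_table["mean_hu"] <= SOLID_HU)) if len(lesion_table) else pd.Series(dtype=bool)
    for lobe in LOBES:
        in_lobe = lesion_table["lobe"] == lobe if len(lesion_table) else pd.Series(dtype=bool)
        out[f"{lobe}_lesion_count"] = float(in_lobe.sum())
        out[f"{lobe}_any_solid"] = float((in_lobe & solid).any()) if len(lesion_table) else 0.0
        out[f"{lobe}_any_part_solid"] = float((in_lobe & part).any()) if len(lesion_table) else 0.0
    out["total_lesion_count"] = float(len(lesion_table))
    out["total_lesion_volume_mm3"] = float(lesion_table["volume_mm3"].sum()) if len(lesion_table) else 0.0
    return out


def extract_all(volume: Volume3D, voi_set: LesionVOISet,
                lung_lesion_table: pd.DataFrame | None = None,
                bin_size: float = 100.0) -> pd.Series:
    """Extract the full ordered 173-feature vector from one normalised image.

    ``volume`` must already be intensity-normalised (non-negative working
    scale); ``lung_lesion_table`` supplies the lung-level lesion summary.
    Any failing feature family raises a ValueError naming that family.
    """
    values: "OrderedDict[str, float]" = OrderedDict()
    masks = {"tumor": voi_set.tumor, "peritumor": voi_set.peritumor,
             "extratumor": voi_set.extratumor}
    for voi, mask in masks.items():
        vox = volume.data[mask]
        for family, fn in (("first_order", lambda: texture.first_order_features(vox, bin_size)),
                           ("glcm", lambda: texture.glcm_features(volume.data, mask, bin_size)),
                           ("glrlm", lambda: texture.glrlm_features(volume.data, mask, bin_size))):
            try:
                feats = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with family context
                raise ValueError(f"{family} features failed on {voi} VOI: {exc}") from exc
            prefix = {"first_order": "fo", "glcm": "glcm", "glrlm": "glrlm"}[family]
            for k, v in feats.items():
                values[f"{voi}_{prefix}_{k}"] = v
    try:
        sp = spatial.nested_spatial_features(volume.data, voi_set.tumor,
                                             volume.spacing, volume.origin)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"nested_spatial features failed: {exc}") from exc
    for n in SPATIAL_NAMES:
        values[f"tumor_{n}"] = sp[n]
    try:
        values.update(intensity_ratios(volume.data[voi_set.tumor],
                                       volume.data[voi_set.peritumor]))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"intensity_ratio features failed: {exc}") from exc
    values.update(lung_level_features(lung_lesion_table))
    vec = pd.Series(values, dtype=float)
    assert tuple(vec.index) == FEATURE_NAMES
    return vec
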
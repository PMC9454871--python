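"""Nested intensity-weighted centroid and spatial-dispersion features.

The lesion's intensity distribution in space is summarised by a nested family
of weighted centers: C100 uses every tumor voxel, C50 and C20 the top 50% and
20% of voxels by intensity.  The center weights each voxel coordinate by its
intensity d; the dispersion LocSd weights squared distances to the center by
d^2 (the two weightings are deliberately different and kept exactly as
defined).  LocSd is additionally reported normalised by tumor volume, and the
Euclidean shifts d50 = ||C50 - C100|| and d20 = ||C20 - C100|| quantify how
far the high-intensity core sits from the bulk centroid — a proxy for
clustered high-intensity subregions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TOP_FRACTIONS = (100, 50, 20)


@dataclass(frozen=True)
class WeightedCenter:
    """Intensity-weighted mm coordinates of the top-p% voxels."""
    coords: tuple[float, float, float]
    fraction: int

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.coords, dtype=dtype)


def _voxel_mm_coords(mask: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    idx = np.argwhere(np.asarray(mask, dtype=bool))
    return np.asarray(origin, dtype=float) + idx * np.asarray(spacing, dtype=float)


def top_fraction_selector(intensities: np.ndarray, fraction: int) -> np.ndarray:
    """Boolean selector of the ceil(p% * N) highest-intensity voxels.

    Voxels tied with the cutoff intensity are all included, so the selection
    is symmetric under voxel reordering (a homogeneous lesion selects every
    voxel at any fraction).
    """
    if fraction not in TOP_FRACTIONS:
        raise ValueError(f"fraction must be one of {TOP_FRACTIONS}")
    d = np.asarray(intensities, dtype=float)
    n = d.size
    k = int(np.ceil(fraction / 100.0 * n))
    cutoff = np.sort(d)[n - k]
    return d >= cutoff


def weighted_center(volume, mask, fraction: int = 100, spacing=(1.0, 1.0, 1.0),
                    origin=(0.0, 0.0, 0.0)) -> WeightedCenter:
    """Intensity-weighted mean mm coordinate over the top-p% voxels.

    Weights are the (non-negative) voxel intensities themselves; all-zero
    weights are rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    d = np.asarray(volume, dtype=float)[mask]
    if np.any(d < 0):
        raise ValueError("weighted center requires non-negative intensities "
                         "(apply intensity normalisation first)")
    xyz = _voxel_mm_coords(mask, spacing, origin)
    sel = top_fraction_selector(d, fraction)
    w = d[sel]
    if w.sum() == 0:
        raise ValueError("all selected voxel weights are zero")
    c = (xyz[sel] * w[:, None]).sum(axis=0) / w.sum()
    return WeightedCenter(tuple(float(v) for v in c), fraction)


def loc_sd(volume, mask, center, fraction: int = 100, spacing=(1.0, 1.0, 1.0),
           origin=(0.0, 0.0, 0.0)) -> float:
    """Intensity-squared-weighted spatial dispersion (mm) about ``center``.

    sqrt( sum d^2 ||x - c||^2 / sum d^2 ) over the top-p% voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    d = np.asarray(volume, dtype=float)[mask]
    xyz = _voxel_mm_coords(mask, spacing, origin)
    sel = top_fraction_selector(d, fraction)
    w2 = d[sel] ** 2
    if w2.sum() == 0:
        raise ValueError("all selected voxel weights are zero")
    c = np.asarray(center, dtype=float)
    sq = ((xyz[sel] - c) ** 2).sum(axis=1)
    return float(np.sqrt(np.sum(w2 * sq) / w2.sum()))


def center_shift(c_p: WeightedCenter, c_100: WeightedCenter) -> float:
    """Euclidean distance (mm) between a nested center and the full center."""
    return float(np.linalg.norm(np.asarray(c_p) - np.asarray(c_100)))


def nested_spatial_features(volume, mask, spacing, origin=(0.0, 0.0, 0.0)) -> dict:
    """The 9 nested spatial features: V, LocSd{100,50,20}, their volume-
    normalised versions, and the center shifts d50, d20."""
    spacing = np.asarray(spacing, dtype=float)
    vol_mm3 = float(np.asarray(mask, dtype=bool).sum() * spacing.prod())
    centers = {p: weighted_center(volume, mask, p, spacing, origin)
               for p in TOP_FRACTIONS}
    out = {"volume_mm3": vol_mm3}
    for p in TOP_FRACTIONS:
        ls = loc_sd(volume, mask, centers[p], p, spacing, origin)
        out[f"locsd{p}"] = ls
        out[f"locsd{p}v"] = ls / vol_mm3
    out["d50"] = center_shift(centers[50], centers[100])
    out["d20"] = center_shift(centers[20], centers[100])
    return out
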
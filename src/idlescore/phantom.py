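"""Synthetic thoracic CT phantoms with planted lesions.

The phantom is a desk-scale stand-in for a screening chest CT: an air
background (-1000 HU), an ellipsoidal soft-tissue body shell (~300 HU), a
lung cavity (-800 HU with Gaussian noise), and one or more planted
ellipsoidal lesions.  Three generative knobs control the lesion's intensity
structure:

* ``solidity`` in (0, 1] sets the mean contrast over lung background (1 is a
  fully solid ~+50 HU lesion, low values give ground-glass-like lesions);
* ``skewness`` sets the sample skewness of the voxel intensity distribution
  (skew-normal noise);
* ``cluster_count`` plants that many compact high-intensity blobs inside the
  lesion, displacing the high-intensity weighted centers from the bulk
  centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ct.volume import GeometryError, Volume3D

LUNG_HU = -800.0
BODY_HU = 300.0
AIR_HU = -1000.0
LUNG_NOISE_SD = 20.0
CLUSTER_BOOST_HU = 250.0
LESION_NOISE_SD = 60.0

#: clearance (mm) required between the lesion and the volume boundary
CLEARANCE_MM = 10.0


@dataclass(frozen=True)
class LesionParams:
    """Generative description of one planted lesion."""
    diameter_mm: float
    solidity: float = 1.0
    skewness: float = 0.0
    cluster_count: int = 0
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def mean_hu(self) -> float:
        """Mean lesion intensity implied by solidity."""
        return LUNG_HU + 850.0 * self.solidity


def _skewnorm_shape(target_skew: float) -> float:
    """Shape parameter of a skew-normal with the requested sample skewness."""
    g = abs(float(target_skew))
    if g < 1e-8:
        return 0.0
    g = min(g, 0.99)
    num = (np.pi / 2.0) * g ** (2.0 / 3.0)
    den = g ** (2.0 / 3.0) + ((4.0 - np.pi) / 2.0) ** (2.0 / 3.0)
    delta = np.sqrt(num / den)
    a = delta / np.sqrt(1.0 - delta ** 2)
    return float(np.sign(target_skew) * a)


def _ellipsoid_mask(shape, center_vox, semi_axes_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center_vox, semi_axes_vox):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _plant_lesion(data, mask_grid, params: LesionParams, center_vox, spacing, rng):
    """Fill one ellipsoidal lesion; returns its voxel mask."""
    from scipy import stats

    ratios = np.asarray(params.axis_ratios, dtype=float)
    ratios = ratios / ratios.prod() ** (1.0 / 3.0)
    semi_mm = params.diameter_mm / 2.0 * ratios
    semi_vox = semi_mm / np.asarray(spacing, dtype=float)
    mask = _ellipsoid_mask(data.shape, center_vox, np.maximum(semi_vox, 0.5))
    n = int(mask.sum())
    if n == 0:
        raise GeometryError("lesion diameter below voxel resolution")
    a = _skewnorm_shape(params.skewness)
    noise = stats.skewnorm.rvs(a, size=n, random_state=rng) if a != 0 else rng.normal(size=n)
    noise = noise - stats.skewnorm.mean(a) if a != 0 else noise
    data[mask] = params.mean_hu() + LESION_NOISE_SD * noise
    # compact high-intensity blobs inside the lesion core
    for _ in range(int(params.cluster_count)):
        off = rng.uniform(-0.55, 0.55, size=3) * semi_vox
        r_mm = max(1.5, 0.18 * params.diameter_mm)
        blob = _ellipsoid_mask(data.shape, np.asarray(center_vox) + off,
                               np.maximum(r_mm / np.asarray(spacing), 0.5))
        blob &= mask
        data[blob] += CLUSTER_BOOST_HU
    mask_grid |= mask
    return mask


def generate_ct_volume(params: LesionParams, spacing=(0.5, 0.5, 0.5),
                       shape=(96, 96, 96), seed=0, center_mm=None):
    """Generate a lung phantom with one planted lesion.

    Returns ``(Volume3D, lesion_mask)``.  The lesion must fit inside the
    volume with at least 1 cm clearance to every face, else a
    :class:`GeometryError` is raised.  Fixed seed and parameters give a
    byte-identical volume.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spacing = np.asarray(spacing, dtype=float)
    shape = tuple(int(n) for n in shape)
    extent = np.array(shape) * spacing
    if center_mm is None:
        center_mm = extent / 2.0
    center_mm = np.asarray(center_mm, dtype=float)
    r = params.diameter_mm / 2.0
    if np.any(center_mm - r < CLEARANCE_MM) or np.any(extent - center_mm - r < CLEARANCE_MM):
        raise GeometryError(
            f"lesion (diameter {params.diameter_mm} mm) does not fit with "
            f"{CLEARANCE_MM:.0f} mm clearance inside a {tuple(extent)} mm volume")

    data = np.full(shape, AIR_HU, dtype=float)
    center_vox = np.array(shape) / 2.0 - 0.5
    body = _ellipsoid_mask(shape, center_vox, np.array(shape) * 0.48)
    data[body] = BODY_HU + rng.normal(0.0, 30.0, size=int(body.sum()))
    lung = _ellipsoid_mask(shape, center_vox, np.array(shape) * 0.38)
    data[lung] = LUNG_HU + rng.normal(0.0, LUNG_NOISE_SD, size=int(lung.sum()))

    lesion_mask = np.zeros(shape, dtype=bool)
    _plant_lesion(data, lesion_mask, params, center_mm / spacing, spacing, rng)
    return Volume3D(data, tuple(spacing), (0.0, 0.0, 0.0)), lesion_mask


def add_lesion(volume: Volume3D, params: LesionParams, center_mm, rng) -> np.ndarray:
    """Plant an additional lesion (e.g., a secondary nodule) in an existing
    phantom, in place; returns its voxel mask."""
    center_vox = np.asarray(center_mm, dtype=float) / np.asarray(volume.spacing)
    mask = np.zeros(volume.shape, dtype=bool)
    _plant_lesion(volume.data, mask, params, center_vox, volume.spacing, rng)
    return mask


def gross_box(lesion_mask: np.ndarray, spacing, margin_mm: float = 10.0):
    """Axis-aligned bounding cube of a lesion with >= ``margin_mm`` margin,
    clipped to the grid."""
    idx = np.argwhere(lesion_mask)
    if idx.size == 0:
        raise ValueError("empty lesion mask")
    m = np.ceil(margin_mm / np.asarray(spacing, dtype=float)).astype(int)
    lo = np.maximum(idx.min(axis=0) - m, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + m, lesion_mask.shape)
    return lo.tolist(), hi.tolist()
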
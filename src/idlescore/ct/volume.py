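"""3D CT volume container and image-domain preprocessing.

Covers the preprocessing chain applied to each screening CT before feature
extraction: resampling to a 0.5 mm isotropic grid, whole-lung segmentation
(to drop bone and chest-wall voxels), lesion segmentation inside a gross
bounding cube (median filter, Otsu threshold, morphological cleanup, largest
component), and intensity normalisation that subtracts the median of the
adjacent normal lung and shifts by +300 so that all working intensities are
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

ISO_SPACING_MM = 0.5
NORMALIZATION_SHIFT = 300.0

#: HU threshold below which voxels are lung/air candidates.
LUNG_THRESHOLD_HU = -300.0
#: HU threshold above which voxels count as bone/calcification.
BONE_THRESHOLD_HU = 150.0


class SegmentationError(ValueError):
    """A segmentation step produced an empty or degenerate mask."""


class GeometryError(ValueError):
    """A lesion or box does not fit the volume geometry."""


@dataclass
class Volume3D:
    """Regular 3D scalar grid with voxel spacing and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (ISO_SPACING_MM,) * 3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self):
        return self.data.shape

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine()), str(path))

    @classmethod
    def from_nifti(cls, path) -> "Volume3D":
        import nibabel as nib
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        return cls(np.asarray(img.dataobj, dtype=float), spacing, tuple(aff[:3, 3]))


@dataclass
class LesionVOISet:
    """Intra-, peri-, extra-tumor and adjacent-normal voxel masks on one grid."""

    tumor: np.ndarray
    peritumor: np.ndarray
    extratumor: np.ndarray
    adjacent_normal: np.ndarray

    def __post_init__(self):
        shapes = {m.shape for m in (self.tumor, self.peritumor,
                                    self.extratumor, self.adjacent_normal)}
        if len(shapes) != 1:
            raise ValueError("all VOI masks must share one grid")
        if self.tumor.sum() == 0:
            raise SegmentationError("tumor mask is empty")
        if np.any(self.tumor & self.peritumor):
            raise ValueError("tumor and peritumor masks overlap")


def resample_isotropic(volume: Volume3D, target_mm: float = ISO_SPACING_MM) -> Volume3D:
    """Trilinear resampling onto an isotropic grid (default 0.5 mm).

    The field of view is preserved to within one voxel; an input already on
    the target grid is returned unchanged (identity interpolation).
    """
    sp = np.asarray(volume.spacing, dtype=float)
    if np.any(sp <= 0) or target_mm <= 0:
        raise ValueError("degenerate spacing")
    if np.allclose(sp, target_mm):
        return Volume3D(volume.data.copy(), (target_mm,) * 3, volume.origin)
    new_shape = np.maximum(np.round(np.array(volume.shape) * sp / target_mm), 1).astype(int)
    grids = np.meshgrid(*[np.arange(n) * target_mm / s for n, s in zip(new_shape, sp)],
                        indexing="ij")
    out = ndimage.map_coordinates(volume.data, np.array(grids), order=1, mode="nearest")
    return Volume3D(out, (target_mm,) * 3, volume.origin)


def segment_lung(volume: Volume3D, lung_threshold: float = LUNG_THRESHOLD_HU,
                 bone_threshold: float = BONE_THRESHOLD_HU) -> np.ndarray:
    """Threshold + connected-component lung mask.

    Low-intensity voxels are candidates; components touching the image border
    (outside air) are removed; the largest remaining component is kept and
    morphologically closed.  Voxels at or above the bone threshold never
    enter the mask.
    """
    cand = volume.data < lung_threshold
    lab, n = ndimage.label(cand)
    if n == 0:
        raise SegmentationError("no voxels below the lung threshold")
    border_labels = set()
    for ax in range(3):
        border_labels |= set(np.unique(np.take(lab, [0, -1], axis=ax)))
    border_labels.discard(0)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    interior = [i + 1 for i in range(n) if (i + 1) not in border_labels]
    if not interior:
        raise SegmentationError("lung mask is empty (all low components touch the border)")
    best = interior[int(np.argmax([sizes[i - 1] for i in interior]))]
    mask = lab == best
    mask = ndimage.binary_closing(mask, structure=ndimage.generate_binary_structure(3, 1),
                                  iterations=2)
    # fill interior holes so lesions (denser than the threshold) stay inside
    mask = ndimage.binary_fill_holes(mask)
    mask &= volume.data < bone_threshold
    if mask.sum() == 0:
        raise SegmentationError("lung mask is empty")
    return mask


def _box_slices(gross_box) -> tuple[slice, slice, slice]:
    lo, hi = gross_box
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def segment_lesion(volume: Volume3D, gross_box, lung_mask: np.ndarray | None = None,
                   min_contrast: float = 100.0) -> np.ndarray:
    """Segment a lesion inside its gross bounding cube.

    Median filter (3^3) -> Otsu threshold within the box -> morphological
    opening and closing -> largest connected component.  When a lung mask is
    given, only lung voxels are considered, so chest wall and bone inside
    the cube cannot be mistaken for the lesion.  A box whose Otsu split
    separates the intensities by less than ``min_contrast`` (HU) is treated
    as containing no lesion.
    """
    from skimage.filters import threshold_otsu

    sl = _box_slices(gross_box)
    for s, n in zip(sl, volume.shape):
        if s.start < 0 or s.stop > n or s.stop - s.start < 3:
            raise GeometryError("gross box does not fit inside the volume grid")
    sub = volume.data[sl]
    smooth = ndimage.median_filter(sub, size=3)
    inside = np.ones(sub.shape, dtype=bool) if lung_mask is None else lung_mask[sl]
    if inside.sum() < 2:
        raise SegmentationError("gross box contains no lung voxels")
    vals = smooth[inside]
    # Otsu is unreliable when the lesion occupies a tiny fraction of the box
    # (the cut lands inside the lesion's own distribution); cap it at a
    # robust parenchyma-based threshold.
    bg_med = float(np.median(vals))
    bg_sd = 1.4826 * float(np.median(np.abs(vals - bg_med)))
    thr = min(threshold_otsu(vals), bg_med + 6.0 * bg_sd)
    fg = (smooth > thr) & inside
    if fg.sum() == 0:
        raise SegmentationError("no lesion component found in the gross box")
    st = ndimage.generate_binary_structure(3, 1)
    fg = ndimage.binary_opening(fg, structure=st)
    fg = ndimage.binary_closing(fg, structure=st)
    lab, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no lesion component found in the gross box")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    comp = lab == (int(np.argmax(sizes)) + 1)
    bg = inside & ~comp
    if bg.sum() == 0 or smooth[comp].mean() - smooth[bg].mean() < min_contrast:
        raise SegmentationError("gross box shows no lesion contrast")
    mask = np.zeros(volume.shape, dtype=bool)
    mask[sl] = comp
    return mask


def build_voi_set(tumor_mask: np.ndarray, lung_mask: np.ndarray, volume: Volume3D,
                  gross_box=None, peri_mm: float = 5.0,
                  adjacent_mm: tuple[float, float] = (10.0, 15.0)) -> LesionVOISet:
    """Derive peri-, extra-tumor, and adjacent-normal VOIs from the tumor.

    peritumor: <= ``peri_mm`` from the tumor surface, within the lung;
    adjacent normal: the ``adjacent_mm`` distance shell within the lung
    (widened inward to ``peri_mm`` if the nominal shell is empty on small
    fields of view); extratumor: lung beyond the peritumoral shell, clipped
    to the gross cube when one is given.
    """
    dist = ndimage.distance_transform_edt(~tumor_mask.astype(bool),
                                          sampling=volume.spacing)
    lung = lung_mask.astype(bool) & ~tumor_mask
    peri = (dist > 0) & (dist <= peri_mm) & lung
    adj = (dist > adjacent_mm[0]) & (dist <= adjacent_mm[1]) & lung
    if adj.sum() == 0:
        adj = (dist > peri_mm) & (dist <= adjacent_mm[1]) & lung
    if adj.sum() == 0:
        raise SegmentationError("no adjacent normal lung tissue available")
    extra = lung & (dist > peri_mm)
    if gross_box is not None:
        boxed = np.zeros_like(extra)
        boxed[_box_slices(gross_box)] = True
        extra &= boxed
    if extra.sum() == 0:
        raise SegmentationError("extratumor VOI is empty")
    if peri.sum() == 0:
        raise SegmentationError("peritumor VOI is empty")
    return LesionVOISet(tumor_mask.astype(bool), peri, extra, adj)


def normalize_intensities(volume: Volume3D, voi_set: LesionVOISet) -> Volume3D:
    """Median-of-adjacent-normal subtraction plus a +300 shift.

    d' = d - median(adjacent normal) + 300.  The same affine shift is applied
    to every voxel so all VOIs live on one consistent non-negative-centred
    scale; the shift makes energy-type features informative.
    """
    adj = voi_set.adjacent_normal
    if adj.sum() == 0:
        raise SegmentationError("adjacent normal mask is empty")
    med = float(np.median(volume.data[adj]))
    return Volume3D(volume.data - med + NORMALIZATION_SHIFT, volume.spacing, volume.origin)
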
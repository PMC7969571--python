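"""Assemble per-slice label maps into a 3D thorax model.

Each labelled slice is one-hot encoded per class, placed at its
``slice_position``, resampled in-plane onto a common target lattice, and
interpolated through-plane linearly — trilinear interpolation overall.  The
result is a :class:`LabelVolume` holding fractional per-class occupancy, so
partial-volume information survives into volumetry instead of being destroyed
by an argmax relabelling (an argmax rendering is still available for export).

Target lattice: in-plane resolution is the finest pixel spacing present in
the series; through-plane resolution dz = min(2 mm, finest in-plane spacing).
Slices represent slabs, so the volume extends half a slice thickness beyond
the first and last slice centers by constant extension; inter-slice gaps are
spanned linearly with no gap-aware correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import ndimage

from .imaging_io import (
    FOREGROUND_CLASSES,
    LabelClass,
    N_CLASSES,
    SeriesRecord,
)


@dataclass
class LabelVolume:
    """Per-class occupancy on a regular 3D lattice.

    ``occupancy`` maps foreground class id → float array of shape
    (nz, rows, cols) with values in [0, 1]; the background occupancy is
    implicit (1 − sum of foreground), which makes per-voxel normalization
    exact by construction.  A crisp integer label grid may be attached as
    ``labels`` (phantom ground truth); occupancy is then derived on demand.

    ``voxel_size`` is (dz, dy, dx) in mm and ``origin`` the world coordinate
    of the corner of voxel (0, 0, 0); voxel centers sit half a voxel inside.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    occupancy: Dict[int, np.ndarray] = field(default_factory=dict)
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be strictly positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != tuple(self.shape):
                raise ValueError("labels shape disagrees with declared shape")

    @classmethod
    def from_labels(cls, labels: np.ndarray, voxel_size, origin=(0.0, 0.0, 0.0)) -> "LabelVolume":
        labels = np.asarray(labels)
        return cls(shape=tuple(labels.shape), voxel_size=tuple(voxel_size),
                   origin=tuple(origin), labels=labels)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def occupancy_of(self, cls_id: int) -> np.ndarray:
        cls_id = int(cls_id)
        if self.labels is not None:
            return (self.labels == cls_id).astype(np.float32)
        if cls_id == LabelClass.background:
            total = np.zeros(self.shape, dtype=np.float32)
            for occ in self.occupancy.values():
                total += occ
            return np.clip(1.0 - total, 0.0, 1.0)
        return self.occupancy.get(cls_id, np.zeros(self.shape, dtype=np.float32))

    def volume_ml(self, cls_id: int) -> float:
        cls_id = int(cls_id)
        if self.labels is not None:
            count = float(np.count_nonzero(self.labels == cls_id))
            return count * self.voxel_volume_mm3 / 1000.0
        if cls_id == LabelClass.background:
            total = float(np.prod(self.shape)) * self.voxel_volume_mm3 / 1000.0
            return total - sum(
                self.volume_ml(c) for c in self.occupancy
            )
        occ = self.occupancy.get(cls_id)
        if occ is None:
            return 0.0
        return float(occ.sum(dtype=np.float64)) * self.voxel_volume_mm3 / 1000.0

    def argmax_labels(self) -> np.ndarray:
        """Crisp per-voxel labels (ties broken toward the lowest class id)."""
        if self.labels is not None:
            return self.labels
        best = self.occupancy_of(LabelClass.background)
        out = np.zeros(self.shape, dtype=np.uint8)
        for cls_id in sorted(self.occupancy):
            occ = self.occupancy[cls_id]
            better = occ > best
            out[better] = cls_id
            best = np.where(better, occ, best)
        return out


def structure_volume(volume: LabelVolume, cls: LabelClass | int) -> float:
    """Volume of one class in ml: sum of occupancy × voxel volume / 1000."""
    return volume.volume_ml(int(cls))


def _resample_slice_onehot(labels: np.ndarray, geometry, target_y: np.ndarray,
                           target_x: np.ndarray) -> Dict[int, np.ndarray]:
    """Linearly resample one slice's one-hot class fields onto target voxel
    centers given in world mm (rows=y, cols=x). Outside the slice FOV the
    foreground occupancy is 0 (background)."""
    # world → fractional index under the center-of-pixel convention
    iy = target_y / geometry.pixel_spacing_row - 0.5
    ix = target_x / geometry.pixel_spacing_col - 0.5
    grid_iy, grid_ix = np.meshgrid(iy, ix, indexing="ij")
    coords = np.stack([grid_iy, grid_ix])
    out: Dict[int, np.ndarray] = {}
    for cls_id in np.unique(labels):
        if cls_id == LabelClass.background:
            continue
        onehot = (labels == cls_id).astype(np.float32)
        out[int(cls_id)] = ndimage.map_coordinates(
            onehot, coords, order=1, mode="constant", cval=0.0
        )
    return out


def assemble(series: SeriesRecord, *, max_dz_mm: float = 2.0) -> LabelVolume:
    """Stack a labelled series into a fractional-occupancy 3D model.

    Requires >= 2 labelled slices at strictly increasing positions. Slices
    with differing in-plane extents are resampled onto the union bounding
    box of all slice footprints.
    """
    if len(series.slices) < 2:
        raise ValueError(
            "assemble needs >= 2 slices; wrap a single slice as a one-slab "
            "volume instead (LabelVolume.from_labels with dz = slice thickness)"
        )
    for i, s in enumerate(series.slices):
        if s.labels is None:
            raise ValueError(f"slice index {i} has no label map")
    positions = series.positions
    if not np.all(np.diff(positions) > 0):
        raise ValueError("slice positions must be strictly increasing")

    geoms = [s.geometry for s in series.slices]
    dxy = min(min(g.pixel_spacing_row, g.pixel_spacing_col) for g in geoms)
    dz = min(max_dz_mm, dxy)

    # union in-plane bounding box in world mm
    y_extent = max(g.rows * g.pixel_spacing_row for g in geoms)
    x_extent = max(g.cols * g.pixel_spacing_col for g in geoms)
    ny = int(round(y_extent / dxy))
    nx = int(round(x_extent / dxy))
    target_y = (np.arange(ny) + 0.5) * dxy
    target_x = (np.arange(nx) + 0.5) * dxy

    z_min = positions[0] - geoms[0].slice_thickness / 2.0
    z_max = positions[-1] + geoms[-1].slice_thickness / 2.0
    nz = max(1, int(round((z_max - z_min) / dz)))
    z_centers = z_min + (np.arange(nz) + 0.5) * dz

    per_slice = [
        _resample_slice_onehot(s.labels, s.geometry, target_y, target_x)
        for s in series.slices
    ]
    classes = sorted({c for sl in per_slice for c in sl})
    zeros = np.zeros((ny, nx), dtype=np.float32)

    occupancy = {c: np.zeros((nz, ny, nx), dtype=np.float32) for c in classes}
    # linear interpolation between bracketing slice centers; constant
    # extension beyond the first/last center (slices represent slabs)
    idx_hi = np.searchsorted(positions, z_centers)
    for k, zc in enumerate(z_centers):
        hi = idx_hi[k]
        if hi == 0:
            lo, hi, w = 0, 0, 0.0
        elif hi >= len(positions):
            lo = hi = len(positions) - 1
            w = 0.0
        else:
            lo = hi - 1
            w = (zc - positions[lo]) / (positions[hi] - positions[lo])
        for c in classes:
            a = per_slice[lo].get(c, zeros)
            b = per_slice[hi].get(c, zeros)
            occupancy[c][k] = (1.0 - w) * a + w * b

    return LabelVolume(
        shape=(nz, ny, nx),
        voxel_size=(dz, dxy, dxy),
        origin=(float(z_min), 0.0, 0.0),
        occupancy=occupancy,
    )


def export_nifti(volume: LabelVolume, path) -> None:
    """Write the argmax-rendered model as NIfTI (for external viewers)."""
    import nibabel as nib

    labels = volume.argmax_labels()
    # NIfTI convention: fastest axis first → (x, y, z)
    data = np.transpose(labels, (2, 1, 0)).astype(np.uint8)
    dz, dy, dx = volume.voxel_size
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = [volume.origin[2], volume.origin[1], volume.origin[0]]
    nib.save(nib.Nifti1Image(data, affine), str(path))
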
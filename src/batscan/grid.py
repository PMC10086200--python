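"""Volume and ROI containers shared by every pipeline stage.

Arrays follow a fixed axis-order contract: ``(slice, row, column)``,
0-based.  ``spacing`` gives millimetres per axis in the *same* order, so a
conventional axial CT with 5 mm slices and 1 mm in-plane pixels has
``spacing=(5.0, 1.0, 1.0)``.  CT volumes carry Hounsfield units, PET
volumes carry SUV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

REGIONS = ("cervical", "supraclavicular", "axillary", "mediastinal")
BILATERAL_REGIONS = ("cervical", "supraclavicular", "axillary")
LATERALITIES = ("left", "right", "midline")


@dataclass
class VolumeGrid:
    """A 3D scalar field (HU or SUV) with voxel spacing and origin in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different values."""
        return VolumeGrid(values, self.spacing, self.origin)


@dataclass
class DepotROI:
    """One adipose depot: binary mask plus anatomic metadata.

    The unit of feature extraction and BAT labeling. Bilateral regions
    (cervical / supraclavicular / axillary) come in left-right pairs within
    a patient; mediastinal depots sit on the midline.
    """

    mask: np.ndarray
    region: str
    laterality: str
    patient_id: str
    depot_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("depot mask must be 3D")
        if not self.mask.any():
            raise ValueError(f"depot {self.depot_id}: empty mask")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.region == "mediastinal" and self.laterality != "midline":
            raise ValueError("mediastinal depots are midline")
        if self.region != "mediastinal" and self.laterality == "midline":
            raise ValueError(f"{self.region} depots are bilateral, not midline")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def check_congruent(*arrays_or_grids) -> tuple[int, int, int]:
    """Assert that all volumes/masks of one patient share a single shape."""
    shapes = set()
    for a in arrays_or_grids:
        shapes.add(a.shape if not isinstance(a, VolumeGrid) else a.values.shape)
    if len(shapes) != 1:
        raise ValueError(f"incongruent shapes: {sorted(shapes)}")
    return shapes.pop()


def _affine(spacing, origin) -> np.ndarray:
    # array axes (slice,row,col) map to world (z,y,x); NIfTI stores x,y,z
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing[2], spacing[1], spacing[0]
    aff[:3, 3] = (origin[2], origin[1], origin[0])
    return aff


def save_volume(vol: VolumeGrid, path: str) -> None:
    """Write a VolumeGrid as NIfTI (axes reordered to x,y,z on disk)."""
    img = nib.Nifti1Image(np.transpose(vol.values, (2, 1, 0)), _affine(vol.spacing, vol.origin))
    nib.save(img, path)


def save_mask(mask: np.ndarray, spacing, path: str) -> None:
    img = nib.Nifti1Image(np.transpose(mask.astype(np.uint8), (2, 1, 0)), _affine(spacing, (0, 0, 0)))
    nib.save(img, path)


def load_volume(path: str) -> VolumeGrid:
    """Read a NIfTI volume back into the (slice,row,col) contract."""
    img = nib.load(path)
    values = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(float)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = (float(img.affine[2, 3]), float(img.affine[1, 3]), float(img.affine[0, 3]))
    return VolumeGrid(values, spacing, origin)


def load_mask(path: str) -> np.ndarray:
    img = nib.load(path)
    return np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)) > 0
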
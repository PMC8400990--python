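"""Volume input/output and masking.

Scans, brain masks and atlas parcellations are carried as NIfTI-1 images
already registered to a common (MNI-like) space; this module only reads
them, applies the brain mask voxelwise, and exposes the atlas with its
region dictionary.  Registration, re-slicing and skull stripping are out
of scope — inputs are assumed preprocessed.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: tolerance for declaring two affines "the same grid"
AFFINE_ATOL = 1e-4


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with its voxel→world (mm) affine.

    ``data`` holds intensities in arbitrary units; ``affine`` is the 4×4
    NIfTI voxel-index→world transform; ``spacing`` the per-axis voxel
    size in mm.  Voxel indices are 0-based; all downstream geometry is
    expressed in world mm through the affine.
    """

    data: np.ndarray
    affine: np.ndarray
    spacing: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3D")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("volume must have at least 2 voxels per axis")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.spacing is None:
            self.spacing = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (…,3) voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (…,3) world mm coordinates to (fractional) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class LabelVolume:
    """Integer atlas parcellation on the same grid as its scan.

    Label 0 is reserved for background / non-cortex.  ``region_table``
    maps every valid nonzero label id to a region name; the packaged
    AAL cortical scheme has exactly 76 entries.
    """

    labels: np.ndarray
    affine: np.ndarray
    region_table: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = np.rint(self.labels).astype(np.int64)
            if not np.allclose(self.labels, as_int, atol=1e-6):
                raise ValueError("labels must be integer-valued")
            self.labels = as_int
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if not self.region_table:
            raise ValueError("region table is empty")
        self.region_table = {int(k): str(v) for k, v in self.region_table.items()}
        present = set(np.unique(self.labels)) - {0}
        unknown = sorted(present - set(self.region_table))
        if unknown:
            logger.warning(
                "atlas contains %d label id(s) outside the region table %s; "
                "treating them as background", len(unknown), unknown[:10]
            )
            lut = np.zeros(self.labels.max() + 1, dtype=self.labels.dtype)
            for k in self.region_table:
                if k <= self.labels.max():
                    lut[k] = k
            self.labels = lut[self.labels]

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_table)

    def as_grid(self) -> VolumeGrid:
        return VolumeGrid(self.labels.astype(float), self.affine)


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D NIfTI-1 image into a :class:`VolumeGrid`.

    Intensities are returned as stored (after the format's scl
    slope/intercept); no rescaling or re-slicing is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError("volume must be 3D")
    return VolumeGrid(np.asarray(data, dtype=np.float64), img.affine)


def write_volume(vol: VolumeGrid, path: str | Path, dtype=np.float64) -> Path:
    """Write a :class:`VolumeGrid` (or label array) as NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    nib.save(img, str(path))
    return path


def write_labels(lab: LabelVolume, path: str | Path) -> Path:
    img = nib.Nifti1Image(lab.labels.astype(np.int32), lab.affine)
    nib.save(img, str(path))
    return path


def apply_brain_mask(scan: VolumeGrid, mask: VolumeGrid) -> VolumeGrid:
    """Zero every scan voxel outside the brain mask.

    The mask is binarized at > 0; grids must agree in shape and affine
    (within ``AFFINE_ATOL``).  Masked-out voxels are set to 0, the
    background value assumed by isosurface extraction.
    """
    if scan.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: scan {scan.shape} vs mask {mask.shape}"
        )
    if not np.allclose(scan.affine, mask.affine, atol=AFFINE_ATOL):
        raise ValueError("affine mismatch between scan and mask")
    out = np.where(mask.data > 0, scan.data, 0.0)
    return VolumeGrid(out, scan.affine.copy(), scan.spacing.copy())


def read_region_table(path: str | Path) -> dict[int, str]:
    """Read a 2-column TSV (label_id, region_name) region dictionary."""
    table: dict[int, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            lid, name = line.split("\t")[:2]
            if i == 0 and not lid.lstrip("-").isdigit():
                continue  # header row
            table[int(lid)] = name
    if not table:
        raise ValueError(f"empty region table: {path}")
    return table


def aal_cortical_table() -> dict[int, str]:
    """The packaged AAL cortical region dictionary (76 regions).

    The cerebrum parcels of the AAL scheme minus the subcortical nuclei
    and olfactory cortex, keeping the standard AAL label ids.
    """
    res = importlib.resources.files("cortexcad.data") / "aal_cortical_76.tsv"
    with importlib.resources.as_file(res) as p:
        return read_region_table(p)


def load_atlas(path: str | Path, region_table_path: str | Path | None = None) -> LabelVolume:
    """Load an atlas label image plus its region dictionary.

    With no ``region_table_path`` the packaged AAL cortical table is
    used.  Labels present in the image but absent from the table are
    mapped to background with a logged warning.
    """
    grid = read_volume(path)
    if region_table_path is None:
        table = aal_cortical_table()
    else:
        table = read_region_table(region_table_path)
    return LabelVolume(grid.data, grid.affine, table)
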
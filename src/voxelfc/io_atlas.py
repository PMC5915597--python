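"""Imaging and phenotype I/O: labelled atlas volumes, masked BOLD scans,
and phenotype tables.

The atlas defines the *voxel enumeration* used everywhere downstream: brain
voxels (nonzero labels) are ordered by ascending Fortran-order linear index
(first array axis fastest). Every voxel x time matrix, pair index and store
row refers to voxels through this enumeration, so it must be bijective and
stable across save/load round trips.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Atlas",
    "SubjectScan",
    "PHENOTYPE_COLUMNS",
    "load_atlas",
    "save_atlas",
    "load_scan",
    "save_scan",
    "load_phenotypes",
    "voxel_indices",
    "voxel_to_world",
]

#: Required columns of a phenotype table, one row per subject.
PHENOTYPE_COLUMNS = (
    "subject_id",
    "site",
    "group",
    "age",
    "sex",
    "education",
    "mean_fd",
    "medicated",
    "hamd",
    "bdi",
    "illness_duration",
)


@dataclasses.dataclass
class Atlas:
    """Integer-labelled parcellation volume with world-coordinate affine.

    Parameters
    ----------
    labels
        3D integer array; 0 is background, positive values are region ids.
    affine
        4x4 voxel-to-world (mm) transform applied to 0-based voxel indices.
    region_names
        Mapping from region id to region name.
    """

    labels: np.ndarray
    affine: np.ndarray
    region_names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("atlas label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("atlas labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        present = np.unique(self.labels)
        present = present[present > 0]
        missing = [int(k) for k in present if int(k) not in self.region_names]
        if missing:
            raise ValueError(f"labels missing from region-name table: {missing}")
        # Fixed enumeration: ascending Fortran-order (x fastest) linear index.
        flat = self.labels.ravel(order="F")
        self._flat_index = np.flatnonzero(flat > 0)
        self._voxel_labels = flat[self._flat_index].astype(np.int32)
        coords = np.unravel_index(self._flat_index, self.labels.shape, order="F")
        self._voxel_coords = np.stack(coords, axis=1).astype(np.int64)

    # -- enumeration ----------------------------------------------------

    @property
    def n_voxels(self) -> int:
        """Number of brain-mask (nonzero-label) voxels."""
        return int(self._flat_index.size)

    @property
    def voxel_labels(self) -> np.ndarray:
        """Region id of each enumerated brain voxel, shape (n_voxels,)."""
        return self._voxel_labels

    @property
    def voxel_coords(self) -> np.ndarray:
        """(i, j, k) voxel coordinates per enumerated voxel, shape (n, 3)."""
        return self._voxel_coords

    def voxel_indices(self, region_id: int) -> np.ndarray:
        """Enumeration positions of the voxels in one region, in order."""
        region_id = int(region_id)
        if region_id <= 0 or region_id not in self.region_names:
            raise KeyError(f"unknown region id {region_id}")
        return np.flatnonzero(self._voxel_labels == region_id)

    def voxel_to_world(self, index: int | np.ndarray) -> np.ndarray:
        """World (mm) coordinates of enumerated voxel(s) via the affine."""
        index = np.asarray(index)
        if np.any(index < 0) or np.any(index >= self.n_voxels):
            raise IndexError("voxel enumeration index out of range")
        ijk = self._voxel_coords[index]
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def validate_roi(self, roi_id: int) -> None:
        """Check that a seed region exists and has at least two voxels."""
        n = self.voxel_indices(roi_id).size
        if n < 2:
            raise ValueError(f"seed region {roi_id} has {n} voxels; need >= 2")


@dataclasses.dataclass
class SubjectScan:
    """A masked BOLD scan: voxel x time matrix in atlas enumeration order."""

    data: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("scan data must be voxel x time (2D)")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints for correlation")
        if np.isnan(self.data).any():
            raise ValueError("scan contains NaN values inside the mask")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[1])


def load_atlas(label_volume_path: str | Path, names_path: str | Path) -> Atlas:
    """Read an atlas from a NIfTI label volume plus a TSV of (id, name).

    The TSV must have columns ``region_id`` and ``name``; duplicate ids or
    labels absent from the table are errors.
    """
    img = nib.load(str(label_volume_path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise ValueError("label volume has non-integer values")
        data = data.astype(np.int32)
    names = pd.read_csv(names_path, sep="\t")
    if not {"region_id", "name"} <= set(names.columns):
        raise ValueError("region-name table needs columns: region_id, name")
    if names["region_id"].duplicated().any():
        raise ValueError("duplicate region ids in name table")
    region_names = {int(r): str(n) for r, n in zip(names["region_id"], names["name"])}
    return Atlas(labels=data, affine=img.affine, region_names=region_names)


def save_atlas(atlas: Atlas, label_volume_path: str | Path, names_path: str | Path) -> None:
    """Write an atlas as NIfTI + region-name TSV (inverse of :func:`load_atlas`)."""
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), atlas.affine)
    nib.save(img, str(label_volume_path))
    rows = sorted(atlas.region_names.items())
    pd.DataFrame(rows, columns=["region_id", "name"]).to_csv(
        names_path, sep="\t", index=False
    )


def load_scan(path: str | Path, atlas: Atlas, subject_id: str | None = None) -> SubjectScan:
    """Read a 4D NIfTI scan, mask it by the atlas and order rows by enumeration.

    The scan grid and affine must match the atlas exactly. Constant (zero
    variance) voxels are accepted here; downstream FC computation flags them.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume")
    if img.shape[:3] != atlas.labels.shape:
        raise ValueError(f"{path}: grid {img.shape[:3]} != atlas {atlas.labels.shape}")
    if not np.allclose(img.affine, atlas.affine, atol=1e-4):
        raise ValueError(f"{path}: affine does not match atlas affine")
    vol = np.asanyarray(img.dataobj, dtype=np.float64)
    n_t = vol.shape[3]
    flat = vol.reshape((-1, n_t), order="F")
    data = flat[atlas._flat_index]
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return SubjectScan(data=data, subject_id=sid)


def save_scan(scan: SubjectScan, atlas: Atlas, path: str | Path) -> None:
    """Embed a masked scan back into the atlas grid and write 4D NIfTI."""
    if scan.data.shape[0] != atlas.n_voxels:
        raise ValueError("scan rows do not match atlas enumeration")
    n_t = scan.n_timepoints
    flat = np.zeros((int(np.prod(atlas.labels.shape)), n_t), dtype=np.float32)
    flat[atlas._flat_index] = scan.data
    vol = flat.reshape(atlas.labels.shape + (n_t,), order="F")
    nib.save(nib.Nifti1Image(vol, atlas.affine), str(path))


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV and validate required columns and uniqueness."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in phenotype table")
    return df


# Functional aliases for the method-style API ----------------------------


def voxel_indices(atlas: Atlas, region_id: int) -> np.ndarray:
    return atlas.voxel_indices(region_id)


def voxel_to_world(atlas: Atlas, index: int | np.ndarray) -> np.ndarray:
    return atlas.voxel_to_world(index)
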
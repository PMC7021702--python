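"""Volumetric image and subject-manifest I/O.

Establishes the grid and coordinate conventions shared by every other
module: voxel indices are 0-based, arrays are indexed ``(x, y, z)``, and
world (mm) coordinates follow the NIfTI affine.  All subjects of a study
must live on one identical grid; no resampling is performed here.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("AD", "MCI", "CTRL")

#: affines closer than this (max abs difference, mm) count as identical
AFFINE_ATOL = 1e-4


@dataclass(frozen=True)
class VolumeGrid:
    """Sampling grid of a 3-D volume: shape, voxel size and affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel-index -> world-mm

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm, from the affine column norms."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    def matches(self, other: "VolumeGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    @classmethod
    def isotropic(cls, shape, voxel_size_mm: float = 2.5) -> "VolumeGrid":
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        return cls(tuple(shape), affine)


@dataclass
class ScalarVolume:
    """One scalar value per voxel on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if np.issubdtype(self.values.dtype, np.floating):
            bad = int(np.count_nonzero(~np.isfinite(self.values)))
            if bad:
                raise ValueError(f"volume contains {bad} non-finite voxels")


@dataclass
class SubjectManifest:
    """Cohort table: one row per subject with id, group and FA-volume path."""

    table: pd.DataFrame  # columns: id, group, path

    def __post_init__(self):
        required = {"id", "group", "path"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("no subjects in manifest")
        dupes = self.table["id"][self.table["id"].duplicated()].tolist()
        if dupes:
            raise ValueError(f"duplicate subject ids: {dupes}")
        bad = sorted(set(self.table["group"]) - set(VALID_GROUPS))
        if bad:
            raise ValueError(
                f"unknown group label(s) {bad}; allowed labels are {list(VALID_GROUPS)}"
            )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def groups(self) -> list[str]:
        return list(self.table["group"])

    def group_counts(self) -> dict[str, int]:
        return dict(Counter(self.table["group"]))

    def subset(self, groups) -> "SubjectManifest":
        sub = self.table[self.table["group"].isin(list(groups))].reset_index(drop=True)
        return SubjectManifest(sub)


def read_volume(path, expect_integer: bool = False) -> ScalarVolume:
    """Read a single 3-D NIfTI volume.

    Integer-typed images (atlas labels) are preserved losslessly; floating
    images are returned as float64.  Raises on missing files, 4-D images and
    non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"expected 3-D volume, got {len(img.shape)}-D image at {path}"
        )
    if expect_integer or np.issubdtype(img.get_data_dtype(), np.integer):
        values = np.asarray(img.dataobj).astype(np.int32)
    else:
        values = img.get_fdata(dtype=np.float64)
    grid = VolumeGrid(tuple(img.shape), np.asarray(img.affine))
    return ScalarVolume(grid, values)


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a :class:`ScalarVolume` as NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    values = vol.values
    if np.issubdtype(values.dtype, np.integer):
        data = values.astype(np.int32)
    else:
        data = values.astype(np.float64)
    img = nib.Nifti1Image(data, vol.grid.affine)
    nib.save(img, str(path))


def read_manifest(path, check_files: bool = True) -> SubjectManifest:
    """Read a CSV subject manifest with columns ``id,group,path``.

    Relative volume paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    try:
        table = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError("no subjects: manifest file is empty") from None
    if len(table) == 0:
        raise ValueError("no subjects: manifest has a header but no rows")
    table["path"] = [
        str(p) if os.path.isabs(str(p)) else str(path.parent / str(p))
        for p in table["path"]
    ]
    manifest = SubjectManifest(table.reset_index(drop=True))
    if check_files:
        for sid, p in zip(manifest.subject_ids, manifest.table["path"]):
            if not Path(p).exists():
                raise FileNotFoundError(f"volume for subject {sid!r} not found: {p}")
    logger.info("manifest loaded: %s", manifest.group_counts())
    return manifest


def write_manifest(manifest: SubjectManifest, path, relative: bool = False) -> None:
    """Write the manifest CSV; with ``relative`` the volume paths are stored
    relative to the manifest's own directory (portable cohort folders)."""
    table = manifest.table[["id", "group", "path"]].copy()
    if relative:
        base = Path(path).parent.resolve()
        table["path"] = [
            os.path.relpath(Path(p).resolve(), base) for p in table["path"]
        ]
    table.to_csv(path, index=False)


def load_cohort_volumes(manifest: SubjectManifest) -> list[ScalarVolume]:
    """Load all subject volumes, enforcing a single shared grid."""
    vols = []
    ref_grid = None
    ref_id = None
    for sid, p in zip(manifest.subject_ids, manifest.table["path"]):
        vol = read_volume(p)
        if ref_grid is None:
            ref_grid, ref_id = vol.grid, sid
        elif not vol.grid.matches(ref_grid):
            raise ValueError(
                f"grid mismatch: subject {sid!r} is not on the grid of "
                f"subject {ref_id!r}"
            )
        vols.append(vol)
    return vols
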
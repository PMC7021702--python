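"""Atlas masks and the subjects x voxels FA feature matrix."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from favoxel.volume_io import (
    ScalarVolume,
    SubjectManifest,
    load_cohort_volumes,
)

#: derived region: voxelwise intersection of the hippocampal cingulum and
#: the parahippocampal gyrus (nonempty only when the two source masks,
#: typically from different atlases, overlap)
DERIVED_REGIONS = {
    "parahippocampal_cingulum": ("cingulum_hippocampal", "parahippocampal_gyrus"),
}


@dataclass
class AtlasLabels:
    """Integer label volume plus a region-name -> label-set table."""

    labels: ScalarVolume
    name_table: dict[str, set[int]]
    provenance: str = "toy"

    def __post_init__(self):
        if not np.issubdtype(self.labels.values.dtype, np.integer):
            raise ValueError("atlas label volume must be integer typed")
        present = set(np.unique(self.labels.values).tolist())
        for name, lbls in self.name_table.items():
            self.name_table[name] = {int(v) for v in lbls}
            if not self.name_table[name] & present:
                raise ValueError(
                    f"region {name!r} maps to no label present in the volume"
                )

    @property
    def region_names(self) -> list[str]:
        return sorted(self.name_table)

    def save(self, volume_path, names_path) -> None:
        from favoxel.volume_io import write_volume

        write_volume(self.labels, volume_path)
        Path(names_path).write_text(
            json.dumps(
                {
                    "provenance": self.provenance,
                    "regions": {k: sorted(v) for k, v in self.name_table.items()},
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, volume_path, names_path) -> "AtlasLabels":
        from favoxel.volume_io import read_volume

        vol = read_volume(volume_path, expect_integer=True)
        meta = json.loads(Path(names_path).read_text())
        table = {k: set(v) for k, v in meta["regions"].items()}
        return cls(vol, table, provenance=meta.get("provenance", "unknown"))


def region_mask(atlas: AtlasLabels, region: str) -> ScalarVolume:
    """Boolean mask for a named region, a derived region, or "whole_brain".

    "whole_brain" is the union of all labels (> 0).  Named regions pool
    their left/right labels.  Unknown names raise with the valid list.
    """
    vals = atlas.labels.values
    if region == "whole_brain":
        mask = vals > 0
    elif region in atlas.name_table:
        mask = np.isin(vals, sorted(atlas.name_table[region]))
    elif region in DERIVED_REGIONS:
        a, b = DERIVED_REGIONS[region]
        mask = region_mask(atlas, a).values & region_mask(atlas, b).values
    else:
        valid = atlas.region_names + sorted(DERIVED_REGIONS) + ["whole_brain"]
        raise KeyError(f"unknown region {region!r}; valid regions: {valid}")
    return ScalarVolume(atlas.labels.grid, mask)


@dataclass
class FeatureMatrix:
    """FA values per (subject, voxel) with voxel-coordinate bookkeeping.

    Columns follow lexicographic (x, y, z) voxel order of the mask, so the
    matrix is a pure deterministic function of the volumes and the mask.
    """

    values: np.ndarray  # (n_subjects, n_voxels)
    voxel_index: np.ndarray  # (n_voxels, 3) int voxel coordinates
    subject_ids: list[str]
    groups: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x voxels)")
        if self.values.shape != (len(self.subject_ids), len(self.voxel_index)):
            raise ValueError("values shape inconsistent with ids/voxel index")
        if len(self.subject_ids) != len(self.groups):
            raise ValueError("one group label per subject required")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset_groups(self, groups) -> "FeatureMatrix":
        groups = list(groups)
        keep = [i for i, g in enumerate(self.groups) if g in groups]
        return FeatureMatrix(
            self.values[keep],
            self.voxel_index,
            [self.subject_ids[i] for i in keep],
            [self.groups[i] for i in keep],
        )

    def to_tsv(self, tsv_path, coords_path) -> None:
        import pandas as pd

        cols = ["_".join(map(str, c)) for c in self.voxel_index]
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=cols)
        df.insert(0, "group", self.groups)
        df.to_csv(tsv_path, sep="\t", index_label="id")
        Path(coords_path).write_text(json.dumps(self.voxel_index.tolist()))


def mask_coordinates(mask: ScalarVolume) -> np.ndarray:
    """Lexicographically ordered (x, y, z) coordinates of the mask voxels."""
    return np.argwhere(mask.values.astype(bool))


def features_from_arrays(
    fa_arrays: np.ndarray,
    subject_ids: list[str],
    groups: list[str],
    mask: ScalarVolume,
) -> FeatureMatrix:
    """Build a FeatureMatrix from an in-memory (n, nx, ny, nz) FA stack."""
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError("empty mask: no voxels to extract")
    coords = mask_coordinates(mask)
    values = np.asarray(fa_arrays)[:, m]  # boolean indexing follows C order
    nan_cols = np.isnan(values).any(axis=0)
    if nan_cols.any():
        bad = coords[np.argmax(nan_cols)]
        raise ValueError(f"NaN FA inside mask at voxel {tuple(bad)}")
    return FeatureMatrix(values, coords, list(subject_ids), list(groups))


def extract_features(manifest: SubjectManifest, mask: ScalarVolume) -> FeatureMatrix:
    """Load every subject's FA volume and assemble the feature matrix.

    All volumes must share the mask's grid; the offending subject is named
    on mismatch.
    """
    vols = load_cohort_volumes(manifest)
    for sid, vol in zip(manifest.subject_ids, vols):
        if not vol.grid.matches(mask.grid):
            raise ValueError(f"grid mismatch: subject {sid!r} not on the mask's grid")
    stack = np.stack([v.values for v in vols])
    return features_from_arrays(stack, manifest.subject_ids, manifest.groups, mask)
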
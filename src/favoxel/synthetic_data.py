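"""Synthetic three-group FA cohort, DWI simulator and toy atlas.

The cohort generator emulates the statistical structure the downstream
analysis assumes: per-subject FA volumes on one shared grid, drawn from a
smooth spatially-correlated field, with a group-level FA *decrease* planted
inside one designated bilateral white-matter region for the AD group
(attenuated or absent for MCI).  Outside the planted region the three
groups share one distribution.  A tensor phantom and a Rician-noise DWI
simulator exercise the tensor-fitting stage; the toy atlas stands in for
anatomical label atlases with eight named bilateral regions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from favoxel.roi_features import AtlasLabels, region_mask
from favoxel.tensor_fa import (
    DWIDataset,
    GradientScheme,
    TensorVolume,
)
from favoxel.volume_io import (
    ScalarVolume,
    SubjectManifest,
    VolumeGrid,
    write_manifest,
    write_volume,
)
import pandas as pd

#: the eight bilateral white-matter regions of the toy atlas
TOY_REGIONS = (
    "parahippocampal_gyrus",
    "uncinate_fasciculus",
    "superior_longitudinal_fasciculus",
    "cingulum_hippocampal",
    "cingulum_cingulate",
    "fornix",
    "splenium_cc",
    "genu_cc",
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings of the synthetic cohort.

    FA is unitless in [0, 1]; ``smoothness`` is the FWHM (mm) of the
    spatial correlation of both the shared baseline field and the
    per-subject voxel-level jitter; ``effect_delta_ad``/``effect_delta_mci``
    are the expected FA decreases planted at every voxel of
    ``effect_region``.  Between-subject variability has two components:
    ``subject_sd`` scales a smooth voxel-level Gaussian field, and
    ``region_offset_sd`` scales one scalar FA offset per atlas region per
    subject, emulating tract-level (spatially coherent) variation across
    individuals — the component that keeps regional mean FA from being a
    noise-free statistic, as in real cohorts.
    """

    shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 2.5
    n_per_group: int = 15
    baseline_fa_mean: float = 0.5
    baseline_fa_sd: float = 0.03
    smoothness: float = 6.0
    effect_region: str = "cingulum_hippocampal"
    effect_delta_ad: float = 0.10
    effect_delta_mci: float = 0.0
    subject_sd: float = 0.04
    region_offset_sd: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.baseline_fa_mean < 1:
            raise ValueError("baseline_fa_mean must lie in (0, 1)")
        if self.effect_delta_ad < 0 or self.effect_delta_mci < 0:
            raise ValueError("effect deltas must be >= 0")
        if self.baseline_fa_mean - max(self.effect_delta_ad, self.effect_delta_mci) < 0:
            raise ValueError("delta produces negative expected FA")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid.isotropic(self.shape, self.voxel_size_mm)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["shape"] = list(d["shape"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["shape"] = tuple(d["shape"])
        return cls(**d)


def make_toy_atlas(grid: VolumeGrid) -> AtlasLabels:
    """Deterministic eight-region bilateral label volume.

    Each region is a pair of rectangular blocks mirrored across the
    mid-sagittal (x) plane, stacked along z; left and right blocks carry
    distinct labels merged under one region name.  Requires a grid of at
    least 16 voxels per axis.
    """
    nx, ny, nz = grid.shape
    if min(nx, ny, nz) < 16:
        raise ValueError(
            f"grid too small for the toy atlas: need >= 16 voxels per axis, got {grid.shape}"
        )
    labels = np.zeros(grid.shape, dtype=np.int32)
    y0, y1 = ny // 4, 3 * ny // 4
    x_left = slice(1, nx // 2 - 1)
    x_right = slice(nx - (nx // 2 - 1), nx - 1)  # mirror of x_left
    usable_z = nz - 2
    name_table: dict[str, set[int]] = {}
    for i, name in enumerate(TOY_REGIONS):
        z0 = 1 + (i * usable_z) // 8
        z1 = 1 + ((i + 1) * usable_z) // 8
        left_label, right_label = i + 1, i + 9
        labels[x_left, y0:y1, z0:z1] = left_label
        labels[x_right, y0:y1, z0:z1] = right_label
        name_table[name] = {left_label, right_label}
    return AtlasLabels(ScalarVolume(grid, labels), name_table, provenance="toy")


def _smooth_unit_field(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    """Zero-mean, unit-variance spatially correlated Gaussian field."""
    field = rng.standard_normal(cfg.shape)
    if cfg.smoothness <= 0:
        return field
    sigma_vox = cfg.smoothness * _FWHM_TO_SIGMA / cfg.voxel_size_mm
    smoothed = gaussian_filter(field, sigma_vox, mode="nearest")
    # restore unit marginal variance lost to averaging (impulse-response norm)
    impulse = np.zeros(cfg.shape)
    impulse[tuple(s // 2 for s in cfg.shape)] = 1.0
    kernel_norm = np.sqrt((gaussian_filter(impulse, sigma_vox, mode="nearest") ** 2).sum())
    return smoothed / kernel_norm


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # stream 0 = shared baseline field, streams 1.. = per-subject jitter
    return np.random.default_rng(np.random.SeedSequence([seed, subject_index + 1]))


def cohort_arrays(
    cfg: CohortConfig, atlas: AtlasLabels
) -> tuple[list[str], list[str], np.ndarray]:
    """In-memory cohort: (subject ids, group labels, FA array of shape (n, *grid)).

    Subjects are ordered AD, MCI, CTRL with ``n_per_group`` each; all
    randomness derives deterministically from ``cfg.seed`` and the subject
    index.  Each subject is baseline field, minus the group's planted delta
    inside the effect region, plus one regional FA offset per atlas region
    (both hemispheres share the offset; the background gets its own), plus
    a smooth voxel-level jitter field.
    """
    effect = region_mask(atlas, cfg.effect_region).values.astype(bool)
    baseline = (
        cfg.baseline_fa_mean
        + cfg.baseline_fa_sd * _smooth_unit_field(_subject_rng(cfg.seed, -1), cfg)
    )
    labvol = atlas.labels.values
    region_voxel_sets = [
        np.isin(labvol, sorted(lbls)) for _, lbls in sorted(atlas.name_table.items())
    ] + [labvol == 0]
    deltas = {"AD": cfg.effect_delta_ad, "MCI": cfg.effect_delta_mci, "CTRL": 0.0}
    ids, groups = [], []
    fa = np.empty((3 * cfg.n_per_group,) + tuple(cfg.shape))
    idx = 0
    for group in ("AD", "MCI", "CTRL"):
        for k in range(cfg.n_per_group):
            rng = _subject_rng(cfg.seed, idx)
            vol = baseline.copy()
            vol[effect] -= deltas[group]
            offsets = rng.normal(0.0, cfg.region_offset_sd, len(region_voxel_sets))
            if cfg.region_offset_sd > 0:
                for sel, off in zip(region_voxel_sets, offsets):
                    vol[sel] += off
            if cfg.subject_sd > 0:
                vol += cfg.subject_sd * _smooth_unit_field(rng, cfg)
            fa[idx] = np.clip(vol, 0.0, 1.0)
            ids.append(f"{group}{k + 1:02d}")
            groups.append(group)
            idx += 1
    return ids, groups, fa


def generate_cohort(
    cfg: CohortConfig, atlas: AtlasLabels, out_dir
) -> SubjectManifest:
    """Write the synthetic cohort's FA volumes and CSV manifest to disk."""
    if cfg.effect_region not in atlas.name_table:
        raise KeyError(
            f"unknown effect region {cfg.effect_region!r}; "
            f"valid regions: {sorted(atlas.name_table)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids, groups, fa = cohort_arrays(cfg, atlas)
    grid = cfg.grid
    paths = []
    for sid, vol in zip(ids, fa):
        p = out_dir / f"{sid}_fa.nii.gz"
        write_volume(ScalarVolume(grid, vol), p)
        paths.append(str(p.resolve()))
    manifest = SubjectManifest(
        pd.DataFrame({"id": ids, "group": groups, "path": paths})
    )
    write_manifest(manifest, out_dir / "manifest.csv", relative=True)
    cfg.to_yaml(out_dir / "cohort_config.yaml")
    return manifest


def _axial_eigenvalues(fa: float, md: float = 0.7e-3) -> tuple[float, float]:
    """(l1, l2=l3) of an axially symmetric tensor with given FA and mean
    diffusivity (mm^2/s).  For l2 = l3 the FA formula reduces to
    FA = (l1 - l2) / sqrt(l1^2 + 2 l2^2), inverted in closed form."""
    if not 0 <= fa < 1:
        raise ValueError(f"unreachable FA target {fa}: need 0 <= FA < 1")
    if fa == 0:
        return md, md
    r = (fa**2 + fa * np.sqrt(3 - 2 * fa**2)) / (1 - fa**2)  # l1/l2 - 1
    l2 = 3 * md / (3 + r)
    return l2 * (1 + r), l2


def make_tensor_phantom(
    grid: VolumeGrid,
    atlas: AtlasLabels,
    fa_target_by_region: dict[str, float],
    md: float = 0.7e-3,
    background_fa: float = 0.0,
) -> TensorVolume:
    """Axially symmetric tensor field whose analytic FA hits each region's
    target exactly; the principal axis rotates smoothly with position.
    Fully deterministic."""
    nx, ny, nz = grid.shape
    x, _, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    theta = 2 * np.pi * x / max(nx, 1)
    phi = np.pi * (z + 1) / (nz + 2)  # keep away from the poles
    e = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=-1,
    )
    fa_map = np.full(grid.shape, float(background_fa))
    for name, target in fa_target_by_region.items():
        fa_map[region_mask(atlas, name).values.astype(bool)] = float(target)
    l1 = np.empty(grid.shape)
    l2 = np.empty(grid.shape)
    for target in np.unique(fa_map):
        a, b = _axial_eigenvalues(float(target), md)
        sel = fa_map == target
        l1[sel], l2[sel] = a, b
    eye = np.eye(3)
    D = (l1 - l2)[..., None, None] * (e[..., :, None] * e[..., None, :]) + l2[
        ..., None, None
    ] * eye
    return TensorVolume.from_matrices(grid, D)


def simulate_dwi(
    tensors: TensorVolume,
    scheme: GradientScheme,
    snr: float = np.inf,
    seed: int = 0,
    s0: float = 1000.0,
) -> DWIDataset:
    """Mono-exponential tensor signal S = S0 exp(-b g^T D g), with Rician
    noise at finite SNR (two Gaussian channels of sd S0/snr, magnitude
    taken)."""
    if not (snr > 0):
        raise ValueError("snr must be positive (np.inf for noise-free)")
    D = tensors.as_matrices()
    if np.linalg.eigvalsh(D).min() < -1e-12:
        raise ValueError("all tensors must be positive semidefinite")
    g = scheme.directions
    b = scheme.b_values
    # quadratic form g^T D g per voxel per direction
    q = np.einsum("mi,...ij,mj->...m", g, D, g)
    signal = s0 * np.exp(-b * q)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sd = s0 / snr
        n1 = rng.normal(0.0, sd, signal.shape)
        n2 = rng.normal(0.0, sd, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DWIDataset(tensors.grid, signal, scheme)
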
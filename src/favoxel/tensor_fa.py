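"""Diffusion-tensor fitting and fractional-anisotropy computation.

The single-tensor model of diffusion MRI relates the measured signal to the
3x3 symmetric diffusion tensor D via

    S(b, g) = S0 * exp(-b * g^T D g)

where b is the diffusion weighting (s/mm^2) and g a unit gradient
direction.  The tensor is estimated per voxel by ordinary log-linear least
squares; fractional anisotropy is the normalised eigenvalue dispersion

    FA = sqrt(3/2) * sqrt(sum_i (l_i - lbar)^2) / sqrt(sum_i l_i^2)

with eigenvalues l_1 >= l_2 >= l_3 and their mean lbar.  FA is 0 for
isotropic diffusion and approaches 1 when a single eigenvalue dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from favoxel.volume_io import ScalarVolume, VolumeGrid

#: signals at or below 0 are floored at this fraction of S0 before the log
SIGNAL_FLOOR_FRAC = 1e-10

# component order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
_DIAG = (0, 1, 2)
_OFFDIAG = ((0, 1), (0, 2), (1, 2))


@dataclass
class GradientScheme:
    """Per-volume diffusion weightings and unit gradient directions."""

    b_values: np.ndarray  # (m,), s/mm^2
    directions: np.ndarray  # (m, 3), unit norm where b > 0

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if len(self.b_values) != len(self.directions):
            raise ValueError("b_values and directions must have equal length")
        dw = self.b_values > 0
        norms = np.linalg.norm(self.directions[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("all nonzero-b gradient directions must be unit norm")

    def __len__(self) -> int:
        return len(self.b_values)

    @classmethod
    def standard(cls, n_directions: int = 32, b: float = 1000.0) -> "GradientScheme":
        """One b=0 volume plus ``n_directions`` directions at b (s/mm^2).

        Directions are spread on the sphere by the Fibonacci spiral, a
        deterministic near-uniform scheme.
        """
        i = np.arange(n_directions)
        golden = (1 + 5**0.5) / 2
        z = 1 - 2 * (i + 0.5) / n_directions
        theta = 2 * np.pi * i / golden
        r = np.sqrt(np.clip(1 - z**2, 0, None))
        dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        b_values = np.concatenate([[0.0], np.full(n_directions, float(b))])
        directions = np.vstack([[0.0, 0.0, 0.0], dirs])
        return cls(b_values, directions)


@dataclass
class DWIDataset:
    """4-D diffusion-weighted signal set on a shared grid."""

    grid: VolumeGrid
    signals: np.ndarray  # (nx, ny, nz, m), >= 0
    scheme: GradientScheme

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape[:3] != self.grid.shape:
            raise ValueError("signal volume shape does not match grid")
        if self.signals.shape[3] != len(self.scheme):
            raise ValueError("scheme length must equal number of 3-D volumes")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite")


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor, 6 unique components (mm^2/s).

    Component order along the last axis: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.
    """

    grid: VolumeGrid
    components: np.ndarray  # (nx, ny, nz, 6)
    valid: np.ndarray | None = None  # True where the fit was usable

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != self.grid.shape + (6,):
            raise ValueError("tensor component array must be shape grid + (6,)")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("tensor components must be finite")
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)

    def as_matrices(self) -> np.ndarray:
        """Return the (..., 3, 3) symmetric matrix form."""
        c = self.components
        D = np.zeros(c.shape[:-1] + (3, 3))
        for k, i in enumerate(_DIAG):
            D[..., i, i] = c[..., k]
        for k, (i, j) in enumerate(_OFFDIAG, start=3):
            D[..., i, j] = c[..., k]
            D[..., j, i] = c[..., k]
        return D

    @classmethod
    def from_matrices(cls, grid: VolumeGrid, D: np.ndarray) -> "TensorVolume":
        c = np.empty(grid.shape + (6,))
        for k, i in enumerate(_DIAG):
            c[..., k] = D[..., i, i]
        for k, (i, j) in enumerate(_OFFDIAG, start=3):
            c[..., k] = D[..., i, j]
        return cls(grid, c)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Rows b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz) for b > 0."""
    g = scheme.directions
    b = scheme.b_values
    return b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(dwi: DWIDataset) -> TensorVolume:
    """Ordinary log-linear least-squares tensor fit, per voxel.

    Solves ln(S/S0) = -b g^T D g with S0 the mean of the b=0 volumes.
    Voxels with S0 <= 0 are marked invalid (zero tensor, excluded via the
    validity mask).  Non-positive diffusion-weighted signals are floored at
    a tiny fraction of S0 before the logarithm and flag the voxel invalid.
    """
    b0_mask = dwi.scheme.b_values == 0
    if not np.any(b0_mask):
        raise ValueError("at least one b=0 volume is required")
    dw_mask = ~b0_mask
    B = design_matrix(dwi.scheme)[dw_mask]
    if dw_mask.sum() < 6 or np.linalg.matrix_rank(B) < 6:
        raise ValueError(
            "insufficient gradient directions: the tensor fit needs >= 6 "
            "non-collinear diffusion-weighted directions"
        )
    pinv = np.linalg.pinv(B)  # (6, m_dw)

    S0 = dwi.signals[..., b0_mask].mean(axis=-1)
    S = dwi.signals[..., dw_mask]

    valid = S0 > 0
    S0_safe = np.where(valid, S0, 1.0)
    floor = SIGNAL_FLOOR_FRAC * S0_safe[..., None]
    floored = S <= 0
    valid &= ~floored.any(axis=-1)
    S_safe = np.maximum(S, floor)

    y = -np.log(S_safe / S0_safe[..., None])  # (..., m_dw)
    comps = np.einsum("km,...m->...k", pinv, y)
    comps[~valid] = 0.0
    return TensorVolume(dwi.grid, comps, valid=valid)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalue triples (..., 3); negatives clamped to 0 first."""
    lam = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)  # zero tensor -> FA 0 by convention
    return np.clip(fa, 0.0, 1.0)


def compute_fa(tensors: TensorVolume) -> ScalarVolume:
    """Per-voxel FA map in [0, 1]; invalid voxels get FA 0."""
    evals = np.linalg.eigvalsh(tensors.as_matrices())
    fa = fa_from_eigenvalues(evals)
    fa[~tensors.valid] = 0.0
    return ScalarVolume(tensors.grid, fa)


def read_bval_bvec(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL-style gradient scheme (bvals: one row; bvecs: 3 rows)."""
    b_values = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientScheme(b_values, bvecs)


def write_bval_bvec(scheme: GradientScheme, bval_path, bvec_path) -> None:
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in scheme.b_values) + "\n")
    lines = [
        " ".join(f"{v:.10f}" for v in scheme.directions[:, ax]) for ax in range(3)
    ]
    Path(bvec_path).write_text("\n".join(lines) + "\n")
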
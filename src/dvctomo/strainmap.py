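"""Nodal displacements to per-voxel deformation gradients and
Green-Lagrange strain tensors.

Each voxel's affine map is least-squares fitted from the displacements
of the nodes constituting the voxel (its 8 corners on a structured node
lattice); the deformation gradient is the affine's linear part and the
strain follows as ``E = 1/2 (F^T F - I)``, which vanishes under rigid
rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dvctomo.dvc_core import DisplacementField, NodeStatus
from dvctomo.register_blend import AffineTransform

__all__ = [
    "StrainField",
    "nodal_displacements",
    "voxel_affine",
    "green_lagrange",
    "strain_field",
]


@dataclass
class StrainField:
    """Per-cell deformation gradient and Green-Lagrange tensor."""

    cell_coords: np.ndarray  # (m, 3), cell centers in reference voxels
    F: np.ndarray  # (m, 3, 3)
    E: np.ndarray  # (m, 3, 3), symmetric

    def __post_init__(self) -> None:
        self.cell_coords = np.asarray(self.cell_coords, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if np.abs(self.E - np.transpose(self.E, (0, 2, 1))).max(initial=0.0) > 1e-9:
            raise ValueError("strain tensors must be symmetric")


def nodal_displacements(ref_coords, def_coords) -> np.ndarray:
    """Displacements ``u = def - ref`` per node."""
    ref_coords = np.asarray(ref_coords, dtype=float)
    def_coords = np.asarray(def_coords, dtype=float)
    if ref_coords.shape != def_coords.shape:
        raise ValueError("node sets must have matching shapes")
    return def_coords - ref_coords


def _fit_affine(corners: np.ndarray, displacements: np.ndarray):
    """Least-squares displacement gradient + offset from corner nodes.

    Coordinates are centered first, so for coplanar corner sets the
    minimum-norm solution carries zero gradient along the degenerate
    (axis-aligned) direction.
    """
    X = np.asarray(corners, dtype=float)
    U = np.asarray(displacements, dtype=float)
    c = X.mean(axis=0)
    Xc = X - c
    G, *_ = np.linalg.lstsq(Xc, U, rcond=None)
    G = G.T  # u ≈ G (x - c) + u0
    u0 = U.mean(axis=0)
    return G, u0, c


def voxel_affine(node_positions, node_displacements) -> AffineTransform:
    """Affine map of one voxel from its 8 corner nodes.

    Exact when the 8 displacements are affine-consistent; errors on a
    degenerate corner set.
    """
    X = np.asarray(node_positions, dtype=float)
    U = np.asarray(node_displacements, dtype=float)
    if X.shape != (8, 3) or U.shape != (8, 3):
        raise ValueError("expected 8 corner positions and 8 displacement vectors")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc, tol=1e-9 * max(np.abs(Xc).max(), 1e-300)) < 3:
        raise ValueError("degenerate corner set: corners do not span 3D")
    G, u0, c = _fit_affine(X, U)
    linear = np.eye(3) + G
    # T(x) = x + u(x) = linear @ x + (u0 - G c)
    return AffineTransform(linear=linear, translation=u0 - G @ c, kind="general")


def green_lagrange(F) -> np.ndarray:
    """Green-Lagrange strain ``E = 1/2 (F^T F - I)``."""
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3) or not np.all(np.isfinite(F)):
        raise ValueError("F must be a finite 3x3 matrix")
    return 0.5 * (F.T @ F - np.eye(3))


def strain_field(f: DisplacementField, spacing: float = 1.0) -> StrainField:
    """Per-cell strain over the field's structured node lattice.

    The field must be filtered (no unconverged nodes) and carry a node
    grid.  Cells are formed between adjacent lattice nodes; along
    lattice axes of extent 1 (plane fields) the deformation gradient is
    taken as zero in that direction.
    """
    if np.any(f.status == NodeStatus.UNCONVERGED):
        raise ValueError("strain_field requires a filtered field (no unconverged nodes)")
    if f.grid_shape is None:
        raise ValueError("strain_field requires a field with lattice structure")
    grid_shape = tuple(f.grid_shape)
    if len(grid_shape) == 2:
        # plane field: treat as a 1-thick 3D lattice
        grid_shape = (1,) + grid_shape
    coords = f.node_coords.reshape(grid_shape + (3,)).astype(float)
    u = f.u.reshape(grid_shape + (3,))

    cell_dims = tuple(max(s - 1, 1) for s in grid_shape)
    centers, Fs, Es = [], [], []
    for i in range(cell_dims[0]):
        for j in range(cell_dims[1]):
            for k in range(cell_dims[2]):
                sel_i = [i, i + 1] if grid_shape[0] > 1 else [i]
                sel_j = [j, j + 1] if grid_shape[1] > 1 else [j]
                sel_k = [k, k + 1] if grid_shape[2] > 1 else [k]
                corner_x = coords[np.ix_(sel_i, sel_j, sel_k)].reshape(-1, 3)
                corner_u = u[np.ix_(sel_i, sel_j, sel_k)].reshape(-1, 3)
                G, _, c = _fit_affine(corner_x, corner_u)
                F = np.eye(3) + G
                centers.append(c)
                Fs.append(F)
                Es.append(green_lagrange(F))
    return StrainField(cell_coords=np.array(centers), F=np.array(Fs), E=np.array(Es))
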
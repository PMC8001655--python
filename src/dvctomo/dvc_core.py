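"""Two-step digital volume correlation and window-size calibration.

Displacement of a node is recovered in two stages.  First an integer
step: zero-mean normalized cross-correlation (Pearson NCC) between the
reference correlation window and candidate windows in the deformed
volume, maximized by steepest-ascent hill climbing over the
26-neighborhood of candidate displacements (with an exhaustive-search
fallback that doubles as the test oracle).  Second a sub-voxel step: a
3D Lucas-Kanade refinement that Gauss-Newton-minimizes the sum of
squared intensity differences under a 12-parameter local affine warp of
the window, sampling the reference volume with trilinear interpolation.

Because the refinement warps the *reference* volume onto the deformed
window's integer grid, a deformation synthesized by trilinear
resampling is recovered exactly (zero-residual minimum).

The calibration protocol tracks a node region through a staircase of
prescribed rigid in-plane shifts and reports per-window-size recovery
statistics (unconverged count, mean in-plane magnitude, its standard
deviation, mean-bias error and root-mean-square error).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import ndimage

from dvctomo.volio import Volume

__all__ = [
    "CorrelationConfig",
    "DisplacementField",
    "NodeStatus",
    "CalibrationRow",
    "prefilter",
    "ncc",
    "integer_search",
    "exhaustive_search",
    "subvoxel_refine",
    "correlate_plane",
    "filter_field",
    "mbe",
    "rmse",
    "ideal_in_plane_magnitude",
    "calibrate_window",
    "calibration_to_dataframe",
]


class NodeStatus(IntEnum):
    CONVERGED = 0
    UNCONVERGED = 1
    REPLACED = 2


@dataclass(frozen=True)
class CorrelationConfig:
    """Parameters of the correlation procedure.

    ``window_size`` is the cubic correlation-window edge, ``node_offset``
    the node-grid spacing on the evaluated plane, ``prefilter_kernel``
    the 3D median prefilter cube edge (1 disables filtering).
    """

    window_size: int = 18
    node_offset: int = 24
    prefilter_kernel: int = 13
    search_radius: int = 10
    max_iterations: int = 50
    tolerance: float = 1e-3

    def __post_init__(self) -> None:
        if self.window_size < 6 or self.window_size % 2 != 0:
            raise ValueError("window_size must be even and >= 6")
        if self.prefilter_kernel < 1 or self.prefilter_kernel % 2 == 0:
            raise ValueError("prefilter_kernel must be odd and >= 1")
        if self.node_offset < 1:
            raise ValueError("node_offset must be >= 1")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def window_voxels(self) -> int:
        """Number of voxels in the correlation window (edge cubed)."""
        return self.window_size**3


@dataclass
class DisplacementField:
    """Nodal displacements with correlation coefficients and validity."""

    node_coords: np.ndarray  # (n, 3) int, reference-state voxel coords
    u: np.ndarray  # (n, 3) float, voxels
    ncc: np.ndarray  # (n,)
    status: np.ndarray  # (n,) NodeStatus codes
    grid_shape: tuple | None = None  # node-lattice shape when nodes form a grid
    affine: np.ndarray | None = None  # (n, 3, 3) local linear part per node

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords)
        self.u = np.asarray(self.u, dtype=float)
        self.ncc = np.asarray(self.ncc, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        n = self.node_coords.shape[0]
        if self.u.shape != (n, 3) or self.ncc.shape != (n,) or self.status.shape != (n,):
            raise ValueError("inconsistent displacement-field array lengths")
        conv = self.status == NodeStatus.CONVERGED
        if np.any(np.abs(self.ncc[conv]) > 1.0 + 1e-9):
            raise ValueError("|ncc| must be <= 1 for converged nodes")
        valid = self.status != NodeStatus.UNCONVERGED
        if not np.all(np.isfinite(self.u[valid])):
            raise ValueError("u must be finite for non-unconverged nodes")

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


# ---------------------------------------------------------------------------
# prefilter

def prefilter(v: Volume, kernel: int) -> Volume:
    """3D median filter over a ``kernel``-cube, edge-replicated borders."""
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("median prefilter kernel must be odd and >= 1")
    if kernel == 1:
        return v.with_data(v.data.copy())
    filtered = ndimage.median_filter(v.astype_float(), size=kernel, mode="nearest")
    return v.with_data(filtered)


# ---------------------------------------------------------------------------
# integer step

def _window_slices(node, half, shape, disp=(0, 0, 0)):
    lo = [int(node[a]) + int(disp[a]) - half for a in range(3)]
    hi = [lo[a] + 2 * half for a in range(3)]
    if any(lo[a] < 0 or hi[a] > shape[a] for a in range(3)):
        return None
    return tuple(slice(lo[a], hi[a]) for a in range(3))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean, unit-variance (Pearson) correlation of two windows."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("zero-variance window: NCC undefined")
    return float((a * b).sum() / denom)


_NEIGHBORS26 = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)],
    dtype=int,
)


def _extract_ref_window(ref_data, node, half):
    sl = _window_slices(node, half, ref_data.shape)
    if sl is None:
        raise ValueError(f"correlation window out of bounds at node {tuple(node)}")
    w = ref_data[sl]
    if np.ptp(w) == 0:
        raise ValueError(f"zero-variance reference window at node {tuple(node)}")
    return w


def integer_search(ref: Volume, deformed: Volume, node, cfg: CorrelationConfig, init=(0, 0, 0)):
    """Integer displacement by NCC hill climbing over the 26-neighborhood.

    Candidates are bounded by ``cfg.search_radius`` (Chebyshev) around
    ``init``; returns ``(displacement, ncc)`` at the local NCC maximum.
    """
    node = np.asarray(node, dtype=int)
    init = np.asarray(init, dtype=int)
    half = cfg.window_size // 2
    ref_data = ref.astype_float()
    def_data = deformed.astype_float()
    w_ref = _extract_ref_window(ref_data, node, half)

    def score(d):
        sl = _window_slices(node, half, def_data.shape, d)
        if sl is None:
            return -np.inf
        w = def_data[sl]
        if np.ptp(w) == 0:
            return -np.inf
        return ncc(w_ref, w)

    current = init.copy()
    best = score(current)
    if not np.isfinite(best):
        raise ValueError(f"search window out of bounds or degenerate at node {tuple(node)}")
    while True:
        cand = current + _NEIGHBORS26
        inside = np.all(np.abs(cand - init) <= cfg.search_radius, axis=1)
        improved = False
        best_step, best_val = None, best
        for c in cand[inside]:
            val = score(c)
            if val > best_val:
                best_step, best_val = c, val
                improved = True
        if not improved:
            break
        current, best = best_step, best_val
    return current, best


def exhaustive_search(ref: Volume, deformed: Volume, node, cfg: CorrelationConfig, init=(0, 0, 0)):
    """Brute-force NCC argmax over the full search cube (slow oracle)."""
    node = np.asarray(node, dtype=int)
    init = np.asarray(init, dtype=int)
    half = cfg.window_size // 2
    ref_data = ref.astype_float()
    def_data = deformed.astype_float()
    w_ref = _extract_ref_window(ref_data, node, half)
    best_d, best_val = None, -np.inf
    r = cfg.search_radius
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                d = init + (dz, dy, dx)
                sl = _window_slices(node, half, def_data.shape, d)
                if sl is None:
                    continue
                w = def_data[sl]
                if np.ptp(w) == 0:
                    continue
                val = ncc(w_ref, w)
                if val > best_val:
                    best_d, best_val = d, val
    if best_d is None:
        raise ValueError(f"no admissible candidate window at node {tuple(node)}")
    return best_d, best_val


# ---------------------------------------------------------------------------
# sub-voxel step

class _TrackContext:
    """Caches the reference volume's trilinear samplers and gradients so
    per-node refinement does not recompute whole-volume gradients."""

    def __init__(self, ref: Volume, deformed: Volume, grad=None):
        self.ref = ref.astype_float()
        self.deformed = deformed.astype_float()
        self.grad = np.gradient(self.ref) if grad is None else grad

    def sample(self, coords):
        return ndimage.map_coordinates(self.ref, coords, order=1, mode="nearest")

    def sample_grad(self, coords):
        return [ndimage.map_coordinates(g, coords, order=1, mode="nearest") for g in self.grad]


def subvoxel_refine(ref: Volume, deformed: Volume, node, init, cfg: CorrelationConfig, _ctx=None):
    """Lucas-Kanade sub-voxel refinement with a 12-parameter affine warp.

    Starting from the integer displacement ``init``, Gauss-Newton
    minimizes ``sum_x (Ref(x - b - A(x - c)) - Def(x))^2`` over the
    deformed window's integer grid, where ``c = node + init``.  Iterates
    until the translation-update norm drops below ``cfg.tolerance`` or
    ``cfg.max_iterations`` is hit.

    Returns ``(u, linear, status, n_iter)``: the node's total sub-voxel
    displacement, the local forward affine linear part and a NodeStatus
    (unconverged is data, not an exception).
    """
    ctx = _ctx if _ctx is not None else _TrackContext(ref, deformed)
    node = np.asarray(node, dtype=float)
    init = np.asarray(init, dtype=int)
    half = cfg.window_size // 2
    c = node + init
    sl = _window_slices(node.astype(int), half, ctx.deformed.shape, init)
    if sl is None:
        return np.full(3, np.nan), np.eye(3), NodeStatus.UNCONVERGED, 0
    target = ctx.deformed[sl].ravel()
    offs = np.mgrid[-half : half, -half : half, -half : half].reshape(3, -1).astype(float)

    b = init.astype(float).copy()  # total translation, seeded at the integer step
    A = np.zeros((3, 3))  # local warp linear part (back-map form)
    x0 = node + init  # integer window center in the deformed grid
    status = NodeStatus.UNCONVERGED
    n_iter = 0
    for n_iter in range(1, cfg.max_iterations + 1):
        coords = (x0[:, None] + offs) - b[:, None] - A @ offs
        model = ctx.sample(coords)
        resid = model - target
        g = ctx.sample_grad(coords)  # gradient of Ref at back-mapped points
        n = offs.shape[1]
        J = np.empty((n, 12))
        for k in range(3):
            J[:, k] = -g[k]  # d resid / d b_k
            for j in range(3):
                J[:, 3 + 3 * k + j] = -g[k] * offs[j]  # d resid / d A_kj
        H = J.T @ J
        rhs = -J.T @ resid
        try:
            if np.linalg.cond(H) > 1e13:
                return np.full(3, np.nan), np.eye(3), NodeStatus.UNCONVERGED, n_iter
            delta = np.linalg.solve(H, rhs)
        except np.linalg.LinAlgError:
            return np.full(3, np.nan), np.eye(3), NodeStatus.UNCONVERGED, n_iter
        b += delta[:3]
        A += delta[3:].reshape(3, 3)
        if np.linalg.norm(delta[:3]) < cfg.tolerance:
            status = NodeStatus.CONVERGED
            break
    if status != NodeStatus.CONVERGED:
        return np.full(3, np.nan), np.eye(3), NodeStatus.UNCONVERGED, n_iter

    # Back-map form: X_ref = x - b - A (x - c).  The node's deformed position
    # y solves X_ref(y) = node, and the forward linear part of the local
    # material map is (I - A)^(-1).
    I = np.eye(3)
    try:
        linear = np.linalg.inv(I - A)
    except np.linalg.LinAlgError:
        return np.full(3, np.nan), np.eye(3), NodeStatus.UNCONVERGED, n_iter
    y = linear @ (node + b - A @ c)
    u = y - node
    return u, linear, status, n_iter


# ---------------------------------------------------------------------------
# plane correlation

def correlate_plane(
    ref: Volume,
    deformed: Volume,
    axis: int,
    index: int,
    cfg: CorrelationConfig,
    thickness: int = 100,
    region=None,
) -> DisplacementField:
    """Correlate the medial plane of a slab of the given thickness.

    Nodes are laid on the plane ``axis = index`` with ``cfg.node_offset``
    spacing; each is processed prefilter -> integer search -> sub-voxel
    refinement.  ``region`` optionally restricts the two in-plane axes to
    ``((lo0, hi0), (lo1, hi1))`` half-open voxel ranges.  Nodes whose
    window or search range would leave the volume are never instantiated.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    shape = ref.data.shape
    half_t = thickness // 2
    if index - half_t < 0 or index + half_t > shape[axis]:
        raise ValueError("slab out of volume bounds")
    ref_f = prefilter(ref, cfg.prefilter_kernel)
    def_f = prefilter(deformed, cfg.prefilter_kernel)

    margin = cfg.window_size // 2 + cfg.search_radius + 1
    plane_axes = [a for a in range(3) if a != axis]
    ranges = []
    for i, a in enumerate(plane_axes):
        lo, hi = margin, shape[a] - margin
        if region is not None:
            lo, hi = max(lo, region[i][0]), min(hi, region[i][1])
        ranges.append(np.arange(lo, hi, cfg.node_offset))
    if index - margin < 0 or index + margin > shape[axis]:
        raise ValueError("medial plane too close to the volume border for this window")

    grid = np.meshgrid(*ranges, indexing="ij")
    nodes = np.zeros((grid[0].size, 3), dtype=int)
    nodes[:, axis] = index
    nodes[:, plane_axes[0]] = grid[0].ravel()
    nodes[:, plane_axes[1]] = grid[1].ravel()

    ctx = _TrackContext(ref_f, def_f)
    u = np.zeros((nodes.shape[0], 3))
    ncc_vals = np.zeros(nodes.shape[0])
    status = np.full(nodes.shape[0], int(NodeStatus.UNCONVERGED))
    affines = np.tile(np.eye(3), (nodes.shape[0], 1, 1))
    for i, nd in enumerate(nodes):
        try:
            d_int, cc = integer_search(ref_f, def_f, nd, cfg)
        except ValueError:
            u[i] = np.nan
            continue
        ui, lin, st, _ = subvoxel_refine(ref_f, def_f, nd, d_int, cfg, _ctx=ctx)
        u[i] = ui
        ncc_vals[i] = cc
        status[i] = int(st)
        affines[i] = lin
    return DisplacementField(
        node_coords=nodes,
        u=u,
        ncc=ncc_vals,
        status=status,
        grid_shape=tuple(len(r) for r in ranges),
        affine=affines,
    )


# ---------------------------------------------------------------------------
# field filtering

def filter_field(
    f: DisplacementField,
    neighborhood: int = 1,
    outlier_k: float = 3.0,
    min_deviation: float = 0.05,
) -> DisplacementField:
    """Two-step displacement-field repair on the node grid.

    Step 1 replaces unconverged nodes by the component-wise median of
    converged neighbors within the Chebyshev ``neighborhood``; step 2
    replaces nodes deviating from their local median by more than
    ``outlier_k`` local median absolute deviations (``min_deviation``
    voxels floors the threshold so sub-voxel noise never triggers
    replacement).  Replaced nodes are flagged; the operation is
    idempotent on its own output.
    """
    if f.n_nodes == 0:
        raise ValueError("empty displacement field")
    if f.grid_shape is None or len(f.grid_shape) != 2:
        raise ValueError("filter_field needs a field with a 2D node grid")
    if np.all(f.status == NodeStatus.UNCONVERGED):
        raise ValueError("all nodes unconverged; nothing to interpolate from")
    gy, gx = f.grid_shape
    u = f.u.reshape(gy, gx, 3).copy()
    status = f.status.reshape(gy, gx).copy()

    def neighbor_block(arr, i, j):
        return arr[
            max(i - neighborhood, 0) : i + neighborhood + 1,
            max(j - neighborhood, 0) : j + neighborhood + 1,
        ]

    # step 1: fill unconverged from converged neighbors
    conv = status == NodeStatus.CONVERGED
    new_u = u.copy()
    new_status = status.copy()
    for i, j in zip(*np.nonzero(status == NodeStatus.UNCONVERGED)):
        block_u = neighbor_block(u, i, j)
        block_ok = neighbor_block(conv, i, j)
        if block_ok.any():
            new_u[i, j] = np.median(block_u[block_ok], axis=0)
            new_status[i, j] = NodeStatus.REPLACED
    u, status = new_u, new_status

    # step 2: median/MAD outlier replacement, iterated to a fixed point so
    # the whole operation is idempotent
    valid = status != NodeStatus.UNCONVERGED
    for _ in range(20):
        new_u = u.copy()
        new_status = status.copy()
        changed = False
        for i in range(gy):
            for j in range(gx):
                if not valid[i, j]:
                    continue
                block_u = neighbor_block(u, i, j)
                block_ok = neighbor_block(valid, i, j)
                vals = block_u[block_ok]
                med = np.median(vals, axis=0)
                mad = np.median(np.abs(vals - med), axis=0)
                if np.any(np.abs(u[i, j] - med) > outlier_k * mad + min_deviation):
                    new_u[i, j] = med
                    new_status[i, j] = NodeStatus.REPLACED
                    changed = True
        u, status = new_u, new_status
        if not changed:
            break
    return DisplacementField(
        node_coords=f.node_coords.copy(),
        u=new_u.reshape(-1, 3),
        ncc=f.ncc.copy(),
        status=new_status.reshape(-1),
        grid_shape=f.grid_shape,
        affine=None if f.affine is None else f.affine.copy(),
    )


# ---------------------------------------------------------------------------
# error metrics

def mbe(expected, observed) -> float:
    """Mean-bias error: mean of (expected - observed)."""
    p = np.asarray(expected, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size == 0 or p.size != o.size:
        raise ValueError("expected and observed must be equal-length, non-empty")
    return float(np.mean(p - o))


def rmse(expected, observed) -> float:
    """Root-mean-square error of (expected - observed)."""
    p = np.asarray(expected, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size == 0 or p.size != o.size:
        raise ValueError("expected and observed must be equal-length, non-empty")
    return float(np.sqrt(np.mean((p - o) ** 2)))


# ---------------------------------------------------------------------------
# window-size calibration

@dataclass
class CalibrationRow:
    """Per-window-size recovery statistics of the virtual rigid-motion
    experiment (final load step, converged nodes only)."""

    window_size: int
    unconverged: int
    mean_uYZ: float
    sigma_YZ: float
    mbe: float
    rmse: float
    elapsed_s: float = 0.0


def ideal_in_plane_magnitude(total_shift) -> float:
    """Euclidean magnitude of the total prescribed in-plane motion."""
    return float(np.linalg.norm(np.asarray(total_shift, dtype=float)))


def calibrate_window(
    v: Volume,
    step_shifts,
    region_nodes,
    window_sizes,
    cfg: CorrelationConfig | None = None,
    void_threshold: float | None = None,
) -> list[CalibrationRow]:
    """Virtual rigid-motion experiment sweeping the correlation window.

    ``step_shifts`` is an ``(n_steps, 3)`` list of per-step integer voxel
    shifts; the volume is numerically shifted by the cumulative motion at
    each step and all ``region_nodes`` are tracked through the staircase
    (each step's integer search seeded at the previous step's result).
    ``void_threshold`` drops nodes whose reference intensity falls below
    it.  In-plane means the axes with any prescribed motion.

    Statistics per window size (final step, over converged nodes):
    unconverged count, mean in-plane displacement magnitude, standard
    deviation of the deviation from the ideal magnitude, MBE and RMSE
    against the prescribed magnitude.
    """
    if cfg is None:
        cfg = CorrelationConfig()
    steps = np.asarray(step_shifts, dtype=int)
    if steps.ndim != 2 or steps.shape[1] != 3 or steps.shape[0] < 1:
        raise ValueError("step_shifts must be (n_steps, 3) integers")
    nodes = np.asarray(region_nodes, dtype=int)
    total = steps.sum(axis=0)
    moved_axes = np.nonzero(np.any(steps != 0, axis=0))[0]
    if moved_axes.size == 0:
        moved_axes = np.arange(3)
    ideal = ideal_in_plane_magnitude(total[moved_axes])

    data = v.astype_float()
    fill = float(data.min())
    ref_f = prefilter(v, cfg.prefilter_kernel)
    if void_threshold is not None:
        keep = ref_f.astype_float()[tuple(nodes.T)] > void_threshold
        nodes = nodes[keep]
    if nodes.shape[0] == 0:
        raise ValueError("no nodes to track after void filtering")

    # integer shifts commute with the median filter away from borders, so
    # the deformed staircase is built from the already-filtered volume
    cum = np.cumsum(steps, axis=0)
    max_margin = int(np.abs(cum).max()) + max(window_sizes) // 2 + 1
    lim = np.array(ref_f.data.shape)
    if np.any(nodes - max_margin < 0) or np.any(nodes + max_margin > lim):
        raise ValueError("prescribed motion pushes the tracked region out of bounds")
    deformed_steps = [
        ref_f.with_data(ndimage.shift(ref_f.astype_float(), c, order=0, mode="constant", cval=fill))
        for c in cum
    ]
    ref_grad = np.gradient(ref_f.astype_float())
    contexts = [_TrackContext(ref_f, d, grad=ref_grad) for d in deformed_steps]

    rows = []
    for w in window_sizes:
        cfg_w = replace(cfg, window_size=int(w))
        t0 = time.perf_counter()
        finals = np.full((nodes.shape[0], 3), np.nan)
        converged = np.zeros(nodes.shape[0], dtype=bool)
        for i, nd in enumerate(nodes):
            d_prev = np.zeros(3, dtype=int)
            ok = True
            u_final = None
            for def_k, ctx in zip(deformed_steps, contexts):
                try:
                    d_int, _ = integer_search(ref_f, def_k, nd, cfg_w, init=d_prev)
                except ValueError:
                    ok = False
                    break
                u_k, _, st, _ = subvoxel_refine(ref_f, def_k, nd, d_int, cfg_w, _ctx=ctx)
                if st != NodeStatus.CONVERGED:
                    ok = False
                    break
                d_prev = np.round(u_k).astype(int)
                u_final = u_k
            if ok and u_final is not None:
                finals[i] = u_final
                converged[i] = True
        elapsed = time.perf_counter() - t0
        n_bad = int(np.count_nonzero(~converged))
        if converged.any():
            mags = np.linalg.norm(finals[converged][:, moved_axes], axis=1)
            mean_u = float(np.mean(mags))
            sigma = float(np.std(mags - ideal))
            row_mbe = mbe(np.full(mags.size, ideal), mags)
            row_rmse = rmse(np.full(mags.size, ideal), mags)
        else:
            mean_u = sigma = row_mbe = row_rmse = float("nan")
        rows.append(
            CalibrationRow(
                window_size=int(w),
                unconverged=n_bad,
                mean_uYZ=mean_u,
                sigma_YZ=sigma,
                mbe=row_mbe,
                rmse=row_rmse,
                elapsed_s=elapsed,
            )
        )
    return rows


def calibration_to_dataframe(rows: list[CalibrationRow]) -> pd.DataFrame:
    """Calibration rows as a table mirroring the standard report layout."""
    return pd.DataFrame(
        {
            "window_size": [r.window_size for r in rows],
            "NaN": [r.unconverged for r in rows],
            "mean_uYZ": [r.mean_uYZ for r in rows],
            "sigma_YZ": [r.sigma_YZ for r in rows],
            "MBE": [r.mbe for r in rows],
            "RMSE": [r.rmse for r in rows],
            "elapsed_s": [r.elapsed_s for r in rows],
        }
    )
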
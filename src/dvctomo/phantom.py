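"""Synthetic bone phantoms with known ground truth.

Generates cylindrical cortical-bone-like volumes (axial canal system,
high-frequency speckle texture), inserts thin planar cracks, applies
prescribed rigid/affine deformations and produces parallel-beam
projection series with a slow linear focal-spot drift.  Every generator
is a pure function of its spec and seed, and ground truth (masks,
shifts, transforms) is always emitted alongside the data so downstream
tests never re-derive it from images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from dvctomo.projprep import ScanPlan
from dvctomo.register_blend import AffineTransform
from dvctomo.volio import ProjectionSeries, Volume

__all__ = [
    "PhantomSpec",
    "CrackSpec",
    "DriftPath",
    "make_bone_phantom",
    "insert_crack",
    "apply_deformation",
    "make_drifting_projections",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the cylindrical bone phantom.

    The tissue cylinder runs along z; ``canal_count`` axial cylinders of
    ``canal_radius`` (um) emulate the Haversian canal system.  Texture is
    a multiplicative smoothed random field (correlation length ~3
    voxels) of relative amplitude ``texture_amplitude``; ``noise_sigma``
    adds white noise everywhere.
    """

    shape: tuple = (64, 64, 64)
    voxel_size: float = 2.0  # um
    canal_count: int = 0
    canal_radius: float = 10.0  # um
    texture_amplitude: float = 0.15
    tissue_level: float = 1.0
    void_level: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    cylinder_radius: float | None = None  # um; default 0.45 * min(ny, nx) voxels

    def __post_init__(self) -> None:
        if self.void_level >= self.tissue_level:
            raise ValueError("void_level must be below tissue_level")
        if self.canal_count > 0 and self.canal_radius < self.voxel_size:
            raise ValueError("canal radius must be at least one voxel")


@dataclass(frozen=True)
class CrackSpec:
    """A thin planar (optionally wavy) crack.

    ``center`` is in voxel coordinates, ``normal`` the plane normal,
    ``half_extent`` the two in-plane half-lengths in um and ``width`` the
    opening in um.  A voxel belongs to the crack when its signed distance
    ``d`` to the (perturbed) plane satisfies ``-width/2 <= d < width/2``.
    """

    center: tuple
    normal: tuple
    half_extent: tuple  # (a, b) um
    width: float  # um
    waviness: float = 0.0  # um, low-frequency surface perturbation amplitude

    def unit_normal(self) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("crack normal must be non-zero")
        return n / norm


@dataclass(frozen=True)
class DriftPath:
    """Linear focal-spot drift: detector-plane (row, col) shift at the
    start and end of each sub-scan, in pixels."""

    shift_at_start: np.ndarray  # (n_subscans, 2)
    shift_at_end: np.ndarray  # (n_subscans, 2)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift_at_start", np.atleast_2d(np.asarray(self.shift_at_start, dtype=float)))
        object.__setattr__(self, "shift_at_end", np.atleast_2d(np.asarray(self.shift_at_end, dtype=float)))
        if self.shift_at_start.shape != self.shift_at_end.shape or self.shift_at_start.shape[1] != 2:
            raise ValueError("start/end shifts must both be (n_subscans, 2)")
        if not (np.all(np.isfinite(self.shift_at_start)) and np.all(np.isfinite(self.shift_at_end))):
            raise ValueError("drift shifts must be finite")

    @classmethod
    def linear(cls, total_shift, n_subscans: int) -> "DriftPath":
        """One continuous linear drift from (0, 0) to ``total_shift``."""
        total = np.asarray(total_shift, dtype=float)
        knots = np.outer(np.linspace(0.0, 1.0, n_subscans + 1), total)
        return cls(shift_at_start=knots[:-1], shift_at_end=knots[1:])

    @property
    def n_subscans(self) -> int:
        return self.shift_at_start.shape[0]


# ---------------------------------------------------------------------------

def _cylinder_mask(shape, center_yx, radius_vox):
    yy, xx = np.mgrid[0 : shape[1], 0 : shape[2]]
    r2 = (yy - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2
    return np.broadcast_to(r2 <= radius_vox**2, shape)


def make_bone_phantom(spec: PhantomSpec, return_masks: bool = False):
    """Generate the cylindrical bone phantom (deterministic under seed).

    With ``return_masks`` also returns ``{"tissue": ..., "canal": ...}``
    boolean ground-truth masks.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    if spec.cylinder_radius is None:
        cyl_r = 0.45 * min(ny, nx)
    else:
        cyl_r = spec.cylinder_radius / spec.voxel_size
    tissue = _cylinder_mask(spec.shape, center, cyl_r).copy()

    data = np.full(spec.shape, spec.void_level, dtype=float)
    level = np.full(spec.shape, spec.tissue_level, dtype=float)
    if spec.texture_amplitude > 0:
        texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=3.0)
        texture /= max(texture.std(), 1e-12)
        level = spec.tissue_level * (1.0 + spec.texture_amplitude * texture)
    data[tissue] = level[tissue]

    canal = np.zeros(spec.shape, dtype=bool)
    if spec.canal_count > 0:
        canal_r = spec.canal_radius / spec.voxel_size
        max_off = cyl_r - canal_r - 2.0
        if max_off <= 0:
            raise ValueError("canals do not fit inside the tissue cylinder")
        centers = []
        attempts = 0
        while len(centers) < spec.canal_count:
            attempts += 1
            if attempts > 10000:
                raise ValueError("could not place canals without overlap; reduce count/radius")
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform(0, 1)) * max_off
            cand = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
            if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) > 2 * canal_r + 3 for c in centers):
                centers.append(cand)
        for c in centers:
            canal |= _cylinder_mask(spec.shape, c, canal_r)
        data[canal] = spec.void_level

    if spec.noise_sigma > 0:
        data = data + spec.noise_sigma * rng.standard_normal(spec.shape)

    vol = Volume(data=data, voxel_size=spec.voxel_size)
    if return_masks:
        return vol, {"tissue": tissue & ~canal, "canal": canal}
    return vol


def crack_mask(v: Volume, crack: CrackSpec) -> np.ndarray:
    """Boolean ground-truth mask of the crack voxels inside the volume."""
    n = crack.unit_normal()
    if max(crack.half_extent) <= 0:
        return np.zeros(v.data.shape, dtype=bool)
    # in-plane orthonormal frame
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)

    zz, yy, xx = np.mgrid[0 : v.data.shape[0], 0 : v.data.shape[1], 0 : v.data.shape[2]]
    delta = np.stack(
        [
            (zz - crack.center[0]) * v.voxel_size[0],
            (yy - crack.center[1]) * v.voxel_size[1],
            (xx - crack.center[2]) * v.voxel_size[2],
        ]
    )
    d = np.tensordot(n, delta, axes=1)
    a = np.tensordot(t1, delta, axes=1)
    b = np.tensordot(t2, delta, axes=1)
    if crack.waviness > 0:
        lam = max(2.0 * max(crack.half_extent), 1.0)
        d = d - crack.waviness * np.sin(2 * np.pi * a / lam) * np.cos(2 * np.pi * b / lam)
    half = crack.width / 2.0
    return (
        (d >= -half)
        & (d < half)
        & (np.abs(a) <= crack.half_extent[0])
        & (np.abs(b) <= crack.half_extent[1])
    )


def insert_crack(v: Volume, crack: CrackSpec, void_level: float | None = None):
    """Carve a crack into the volume; returns (volume, ground-truth mask).

    Crack voxels are set to ``void_level`` (defaults to the volume
    minimum).  Errors when the crack misses the tissue entirely.
    """
    mask = crack_mask(v, crack)
    data = v.astype_float().copy()
    if void_level is None:
        void_level = float(data.min())
    if max(crack.half_extent) > 0 and mask.any():
        mid = 0.5 * (data.max() + data.min())
        if data.max() > data.min() and not np.any(data[mask] > mid):
            raise ValueError("crack lies fully outside the tissue region")
    elif max(crack.half_extent) > 0:
        raise ValueError("crack lies fully outside the volume")
    data[mask] = void_level
    return v.with_data(data), mask


def apply_deformation(v: Volume, transform, fill_value: float | None = None) -> Volume:
    """Resample the volume under a prescribed deformation.

    ``transform`` is either an :class:`AffineTransform` mapping reference
    to deformed coordinates (the output is ``v`` at the back-mapped
    position ``T^{-1}(y)``) or a forward displacement field of shape
    ``(3, nz, ny, nx)`` in voxels, in which case the output at ``y``
    samples ``v(y - u(y))``.  Trilinear interpolation; out-of-domain
    voxels take ``fill_value`` (default: volume minimum, the air level).
    """
    data = v.astype_float()
    if fill_value is None:
        fill_value = float(data.min())
    if isinstance(transform, AffineTransform):
        inv = transform.inverse()
        out = ndimage.affine_transform(
            data, inv.linear, offset=inv.translation, order=1, mode="constant", cval=fill_value
        )
    else:
        u = np.asarray(transform, dtype=float)
        if u.shape != (3,) + data.shape:
            raise ValueError("displacement field must have shape (3, nz, ny, nx)")
        if not np.all(np.isfinite(u)):
            raise ValueError("displacement field must be finite")
        grid = np.mgrid[0 : data.shape[0], 0 : data.shape[1], 0 : data.shape[2]].astype(float)
        out = ndimage.map_coordinates(
            data, grid - u, order=1, mode="constant", cval=fill_value
        )
    return v.with_data(out)


# ---------------------------------------------------------------------------

def _project(data: np.ndarray, angle_deg: float) -> np.ndarray:
    """Parallel-beam line-integral projection: rotate in-plane, sum rays."""
    if angle_deg % 360.0 == 0.0:
        rot = data
    else:
        rot = ndimage.rotate(data, angle_deg, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0)
    return rot.sum(axis=2)


def make_drifting_projections(
    v: Volume,
    plan: ScanPlan,
    drift: DriftPath,
    seed: int = 0,
    noise_sigma: float = 0.0,
):
    """Synthesize a projection series with linear focal-spot drift.

    Each sub-scan starts with a reference exposure at the plan's
    reference angle followed by the science projections; the ``i``-th of
    the sub-scan's ``n+1`` frames is shifted (bilinear) by the drift
    linearly interpolated at ``t = i / n``, so the last projection
    carries exactly the sub-scan's end shift.  Returns the series and the
    ground-truth per-frame shifts.
    """
    if drift.n_subscans != plan.n_subscans:
        raise ValueError("drift path and scan plan disagree on sub-scan count")
    if plan.n_projections == 0:
        raise ValueError("empty scan plan")
    rng = np.random.default_rng(seed)
    data = v.astype_float()

    cache: dict[float, np.ndarray] = {}

    def proj(angle):
        key = round(float(angle) % 360.0, 9)
        if key not in cache:
            cache[key] = _project(data, key)
        return cache[key]

    frames, angles, subscan, is_ref, truth = [], [], [], [], []
    n = plan.n_per_subscan
    for k in range(plan.n_subscans):
        frame_angles = [plan.reference_angle_deg] + plan.subscan_angles(k).tolist()
        for i, ang in enumerate(frame_angles):
            t = i / n
            shift = (1.0 - t) * drift.shift_at_start[k] + t * drift.shift_at_end[k]
            frame = proj(ang)
            if np.any(shift != 0):
                frame = ndimage.shift(frame, shift, order=1, mode="constant", cval=0.0)
            if noise_sigma > 0:
                frame = frame + noise_sigma * rng.standard_normal(frame.shape)
            frames.append(frame)
            angles.append(ang)
            subscan.append(k)
            is_ref.append(i == 0)
            truth.append(shift)
    series = ProjectionSeries(
        frames=np.stack(frames),
        angles_deg=np.array(angles),
        subscan_index=np.array(subscan),
        is_reference=np.array(is_ref),
    )
    return series, np.array(truth)
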
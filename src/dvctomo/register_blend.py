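"""Local least-squares volume alignment and differential-tomography blending.

Simple subtraction of the loaded-state volume from the reference is not
enough to reveal thin new cracks; instead the loaded volume is scaled by
an integer multiplier and summed with the reference
(``Vb = Vr + m * Vl``) after local alignment, so morphological changes
stand out at high contrast.  Alignment uses a small cube of DVC support
points near a crack tip, fit by weighted least squares to a rigid or
general affine transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from dvctomo import dvc_core
from dvctomo.volio import Volume

__all__ = [
    "AffineTransform",
    "DEFAULT_NCC_THRESHOLD",
    "pick_support_points",
    "track_support_points",
    "fit_transform",
    "resample",
    "blend",
    "select_multiplier",
]

DEFAULT_NCC_THRESHOLD = 0.9


@dataclass
class AffineTransform:
    """``T(x) = linear @ x + translation`` in voxel coordinates."""

    linear: np.ndarray
    translation: np.ndarray
    kind: str = "general"

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.kind not in ("rigid", "general"):
            raise ValueError("kind must be 'rigid' or 'general'")
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("linear part must be invertible")
        if self.kind == "rigid":
            err = np.abs(self.linear @ self.linear.T - np.eye(3)).max()
            if err > 1e-6 or np.linalg.det(self.linear) < 0:
                raise ValueError("rigid transform requires a proper orthonormal linear part")

    @classmethod
    def identity(cls, kind: str = "rigid") -> "AffineTransform":
        return cls(linear=np.eye(3), translation=np.zeros(3), kind=kind)

    @classmethod
    def from_translation(cls, t, kind: str = "rigid") -> "AffineTransform":
        return cls(linear=np.eye(3), translation=np.asarray(t, dtype=float), kind=kind)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(linear=inv, translation=-inv @ self.translation, kind=self.kind)


# ---------------------------------------------------------------------------

def pick_support_points(
    v: Volume,
    crack_tip,
    standoff: float,
    direction,
    spacing: int = 2,
    void_mask: np.ndarray | None = None,
) -> np.ndarray:
    """A 5x5x5 cube of 125 correlation nodes near a crack tip.

    The cube center sits ``standoff`` voxels from the tip along the
    outward in-plane ``direction``; nodes are spaced ``spacing`` voxels.
    Errors if any node leaves the volume or (when a void mask is
    supplied) lands in void.
    """
    tip = np.asarray(crack_tip, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    center = tip + direction / norm * standoff
    offs = (np.mgrid[-2:3, -2:3, -2:3].reshape(3, -1).T) * spacing
    points = np.round(center + offs).astype(int)
    shape = np.array(v.data.shape)
    if np.any(points < 0) or np.any(points >= shape):
        raise ValueError("support-point grid leaves the volume")
    if void_mask is not None:
        if np.any(void_mask[tuple(points.T)]):
            raise ValueError("support-point grid intersects the void; increase standoff")
    assert points.shape == (125, 3)
    return points


def track_support_points(
    ref: Volume,
    deformed: Volume,
    points: np.ndarray,
    cfg: dvc_core.CorrelationConfig | None = None,
    ncc_threshold: float = DEFAULT_NCC_THRESHOLD,
):
    """Track support points by the two-step DVC and keep well-correlated ones.

    Returns ``(ref_points, def_points, weights)`` for the pairs whose
    integer-step NCC reached ``ncc_threshold`` and whose refinement
    converged; weights are the NCC values.
    """
    if cfg is None:
        cfg = dvc_core.CorrelationConfig(prefilter_kernel=1, node_offset=1)
    ctx = dvc_core._TrackContext(ref, deformed)
    ref_pts, def_pts, weights = [], [], []
    for p in np.asarray(points, dtype=int):
        try:
            d_int, cc = dvc_core.integer_search(ref, deformed, p, cfg)
        except ValueError:
            continue
        if cc < ncc_threshold:
            continue
        u, _, st, _ = dvc_core.subvoxel_refine(ref, deformed, p, d_int, cfg, _ctx=ctx)
        if st != dvc_core.NodeStatus.CONVERGED:
            continue
        ref_pts.append(p.astype(float))
        def_pts.append(p + u)
        weights.append(cc)
    if not ref_pts:
        raise ValueError("no support point survived correlation thresholding")
    return np.array(ref_pts), np.array(def_pts), np.array(weights)


def fit_transform(ref_points, def_points, weights=None, kind: str = "general") -> AffineTransform:
    """Weighted least-squares transform mapping ref points to def points.

    ``kind='rigid'`` solves the weighted orthogonal Procrustes problem
    (rotation + translation); ``kind='general'`` a full 12-parameter
    affine by weighted linear least squares.
    """
    X = np.asarray(ref_points, dtype=float)
    Y = np.asarray(def_points, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = X.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")

    if kind == "general":
        if n < 4:
            raise ValueError("general affine fit needs at least 4 point pairs")
        Xh = np.hstack([X, np.ones((n, 1))])
        WXh = Xh * w[:, None]
        G = Xh.T @ WXh
        if np.linalg.matrix_rank(G, tol=1e-9 * np.abs(G).max()) < 4:
            raise ValueError("degenerate (coplanar) point geometry for affine fit")
        beta = np.linalg.solve(G, Xh.T @ (Y * w[:, None]))
        return AffineTransform(linear=beta[:3].T, translation=beta[3], kind="general")

    if kind == "rigid":
        if n < 3:
            raise ValueError("rigid fit needs at least 3 point pairs")
        wn = w / w.sum()
        xc = (X * wn[:, None]).sum(axis=0)
        yc = (Y * wn[:, None]).sum(axis=0)
        Xc = X - xc
        Yc = Y - yc
        H = (Xc * wn[:, None]).T @ Yc
        U, S, Vt = np.linalg.svd(H)
        if S[1] < 1e-9 * max(S[0], 1e-300):
            raise ValueError("degenerate (collinear) point geometry for rigid fit")
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        return AffineTransform(linear=R, translation=yc - R @ xc, kind="rigid")

    raise ValueError("kind must be 'rigid' or 'general'")


def resample(v: Volume, t: AffineTransform, fill_value: float | None = None) -> Volume:
    """Warp a volume: output voxel ``x`` takes ``v`` at ``t(x)`` (trilinear).

    Out-of-domain samples are filled with ``fill_value`` (defaults to the
    volume minimum, i.e. the air level of a bone scan).
    """
    data = v.astype_float()
    if fill_value is None:
        fill_value = float(data.min())
    out = ndimage.affine_transform(
        data, t.linear, offset=t.translation, order=1, mode="constant", cval=fill_value
    )
    return v.with_data(out)


def blend(vr: Volume, vl: Volume, m: int) -> Volume:
    """Differential-tomography blend ``Vb = Vr + m * Vl`` (float, unclipped)."""
    if vr.data.shape != vl.data.shape:
        raise ValueError("volumes must share one shape")
    if not np.allclose(vr.voxel_size, vl.voxel_size):
        raise ValueError("volumes must share one voxel size")
    return vr.with_data(vr.astype_float() + float(m) * vl.astype_float())


def select_multiplier(
    vr: Volume,
    vl: Volume,
    void_mask: np.ndarray,
    tissue_mask: np.ndarray,
    m_range=(2, 50),
) -> tuple[int, pd.DataFrame]:
    """Pick the blending multiplier maximizing void/tissue contrast.

    For each integer ``m`` the contrast-to-noise ratio between the two
    masked populations of the blended volume is computed:
    ``CNR = |mean_tissue - mean_void| / pooled std``.  Returns the
    arg-max ``m`` and the full per-m curve.
    """
    void_mask = np.asarray(void_mask, dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not void_mask.any() or not tissue_mask.any():
        raise ValueError("void and tissue masks must be non-empty")
    if np.any(void_mask & tissue_mask):
        raise ValueError("void and tissue masks must be disjoint")
    lo, hi = int(m_range[0]), int(m_range[1])
    if lo < 1 or hi < lo:
        raise ValueError("m_range must be a positive integer interval")
    ms = np.arange(lo, hi + 1)
    cnrs = np.zeros(ms.size)
    for i, m in enumerate(ms):
        vb = blend(vr, vl, int(m)).data
        tv, vv = vb[tissue_mask], vb[void_mask]
        pooled = np.sqrt(0.5 * (tv.var() + vv.var()))
        contrast = abs(tv.mean() - vv.mean())
        if pooled == 0:
            cnrs[i] = np.inf if contrast > 0 else 0.0
        else:
            cnrs[i] = contrast / pooled
    curve = pd.DataFrame({"m": ms, "cnr": cnrs})
    best = int(ms[int(np.argmax(cnrs))])
    return best, curve
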
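"""Projection-level corrections: flat-field normalization, scan-plan
construction and focal-spot drift estimation/compensation.

A long tomographic acquisition is split into interleaved sub-scans, each
covering the full rotation at coarse angular spacing and led by a
repeated exposure at one fixed reference angle.  Slow thermo-mechanical
drift of the X-ray focal spot translates every frame on the detector;
comparing the reference exposures yields the drift at the sub-scan
boundaries and each projection is shifted back by the linearly
interpolated amount before reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from dvctomo.volio import ProjectionSeries

__all__ = [
    "ScanPlan",
    "DriftEstimate",
    "build_scan_plan",
    "flat_field_correct",
    "estimate_reference_shifts",
    "correct_drift",
]


@dataclass(frozen=True)
class ScanPlan:
    """Acquisition layout: sub-scan count, projections per sub-scan,
    angular shift between consecutive sub-scans and the fixed angle of
    the per-sub-scan reference exposure."""

    n_subscans: int
    n_per_subscan: int
    subscan_shift_deg: float
    reference_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subscans < 1 or self.n_per_subscan < 1:
            raise ValueError("sub-scan counts must be >= 1")
        if not (0.0 <= self.reference_angle_deg < 360.0):
            raise ValueError("reference angle must lie in [0, 360)")

    @property
    def n_projections(self) -> int:
        return self.n_subscans * self.n_per_subscan

    @property
    def frames_per_subscan(self) -> int:
        # one leading reference exposure plus the science projections
        return self.n_per_subscan + 1

    @property
    def total_frames(self) -> int:
        return self.n_subscans * self.frames_per_subscan

    def subscan_angles(self, k: int) -> np.ndarray:
        """Science-projection angles of sub-scan ``k`` (degrees, [0, 360))."""
        j = np.arange(self.n_per_subscan)
        return (self.subscan_shift_deg * k + 360.0 * j / self.n_per_subscan) % 360.0

    def all_angles(self) -> np.ndarray:
        """All science-projection angles in acquisition order."""
        return np.concatenate([self.subscan_angles(k) for k in range(self.n_subscans)])

    def is_equiangular(self, tol: float = 1e-9) -> bool:
        """Whether the merged projection set is uniformly spaced over 360°."""
        ang = np.sort(self.all_angles())
        gaps = np.diff(np.append(ang, ang[0] + 360.0))
        return bool(np.ptp(gaps) <= tol)

    def frame_annotations(self):
        """Per-frame (angles, subscan_index, is_reference) in acquisition order."""
        angles, subscan, is_ref = [], [], []
        for k in range(self.n_subscans):
            angles.append(self.reference_angle_deg)
            subscan.append(k)
            is_ref.append(True)
            angles.extend(self.subscan_angles(k).tolist())
            subscan.extend([k] * self.n_per_subscan)
            is_ref.extend([False] * self.n_per_subscan)
        return angles, subscan, is_ref


def build_scan_plan(
    n_subscans: int,
    n_per_subscan: int,
    subscan_shift_deg: float,
    reference_angle_deg: float = 0.0,
) -> tuple[ScanPlan, np.ndarray]:
    """Construct a scan plan and return it with the full angle list."""
    plan = ScanPlan(
        n_subscans=n_subscans,
        n_per_subscan=n_per_subscan,
        subscan_shift_deg=subscan_shift_deg,
        reference_angle_deg=reference_angle_deg,
    )
    return plan, plan.all_angles()


@dataclass
class DriftEstimate:
    """Focal-spot drift: reference-frame shifts plus per-frame
    linearly interpolated detector-plane shifts, in pixels (row, col)."""

    reference_shifts: np.ndarray  # (n_subscans, 2)
    subscan_start: np.ndarray  # (n_subscans, 2)
    subscan_end: np.ndarray  # (n_subscans, 2)
    frame_shifts: np.ndarray  # (n_frames, 2), every frame incl. references

    def __post_init__(self) -> None:
        for name in ("reference_shifts", "subscan_start", "subscan_end", "frame_shifts"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


# ---------------------------------------------------------------------------

def flat_field_correct(raw, open_beam, dark, bad_pixel_mask=None):
    """Normalize a raw frame: ``(raw - dark) / (open_beam - dark)``.

    Pixels with a non-positive denominator are treated as bad; bad pixels
    are replaced by the median of their valid 8-neighbors.
    """
    raw = np.asarray(raw, dtype=float)
    open_beam = np.asarray(open_beam, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if raw.shape != open_beam.shape or raw.shape != dark.shape:
        raise ValueError("raw, open-beam and dark frames must share one shape")
    denom = open_beam - dark
    bad = denom <= 0
    if bad_pixel_mask is not None:
        bad_pixel_mask = np.asarray(bad_pixel_mask, dtype=bool)
        if bad_pixel_mask.shape != raw.shape:
            raise ValueError("bad pixel mask shape mismatch")
        bad = bad | bad_pixel_mask
    if bad.all():
        raise ValueError("every pixel is flagged bad; cannot correct frame")
    corrected = np.zeros_like(raw)
    np.divide(raw - dark, denom, out=corrected, where=~bad)
    if bad.any():
        for i, j in zip(*np.nonzero(bad)):
            i0, i1 = max(i - 1, 0), min(i + 2, raw.shape[0])
            j0, j1 = max(j - 1, 0), min(j + 2, raw.shape[1])
            patch = corrected[i0:i1, j0:j1]
            valid = ~bad[i0:i1, j0:j1]
            if valid.any():
                corrected[i, j] = np.median(patch[valid])
    return corrected


def _ncc_shift_2d(template, moving, search_radius: int = 10, min_peak: float = 0.2):
    """Shift ``s`` (row, col) such that ``moving(x) ≈ template(x - s)``.

    Windowed integer NCC search: the template's interior block (cropped
    by ``search_radius``) is correlated against every candidate block of
    the moving frame within the search radius, then the integer peak is
    refined by a per-axis quadratic (3-point parabola) fit.
    """
    a = np.asarray(template, dtype=float)
    b = np.asarray(moving, dtype=float)
    r = int(min(search_radius, (min(a.shape) - 5) // 3))
    if r < 1:
        raise ValueError("frames too small for drift estimation")
    block = a[r:-r, r:-r]
    block = block - block.mean()
    na = np.sqrt((block * block).sum())
    if na == 0:
        raise ValueError("constant frame: correlation undefined")
    h, w = block.shape
    corr = np.full((2 * r + 1, 2 * r + 1), -np.inf)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            cand = b[r + dy : r + dy + h, r + dx : r + dx + w]
            cand = cand - cand.mean()
            nb = np.sqrt((cand * cand).sum())
            if nb == 0:
                continue
            corr[dy + r, dx + r] = (block * cand).sum() / (na * nb)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    if corr[peak] < min_peak:
        raise ValueError(f"correlation peak {corr[peak]:.3f} below threshold {min_peak}")
    shift = np.array(peak, dtype=float) - r
    for axis in range(2):
        idx = list(peak)
        if 0 < peak[axis] < corr.shape[axis] - 1:
            idx[axis] = peak[axis] - 1
            cm = corr[tuple(idx)]
            idx[axis] = peak[axis] + 1
            cp = corr[tuple(idx)]
            c0 = corr[peak]
            denom2 = cm - 2.0 * c0 + cp
            if np.isfinite(cm) and np.isfinite(cp) and denom2 < 0:
                shift[axis] += 0.5 * (cm - cp) / denom2
    return shift


def _refine_shift_2d(template, moving, init, max_iter: int = 20, tol: float = 1e-4):
    """Polish a 2D shift by Gauss-Newton on the bilinear-sampling SSD.

    Uses the same interpolation model as the drift synthesis, so for
    frames generated by bilinear shifting the refined value is exact to
    numerical precision.
    """
    t = np.asarray(template, dtype=float)
    m = np.asarray(moving, dtype=float)
    gz, gy = np.gradient(t)
    rows, cols = np.mgrid[0 : t.shape[0], 0 : t.shape[1]]
    s = np.asarray(init, dtype=float).copy()
    pad = int(np.ceil(np.max(np.abs(s)))) + 2
    interior = (slice(pad, t.shape[0] - pad), slice(pad, t.shape[1] - pad))
    r_in, c_in = rows[interior], cols[interior]
    m_in = m[interior]
    for _ in range(max_iter):
        coords = np.stack([r_in.ravel() - s[0], c_in.ravel() - s[1]])
        model = ndimage.map_coordinates(t, coords, order=1, mode="nearest")
        resid = model - m_in.ravel()
        jr = -ndimage.map_coordinates(gz, coords, order=1, mode="nearest")
        jc = -ndimage.map_coordinates(gy, coords, order=1, mode="nearest")
        J = np.stack([jr, jc], axis=1)
        H = J.T @ J
        if np.linalg.cond(H) > 1e12:
            break
        delta = np.linalg.solve(H, -J.T @ resid)
        s += delta
        if np.linalg.norm(delta) < tol:
            break
    return s


def estimate_reference_shifts(series: ProjectionSeries, refine: bool = True) -> DriftEstimate:
    """Estimate focal-spot drift from the repeated reference exposures.

    The first reference frame defines the zero-drift datum.  Sub-scan
    ``k``'s endpoint shifts are the ``k``-th and ``(k+1)``-th reference
    shifts; the last sub-scan extrapolates its own trend.  Per-frame
    shifts follow by linear interpolation over acquisition index.
    """
    ref_idx = np.nonzero(series.is_reference)[0]
    if ref_idx.size < 2:
        raise ValueError("need at least 2 reference frames to estimate drift")
    template = series.frames[ref_idx[0]].astype(float)
    ref_shifts = np.zeros((ref_idx.size, 2))
    for i, fi in enumerate(ref_idx[1:], start=1):
        s = _ncc_shift_2d(template, series.frames[fi].astype(float))
        if refine:
            s = _refine_shift_2d(template, series.frames[fi].astype(float), s)
        ref_shifts[i] = s

    subscans = np.unique(series.subscan_index)
    n_sub = subscans.size
    start = np.zeros((n_sub, 2))
    end = np.zeros((n_sub, 2))
    for k in range(n_sub):
        start[k] = ref_shifts[min(k, ref_shifts.shape[0] - 1)]
        if k + 1 < ref_shifts.shape[0]:
            end[k] = ref_shifts[k + 1]
        else:  # extrapolate the final sub-scan's trend
            end[k] = 2.0 * ref_shifts[k] - ref_shifts[k - 1]

    frame_shifts = np.zeros((series.n_frames, 2))
    for k_pos, k in enumerate(subscans):
        sel = np.nonzero(series.subscan_index == k)[0]
        count = sel.size
        if count == 1:
            frame_shifts[sel[0]] = start[k_pos]
            continue
        t = np.arange(count, dtype=float) / (count - 1)
        frame_shifts[sel] = start[k_pos] + np.outer(t, end[k_pos] - start[k_pos])
    return DriftEstimate(
        reference_shifts=ref_shifts,
        subscan_start=start,
        subscan_end=end,
        frame_shifts=frame_shifts,
    )


def correct_drift(series: ProjectionSeries, est: DriftEstimate) -> ProjectionSeries:
    """Shift every frame opposite to its interpolated drift and drop the
    reference exposures from the output science set."""
    if est.frame_shifts.shape[0] != series.n_frames:
        raise ValueError(
            f"drift estimate covers {est.frame_shifts.shape[0]} frames, series has {series.n_frames}"
        )
    keep = np.nonzero(~series.is_reference)[0]
    corrected = np.empty((keep.size,) + series.frames.shape[1:], dtype=float)
    for out_i, i in enumerate(keep):
        frame = series.frames[i].astype(float)
        shift = est.frame_shifts[i]
        if np.abs(shift).max() > 1e-6:  # sub-nanopixel shifts only corrupt edges
            frame = ndimage.shift(frame, -shift, order=1, mode="constant", cval=0.0)
        corrected[out_i] = frame
    return ProjectionSeries(
        frames=corrected,
        angles_deg=series.angles_deg[keep],
        subscan_index=series.subscan_index[keep],
        is_reference=np.zeros(keep.size, dtype=bool),
    )
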
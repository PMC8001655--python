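"""Volume and projection-series I/O with physical-scale metadata.

Conventions
-----------
* Array axis order is ``(z, y, x)``; the z axis is the axial (stack)
  direction and one TIFF page holds one ``(y, x)`` slice.
* Indices are 0-based, voxel centers sit at integer coordinates and the
  physical position of voxel ``(i, j, k)`` is
  ``origin + index * voxel_size`` (micrometres).
* Intensities are stored as acquired (often integer) but every
  computation in the toolkit promotes to floating point.

Two on-disk formats are supported: multi-page grayscale TIFF (metadata
embedded in the image description) and raw binary next to a small
key-value text sidecar (``<path>.meta``).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "ProjectionSeries",
    "read_volume",
    "write_volume",
    "read_projections",
    "write_projections",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _as_triplet(value, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 sequence, got {value!r}")
    return arr


@dataclass
class Volume:
    """A reconstructed 3D intensity grid with voxel size in micrometres."""

    data: np.ndarray
    voxel_size: np.ndarray  # um per axis, (z, y, x)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every volume dimension must be >= 1")
        self.voxel_size = _as_triplet(self.voxel_size, "voxel_size")
        if np.any(self.voxel_size <= 0) or not np.all(np.isfinite(self.voxel_size)):
            raise ValueError("voxel_size must be positive and finite on every axis")
        self.origin = _as_triplet(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype_float(self) -> np.ndarray:
        """Intensity grid promoted to float64 (no copy if already float64)."""
        return np.asarray(self.data, dtype=np.float64)

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume sharing this volume's physical metadata."""
        return Volume(data=data, voxel_size=self.voxel_size.copy(), origin=self.origin.copy())


@dataclass
class ProjectionSeries:
    """An ordered stack of 2D radiographs with acquisition annotations.

    ``is_reference`` flags the repeated fixed-angle exposures used for
    focal-spot drift estimation; ``subscan_index`` groups frames into the
    interleaved sub-scans they were acquired in.
    """

    frames: np.ndarray  # (n, h, w)
    angles_deg: np.ndarray
    subscan_index: np.ndarray
    is_reference: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must form a 3D (n, h, w) stack")
        n = self.frames.shape[0]
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.subscan_index = np.asarray(self.subscan_index, dtype=int)
        self.is_reference = np.asarray(self.is_reference, dtype=bool)
        for name in ("angles_deg", "subscan_index", "is_reference"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per frame ({n})")
        for k in np.unique(self.subscan_index):
            sel = (self.subscan_index == k) & ~self.is_reference
            ang = self.angles_deg[sel]
            if ang.size > 1 and not np.all(np.diff(ang) > 0):
                raise ValueError(f"non-reference angles not strictly increasing in sub-scan {k}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Volumes

def write_volume(v: Volume, path) -> None:
    """Persist a volume as multi-page TIFF or raw + sidecar (by extension)."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(
            path,
            v.data,
            photometric="minisblack",
            metadata={
                "voxel_size_um": [float(s) for s in v.voxel_size],
                "origin_um": [float(o) for o in v.origin],
            },
        )
    else:
        path.write_bytes(np.ascontiguousarray(v.data).tobytes())
        meta = Path(str(path) + ".meta")
        lines = [
            f"shape: {v.data.shape[0]} {v.data.shape[1]} {v.data.shape[2]}",
            f"dtype: {v.data.dtype.name}",
            "voxel_size_um: " + " ".join(repr(float(s)) for s in v.voxel_size),
            "origin_um: " + " ".join(repr(float(o)) for o in v.origin),
        ]
        meta.write_text("\n".join(lines) + "\n")


def _read_sidecar(path: Path) -> dict:
    meta_path = Path(str(path) + ".meta")
    if not meta_path.is_file():
        raise FileNotFoundError(f"raw volume has no sidecar metadata file: {meta_path}")
    out: dict = {}
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if not line or ":" not in line:
            continue
        key, value = line.split(":", 1)
        out[key.strip()] = value.strip()
    return out


def read_volume(path, voxel_size_override=None) -> Volume:
    """Read a TIFF stack or raw-binary volume.

    ``voxel_size_override`` (um) substitutes for missing or wrong stored
    metadata; for raw files it makes a shape/dtype-bearing sidecar's
    voxel size optional, not the sidecar itself.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such volume file: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"TIFF does not hold a 2D/3D grayscale stack: {path}")
        voxel_size = meta.get("voxel_size_um")
        origin = meta.get("origin_um", (0.0, 0.0, 0.0))
    else:
        meta = _read_sidecar(path)
        if "shape" not in meta or "dtype" not in meta:
            raise ValueError(f"sidecar for {path} lacks shape/dtype")
        shape = tuple(int(t) for t in meta["shape"].split())
        dtype = np.dtype(meta["dtype"])
        data = np.frombuffer(path.read_bytes(), dtype=dtype).reshape(shape).copy()
        voxel_size = [float(t) for t in meta["voxel_size_um"].split()] if "voxel_size_um" in meta else None
        origin = [float(t) for t in meta["origin_um"].split()] if "origin_um" in meta else (0.0, 0.0, 0.0)
    if voxel_size_override is not None:
        voxel_size = voxel_size_override
    if voxel_size is None:
        raise ValueError(f"voxel size missing from {path} and no override given")
    return Volume(data=data, voxel_size=voxel_size, origin=origin)


# ---------------------------------------------------------------------------
# Projection series

def write_projections(series: ProjectionSeries, path) -> None:
    """Write frames as a multi-page TIFF; annotations go to the metadata."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(
        path,
        series.frames,
        photometric="minisblack",
        metadata={
            "angles_deg": [float(a) for a in series.angles_deg],
            "subscan_index": [int(k) for k in series.subscan_index],
            "is_reference": [bool(r) for r in series.is_reference],
        },
    )


def read_projections(path, plan) -> ProjectionSeries:
    """Read a projection TIFF and annotate frames per the scan plan.

    The frame count must equal ``plan.total_frames`` (one reference frame
    leading each sub-scan).  Stored annotations, when present and
    consistent, are preserved verbatim.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such projection file: {path}")
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != plan.total_frames:
        raise ValueError(
            f"frame count {frames.shape[0]} does not match scan plan total {plan.total_frames}"
        )
    if "angles_deg" in meta:
        angles = _meta_list(meta["angles_deg"], float)
        subscan = _meta_list(meta["subscan_index"], int)
        is_ref = _meta_list(meta["is_reference"], bool)
    else:
        angles, subscan, is_ref = plan.frame_annotations()
    return ProjectionSeries(
        frames=frames,
        angles_deg=np.asarray(angles, dtype=float),
        subscan_index=np.asarray(subscan, dtype=int),
        is_reference=np.asarray(is_ref, dtype=bool),
    )


def _meta_list(value, cast):
    # tifffile may round-trip metadata lists as their repr string
    if isinstance(value, str):
        value = ast.literal_eval(value)
    return [cast(x) for x in value]
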
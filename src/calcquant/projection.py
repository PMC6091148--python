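"""Thin-slab minimum/maximum intensity projections.

Calcium is displayed dark on proton-density in-phase MR (MinIP) and bright
on CT (MIP); thin slabs of 4-15 mm are the conventional display.  Axis-
aligned slabs reduce voxels directly (bit-exact); oblique slabs resample
planes perpendicular to the normal first.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .volume_io import ScalarVolume

__all__ = ["ProjectionSpec", "thin_slab_projection", "save_projection"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class ProjectionSpec:
    """Slab geometry for a projection.

    ``orientation`` is an axis name ("x"/"y"/"z") or an arbitrary normal
    vector.  ``slab_center_mm`` is the physical coordinate of the slab center
    along the normal; None centers the slab on the volume (or on a mask
    centroid chosen by the caller).
    """

    orientation: str | tuple[float, float, float] = "y"
    slab_thickness_mm: float = 8.0
    slab_center_mm: float | None = None
    mode: str = "min"

    def __post_init__(self) -> None:
        if self.slab_thickness_mm <= 0:
            raise ValueError("slab thickness must be positive")
        if self.mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")


def _axis_aligned(vol: ScalarVolume, spec: ProjectionSpec, axis: int) -> np.ndarray:
    spacing = vol.spacing[axis]
    n = vol.data.shape[axis]
    centers = vol.origin[axis] + np.arange(n) * spacing
    center = (
        spec.slab_center_mm
        if spec.slab_center_mm is not None
        else vol.origin[axis] + (n - 1) * spacing / 2.0
    )
    half = spec.slab_thickness_mm / 2.0
    if center < centers[0] - spacing / 2 - half or center > centers[-1] + spacing / 2 + half:
        raise ValueError("slab lies outside the volume")
    inside = np.abs(centers - center) <= half + 1e-9
    if spec.slab_thickness_mm < spacing or not inside.any():
        warnings.warn(
            "slab thinner than one voxel; using the nearest single slice",
            stacklevel=3,
        )
        inside = np.zeros(n, dtype=bool)
        inside[np.argmin(np.abs(centers - center))] = True
    sub = np.compress(inside, vol.data, axis=axis)
    reduce = np.min if spec.mode == "min" else np.max
    return reduce(sub, axis=axis)


def _oblique(vol: ScalarVolume, spec: ProjectionSpec) -> np.ndarray:
    if not vol.is_isotropic:
        raise ValueError("oblique projection requires an isotropic volume")
    s = vol.spacing[0]
    n = np.asarray(spec.orientation, dtype=float)
    n = n / np.linalg.norm(n)
    # orthonormal in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    shape = np.asarray(vol.data.shape)
    center_idx = (shape - 1) / 2.0
    if spec.slab_center_mm is not None:
        # offset along the normal from the volume center, in mm
        center_idx = center_idx + n * (spec.slab_center_mm / s)
    half_diag = int(np.ceil(np.linalg.norm(shape) / 2.0))
    uu = np.arange(-half_diag, half_diag + 1)
    depth = np.arange(
        -spec.slab_thickness_mm / 2.0, spec.slab_thickness_mm / 2.0 + 1e-9, s
    ) / s
    if depth.size == 0:
        depth = np.array([0.0])
        warnings.warn("slab thinner than one voxel; single oblique slice", stacklevel=3)
    fill = np.inf if spec.mode == "min" else -np.inf
    reduce = np.minimum if spec.mode == "min" else np.maximum
    out = np.full((uu.size, uu.size), fill)
    gu, gv = np.meshgrid(uu, uu, indexing="ij")
    for d in depth:
        coords = (
            center_idx[:, None, None]
            + u[:, None, None] * gu
            + v[:, None, None] * gv
            + n[:, None, None] * d
        )
        plane = ndimage.map_coordinates(
            vol.data.astype(float), coords, order=1, mode="constant", cval=np.nan
        )
        valid = ~np.isnan(plane)
        out[valid] = reduce(out[valid], plane[valid])
    if not np.isfinite(out).any():
        raise ValueError("slab lies outside the volume")
    out[~np.isfinite(out)] = np.nan
    return out


def thin_slab_projection(vol: ScalarVolume, spec: ProjectionSpec) -> np.ndarray:
    """Project a slab of the volume to a 2-D image by per-pixel min or max.

    Output pixel size equals the in-plane voxel size.  Oblique pixels with no
    valid sample are NaN.
    """
    if isinstance(spec.orientation, str):
        if spec.orientation not in _AXES:
            raise ValueError(f"unknown axis {spec.orientation!r}")
        return _axis_aligned(vol, spec, _AXES[spec.orientation])
    return _oblique(vol, spec)


def save_projection(image: np.ndarray, path: str | Path) -> Path:
    """Save a projection as 16-bit PNG with a window/level JSON sidecar."""
    path = Path(path)
    img = np.asarray(image, dtype=float)
    finite = img[np.isfinite(img)]
    lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 1.0)
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    out = np.clip((np.nan_to_num(img, nan=lo) - lo) * scale, 0, 65535)
    Image.fromarray(out.astype(np.uint16)).save(path)
    path.with_suffix(".json").write_text(
        json.dumps({"window": hi - lo, "level": (hi + lo) / 2.0, "min": lo, "max": hi})
    )
    return path
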
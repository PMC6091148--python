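"""3-D scalar volumes: NIfTI I/O, isotropic resampling, segment tables.

The analysis operates on :class:`ScalarVolume` objects — a 3-D intensity grid
(Hounsfield units for CT, arbitrary signal units for MR) with per-axis voxel
spacing in mm.  Before any volumetry, volumes are rescaled to a common 0.5 mm
isotropic grid by separable cubic (tricubic) interpolation so that per-segment
calcium volumes are comparable across modalities with different native grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CT",
    "MR",
    "ScalarVolume",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "SEGMENT_TABLE_COLUMNS",
    "validate_segment_table",
    "read_segment_table",
    "write_segment_table",
]

CT = "CT"
MR = "MR"

#: Target isotropic voxel size (mm) used before volume measurement.
ANALYSIS_SPACING_MM = 0.5


@dataclass
class ScalarVolume:
    """A 3-D scalar intensity grid with physical voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities; must be finite everywhere.
    spacing : tuple of 3 floats
        Per-axis voxel size in mm, all strictly positive.
    origin : tuple of 3 floats
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    modality : str or None
        ``"CT"``, ``"MR"`` or None when not applicable.

    Voxel centers lie at ``origin + index * spacing`` (right-handed axes);
    the physical extent of the grid is ``shape * spacing`` (each voxel owns a
    half-voxel margin around its center).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must have exactly 3 axes, got {self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite everywhere")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.modality is not None and self.modality not in (CT, MR):
            raise ValueError(f"modality must be 'CT', 'MR' or None, got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag((*self.spacing, 1.0))
        aff[:3, 3] = self.origin
        return aff

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Total extent (mm) along each axis, counting half-voxel margins."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[0] - s[2]) < 1e-9

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.data.shape[a]) * self.spacing[a]
            for a in range(3)
        )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path, modality: str | None = None) -> ScalarVolume:
    """Read a 3-D NIfTI volume.

    Spacing is taken from the header zooms, origin from the affine
    translation.  Modality is taken from the explicit argument or, failing
    that, from a JSON sidecar written by :func:`write_volume`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3 spatial dimensions, got {data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if modality is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            modality = meta.get("modality")
    return ScalarVolume(data, spacing, origin, modality)


def write_volume(vol: ScalarVolume, path: str | Path) -> Path:
    """Write a :class:`ScalarVolume` as NIfTI plus a JSON metadata sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, path)
    _sidecar_path(path).write_text(
        json.dumps({"modality": vol.modality, "spacing_mm": list(vol.spacing)})
    )
    return path


def resample_isotropic(
    vol: ScalarVolume, target_mm: float = ANALYSIS_SPACING_MM
) -> ScalarVolume:
    """Resample a volume to isotropic resolution by tricubic interpolation.

    The output grid covers the full physical extent of the input (half-voxel
    convention): output voxel centers along each axis lie at
    ``origin - spacing/2 + (k + 1/2) * target_mm``.  When input spacing
    already equals ``target_mm`` on every axis this is an identity map.
    Coordinates outside the input grid take the nearest-edge value, which
    avoids manufacturing dark out-of-field voxels that a low-signal MR
    threshold would misclassify as calcium.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    spacing = np.asarray(vol.spacing)
    shape = np.asarray(vol.data.shape)
    extent = shape * spacing
    if np.any(target_mm > extent):
        raise ValueError(
            f"target spacing {target_mm} mm exceeds physical extent {tuple(extent)} mm"
        )
    out_shape = np.ceil(extent / target_mm - 1e-9).astype(int)
    # input index coordinate of each output voxel center
    index_coords = [
        (-spacing[a] / 2.0 + (np.arange(out_shape[a]) + 0.5) * target_mm) / spacing[a]
        for a in range(3)
    ]
    grid = np.meshgrid(*index_coords, indexing="ij")
    out = ndimage.map_coordinates(
        vol.data.astype(np.float64), np.stack(grid), order=3, mode="nearest"
    )
    new_origin = tuple(
        vol.origin[a] - vol.spacing[a] / 2.0 + target_mm / 2.0 for a in range(3)
    )
    return ScalarVolume(out, (target_mm,) * 3, new_origin, vol.modality)


# ---------------------------------------------------------------------------
# Segment tables
# ---------------------------------------------------------------------------

SEGMENT_TABLE_COLUMNS = [
    "exam_id",
    "segment",
    "modality",
    "volume_mm3",
    "group",
    "excluded",
    "reason",
]


def validate_segment_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate per-segment bookkeeping invariants; return the table.

    Volumes must be non-negative, severity groups in {1, 2, 3}, and the
    exclusion reason non-empty exactly when a row is flagged excluded.
    """
    missing = [c for c in SEGMENT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    vols = table["volume_mm3"].dropna()
    if (vols < 0).any():
        raise ValueError("segment table contains negative volumes")
    groups = table["group"].dropna()
    if not groups.isin([1, 2, 3]).all():
        raise ValueError("severity group must be 1, 2 or 3")
    excluded = table["excluded"].astype(bool)
    reason = table["reason"].fillna("").astype(str)
    if ((reason != "") != excluded).any():
        raise ValueError("exclusion reason must be nonempty iff excluded")
    return table


def write_segment_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_segment_table(table)
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_segment_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["reason"] = table["reason"].fillna("")
    return validate_segment_table(table)
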
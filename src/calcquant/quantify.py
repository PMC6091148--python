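"""Threshold segmentation and volumetry of vascular calcium within vessel ROIs.

Modality-specific rules, applied after resampling to the 0.5 mm isotropic
analysis grid:

* **CT**: voxels strictly above a fixed Hounsfield cutoff (default 560 HU,
  the level separating dense calcium from contrast-enhanced lumen).
* **MR**: voxels with signal strictly below ``mean - k*SD`` of the ROI
  background — k = 3 in the ilio-femoral region, k = 2 in the aorto-iliac
  region where background variability is higher.  Background statistics are
  estimated on the ROI itself with one re-estimation pass that excludes
  already-classified voxels, so that dense calcium does not inflate the SD
  and suppress its own detection.

Volumes are voxel counts times voxel volume (0.125 mm³ at 0.5 mm isotropic);
no connected-component or minimum-size filtering is applied, so isolated
noise voxels contribute their expected Gaussian-tail fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import CT, MR, ScalarVolume, SEGMENT_TABLE_COLUMNS, validate_segment_table

__all__ = [
    "ILIO_FEMORAL",
    "AORTO_ILIAC",
    "REGION_SEGMENTS",
    "SegmentROI",
    "ThresholdPolicy",
    "CalcificationMeasurement",
    "build_segment_roi",
    "roi_from_definition",
    "segment_ct",
    "segment_mr",
    "measure_volume",
    "classify_severity",
    "quantify_exam",
    "assemble_cohort_table",
    "cohort_accounting",
]

ILIO_FEMORAL = "ilio_femoral"
AORTO_ILIAC = "aorto_iliac"

REGION_SEGMENTS: dict[str, tuple[str, ...]] = {
    ILIO_FEMORAL: (
        "common_femoral_proximal_left",
        "common_femoral_proximal_right",
        "superficial_femoral_distal_left",
        "superficial_femoral_distal_right",
    ),
    AORTO_ILIAC: (
        "distal_aorta",
        "common_iliac_left",
        "common_iliac_right",
        "external_iliac_left",
        "external_iliac_right",
    ),
}


@dataclass
class SegmentROI:
    """A named vessel-segment mask on the analysis grid."""

    label: str
    region: str
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.region not in REGION_SEGMENTS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.label not in REGION_SEGMENTS[self.region]:
            raise ValueError(
                f"label {self.label!r} is not a {self.region} segment"
            )
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3 or not self.mask.any():
            raise ValueError("ROI mask must be a nonempty 3-D binary volume")
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class ThresholdPolicy:
    """Modality-specific segmentation thresholds (defaults per protocol)."""

    ct_hu_cutoff: float = 560.0
    mr_k_ilio_femoral: float = 3.0
    mr_k_aorto_iliac: float = 2.0

    def __post_init__(self) -> None:
        if self.ct_hu_cutoff <= 0:
            raise ValueError("CT cutoff must be positive")
        if self.mr_k_ilio_femoral <= 0 or self.mr_k_aorto_iliac <= 0:
            raise ValueError("MR SD multipliers must be positive")

    def mr_k(self, region: str) -> float:
        if region == ILIO_FEMORAL:
            return self.mr_k_ilio_femoral
        if region == AORTO_ILIAC:
            return self.mr_k_aorto_iliac
        raise ValueError(f"unknown region {region!r}")


@dataclass
class CalcificationMeasurement:
    """Per-segment calcium volume with threshold provenance."""

    segment: str
    modality: str
    volume_mm3: float
    voxel_count: int
    threshold: float
    background_mean: float | None = None
    background_sd: float | None = None


def _check_grid(vol: ScalarVolume, roi: SegmentROI) -> None:
    if vol.data.shape != roi.mask.shape:
        raise ValueError(
            f"volume grid {vol.data.shape} does not match ROI grid {roi.mask.shape}"
        )
    if not np.allclose(vol.spacing, roi.spacing):
        raise ValueError("volume and ROI voxel spacing differ")
    if not vol.is_isotropic:
        raise ValueError(
            "volume must be resampled to an isotropic grid before segmentation"
        )


def build_segment_roi(
    label: str,
    region: str,
    landmark_mm,
    direction,
    grid: ScalarVolume,
    length_mm: float = 50.0,
    radius_mm: float = 5.0,
) -> SegmentROI:
    """Rasterize a cylindrical segment ROI onto a volume's grid.

    The cylinder starts at the anatomical landmark and extends ``length_mm``
    along ``direction`` with the given radius — e.g. the 5 cm of common
    femoral artery immediately above the femoral bifurcation.
    """
    if length_mm <= 0 or radius_mm <= 0:
        raise ValueError("length and radius must be positive")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be nonzero")
    d = d / norm
    p0 = np.asarray(landmark_mm, dtype=float)
    cx, cy, cz = grid.voxel_centers()
    xx, yy, zz = np.meshgrid(cx, cy, cz, indexing="ij")
    dx, dy, dz = xx - p0[0], yy - p0[1], zz - p0[2]
    t = dx * d[0] + dy * d[1] + dz * d[2]
    perp2 = dx**2 + dy**2 + dz**2 - t**2
    mask = (t >= 0) & (t <= length_mm) & (perp2 <= radius_mm**2)
    if not mask.any():
        raise ValueError(f"segment cylinder for {label!r} lies entirely outside grid")
    return SegmentROI(label=label, region=region, mask=mask, spacing=grid.spacing)


def roi_from_definition(definition: dict, grid: ScalarVolume) -> SegmentROI:
    """Build a cylindrical ROI from its JSON-style definition dict."""
    return build_segment_roi(
        label=definition["label"],
        region=definition["region"],
        landmark_mm=definition["landmark_mm"],
        direction=definition["direction"],
        grid=grid,
        length_mm=definition.get("length_mm", 50.0),
        radius_mm=definition.get("radius_mm", 5.0),
    )


def segment_ct(
    vol: ScalarVolume, roi: SegmentROI, policy: ThresholdPolicy | None = None
) -> np.ndarray:
    """Calcium mask on CT: ROI voxels strictly above the HU cutoff."""
    policy = policy or ThresholdPolicy()
    if vol.modality != CT:
        raise ValueError(f"segment_ct requires a CT volume, got {vol.modality!r}")
    _check_grid(vol, roi)
    return roi.mask & (vol.data > policy.ct_hu_cutoff)


def segment_mr(
    vol: ScalarVolume, roi: SegmentROI, policy: ThresholdPolicy | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Calcium mask on MR: two-pass ``mean - k*SD`` rule on ROI background.

    Pass 1 estimates (mean, SD) over all ROI voxels and classifies voxels
    strictly below ``mean - k*SD``.  Pass 2 re-estimates the statistics over
    the ROI *excluding* pass-1 voxels and classifies once more (a single
    re-pass, for determinism).  Returns the final mask and final (mean, SD).

    Degenerate cases: a ROI with zero SD yields an empty mask with a warning;
    if the pass-2 background is exactly constant (SD 0) the pass-1
    classification stands.
    """
    policy = policy or ThresholdPolicy()
    if vol.modality != MR:
        raise ValueError(f"segment_mr requires an MR volume, got {vol.modality!r}")
    _check_grid(vol, roi)
    k = policy.mr_k(roi.region)
    vals = vol.data[roi.mask]
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn(
            f"{roi.label}: degenerate ROI (zero signal SD); returning empty mask",
            stacklevel=2,
        )
        return np.zeros_like(roi.mask), (mu, 0.0)
    mask1 = roi.mask & (vol.data < mu - k * sd)
    rest = vol.data[roi.mask & ~mask1]
    if rest.size < 2:
        return mask1, (mu, sd)
    mu2 = float(rest.mean())
    sd2 = float(rest.std(ddof=1))
    if sd2 == 0.0:
        return mask1, (mu2, 0.0)
    mask2 = roi.mask & (vol.data < mu2 - k * sd2)
    return mask2, (mu2, sd2)


def measure_volume(mask: np.ndarray, spacing) -> float:
    """Volume of a binary mask: voxel count x voxel volume (isotropic grid)."""
    spacing = tuple(float(s) for s in spacing)
    if not (abs(spacing[0] - spacing[1]) < 1e-9 and abs(spacing[0] - spacing[2]) < 1e-9):
        raise ValueError(
            f"volume measurement requires an isotropic grid, got spacing {spacing}"
        )
    return float(np.count_nonzero(mask) * np.prod(spacing))


def classify_severity(cta_volume_mm3: float) -> int:
    """Severity group from the CTA volume: 0-99 / 100-299 / >=300 mm³."""
    if cta_volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    if cta_volume_mm3 < 100.0:
        return 1
    if cta_volume_mm3 < 300.0:
        return 2
    return 3


def _measure(vol, roi, policy) -> CalcificationMeasurement:
    if vol.modality == CT:
        mask = segment_ct(vol, roi, policy)
        return CalcificationMeasurement(
            segment=roi.label,
            modality=CT,
            volume_mm3=measure_volume(mask, vol.spacing),
            voxel_count=int(mask.sum()),
            threshold=policy.ct_hu_cutoff,
        )
    mask, (mu, sd) = segment_mr(vol, roi, policy)
    k = policy.mr_k(roi.region)
    return CalcificationMeasurement(
        segment=roi.label,
        modality=MR,
        volume_mm3=measure_volume(mask, vol.spacing),
        voxel_count=int(mask.sum()),
        threshold=mu - k * sd,
        background_mean=mu,
        background_sd=sd,
    )


def quantify_exam(
    exam_id: str,
    ct: ScalarVolume,
    mr: ScalarVolume,
    rois: list[SegmentROI],
    policy: ThresholdPolicy | None = None,
    exclusions: list[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Quantify every segment of one paired exam into a segment table.

    One row per (segment, modality) with volume, severity group (always from
    the CTA volume) and exclusion bookkeeping.  Excluded segments carry no
    volumes.  ``exclusions`` is a list of ``(segment_label, reason)``.
    """
    policy = policy or ThresholdPolicy()
    labels = [r.label for r in rois]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate ROI labels in exam")
    excl = dict(exclusions)
    unknown = set(excl) - set(labels)
    if unknown:
        raise ValueError(f"exclusion labels not among ROIs: {sorted(unknown)}")
    for label, reason in excl.items():
        if not reason:
            raise ValueError(f"exclusion of {label!r} requires a nonempty reason")
    rows = []
    for roi in rois:
        if roi.label in excl:
            for modality in (CT, MR):
                rows.append(
                    dict(
                        exam_id=exam_id,
                        segment=roi.label,
                        modality=modality,
                        volume_mm3=np.nan,
                        group=np.nan,
                        excluded=True,
                        reason=excl[roi.label],
                    )
                )
            continue
        m_ct = _measure(ct, roi, policy)
        m_mr = _measure(mr, roi, policy)
        group = classify_severity(m_ct.volume_mm3)
        for m in (m_ct, m_mr):
            rows.append(
                dict(
                    exam_id=exam_id,
                    segment=m.segment,
                    modality=m.modality,
                    volume_mm3=m.volume_mm3,
                    group=group,
                    excluded=False,
                    reason="",
                )
            )
    table = pd.DataFrame(rows, columns=SEGMENT_TABLE_COLUMNS)
    return validate_segment_table(table)


def assemble_cohort_table(
    exam_ids: list[str],
    region: str,
    exclusions: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Bookkeeping-only segment table: one row per (exam, segment).

    Enumerates the region's segment labels for every exam (4 bilateral
    femoral segments per ilio-femoral exam, 5 aorto-iliac segments) and flags
    exclusions given as ``{(exam_id, segment): reason}``.
    """
    if region not in REGION_SEGMENTS:
        raise ValueError(f"unknown region {region!r}")
    exclusions = exclusions or {}
    rows = []
    for exam_id in exam_ids:
        for segment in REGION_SEGMENTS[region]:
            reason = exclusions.get((exam_id, segment), "")
            rows.append(
                dict(
                    exam_id=exam_id,
                    segment=segment,
                    modality="",
                    volume_mm3=np.nan,
                    group=np.nan,
                    excluded=bool(reason),
                    reason=reason,
                )
            )
    unknown = set(exclusions) - {(r["exam_id"], r["segment"]) for r in rows}
    if unknown:
        raise ValueError(f"exclusions refer to unknown segments: {sorted(unknown)}")
    return pd.DataFrame(rows, columns=SEGMENT_TABLE_COLUMNS)


def cohort_accounting(table: pd.DataFrame) -> dict[str, int]:
    """Count available / excluded / analyzed segments of a cohort table.

    ``analyzed + excluded == available`` always holds by construction.
    """
    seg = table.drop_duplicates(subset=["exam_id", "segment"])
    available = len(seg)
    excluded = int(seg["excluded"].astype(bool).sum())
    return {
        "available": available,
        "excluded": excluded,
        "analyzed": available - excluded,
    }
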
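"""Synthetic paired CT/MR exams of calcified vessel segments.

The generator builds digital phantoms of peripheral arteries containing
calcium deposits with analytically known volumes, and renders them under the
contrast regime of the two modalities:

* **CT**: contrast-enhanced lumen (~300 HU) against dense calcium (~1000 HU),
  blurred by an isotropic Gaussian point-spread function.  Thresholding a
  blurred high-contrast edge above the lumen level recovers a region *larger*
  than the true deposit — the blooming artifact that inflates CT volumetry.
* **MR** (proton-density in-phase): intermediate, near-uniform background
  signal with calcium carrying essentially no signal.  Mobile water spins in
  the surface shell of a deposit return detectable signal, which is modelled
  as shrinking the dark core by a fixed surface-layer thickness, so MR
  volumetry *under*-estimates true deposit volume.

A companion generator produces paired ordinal reader scores (5-point Likert)
with a tunable agreement level, for exercising chance-corrected agreement
statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .volume_io import CT, MR, ScalarVolume

__all__ = [
    "Cylinder",
    "Ellipsoid",
    "CTModel",
    "MRModel",
    "PhantomSpec",
    "GroundTruth",
    "voxelize_truth",
    "render_ct",
    "render_mr",
    "simulate_ratings",
    "expected_weighted_kappa",
    "agreement_for_kappa",
    "DEFAULT_SCORE_DIST",
    "Exam",
    "make_exam",
    "make_cohort",
]


@dataclass
class Cylinder:
    """A straight vessel segment: axis endpoints (mm), lumen radius, wall."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    lumen_radius_mm: float
    wall_thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen radius must be positive")
        if self.wall_thickness_mm < 0:
            raise ValueError("wall thickness must be non-negative")


@dataclass
class Ellipsoid:
    """An axis-aligned ellipsoidal calcium deposit with known true volume."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    segment: str | None = None

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("ellipsoid semi-axes must be positive")

    @property
    def analytic_volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class CTModel:
    """CT rendering parameters (Hounsfield units)."""

    soft_tissue_hu: float = 40.0
    wall_hu: float = 60.0
    lumen_hu: float = 300.0
    calcium_hu: float = 1000.0
    psf_fwhm_mm: float = 1.0
    noise_sd_hu: float = 20.0


@dataclass
class MRModel:
    """Proton-density in-phase MR rendering parameters (arbitrary units)."""

    background_mean: float = 100.0
    background_sd: float = 0.0       # slowly-varying tissue heterogeneity
    calcium_fraction: float = 0.0    # calcium signal as fraction of background
    surface_layer_mm: float = 0.4    # mobile-water shell shrinking the dark core
    noise_sd: float = 10.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic paired exam.

    Grid geometry, vessel cylinders, calcium deposits and the two rendering
    models.  Identical spec + seed yields bit-identical rendered volumes.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    vessels: list[Cylinder] = field(default_factory=list)
    deposits: list[Ellipsoid] = field(default_factory=list)
    ct: CTModel = field(default_factory=CTModel)
    mr: MRModel = field(default_factory=MRModel)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not (self.ct.calcium_hu > 560.0 > self.ct.lumen_hu):
            raise ValueError("CT model must satisfy calcium HU > 560 > lumen HU")
        mr = self.mr
        if not (
            mr.calcium_fraction * mr.background_mean
            < mr.background_mean - 3.0 * mr.background_sd
        ):
            raise ValueError("MR calcium signal must lie below mean - 3*SD")
        if self.ct.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be non-negative")
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        lo = np.asarray(self.origin) - np.asarray(self.spacing) / 2.0
        for dep in self.deposits:
            c = np.asarray(dep.center)
            ax = np.asarray(dep.semi_axes)
            if np.any(c - ax < lo) or np.any(c + ax > lo + extent):
                raise ValueError(f"deposit at {dep.center} lies outside the grid")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")

    # JSON round trip -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PhantomSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        d["vessels"] = [Cylinder(**v) for v in d.get("vessels", [])]
        d["deposits"] = [Ellipsoid(**v) for v in d.get("deposits", [])]
        d["ct"] = CTModel(**d.get("ct", {}))
        d["mr"] = MRModel(**d.get("mr", {}))
        for key in ("shape", "spacing", "origin"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic and voxelized truth for every deposit of a phantom."""

    deposit_masks: list[np.ndarray]
    analytic_mm3: np.ndarray
    voxelized_mm3: np.ndarray
    segments: list[str | None]

    def segment_totals(self, voxelized: bool = True) -> dict[str, float]:
        vols = self.voxelized_mm3 if voxelized else self.analytic_mm3
        totals: dict[str, float] = {}
        for seg, v in zip(self.segments, vols):
            if seg is not None:
                totals[seg] = totals.get(seg, 0.0) + float(v)
        return totals

    @property
    def total_mask(self) -> np.ndarray:
        if not self.deposit_masks:
            raise ValueError("no deposits")
        out = np.zeros_like(self.deposit_masks[0], dtype=bool)
        for m in self.deposit_masks:
            out |= m
        return out


def _ellipsoid_mask(dep: Ellipsoid, grids, shrink_mm: float = 0.0) -> np.ndarray:
    ax = np.asarray(dep.semi_axes) - shrink_mm
    if np.any(ax <= 0):
        return np.zeros(grids[0].shape, dtype=bool)
    xx, yy, zz = grids
    c = dep.center
    q = (
        ((xx - c[0]) / ax[0]) ** 2
        + ((yy - c[1]) / ax[1]) ** 2
        + ((zz - c[2]) / ax[2]) ** 2
    )
    return q <= 1.0


def voxelize_truth(spec: PhantomSpec) -> GroundTruth:
    """Binary deposit masks by inside-ellipsoid test at voxel centers.

    Voxelized volume = voxel count x voxel volume; converges to the analytic
    ellipsoid volume as the grid is refined.
    """
    grids = spec.coordinate_grids()
    masks, analytic, voxelized, segments = [], [], [], []
    vv = spec.voxel_volume_mm3
    for dep in spec.deposits:
        m = _ellipsoid_mask(dep, grids)
        masks.append(m)
        analytic.append(dep.analytic_volume_mm3)
        voxelized.append(m.sum() * vv)
        segments.append(dep.segment)
    shape = spec.shape
    if not masks:
        masks = []
    return GroundTruth(
        deposit_masks=masks,
        analytic_mm3=np.asarray(analytic, dtype=float),
        voxelized_mm3=np.asarray(voxelized, dtype=float),
        segments=segments,
    )


def _paint_vessels(spec: PhantomSpec, grids, field_arr: np.ndarray) -> None:
    xx, yy, zz = grids
    ct = spec.ct
    for ves in spec.vessels:
        p0 = np.asarray(ves.start, dtype=float)
        p1 = np.asarray(ves.end, dtype=float)
        axis = p1 - p0
        length = np.linalg.norm(axis)
        if length == 0:
            raise ValueError("vessel with zero length")
        u = axis / length
        dx, dy, dz = xx - p0[0], yy - p0[1], zz - p0[2]
        t = dx * u[0] + dy * u[1] + dz * u[2]
        perp2 = dx**2 + dy**2 + dz**2 - t**2
        along = (t >= 0) & (t <= length)
        outer = ves.lumen_radius_mm + ves.wall_thickness_mm
        field_arr[along & (perp2 <= outer**2)] = ct.wall_hu
        field_arr[along & (perp2 <= ves.lumen_radius_mm**2)] = ct.lumen_hu


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec_seed, stream)))


def render_ct(spec: PhantomSpec) -> ScalarVolume:
    """Render the CT volume: piecewise-constant HU field, Gaussian PSF, noise.

    With ``psf_fwhm_mm = 0`` and ``noise_sd_hu = 0`` the output is exactly
    piecewise constant and deposits occupy exactly their ground-truth masks.
    """
    grids = spec.coordinate_grids()
    field_arr = np.full(spec.shape, spec.ct.soft_tissue_hu, dtype=np.float64)
    _paint_vessels(spec, grids, field_arr)
    for dep in spec.deposits:
        field_arr[_ellipsoid_mask(dep, grids)] = spec.ct.calcium_hu
    if spec.ct.psf_fwhm_mm > 0:
        sigma_mm = spec.ct.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_vox = [sigma_mm / s for s in spec.spacing]
        field_arr = ndimage.gaussian_filter(field_arr, sigma_vox, mode="nearest")
    if spec.ct.noise_sd_hu > 0:
        field_arr = field_arr + _rng(spec.seed, 1).normal(
            0.0, spec.ct.noise_sd_hu, spec.shape
        )
    return ScalarVolume(field_arr, spec.spacing, spec.origin, CT)


def render_mr(spec: PhantomSpec) -> ScalarVolume:
    """Render the proton-density in-phase MR volume.

    Background at the stated mean (plus optional smooth heterogeneity);
    deposit dark cores — each ellipsoid shrunk by the surface-water layer
    thickness — at ``calcium_fraction x background_mean``; Gaussian noise.
    A deposit whose smallest semi-axis does not exceed the layer thickness
    vanishes entirely (rendered empty, with a warning).
    """
    grids = spec.coordinate_grids()
    mr = spec.mr
    field_arr = np.full(spec.shape, mr.background_mean, dtype=np.float64)
    if mr.background_sd > 0:
        texture = _rng(spec.seed, 3).normal(0.0, 1.0, spec.shape)
        texture = ndimage.gaussian_filter(texture, [2.0 / s for s in spec.spacing])
        texture *= mr.background_sd / max(texture.std(), 1e-12)
        field_arr += texture
    dark = mr.calcium_fraction * mr.background_mean
    for dep in spec.deposits:
        if min(dep.semi_axes) <= mr.surface_layer_mm:
            warnings.warn(
                f"deposit at {dep.center}: surface layer {mr.surface_layer_mm} mm "
                "swallows the deposit; rendered empty",
                stacklevel=2,
            )
            continue
        field_arr[_ellipsoid_mask(dep, grids, shrink_mm=mr.surface_layer_mm)] = dark
    if mr.noise_sd > 0:
        field_arr = field_arr + _rng(spec.seed, 2).normal(0.0, mr.noise_sd, spec.shape)
    return ScalarVolume(field_arr, spec.spacing, spec.origin, MR)


# ---------------------------------------------------------------------------
# Paired ordinal reader scores
# ---------------------------------------------------------------------------

#: Marginal distribution of reader-1 scores on the 5-point Likert scale
#: (1 very poor ... 5 excellent).  Mass concentrated on 3-5 with mean 4.1,
#: the regime observed for confidence-to-detect scores of calcified segments.
DEFAULT_SCORE_DIST = (0.0, 0.0, 0.25, 0.40, 0.35)


def _adjacent(category: int, n_categories: int = 5) -> list[int]:
    out = []
    if category > 1:
        out.append(category - 1)
    if category < n_categories:
        out.append(category + 1)
    return out


def simulate_ratings(
    n: int,
    agreement: float,
    seed: int | None = None,
    dist: tuple[float, ...] = DEFAULT_SCORE_DIST,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired ordinal scores in 1..5 with a tunable agreement level.

    Reader 1 draws from ``dist``; reader 2 repeats reader 1's score with
    probability ``agreement`` and otherwise moves to a uniformly chosen
    adjacent category.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must lie in [0, 1]")
    dist = np.asarray(dist, dtype=float)
    dist = dist / dist.sum()
    rng = np.random.default_rng(seed)
    r1 = rng.choice(np.arange(1, len(dist) + 1), size=n, p=dist)
    r2 = r1.copy()
    move = rng.random(n) >= agreement
    for i in np.nonzero(move)[0]:
        r2[i] = rng.choice(_adjacent(int(r1[i]), len(dist)))
    return r1, r2


def _joint_pmf(agreement: float, dist: tuple[float, ...]) -> np.ndarray:
    """Exact joint score distribution implied by the rating generator."""
    dist = np.asarray(dist, dtype=float)
    dist = dist / dist.sum()
    k = len(dist)
    joint = np.zeros((k, k))
    for i in range(k):
        joint[i, i] += dist[i] * agreement
        adj = _adjacent(i + 1, k)
        for j in adj:
            joint[i, j - 1] += dist[i] * (1.0 - agreement) / len(adj)
    return joint


def expected_weighted_kappa(
    agreement: float, dist: tuple[float, ...] = DEFAULT_SCORE_DIST
) -> float:
    """Population linear-weighted kappa of the rating generator (closed form)."""
    joint = _joint_pmf(agreement, dist)
    k = joint.shape[0]
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = 1.0 - np.abs(i - j) / (k - 1)
    p_row = joint.sum(axis=1)
    p_col = joint.sum(axis=0)
    po = float((w * joint).sum())
    pe = float((w * np.outer(p_row, p_col)).sum())
    return (po - pe) / (1.0 - pe)


def agreement_for_kappa(
    kappa: float, dist: tuple[float, ...] = DEFAULT_SCORE_DIST
) -> float:
    """Agreement parameter whose population weighted kappa equals ``kappa``."""
    lo = expected_weighted_kappa(0.0, dist)
    if not lo <= kappa <= 1.0:
        raise ValueError(f"kappa {kappa} out of reachable range [{lo:.3f}, 1]")
    return float(
        optimize.brentq(lambda a: expected_weighted_kappa(a, dist) - kappa, 0.0, 1.0)
    )


# ---------------------------------------------------------------------------
# Exam / cohort generation
# ---------------------------------------------------------------------------


@dataclass
class Exam:
    """One synthetic paired exam: phantom spec, ROI definitions, ground truth."""

    exam_id: str
    region: str
    spec: PhantomSpec
    roi_defs: list[dict]
    truth: GroundTruth
    field_strength: str = "3T"


# geometry constants (mm) for the two anatomical layouts
_SEGMENT_LENGTH = 50.0
_ILIOFEMORAL_VESSEL_R = 3.5
_ROI_RADIUS = {"ilio_femoral": 5.0, "aorto_iliac_aorta": 6.5, "aorto_iliac": 4.5}

# severity stratum -> per-segment true-volume range (mm^3).  Lower bound of
# the mild stratum is kept at 60 mm^3 so that every generated segment stays
# comfortably inside the validity regime of the ROI-referenced mean-k*SD MR
# rule (calcium fraction of the 5-cm ROI below ~9%); upper bound 350 mm^3 for
# the same reason while still covering the severe (>=300 mm^3) stratum.
_SEVERITY_RANGES = {1: (60.0, 99.0), 2: (100.0, 299.0), 3: (300.0, 350.0)}
_SEVERITY_PROBS = (0.40, 0.35, 0.25)


def _make_deposits_for_segment(
    rng: np.random.Generator,
    segment: str,
    axis_xy: tuple[float, float],
    z_range: tuple[float, float],
    vessel_radius: float,
    severity: int,
) -> list[Ellipsoid]:
    lo, hi = _SEVERITY_RANGES[severity]
    target = rng.uniform(lo, hi)
    n_dep = int(rng.integers(1, 4))
    shares = rng.uniform(0.5, 1.0, n_dep)
    shares = shares / shares.sum()
    z0, z1 = min(z_range), max(z_range)
    usable = (z1 - z0) - 8.0
    slot = usable / n_dep
    deposits = []
    max_ar = min(2.8, vessel_radius - 0.3)
    for idx in range(n_dep):
        v = target * shares[idx]
        az = rng.uniform(2.5, max(2.6, min(8.0, slot / 2.0 - 0.5)))
        ar = np.sqrt(3.0 * v / (4.0 * np.pi * az))
        if ar > max_ar:
            ar = max_ar
            az = min(3.0 * v / (4.0 * np.pi * ar**2), slot / 2.0 - 0.5)
        if ar < 1.5:
            ar = 1.5
            az = max(1.5, 3.0 * v / (4.0 * np.pi * ar**2))
        slot_center = z0 + 4.0 + (idx + 0.5) * slot
        jitter = max(0.0, slot / 2.0 - az - 0.5)
        zc = slot_center + rng.uniform(-jitter, jitter)
        rho = rng.uniform(0.0, max(0.0, vessel_radius - ar))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        center = (
            axis_xy[0] + rho * np.cos(phi),
            axis_xy[1] + rho * np.sin(phi),
            zc,
        )
        deposits.append(Ellipsoid(center, (ar, ar, az), segment=segment))
    return deposits


def make_exam(
    region: str,
    seed: int,
    exam_id: str | None = None,
    spacing_mm: float = 0.5,
    ct: CTModel | None = None,
    mr: MRModel | None = None,
    field_strength: str = "3T",
) -> Exam:
    """Generate one paired exam of the given anatomical region.

    ``region`` is ``"ilio_femoral"`` (two limbs x proximal/distal 5-cm
    femoral segments) or ``"aorto_iliac"`` (distal aorta + four iliac
    segments, laid out as parallel tubes — the volumetry does not depend on
    branching geometry).  Identical arguments give identical exams.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    ct = ct or CTModel()
    mr = mr or MRModel()
    s = spacing_mm
    if region == "ilio_femoral":
        shape = (int(40 / s), int(24 / s), int(110 / s))
        vessels, roi_defs, deposits = [], [], []
        bif_z = 55.0
        for side, x in (("left", 12.0), ("right", 28.0)):
            vessels.append(
                Cylinder((x, 12.0, 3.0), (x, 12.0, 107.0), _ILIOFEMORAL_VESSEL_R)
            )
            for label, direction, z_range in (
                (f"common_femoral_proximal_{side}", (0, 0, 1.0), (bif_z, bif_z + 50)),
                (f"superficial_femoral_distal_{side}", (0, 0, -1.0), (bif_z - 50, bif_z)),
            ):
                roi_defs.append(
                    {
                        "label": label,
                        "region": region,
                        "landmark_mm": [x, 12.0, bif_z],
                        "direction": list(direction),
                        "length_mm": _SEGMENT_LENGTH,
                        "radius_mm": _ROI_RADIUS["ilio_femoral"],
                    }
                )
                severity = int(rng.choice([1, 2, 3], p=_SEVERITY_PROBS))
                deposits.extend(
                    _make_deposits_for_segment(
                        rng, label, (x, 12.0), z_range, _ILIOFEMORAL_VESSEL_R, severity
                    )
                )
    elif region == "aorto_iliac":
        shape = (int(50 / s), int(24 / s), int(60 / s))
        layout = [
            ("external_iliac_left", 5.0, 3.0),
            ("common_iliac_left", 15.0, 3.5),
            ("distal_aorta", 25.0, 5.0),
            ("common_iliac_right", 35.0, 3.5),
            ("external_iliac_right", 45.0, 3.0),
        ]
        vessels, roi_defs, deposits = [], [], []
        for label, x, radius in layout:
            vessels.append(Cylinder((x, 12.0, 3.0), (x, 12.0, 57.0), radius))
            roi_radius = (
                _ROI_RADIUS["aorto_iliac_aorta"]
                if label == "distal_aorta"
                else _ROI_RADIUS["aorto_iliac"]
            )
            roi_defs.append(
                {
                    "label": label,
                    "region": region,
                    "landmark_mm": [x, 12.0, 5.0],
                    "direction": [0, 0, 1.0],
                    "length_mm": _SEGMENT_LENGTH,
                    "radius_mm": roi_radius,
                }
            )
            severity = int(rng.choice([1, 2, 3], p=_SEVERITY_PROBS))
            deposits.extend(
                _make_deposits_for_segment(
                    rng, label, (x, 12.0), (5.0, 55.0), radius, severity
                )
            )
    else:
        raise ValueError(f"unknown region {region!r}")

    spec = PhantomSpec(
        shape=shape,
        spacing=(s, s, s),
        vessels=vessels,
        deposits=deposits,
        ct=ct,
        mr=mr,
        seed=seed,
    )
    return Exam(
        exam_id=exam_id or f"exam{seed:04d}",
        region=region,
        spec=spec,
        roi_defs=roi_defs,
        truth=voxelize_truth(spec),
        field_strength=field_strength,
    )


def make_cohort(
    n_exams: int,
    region: str = "ilio_femoral",
    seed: int = 0,
    ct: CTModel | None = None,
    mr: MRModel | None = None,
) -> list[Exam]:
    """Generate a cohort of paired exams.

    Field strength is assigned 1.5T / 3T in a fixed ~5:3 split, mirroring a
    two-site recruitment; all other conditions are identical across exams.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_exams) % (2**31 - 1)
    n_15 = round(n_exams * 5 / 8)
    exams = []
    for i in range(n_exams):
        fs = "1.5T" if i < n_15 else "3T"
        exams.append(
            make_exam(
                region,
                seed=int(seeds[i]),
                exam_id=f"{region[:2]}{i:03d}",
                ct=ct,
                mr=mr,
                field_strength=fs,
            )
        )
    return exams
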
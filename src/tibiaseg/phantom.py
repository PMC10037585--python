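"""Synthetic murine tibia MRI phantom cohorts.

Generates 3D grayscale volumes and ground-truth tibia masks that mimic the
qualitative appearance of high-resolution 3D-GRE mouse-leg MRI: a curved,
tapering tubular bone with a bulky condylar (knee) end, bright heterogeneous
marrow enclosed by a darker cortical rim, over a noisy background.  Cohorts
carry the longitudinal structure of the source study: repeated scans per
mouse, consecutive-day test-retest pairs, subject-level train/validation/test
splits, and per-mouse volume growth within the 6.5-9.9 mm^3 range.

The phantom is an emulation, not an MR simulation: there is no k-space model,
coil bias field, or partial-volume physics.  Its purpose is to give every
stage of the segmentation-and-repeatability pipeline a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import (
    REFERENCE_GEOMETRY,
    BinaryMask,
    ScanVolume,
    VolumeGeometry,
    mask_volume_mm3,
    write_mhd,
)

__all__ = [
    "PhantomSpec",
    "RetestPerturbation",
    "AnnotatorModel",
    "MousePlan",
    "CohortSpec",
    "generate_tibia_phantom",
    "generate_retest_pair",
    "simulate_annotator",
    "plan_cohort",
    "generate_cohort",
    "cohort_census",
]

MAX_14BIT = 2**14 - 1


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single tibia phantom.

    Lengths are in mm; intensities in arbitrary units on the 14-bit scale.
    ``target_volume_mm3`` rescales the radius profile so the analytic tube
    volume hits the requested tibia volume (the study range is 6.5-9.9 mm^3).
    """

    geometry: VolumeGeometry = REFERENCE_GEOMETRY
    shaft_length_mm: float = 17.0
    radius_proximal_mm: float = 0.52
    radius_distal_mm: float = 0.30
    curvature_mm: float = 0.8
    condyle_scale: float = 0.55
    condyle_width: float = 0.12  # fraction of shaft length
    target_volume_mm3: float | None = 8.0
    marrow_intensity: float = 9500.0
    marrow_heterogeneity: float = 0.15  # low-frequency multiplicative field SD
    cortical_rim_voxels: int = 2
    cortical_attenuation: float = 0.30
    background_intensity: float = 1800.0
    background_sd: float = 250.0
    noise_sigma: float = 450.0
    seed: int = 0
    #: rigid pose of the anatomy in the scanner frame (rotation about the
    #: coronal normal through the grid centre, translation in voxels); the
    #: rescan of a test-retest pair re-voxelises the same anatomy at a new
    #: pose, so both scans are equally sharp
    rotation_deg: float = 0.0
    translation_voxels: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: separate stream for scan noise so a rescan can share anatomy (seed)
    #: while drawing fresh noise; None -> derived from ``seed``
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.radius_proximal_mm <= 0 or self.radius_distal_mm <= 0:
            raise ValueError("radii must be positive")
        if self.cortical_rim_voxels < 1:
            raise ValueError("cortical rim thickness must be >= 1 voxel")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class RetestPerturbation:
    """Rigid repositioning between consecutive-day scans.

    Only pose and noise change; the anatomy (and hence the true tibia volume,
    up to nearest-neighbour resampling of the mask) is preserved.
    """

    max_rotation_deg: float = 2.0
    max_translation_voxels: float = 1.5
    independent_noise: bool = True


@dataclass(frozen=True)
class AnnotatorModel:
    """A simulated human annotator as a stochastic mask perturbation.

    ``volume_bias_fraction`` is the expected signed relative volume error of
    the annotation versus the true mask (+0.14 emulates the second expert's
    systematic over-segmentation); ``volume_bias_sd`` spreads the per-case
    bias; ``boundary_jitter_sigma`` (voxels) adds a smooth random displacement
    of the contour that degrades overlap without changing expected volume.
    """

    volume_bias_fraction: float = 0.0
    volume_bias_sd: float = 0.04
    boundary_jitter_sigma: float = 1.0
    seed: int = 0


# ----------------------------------------------------------------------------
# single-phantom generation
# ----------------------------------------------------------------------------


def _bezier(t: np.ndarray, p0: float, p1: float, p2: float, p3: float) -> np.ndarray:
    """Cubic Bezier scalar curve evaluated at t in [0, 1]."""
    u = 1.0 - t
    return u**3 * p0 + 3 * u**2 * t * p1 + 3 * u * t**2 * p2 + t**3 * p3


def _shaft_profile(spec: PhantomSpec, t: np.ndarray):
    """Centerline offsets (mm) and elliptical semi-axes (mm) along the shaft."""
    # Curved centerline: ends anchored on the volume axis, bowed sideways.
    cx = _bezier(t, 0.0, spec.curvature_mm, -0.35 * spec.curvature_mm, 0.0)
    cy = _bezier(t, 0.0, 0.5 * spec.curvature_mm, 0.25 * spec.curvature_mm, 0.0)
    base = spec.radius_proximal_mm + t * (
        spec.radius_distal_mm - spec.radius_proximal_mm
    )
    bulge = 1.0 + spec.condyle_scale * np.exp(-((t / spec.condyle_width) ** 2))
    r = base * bulge
    # hemispherically rounded ends (no flat caps)
    w = 0.04
    lo = t < w
    hi = t > 1.0 - w
    cap = np.ones_like(t)
    cap[lo] = np.sqrt(np.clip(1.0 - ((w - t[lo]) / w) ** 2, 0.0, 1.0))
    cap[hi] = np.sqrt(np.clip(1.0 - ((t[hi] - (1.0 - w)) / w) ** 2, 0.0, 1.0))
    r = r * cap
    # Mild in-plane anisotropy so the cross-section is elliptical.
    return cx, cy, 1.15 * r, r / 1.05


def _radius_scale_for_volume(spec: PhantomSpec) -> float:
    """Scale factor on radii so the analytic tube volume hits the target."""
    if spec.target_volume_mm3 is None:
        return 1.0
    t = np.linspace(0.0, 1.0, 512)
    _, _, a, b = _shaft_profile(spec, t)
    analytic = np.pi * np.trapezoid(a * b, t) * spec.shaft_length_mm
    if analytic <= 0:
        raise ValueError("degenerate radius profile")
    return float(np.sqrt(spec.target_volume_mm3 / analytic))


def _inside_tube(
    spec: PhantomSpec, scale: float, x_mm, y_mm, z_mm, broadcast: bool
) -> np.ndarray:
    """Membership test of physical points in the posed anatomy.

    ``broadcast=True`` treats (x_mm, y_mm, z_mm) as 1D per-axis coordinates
    of a grid; otherwise they are arbitrary same-shape arrays.
    """
    length = spec.shaft_length_mm
    identity_pose = spec.rotation_deg == 0.0 and not any(spec.translation_voxels)
    if broadcast and identity_pose:
        # fast path: cross-sections align with grid planes
        t = (z_mm + length / 2) / length
        inside_shaft = (t >= 0.0) & (t <= 1.0)
        cx, cy, a, b = _shaft_profile(spec, np.clip(t, 0.0, 1.0))
        a = np.maximum(a * scale, 1e-9)
        b = np.maximum(b * scale, 1e-9)
        dx = x_mm[:, None, None] - cx[None, None, :]
        dy = y_mm[None, :, None] - cy[None, None, :]
        mask = (dx / a[None, None, :]) ** 2 + (dy / b[None, None, :]) ** 2 <= 1.0
        mask &= inside_shaft[None, None, :]
        return mask

    if broadcast:
        qx = x_mm[:, None, None]
        qy = y_mm[None, :, None]
        qz = z_mm[None, None, :]
    else:
        qx, qy, qz = x_mm, y_mm, z_mm
    sx, sy, sz = spec.geometry.spacing
    th = np.deg2rad(spec.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    qx = qx - spec.translation_voxels[0] * sx
    qy = qy - spec.translation_voxels[1] * sy
    qz = qz - spec.translation_voxels[2] * sz
    # inverse rotation about axis 1 (mixes axes 0 and 2)
    px = c * qx + s * qz
    pz = -s * qx + c * qz
    py = qy + np.zeros_like(px)

    t = (pz + length / 2) / length
    inside_shaft = (t >= 0.0) & (t <= 1.0)
    cx, cy, a, b = _shaft_profile(spec, np.clip(t, 0.0, 1.0))
    a = np.maximum(a * scale, 1e-9)
    b = np.maximum(b * scale, 1e-9)
    mask = ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 <= 1.0
    mask &= inside_shaft
    return np.broadcast_to(mask, np.broadcast_shapes(px.shape, py.shape))


def _phantom_mask(spec: PhantomSpec) -> np.ndarray:
    """Anti-aliased voxelisation: a voxel is foreground when at least half of
    a 2x2x2 subsample of its volume lies inside the analytic anatomy.  The
    supersampling keeps the voxel count stable (well under 1%) against
    sub-voxel pose shifts, which the test-retest design relies on."""
    geom = spec.geometry
    nx, ny, nz = geom.dims
    sx, sy, sz = geom.spacing
    if spec.shaft_length_mm > nz * sz:
        raise ValueError(
            f"shaft of {spec.shaft_length_mm} mm does not fit in "
            f"{nz * sz:.1f} mm along the long axis"
        )
    scale = _radius_scale_for_volume(spec)
    # resolvability guard on the shaft proper (the rounded end caps taper to 0)
    _, _, a_chk, b_chk = _shaft_profile(spec, np.linspace(0.05, 0.95, 64))
    if min(a_chk.min() * scale / sx, b_chk.min() * scale / sy) < 1.2:
        raise ValueError("geometry too small: tube radius under 1.2 voxels")

    # centre-relative physical coordinates of the voxel grid (mm)
    x_mm = (np.arange(nx) - nx / 2) * sx
    y_mm = (np.arange(ny) - ny / 2) * sy
    z_mm = (np.arange(nz) - nz / 2) * sz

    # Odd per-axis subsample counts avoid structured half-coverage ties;
    # the y axis (the thinnest extent of the tube in voxels) gets the
    # densest sampling.
    off_x = (-0.4, -0.2, 0.0, 0.2, 0.4)
    off_y = (-0.4, -0.2, 0.0, 0.2, 0.4)
    off_z = (-1 / 3, 0.0, 1 / 3)
    n_votes = len(off_x) * len(off_y) * len(off_z)
    votes = np.zeros(geom.dims, dtype=np.uint8)
    for ox in off_x:
        for oy in off_y:
            for oz in off_z:
                votes += _inside_tube(
                    spec, scale,
                    x_mm + ox * sx, y_mm + oy * sy, z_mm + oz * sz,
                    broadcast=True,
                )
    return votes > n_votes // 2


def generate_tibia_phantom(spec: PhantomSpec) -> tuple[ScanVolume, BinaryMask]:
    """Generate one synthetic scan and its ground-truth tibia mask.

    The mask is a single connected curved tapered tube with a condylar bulge;
    the image shows bright, spatially heterogeneous marrow inside a darker
    cortical rim over Gaussian-noise background, clipped to the 14-bit range.
    Identical spec (including seed) gives bit-identical output.  The marrow
    heterogeneity field is drawn from the anatomy seed, while background
    texture and noise come from ``noise_seed`` (default: derived from the
    anatomy seed), so a rescan can share anatomy but draw a fresh scan.
    """
    anatomy_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    noise_entropy = spec.seed if spec.noise_seed is None else spec.noise_seed
    scan_rng = np.random.default_rng(np.random.SeedSequence([noise_entropy, 2]))
    mask = _phantom_mask(spec)

    interior = ndimage.binary_erosion(mask, iterations=spec.cortical_rim_voxels)
    rim = mask & ~interior

    img = np.full(spec.geometry.dims, float(spec.background_intensity))
    if spec.background_sd > 0:
        bg_field = ndimage.gaussian_filter(
            scan_rng.standard_normal(spec.geometry.dims), sigma=6.0
        )
        sd = bg_field.std()
        if sd > 0:
            img += spec.background_sd * bg_field / sd

    marrow = np.full(spec.geometry.dims, float(spec.marrow_intensity))
    if spec.marrow_heterogeneity > 0:
        het = ndimage.gaussian_filter(
            anatomy_rng.standard_normal(spec.geometry.dims), sigma=8.0
        )
        sd = het.std()
        if sd > 0:
            marrow *= 1.0 + spec.marrow_heterogeneity * het / sd
    img[interior] = marrow[interior]
    img[rim] = spec.cortical_attenuation * marrow[rim]

    if spec.noise_sigma > 0:
        img += spec.noise_sigma * scan_rng.standard_normal(spec.geometry.dims)

    img = np.clip(np.rint(img), 0, MAX_14BIT).astype(np.uint16)
    return (
        ScanVolume(geometry=spec.geometry, intensities=img),
        BinaryMask(geometry=spec.geometry, labels=mask.astype(np.uint8)),
    )


# ----------------------------------------------------------------------------
# test-retest pairs
# ----------------------------------------------------------------------------


def generate_retest_pair(
    spec: PhantomSpec, perturbation: RetestPerturbation = RetestPerturbation()
) -> tuple[tuple[ScanVolume, BinaryMask], tuple[ScanVolume, BinaryMask]]:
    """Generate a consecutive-day scan pair: same anatomy, new pose and noise.

    The rescan re-voxelises the same analytic anatomy at a rigidly perturbed
    pose and draws fresh noise, so both scans are equally sharp — as two real
    acquisitions would be — and the ground-truth volume is preserved up to
    voxelisation error.  A volume change above 2% raises, since it would
    break the repeatability design's constant-anatomy assumption.
    """
    test_vol, test_mask = generate_tibia_phantom(spec)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7E57]))
    noise_seed = (
        int(np.random.default_rng(
            np.random.SeedSequence([spec.seed, 0x4E01])
        ).integers(0, 2**31 - 1))
        if perturbation.independent_noise
        else (spec.seed if spec.noise_seed is None else spec.noise_seed)
    )
    v1 = float(test_mask.labels.sum())
    # rejection-sample the pose: voxelisation of the thin tube can alias the
    # count by a couple of percent for unlucky sub-voxel phases, and the
    # repeatability design requires the true volume stable to within 2%
    for _ in range(20):
        angle = rng.uniform(
            -perturbation.max_rotation_deg, perturbation.max_rotation_deg
        )
        shift = rng.uniform(
            -perturbation.max_translation_voxels,
            perturbation.max_translation_voxels,
            size=3,
        )
        if angle == 0.0 and not np.any(shift) and not perturbation.independent_noise:
            return (test_vol, test_mask), (test_vol, test_mask)

        retest_spec = replace(
            spec,
            rotation_deg=spec.rotation_deg + float(angle),
            translation_voxels=tuple(
                float(t0 + dt) for t0, dt in zip(spec.translation_voxels, shift)
            ),
            noise_seed=noise_seed,
        )
        retest_vol, retest_mask = generate_tibia_phantom(retest_spec)
        v2 = float(retest_mask.labels.sum())
        if abs(v2 - v1) / v1 <= 0.02:
            return (test_vol, test_mask), (retest_vol, retest_mask)
    raise ValueError(
        "retest pose repeatedly changed the ground-truth volume by more than "
        "2% (perturbation too large for this geometry?)"
    )


# ----------------------------------------------------------------------------
# simulated annotators
# ----------------------------------------------------------------------------


def simulate_annotator(mask: BinaryMask, model: AnnotatorModel) -> BinaryMask:
    """Perturb a ground-truth mask the way an imperfect human contour would.

    Moves the contour along the signed distance field: a smooth random field
    jitters the boundary, and the level-set threshold is picked so the
    resulting volume matches the (per-case randomised) target bias.
    """
    rng = np.random.default_rng(model.seed)
    labels = mask.labels.astype(bool)
    if (
        model.volume_bias_fraction == 0.0
        and model.volume_bias_sd == 0.0
        and model.boundary_jitter_sigma == 0.0
    ):
        return BinaryMask(geometry=mask.geometry, labels=mask.labels.copy())
    if not labels.any():
        return BinaryMask(geometry=mask.geometry, labels=mask.labels.copy())

    spacing = mask.geometry.spacing
    sdf = ndimage.distance_transform_edt(~labels, sampling=spacing) - (
        ndimage.distance_transform_edt(labels, sampling=spacing)
    )

    if model.boundary_jitter_sigma > 0:
        fld = ndimage.gaussian_filter(
            rng.standard_normal(mask.geometry.dims), sigma=5.0
        )
        sd = fld.std()
        if sd > 0:
            jitter_mm = model.boundary_jitter_sigma * float(np.mean(spacing))
            sdf = sdf + jitter_mm * fld / sd

    bias = model.volume_bias_fraction
    if model.volume_bias_sd > 0:
        bias += rng.normal(0.0, model.volume_bias_sd)
    target = int(np.rint(labels.sum() * (1.0 + bias)))
    target = int(np.clip(target, 1, labels.size - 1))

    flat = sdf.ravel()
    thresh = np.partition(flat, target - 1)[target - 1]
    out = (sdf <= thresh).astype(np.uint8)
    return BinaryMask(geometry=mask.geometry, labels=out)


# ----------------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class MousePlan:
    """Schedule for one animal: primary timepoints and which get a rescan."""

    mouse_id: str
    group: str  # "diseased" | "control"
    split: str  # "train" | "val" | "test"
    timepoints_days: tuple[int, ...]
    paired_timepoints: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.group not in ("diseased", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.split not in ("train", "val", "test"):
            raise ValueError(f"unknown split {self.split!r}")
        extra = set(self.paired_timepoints) - set(self.timepoints_days)
        if extra:
            raise ValueError(
                f"paired timepoints {sorted(extra)} are not scheduled scan days"
            )

    @property
    def n_scans(self) -> int:
        return len(self.timepoints_days) + len(self.paired_timepoints)

    @property
    def n_pairs(self) -> int:
        return len(self.paired_timepoints)


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic cohort: per-mouse schedules plus image parameters.

    The default (:meth:`paper_default`) reproduces the source study's census:
    32 mice (26 diseased, 6 control), 157 scans, 49 consecutive-day pairs,
    train/val/test of 107/17/33 scans with 32/4/13 pairs, controls only in
    train and validation.  Tibia volumes start in the mid-range and grow
    linearly per week, capped to the observed 6.5-9.9 mm^3 envelope.
    """

    mice: tuple[MousePlan, ...]
    geometry: VolumeGeometry = REFERENCE_GEOMETRY
    phantom_template: PhantomSpec = PhantomSpec()
    perturbation: RetestPerturbation = RetestPerturbation()
    start_volume_range: tuple[float, float] = (6.5, 7.5)
    growth_per_week_range: tuple[float, float] = (0.25, 0.55)
    volume_cap_mm3: float = 9.9
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [m.mouse_id for m in self.mice]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mouse ids in cohort")

    # -- canonical cohorts ---------------------------------------------------

    @classmethod
    def paper_default(cls, seed: int = 0) -> "CohortSpec":
        """The full-census cohort matching the published study counts."""
        biweekly = tuple(range(0, 85, 14))  # days 0..84

        def tp(n: int) -> tuple[int, ...]:
            return biweekly[:n]

        mice: list[MousePlan] = []

        def add(group, split, n_tp, pairs):
            i = len(mice) + 1
            mice.append(
                MousePlan(
                    mouse_id=f"m{i:02d}",
                    group=group,
                    split=split,
                    timepoints_days=tp(n_tp),
                    paired_timepoints=tp(n_tp)[:pairs],
                )
            )

        # Training, diseased: 18 mice, 86 scans, 27 pairs.  One long-series
        # mouse (6 biweekly timepoints, 4 rescans) is the single-mouse (TSM)
        # candidate; 6 mice carry 2 pairs; the rest carry 1.
        add("diseased", "train", 6, 4)
        for _ in range(6):
            add("diseased", "train", 4, 2)
        for _ in range(7):
            add("diseased", "train", 3, 1)
        for _ in range(4):
            add("diseased", "train", 2, 1)
        # Training, controls: 5 mice, 21 scans, 5 pairs.
        add("control", "train", 4, 1)
        for _ in range(4):
            add("control", "train", 3, 1)
        # Validation: 2 diseased + 1 control, 17 scans, 4 pairs.
        add("diseased", "val", 4, 2)
        add("diseased", "val", 4, 1)
        add("control", "val", 5, 1)
        # Test: 6 diseased mice, 33 scans, 13 pairs.
        add("diseased", "test", 4, 3)
        add("diseased", "test", 4, 3)
        add("diseased", "test", 3, 2)
        add("diseased", "test", 3, 2)
        add("diseased", "test", 3, 2)
        add("diseased", "test", 3, 1)
        return cls(mice=tuple(mice), seed=seed)

    @classmethod
    def tiny(cls, seed: int = 0) -> "CohortSpec":
        """A scaled-down cohort (6 mice x 4 scans = 24 scans, 12 pairs) on a
        64 x 32 x 128 grid, sized for CPU-scale end-to-end runs.

        The spacing is chosen so the tibia still spans ~8 voxels across:
        much coarser and the voxelised volume of a rigidly repositioned
        phantom aliases by more than the 2% the test-retest design allows.
        """
        geom = VolumeGeometry(dims=(64, 32, 128), spacing=(0.12, 0.10, 0.15))
        mice = []
        splits = ["train"] * 4 + ["val", "test"]
        for i, split in enumerate(splits):
            mice.append(
                MousePlan(
                    mouse_id=f"m{i + 1:02d}",
                    group="diseased",
                    split=split,
                    timepoints_days=(0, 14),
                    paired_timepoints=(0, 14),
                )
            )
        # Preserve physical scales on the coarser grid: the ~0.15 mm cortical
        # rim is one voxel here, and the repositioning magnitude matches the
        # full-resolution default in mm rather than in voxels.
        template = PhantomSpec(geometry=geom, cortical_rim_voxels=1)
        pert = RetestPerturbation(max_rotation_deg=2.0, max_translation_voxels=0.75)
        return cls(
            mice=tuple(mice),
            geometry=geom,
            phantom_template=template,
            perturbation=pert,
            seed=seed,
        )

    # -- growth model --------------------------------------------------------

    def volume_at(self, mouse_index: int, day: int) -> float:
        """Scheduled true tibia volume (mm^3) for a mouse at a given day."""
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 0x600, mouse_index])
        )
        start = rng.uniform(*self.start_volume_range)
        growth = rng.uniform(*self.growth_per_week_range)
        plan = self.mice[mouse_index]
        if plan.group == "control":
            growth *= 0.3  # controls grow slowly (normal maturation only)
        return float(min(start + growth * day / 7.0, self.volume_cap_mm3))


def _scan_rows(spec: CohortSpec):
    """Yield per-scan manifest rows (without file paths)."""
    for mi, plan in enumerate(spec.mice):
        for ti, day in enumerate(plan.timepoints_days):
            paired = day in plan.paired_timepoints
            pair_id = f"{plan.mouse_id}_d{day:03d}" if paired else ""
            roles = ["test", "retest"] if paired else ["unpaired"]
            for role in roles:
                suffix = "r" if role == "retest" else ""
                yield {
                    "scan_id": f"{plan.mouse_id}_d{day:03d}{suffix}",
                    "mouse_id": plan.mouse_id,
                    "group": plan.group,
                    "timepoint_days": day,
                    "split": plan.split,
                    "pair_id": pair_id,
                    "role": role,
                    "_mouse_index": mi,
                    "_tp_index": ti,
                }


def plan_cohort(spec: CohortSpec) -> pd.DataFrame:
    """The cohort manifest as a table, without generating any image files."""
    df = pd.DataFrame(list(_scan_rows(spec)))
    return df.drop(columns=["_mouse_index", "_tp_index"])


def cohort_census(manifest: pd.DataFrame) -> dict:
    """Scan/pair/mouse counts overall and per split."""
    out = {
        "n_mice": manifest["mouse_id"].nunique(),
        "n_scans": len(manifest),
        "n_pairs": manifest.loc[manifest["role"] == "test", "pair_id"].nunique(),
    }
    for split in ("train", "val", "test"):
        sub = manifest[manifest["split"] == split]
        out[f"{split}_scans"] = len(sub)
        out[f"{split}_pairs"] = sub.loc[sub["role"] == "test", "pair_id"].nunique()
        out[f"{split}_mice"] = sub["mouse_id"].nunique()
    return out


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    annotator: AnnotatorModel | None = None,
    annotator_splits: tuple[str, ...] = ("val", "test"),
) -> pd.DataFrame:
    """Generate the full cohort on disk and return its manifest.

    Writes one MHD image + ground-truth mask per scan under ``out_dir`` and a
    ``manifest.csv``.  If an :class:`AnnotatorModel` is given, a second,
    simulated-annotator mask is written for scans in ``annotator_splits``
    (mirroring the study, where the second expert contoured only validation
    and test).  Fully deterministic given ``spec.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for row in _scan_rows(spec):
        mi, ti = row.pop("_mouse_index"), row.pop("_tp_index")
        vol_mm3 = spec.volume_at(mi, row["timepoint_days"])
        plan = spec.mice[mi]
        het = spec.phantom_template.marrow_heterogeneity
        if plan.group == "diseased":  # disease progression: growing heterogeneity
            het = het * (1.0 + 0.08 * ti)
        scan_seed = int(
            np.random.default_rng(
                np.random.SeedSequence([spec.seed, 0x5CA9, mi, ti])
            ).integers(0, 2**31 - 1)
        )
        pspec = replace(
            spec.phantom_template,
            geometry=spec.geometry,
            target_volume_mm3=vol_mm3,
            marrow_heterogeneity=het,
            seed=scan_seed,
        )
        if row["role"] == "unpaired":
            outputs = {"unpaired": generate_tibia_phantom(pspec)}
        elif row["role"] == "test":
            pair = generate_retest_pair(pspec, spec.perturbation)
            outputs = {"test": pair[0], "retest": pair[1]}
        else:
            continue  # retest rows are written together with their test row

        for role, (vol, mask) in outputs.items():
            suffix = "r" if role == "retest" else ""
            scan_id = f"{plan.mouse_id}_d{row['timepoint_days']:03d}{suffix}"
            img_path = out_dir / f"{scan_id}.mhd"
            mask_path = out_dir / f"{scan_id}_mask.mhd"
            write_mhd(vol, img_path)
            write_mhd(mask, mask_path)
            out_row = dict(row)
            out_row["scan_id"] = scan_id
            out_row["role"] = role if row["pair_id"] else "unpaired"
            out_row["image_path"] = str(img_path)
            out_row["mask_path_EA1"] = str(mask_path)
            out_row["mask_path_EA2"] = ""
            if annotator is not None and plan.split in annotator_splits:
                ea2_seed = int(
                    np.random.default_rng(
                        np.random.SeedSequence(
                            [spec.seed, 0xEA2, annotator.seed, mi, ti,
                             1 if role == "retest" else 0]
                        )
                    ).integers(0, 2**31 - 1)
                )
                ea2 = simulate_annotator(mask, replace(annotator, seed=ea2_seed))
                ea2_path = out_dir / f"{scan_id}_mask_ea2.mhd"
                write_mhd(ea2, ea2_path)
                out_row["mask_path_EA2"] = str(ea2_path)
            rows.append(out_row)

    manifest = pd.DataFrame(rows)
    order = [r["scan_id"] for r in _scan_rows(spec)]
    manifest = (
        manifest.set_index("scan_id").loc[order].reset_index()
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
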
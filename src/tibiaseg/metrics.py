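"""Volumetric segmentation accuracy metrics and set-level summaries.

Conventions (S = evaluated segmentation, R = reference mask):

* Jaccard index      JI = 100 * |S ∩ R| / |S ∪ R|            (%)
* Volume intersection VI = 100 * |S ∩ R| / |S|               (%)
* Volume error       VE = 100 * (|S| - |R|) / |R|            (%, signed;
  positive means over-segmentation relative to the reference)
* Hausdorff distance HD = max of the two directed greatest
  nearest-neighbour distances between set-voxel point clouds, in mm.

With v = |S|/|R| = 1 + VE/100 and i = |S ∩ R|/|R| = (VI/100) * v, the three
overlap metrics are algebraically locked together:

    JI = 100 * i / (1 + v - i)

``implied_ji`` evaluates that identity; it holds exactly for every mask pair
and doubles as a consistency check on (VI, VE, JI) triples reported together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .volume_io import BinaryMask

__all__ = [
    "CaseMetrics",
    "SetSummary",
    "jaccard",
    "volume_intersection_ratio",
    "volume_error",
    "hausdorff_mm",
    "case_metrics",
    "summarize",
    "compare_scenarios",
    "implied_ji",
]


@dataclass(frozen=True)
class CaseMetrics:
    """Per-case accuracy of one segmentation against a reference."""

    ji: float  # %
    vi: float  # %
    ve: float  # %, signed
    hd: float  # mm


@dataclass(frozen=True)
class SetSummary:
    """Mean +/- sample SD of each metric over a set of cases."""

    aji: float
    aji_sd: float
    avi: float
    avi_sd: float
    ave: float
    ave_sd: float
    ahd: float
    ahd_sd: float
    n_cases: int
    sd_defined: bool  # False for a single case (SD reported as 0)


def _check_pair(seg: BinaryMask, ref: BinaryMask) -> None:
    if seg.geometry.dims != ref.geometry.dims or not np.allclose(
        seg.geometry.spacing, ref.geometry.spacing
    ):
        raise ValueError(
            f"geometry mismatch: seg {seg.geometry.dims}@{seg.geometry.spacing} "
            f"vs ref {ref.geometry.dims}@{ref.geometry.spacing}"
        )


def jaccard(seg: BinaryMask, ref: BinaryMask) -> float:
    """Jaccard (intersection-over-union) index in percent."""
    _check_pair(seg, ref)
    if ref.voxel_count == 0:
        raise ValueError("reference mask is empty")
    s = seg.labels.astype(bool)
    r = ref.labels.astype(bool)
    union = np.logical_or(s, r).sum()
    return 100.0 * float(np.logical_and(s, r).sum()) / float(union)


def volume_intersection_ratio(seg: BinaryMask, ref: BinaryMask) -> float:
    """Overlap volume as a percentage of the evaluated segmentation's volume."""
    _check_pair(seg, ref)
    if seg.voxel_count == 0:
        raise ValueError("segmentation mask is empty")
    s = seg.labels.astype(bool)
    r = ref.labels.astype(bool)
    return 100.0 * float(np.logical_and(s, r).sum()) / float(s.sum())


def volume_error(seg: BinaryMask, ref: BinaryMask) -> float:
    """Signed relative volume difference in percent (positive = larger than
    the reference, i.e. over-segmentation)."""
    _check_pair(seg, ref)
    if ref.voxel_count == 0:
        raise ValueError("reference mask is empty")
    return 100.0 * (seg.voxel_count - ref.voxel_count) / ref.voxel_count


def hausdorff_mm(seg: BinaryMask, ref: BinaryMask) -> float:
    """Symmetric Hausdorff distance between set-voxel point clouds, in mm.

    Computed from exact Euclidean distance transforms with the voxel spacing
    as physical sampling, so anisotropic grids are handled correctly.
    """
    _check_pair(seg, ref)
    if seg.voxel_count == 0 or ref.voxel_count == 0:
        raise ValueError("Hausdorff distance requires two nonempty masks")
    s = seg.labels.astype(bool)
    r = ref.labels.astype(bool)
    spacing = seg.geometry.spacing
    d_to_r = ndimage.distance_transform_edt(~r, sampling=spacing)
    d_to_s = ndimage.distance_transform_edt(~s, sampling=spacing)
    return float(max(d_to_r[s].max(), d_to_s[r].max()))


def case_metrics(seg: BinaryMask, ref: BinaryMask) -> CaseMetrics:
    """All four per-case metrics for one (segmentation, reference) pair."""
    return CaseMetrics(
        ji=jaccard(seg, ref),
        vi=volume_intersection_ratio(seg, ref),
        ve=volume_error(seg, ref),
        hd=hausdorff_mm(seg, ref),
    )


def summarize(cases: list[CaseMetrics]) -> SetSummary:
    """Arithmetic mean and sample (n-1) SD per metric over the case set."""
    if not cases:
        raise ValueError("cannot summarise an empty case list")
    arr = np.array([[c.ji, c.vi, c.ve, c.hd] for c in cases], dtype=float)
    means = arr.mean(axis=0)
    if len(cases) > 1:
        sds = arr.std(axis=0, ddof=1)
        sd_defined = True
    else:
        sds = np.zeros(4)
        sd_defined = False
    return SetSummary(
        aji=means[0], aji_sd=sds[0],
        avi=means[1], avi_sd=sds[1],
        ave=means[2], ave_sd=sds[2],
        ahd=means[3], ahd_sd=sds[3],
        n_cases=len(cases),
        sd_defined=sd_defined,
    )


def compare_scenarios(
    a, b, alpha_corrected: float = 0.009
) -> tuple[float, float, bool]:
    """Two-tailed paired t-test between case-matched metric lists.

    Returns (t statistic, p-value, significant at the Bonferroni-corrected
    threshold).  Identical lists or zero-variance differences are degenerate:
    reported as (0.0 or nan, p = 1.0 or nan, not significant).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired lists differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 cases")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0, False  # identical samples
        return float("nan"), float("nan"), False  # constant nonzero difference
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), bool(p < alpha_corrected)


def implied_ji(vi: float, ve: float) -> float:
    """Jaccard index implied by a (VI, VE) pair via the overlap identity."""
    if not (0.0 < vi <= 100.0):
        raise ValueError(f"VI must be in (0, 100], got {vi}")
    if ve <= -100.0:
        raise ValueError(f"VE must be > -100, got {ve}")
    v = 1.0 + ve / 100.0
    i = (vi / 100.0) * v
    return 100.0 * i / (1.0 + v - i)
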
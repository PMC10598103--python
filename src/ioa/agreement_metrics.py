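"""Pairwise agreement metrics for binary masks.

Four complementary metrics characterize one observer pair:

* ``dice`` — overlap: 2*tp / (2*tp + fp + fn), range [0, 1], higher = better.
* ``hausdorff_mm`` — symmetric Hausdorff distance between the voxel point
  sets in physical mm (spacing-aware), range [0, inf), lower = better.
* ``probabilistic_distance`` — (fp + fn) / (2*tp), range [0, inf], lower =
  better; strongly penalizes misalignment of correctly sized volumes.
* ``volumetric_similarity`` — 1 - |fp - fn| / (2*tp + fp + fn), range [0, 1];
  compares sizes only, ignores overlap.

``jaccard`` is provided as well (jci = dsc / (2 - dsc)).

True negatives never enter any formula, so all metrics are invariant under
padding both masks with background. Algebraic identities maintained by these
definitions: ``pbd == (1 - dsc) / dsc`` whenever tp > 0, and ``vs >= dsc``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial.distance import cdist

from .volume_model import BinaryMask, OverlapCounts, overlap_counts

__all__ = [
    "UndefinedMetricError",
    "MetricQuartet",
    "dice",
    "jaccard",
    "hausdorff_mm",
    "hausdorff_bruteforce_mm",
    "probabilistic_distance",
    "volumetric_similarity",
    "metric_quartet",
    "dice_from_counts",
    "jaccard_from_counts",
    "pbd_from_counts",
    "vs_from_counts",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is evaluated outside its domain (empty masks)."""


@dataclass(frozen=True)
class MetricQuartet:
    """One observer pair's combined metric record.

    ``undefined`` lists the names of any member metrics that were not
    defined for the pair (e.g. ``hd_mm`` when one mask is empty); undefined
    distance values are stored as NaN.
    """

    dsc: float
    hd_mm: float
    pbd: float
    vs: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"dsc": self.dsc, "hd_mm": self.hd_mm, "pbd": self.pbd, "vs": self.vs}


def _require_not_both_empty(a: BinaryMask, b: BinaryMask, metric: str) -> None:
    if a.is_empty and b.is_empty:
        raise UndefinedMetricError(f"{metric} is undefined for two empty masks")


def dice_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise UndefinedMetricError("dice is undefined for two empty masks")
    return 2.0 * tp / denom


def jaccard_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = tp + fp + fn
    if denom == 0:
        raise UndefinedMetricError("jaccard is undefined for two empty masks")
    return tp / denom


def pbd_from_counts(tp: int, fp: int, fn: int) -> float:
    if tp == 0:
        if fp + fn == 0:
            raise UndefinedMetricError(
                "probabilistic distance is undefined for two empty masks"
            )
        return math.inf
    return (fp + fn) / (2.0 * tp)


def vs_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise UndefinedMetricError(
            "volumetric similarity is undefined for two empty masks"
        )
    return 1.0 - abs(fp - fn) / denom


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice-Sorensen coefficient of two masks on a shared grid."""
    _require_not_both_empty(a, b, "dice")
    c = overlap_counts(a, b)
    return dice_from_counts(c.tp, c.fp, c.fn)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index; satisfies jci == dsc / (2 - dsc)."""
    _require_not_both_empty(a, b, "jaccard")
    c = overlap_counts(a, b)
    return jaccard_from_counts(c.tp, c.fp, c.fn)


def probabilistic_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Probabilistic distance (fp + fn) / (2*tp); +inf when the masks are
    non-empty but disjoint."""
    _require_not_both_empty(a, b, "probabilistic distance")
    c = overlap_counts(a, b)
    return pbd_from_counts(c.tp, c.fp, c.fn)


def volumetric_similarity(a: BinaryMask, b: BinaryMask) -> float:
    """Volumetric similarity 1 - ||A| - |B|| / (|A| + |B|)."""
    _require_not_both_empty(a, b, "volumetric similarity")
    c = overlap_counts(a, b)
    return vs_from_counts(c.tp, c.fp, c.fn)


def _union_bbox(a: np.ndarray, b: np.ndarray) -> tuple[slice, ...]:
    idx = np.argwhere(a | b)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))

def hausdorff_mm(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric Hausdorff distance between voxel point sets, in mm.

    Directed distances are computed with anisotropic Euclidean distance
    transforms (``sampling=spacing_mm``), restricted to the union bounding
    box (which cannot change nearest-voxel distances). Equals
    :func:`hausdorff_bruteforce_mm` up to floating-point noise.
    """
    if a.is_empty or b.is_empty:
        raise UndefinedMetricError("Hausdorff distance requires two non-empty masks")
    problem = a.grid.mismatch(b.grid)
    if problem is not None:
        from .volume_model import GridMismatchError

        raise GridMismatchError(f"masks are on different grids: {problem}")
    box = _union_bbox(a.voxels, b.voxels)
    av = a.voxels[box]
    bv = b.voxels[box]
    if np.array_equal(av, bv):
        return 0.0
    spacing = a.grid.spacing_mm
    dist_to_b = distance_transform_edt(~bv, sampling=spacing)
    dist_to_a = distance_transform_edt(~av, sampling=spacing)
    h_ab = float(dist_to_b[av].max())
    h_ba = float(dist_to_a[bv].max())
    return max(h_ab, h_ba)


def hausdorff_bruteforce_mm(a: BinaryMask, b: BinaryMask) -> float:
    """Verification oracle: direct O(|A|*|B|) max-min distance in mm.

    Intended for small masks (<= ~2000 voxels per side).
    """
    if a.is_empty or b.is_empty:
        raise UndefinedMetricError("Hausdorff distance requires two non-empty masks")
    problem = a.grid.mismatch(b.grid)
    if problem is not None:
        from .volume_model import GridMismatchError

        raise GridMismatchError(f"masks are on different grids: {problem}")
    pa = a.set_coords_mm()
    pb = b.set_coords_mm()
    d = cdist(pa, pb)
    h_ab = d.min(axis=1).max()
    h_ba = d.min(axis=0).max()
    return float(max(h_ab, h_ba))


def metric_quartet(a: BinaryMask, b: BinaryMask) -> MetricQuartet:
    """The four-metric record for one mask pair, from one shared count pass.

    Both masks empty is an error. With exactly one empty mask, DSC and VS
    are 0 and PBD is +inf by their formulas, while HD is undefined and
    reported as NaN with ``undefined=('hd_mm',)``.
    """
    _require_not_both_empty(a, b, "metric quartet")
    c: OverlapCounts = overlap_counts(a, b)
    dsc = dice_from_counts(c.tp, c.fp, c.fn)
    pbd = pbd_from_counts(c.tp, c.fp, c.fn)
    vs = vs_from_counts(c.tp, c.fp, c.fn)
    if a.is_empty or b.is_empty:
        return MetricQuartet(dsc, math.nan, pbd, vs, undefined=("hd_mm",))
    hd = hausdorff_mm(a, b)
    return MetricQuartet(dsc, hd, pbd, vs)
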
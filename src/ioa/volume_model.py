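"""Core geometric data model: voxel grids, binary masks, overlap counting.

All volumetric structures live on an :class:`ImageGrid` — a regular voxel
lattice with a fixed axis order of (slice, row, column), per-axis spacing in
millimetres, and a physical origin placed at the *center* of voxel (0, 0, 0).
Agreement metrics operate on pairs of :class:`BinaryMask` objects that share
an identical grid; harmonizing differing grids is an explicit, user-invoked
step (:func:`resample_nearest`), never a silent one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical ordering of the three target-volume kinds.
VOLUME_KINDS = ("GTV", "ITV", "PTV")

#: Tolerances for treating two grids as geometrically identical.
SPACING_TOL_MM = 1e-6
ORIGIN_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Raised when an operation requires identical grids but got different ones."""


@dataclass(frozen=True)
class ImageGrid:
    """Regular voxel lattice geometry.

    Parameters
    ----------
    shape
        Number of voxels along (slice, row, column). All components >= 1.
    spacing_mm
        Voxel spacing in mm along the same axes. All components > 0.
    origin_mm
        Physical position (mm) of the center of voxel index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("ImageGrid is strictly three-dimensional")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def center_mm(self) -> tuple[float, float, float]:
        """Physical position of the geometric center of the lattice."""
        return tuple(
            o + (n - 1) / 2.0 * s
            for o, n, s in zip(self.origin_mm, self.shape, self.spacing_mm)
        )

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def mm_to_index(self, pos_mm: np.ndarray) -> np.ndarray:
        """Map physical mm coordinates to continuous voxel indices."""
        pos_mm = np.asarray(pos_mm, dtype=float)
        return (pos_mm - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def approx_equal(
        self,
        other: "ImageGrid",
        spacing_tol: float = SPACING_TOL_MM,
        origin_tol: float = ORIGIN_TOL_MM,
    ) -> bool:
        return self.mismatch(other, spacing_tol, origin_tol) is None

    def mismatch(
        self,
        other: "ImageGrid",
        spacing_tol: float = SPACING_TOL_MM,
        origin_tol: float = ORIGIN_TOL_MM,
    ) -> str | None:
        """Name of the first differing geometry component, or None if equal."""
        if self.shape != other.shape:
            return f"shape {self.shape} != {other.shape}"
        if any(
            abs(a - b) > spacing_tol for a, b in zip(self.spacing_mm, other.spacing_mm)
        ):
            return f"spacing_mm {self.spacing_mm} != {other.spacing_mm}"
        if any(
            abs(a - b) > origin_tol for a, b in zip(self.origin_mm, other.origin_mm)
        ):
            return f"origin_mm {self.origin_mm} != {other.origin_mm}"
        return None


@dataclass
class BinaryMask:
    """A delineated volume: boolean membership for every voxel of a grid."""

    grid: ImageGrid
    voxels: np.ndarray
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        if voxels.shape != self.grid.shape:
            raise ValueError(
                f"voxel array shape {voxels.shape} does not match grid {self.grid.shape}"
            )
        self.voxels = voxels.astype(bool, copy=False)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def volume_ml(self) -> float:
        return mask_volume_ml(self)

    def set_indices(self) -> np.ndarray:
        """Integer indices of set voxels, shape (n, 3)."""
        return np.argwhere(self.voxels)

    def set_coords_mm(self) -> np.ndarray:
        """Physical mm coordinates of the centers of set voxels, shape (n, 3)."""
        return self.grid.index_to_mm(self.set_indices())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.voxels.copy(), dict(self.meta))


@dataclass(frozen=True)
class OverlapCounts:
    """Voxel confusion counts between two masks A (first) and B (second).

    Downstream metrics use only ``tp``, ``fp`` and ``fn``: true negatives
    (background agreed by both observers) never enter any metric, so padding
    a mask pair with background changes nothing but ``tn``.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "OverlapCounts":
        """Counts for the pair with arguments exchanged (fp and fn swap)."""
        return OverlapCounts(self.tp, self.fn, self.fp, self.tn)


@dataclass(frozen=True)
class DelineationRecord:
    """One observer's delineation of one volume kind for one case."""

    case_id: str
    observer_id: str
    volume_kind: str
    mask: BinaryMask

    def __post_init__(self) -> None:
        if self.volume_kind not in VOLUME_KINDS:
            raise ValueError(
                f"volume_kind must be one of {VOLUME_KINDS}, got {self.volume_kind!r}"
            )


class CohortStructureSet:
    """Collection of delineation records across cases, observers and kinds.

    At most one record may exist per (case_id, observer_id, volume_kind).
    """

    def __init__(self, records: Iterable[DelineationRecord] = ()) -> None:
        self._records: list[DelineationRecord] = []
        self._keys: set[tuple[str, str, str]] = set()
        for rec in records:
            self.add(rec)

    def add(self, record: DelineationRecord) -> None:
        key = (record.case_id, record.observer_id, record.volume_kind)
        if key in self._keys:
            raise ValueError(f"duplicate record for case/observer/kind {key}")
        self._keys.add(key)
        self._records.append(record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[DelineationRecord]:
        return iter(self._records)

    @property
    def records(self) -> list[DelineationRecord]:
        return list(self._records)

    def case_ids(self) -> list[str]:
        return sorted({r.case_id for r in self._records})

    def volume_kinds(self) -> list[str]:
        present = {r.volume_kind for r in self._records}
        return [k for k in VOLUME_KINDS if k in present]

    def group(self, case_id: str, volume_kind: str) -> list[DelineationRecord]:
        """Records for one (case, kind), sorted by observer id."""
        recs = [
            r
            for r in self._records
            if r.case_id == case_id and r.volume_kind == volume_kind
        ]
        return sorted(recs, key=lambda r: r.observer_id)

    def validate_grids(self) -> None:
        """Check the shared-grid invariant within every (case, kind) group."""
        for case_id in self.case_ids():
            for kind in self.volume_kinds():
                recs = self.group(case_id, kind)
                for rec in recs[1:]:
                    problem = recs[0].mask.grid.mismatch(rec.mask.grid)
                    if problem is not None:
                        raise GridMismatchError(
                            f"case {case_id} {kind}: observers "
                            f"{recs[0].observer_id!r} and {rec.observer_id!r} "
                            f"are on different grids ({problem})"
                        )


def overlap_counts(a: BinaryMask, b: BinaryMask) -> OverlapCounts:
    """Confusion counts (tp, fp, fn, tn) of two masks on an identical grid.

    Raises
    ------
    GridMismatchError
        If the two grids differ, naming the differing geometry component.
    """
    problem = a.grid.mismatch(b.grid)
    if problem is not None:
        raise GridMismatchError(f"masks are on different grids: {problem}")
    av, bv = a.voxels, b.voxels
    tp = int(np.count_nonzero(av & bv))
    fp = int(np.count_nonzero(av & ~bv))
    fn = int(np.count_nonzero(~av & bv))
    tn = a.grid.n_voxels - tp - fp - fn
    return OverlapCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def mask_volume_ml(m: BinaryMask) -> float:
    """Mask volume in millilitres: voxel count x voxel volume (mm^3) / 1000."""
    return m.voxel_count * m.grid.voxel_volume_mm3 / 1000.0


def resample_nearest(m: BinaryMask, target: ImageGrid) -> BinaryMask:
    """Nearest-neighbour resampling of a mask onto a target grid.

    Each target voxel takes the membership of the source voxel whose center
    is nearest (in physical mm) to the target voxel center. Exact midpoint
    ties break toward the lower source index. Target voxels whose centers
    fall outside the source voxel extent become background.
    """
    if m.grid.approx_equal(target):
        return BinaryMask(target, m.voxels.copy())
    src = m.grid
    out = np.zeros(target.shape, dtype=bool)
    axis_idx = []
    axis_valid = []
    for ax in range(3):
        centers = target.origin_mm[ax] + np.arange(target.shape[ax]) * target.spacing_mm[ax]
        cont = (centers - src.origin_mm[ax]) / src.spacing_mm[ax]
        # nearest index with ties toward the lower index: ceil(x - 1/2)
        nearest = np.ceil(cont - 0.5).astype(np.int64)
        valid = (cont >= -0.5) & (cont <= src.shape[ax] - 0.5)
        nearest = np.clip(nearest, 0, src.shape[ax] - 1)
        axis_idx.append(nearest)
        axis_valid.append(valid)
    ii, jj, kk = np.ix_(axis_idx[0], axis_idx[1], axis_idx[2])
    valid = (
        axis_valid[0][:, None, None]
        & axis_valid[1][None, :, None]
        & axis_valid[2][None, None, :]
    )
    out = m.voxels[ii, jj, kk] & valid
    logger.warning(
        "resampled mask from grid %s/%s to %s/%s (nearest-neighbour)",
        src.shape,
        src.spacing_mm,
        target.shape,
        target.spacing_mm,
    )
    return BinaryMask(target, out)
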
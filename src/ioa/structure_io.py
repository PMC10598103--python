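"""Readers/writers for mask volumes and planar contour structure sets.

The native exchange format is the voxel-mask volume (NIfTI via nibabel);
planar contour sets — the clinical style of delineation exchange — are a
convenience ingestion path, stored here as a plain-text JSON dialect of
closed planar polygons in patient-coordinate mm triplets, and rasterized to
masks by even-odd center sampling.

Coordinate conventions: the model's axis order is (slice, row, column);
structure-set point triplets are (col_mm, row_mm, slice_mm), i.e. x/y/z in
the usual planar sense with z along the slice axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage import measure

from .volume_model import (
    VOLUME_KINDS,
    BinaryMask,
    CohortStructureSet,
    DelineationRecord,
    GridMismatchError,
    ImageGrid,
    resample_nearest,
)

logger = logging.getLogger(__name__)

#: slice coordinates within one polygon may vary by at most this much
PLANARITY_TOL_MM = 1e-3


class FormatError(ValueError):
    """Raised for unreadable or malformed volume / structure-set files."""


# ---------------------------------------------------------------------------
# voxel-mask volumes


def write_mask_volume(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a 3-D NIfTI volume (uint8, 0/1).

    The affine stores spacing on the diagonal and the origin in the
    translation column; array axis order is the model's (slice, row, col).
    """
    affine = np.diag(list(mask.grid.spacing_mm) + [1.0]).astype(float)
    affine[:3, 3] = mask.grid.origin_mm
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_mask_volume(path: str | Path) -> BinaryMask:
    """Read a 3-D volume file into a BinaryMask (nonzero voxels are set).

    The affine must map each array axis onto one world axis (axis-aligned,
    flips and permutations allowed); data are reordered to the model's
    axis order with all axes ascending.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # nibabel raises various types
        raise FormatError(f"cannot read volume file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    linear = affine[:3, :3]
    origin = affine[:3, 3].copy()
    perm = [0, 0, 0]
    spacing = [0.0, 0.0, 0.0]
    flip = [False, False, False]
    used = set()
    for axis in range(3):
        col = linear[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-9)[0]
        if len(nz) != 1:
            raise FormatError(f"{path}: affine is not axis-aligned (column {axis})")
        world = int(nz[0])
        if world in used:
            raise FormatError(f"{path}: affine maps two axes onto world axis {world}")
        used.add(world)
        perm[axis] = world
        spacing[world] = abs(float(col[world]))
        flip[axis] = col[world] < 0
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: non-positive voxel spacing {spacing}")
    # flip descending axes, moving the origin to the new first voxel center
    for axis in range(3):
        if flip[axis]:
            data = np.flip(data, axis=axis)
            world = perm[axis]
            origin[world] -= (data.shape[axis] - 1) * spacing[world]
    # reorder array axes so that array axis i corresponds to world axis i
    order = np.argsort(perm)
    data = np.transpose(data, order)
    grid = ImageGrid(
        shape=tuple(int(s) for s in data.shape),
        spacing_mm=tuple(spacing),
        origin_mm=tuple(float(o) for o in origin),
    )
    return BinaryMask(grid, data != 0)


# ---------------------------------------------------------------------------
# planar contour structure sets


@dataclass(frozen=True)
class ContourPolygon:
    """One closed planar polygon on a single slice plane.

    ``vertices`` are (row_mm, col_mm) points; the polygon is implicitly
    closed (last vertex connects back to the first).
    """

    slice_position_mm: float
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        if len(verts) < 3:
            raise ValueError("a contour polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "slice_position_mm", float(self.slice_position_mm))

    def area_mm2(self) -> float:
        """Unsigned polygon area (shoelace formula)."""
        v = np.asarray(self.vertices)
        r, c = v[:, 0], v[:, 1]
        return abs(float(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))) / 2.0


@dataclass
class StructureSetFile:
    """Named ROIs, each a list of planar contour polygons."""

    rois: dict[str, list[ContourPolygon]] = field(default_factory=dict)
    frame_of_reference: str | None = None


def parse_structure_set(path: str | Path) -> StructureSetFile:
    """Parse a JSON structure set of planar closed contours.

    Layout::

        {"frame_of_reference": "...",
         "rois": {"GTV": [[[x, y, z], ...], ...], ...}}

    where each contour is a list of patient-coordinate mm triplets
    (x = column, y = row, z = slice position). Each contour must be planar:
    its z values may vary by at most 1e-3 mm.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read structure set {path}: {exc}") from exc
    if not isinstance(payload, dict) or "rois" not in payload:
        raise FormatError(f"{path}: missing 'rois' mapping")
    rois: dict[str, list[ContourPolygon]] = {}
    for name, contours in payload["rois"].items():
        if not contours:
            raise FormatError(f"{path}: ROI {name!r} has no contour data")
        polys = []
        for contour in contours:
            pts = np.asarray(contour, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
                raise FormatError(
                    f"{path}: ROI {name!r} has a malformed contour "
                    f"(need >= 3 mm triplets)"
                )
            z = pts[:, 2]
            if z.max() - z.min() > PLANARITY_TOL_MM:
                raise FormatError(
                    f"{path}: ROI {name!r} has a non-planar contour "
                    f"(slice coordinate varies by {z.max() - z.min():.6g} mm)"
                )
            vertices = [(float(y), float(x)) for x, y, _ in pts]
            polys.append(ContourPolygon(float(z.mean()), vertices))
        rois[name] = polys
    return StructureSetFile(rois=rois, frame_of_reference=payload.get("frame_of_reference"))


def write_structure_set(ss: StructureSetFile, path: str | Path) -> None:
    payload = {
        "frame_of_reference": ss.frame_of_reference,
        "rois": {
            name: [
                [[c, r, poly.slice_position_mm] for r, c in poly.vertices]
                for poly in polys
            ]
            for name, polys in ss.rois.items()
        },
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# rasterization


def _on_boundary(pr, pc, verts, tol=1e-9):
    """Boolean array: which points (pr, pc) lie on the polygon's edges."""
    on = np.zeros(pr.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        dr, dc = r2 - r1, c2 - c1
        seg2 = dr * dr + dc * dc
        if seg2 == 0.0:
            d2 = (pr - r1) ** 2 + (pc - c1) ** 2
            on |= d2 <= tol * tol
            continue
        t = ((pr - r1) * dr + (pc - c1) * dc) / seg2
        t = np.clip(t, 0.0, 1.0)
        d2 = (pr - (r1 + t * dr)) ** 2 + (pc - (c1 + t * dc)) ** 2
        on |= d2 <= tol * tol
    return on


def _even_odd_inside(pr, pc, verts):
    """Crossing-number (even-odd) point-in-polygon test, vectorized."""
    inside = np.zeros(pr.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        crosses = (c1 > pc) != (c2 > pc)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            r_at = (r2 - r1) * (pc - c1) / (c2 - c1) + r1
        inside ^= crosses & (pr < r_at)
    return inside


def rasterize_contours(
    polys: list[ContourPolygon], grid: ImageGrid
) -> BinaryMask:
    """Rasterize planar polygons to a mask by even-odd center sampling.

    A voxel is set iff its center lies inside an odd number of its slice's
    polygons (so nested contours punch holes), or exactly on any polygon
    edge (deterministic boundary tie-break). Each polygon attaches to the
    nearest slice index whose plane is within half a slice spacing of the
    polygon's slice position; otherwise the polygon is dropped with a
    warning.
    """
    voxels = np.zeros(grid.shape, dtype=bool)
    s_origin, s_spacing, n_slices = grid.origin_mm[0], grid.spacing_mm[0], grid.shape[0]
    by_slice: dict[int, list[ContourPolygon]] = {}
    for poly in polys:
        k = round((poly.slice_position_mm - s_origin) / s_spacing)
        if (
            k < 0
            or k >= n_slices
            or abs(poly.slice_position_mm - (s_origin + k * s_spacing))
            > s_spacing / 2.0 + 1e-9
        ):
            logger.warning(
                "contour at slice position %.3f mm is not within half a slice "
                "spacing of any slice plane; dropped",
                poly.slice_position_mm,
            )
            continue
        by_slice.setdefault(int(k), []).append(poly)
    if not by_slice:
        if polys:
            logger.warning("no contour rasterized to any voxel")
        return BinaryMask(grid, voxels)
    rows = grid.origin_mm[1] + np.arange(grid.shape[1]) * grid.spacing_mm[1]
    cols = grid.origin_mm[2] + np.arange(grid.shape[2]) * grid.spacing_mm[2]
    pr, pc = np.meshgrid(rows, cols, indexing="ij")
    for k, slice_polys in by_slice.items():
        parity = np.zeros(pr.shape, dtype=bool)
        boundary = np.zeros(pr.shape, dtype=bool)
        for poly in slice_polys:
            parity ^= _even_odd_inside(pr, pc, poly.vertices)
            boundary |= _on_boundary(pr, pc, poly.vertices)
        voxels[k] = parity | boundary
    mask = BinaryMask(grid, voxels)
    if mask.is_empty and polys:
        logger.warning("no contour rasterized to any voxel")
    return mask


def mask_to_contours(mask: BinaryMask) -> list[ContourPolygon]:
    """Extract per-slice 0.5-level iso-contours of a mask as planar polygons.

    The inverse of :func:`rasterize_contours` up to sub-voxel boundary
    placement; round-tripping reproduces volumes to within a voxel shell.
    """
    polys: list[ContourPolygon] = []
    grid = mask.grid
    for k in range(grid.shape[0]):
        plane = mask.voxels[k]
        if not plane.any():
            continue
        padded = np.pad(plane.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            verts = []
            for ri, ci in contour[:-1]:  # find_contours closes the loop itself
                r_mm = grid.origin_mm[1] + (ri - 1) * grid.spacing_mm[1]
                c_mm = grid.origin_mm[2] + (ci - 1) * grid.spacing_mm[2]
                verts.append((r_mm, c_mm))
            if len(verts) >= 3:
                polys.append(
                    ContourPolygon(grid.origin_mm[0] + k * grid.spacing_mm[0], verts)
                )
    return polys


def mask_to_structure_set(
    masks: dict[str, BinaryMask], frame_of_reference: str | None = None
) -> StructureSetFile:
    return StructureSetFile(
        rois={name: mask_to_contours(m) for name, m in masks.items()},
        frame_of_reference=frame_of_reference,
    )


# ---------------------------------------------------------------------------
# cohort directory loading


def load_cohort(
    input_dir: str | Path,
    fmt: str = "masks",
    resample_policy: str = "strict",
) -> CohortStructureSet:
    """Load a cohort from the ``case_<id>/observer_<id>/<KIND>.<ext>`` layout.

    ``fmt`` is ``"masks"`` (NIfTI volumes) or ``"contours"`` (JSON structure
    sets; the ROI named like the volume kind is rasterized onto the grid
    recorded in the file's ``grid`` entry). ``resample_policy`` is
    ``"strict"`` (grid mismatch within a group is an error) or
    ``"to_first"`` (later observers are resampled onto the first observer's
    grid, logged at warning level).
    """
    input_dir = Path(input_dir)
    if fmt not in ("masks", "contours"):
        raise ValueError(f"unknown format {fmt!r}")
    if resample_policy not in ("strict", "to_first"):
        raise ValueError(f"unknown resample policy {resample_policy!r}")
    cohort = CohortStructureSet()
    first_grid: dict[tuple[str, str], ImageGrid] = {}
    case_dirs = sorted(p for p in input_dir.iterdir() if p.is_dir() and p.name.startswith("case_"))
    if not case_dirs:
        raise FormatError(f"no case_<id> directories found under {input_dir}")
    for case_dir in case_dirs:
        case_id = case_dir.name[len("case_"):]
        obs_dirs = sorted(
            p for p in case_dir.iterdir() if p.is_dir() and p.name.startswith("observer_")
        )
        for obs_dir in obs_dirs:
            observer_id = obs_dir.name[len("observer_"):]
            for kind in VOLUME_KINDS:
                mask = _load_record(obs_dir, kind, fmt)
                if mask is None:
                    logger.warning(
                        "case %s observer %s: no %s submitted; omitted",
                        case_id,
                        observer_id,
                        kind,
                    )
                    continue
                key = (case_id, kind)
                if key not in first_grid:
                    first_grid[key] = mask.grid
                elif not mask.grid.approx_equal(first_grid[key]):
                    if resample_policy == "to_first":
                        mask = resample_nearest(mask, first_grid[key])
                    else:
                        raise GridMismatchError(
                            f"case {case_id} {kind}: observer {observer_id!r} "
                            f"grid differs from the group grid "
                            f"({first_grid[key].mismatch(mask.grid)}); rerun "
                            f"with resample policy 'to_first' to harmonize"
                        )
                cohort.add(DelineationRecord(case_id, observer_id, kind, mask))
    return cohort


def _load_record(obs_dir: Path, kind: str, fmt: str) -> BinaryMask | None:
    if fmt == "masks":
        for ext in (".nii.gz", ".nii"):
            path = obs_dir / f"{kind}{ext}"
            if path.exists():
                return read_mask_volume(path)
        return None
    path = obs_dir / f"{kind}.json"
    if not path.exists():
        return None
    payload = json.loads(path.read_text())
    if "grid" not in payload:
        raise FormatError(f"{path}: contour file lacks the 'grid' entry")
    g = payload["grid"]
    grid = ImageGrid(tuple(g["shape"]), tuple(g["spacing_mm"]), tuple(g["origin_mm"]))
    ss = parse_structure_set(path)
    if kind not in ss.rois:
        raise FormatError(f"{path}: no ROI named {kind!r}")
    return rasterize_contours(ss.rois[kind], grid)


def write_cohort(
    cohort: CohortStructureSet, out_dir: str | Path, fmt: str = "masks"
) -> None:
    """Write a cohort in the directory layout read back by :func:`load_cohort`."""
    out_dir = Path(out_dir)
    for rec in cohort:
        obs_dir = out_dir / f"case_{rec.case_id}" / f"observer_{rec.observer_id}"
        obs_dir.mkdir(parents=True, exist_ok=True)
        if fmt == "masks":
            write_mask_volume(rec.mask, obs_dir / f"{rec.volume_kind}.nii.gz")
        elif fmt == "contours":
            path = obs_dir / f"{rec.volume_kind}.json"
            ss = mask_to_structure_set({rec.volume_kind: rec.mask})
            g = rec.mask.grid
            payload = {
                "frame_of_reference": None,
                "grid": {
                    "shape": list(g.shape),
                    "spacing_mm": list(g.spacing_mm),
                    "origin_mm": list(g.origin_mm),
                },
                "rois": {
                    name: [
                        [[c, r, poly.slice_position_mm] for r, c in poly.vertices]
                        for poly in polys
                    ]
                    for name, polys in ss.rois.items()
                },
            }
            path.write_text(json.dumps(payload, sort_keys=True) + "\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")
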
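"""Seeded multi-observer GTV/ITV/PTV cohort generator.

Tumors are star-convex radial shapes: a sphere of the target volume whose
radius is modulated by a low-order real spherical-harmonic field. Each
simulated observer perturbs the base shape with a systematic margin bias
plus a smooth zero-mean spherical-harmonic roughness field, producing the
kind of interobserver dispersion the agreement pipeline measures. ITVs are
motion envelopes (union of sinusoidal translations of the observer's GTV)
and PTVs are isotropic mm-margin expansions of the ITV.

Everything is deterministic given the configured base seed; the per-record
seed is ``base_seed * 10000 + case_index * 100 + observer_index``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.special import sph_harm_y

from .volume_model import (
    BinaryMask,
    CohortStructureSet,
    DelineationRecord,
    ImageGrid,
)

logger = logging.getLogger(__name__)

#: relative sd of the base-shape spherical-harmonic coefficients (degrees 0-4)
BASE_SHAPE_SD = 0.05
BASE_SHAPE_MAX_DEGREE = 4
#: maximum degree of the observer roughness field
OBSERVER_MAX_DEGREE = 6


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonic (theta polar, phi azimuth)."""
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    if m > 0:
        return math.sqrt(2.0) * (-1) ** m * np.real(sph_harm_y(l, m, theta, phi))
    return math.sqrt(2.0) * (-1) ** m * np.imag(sph_harm_y(l, -m, theta, phi))


def _lm_pairs(l_min: int, l_max: int) -> list[tuple[int, int]]:
    return [(l, m) for l in range(l_min, l_max + 1) for m in range(-l, l + 1)]


@dataclass(frozen=True)
class RadialShape:
    """Star-convex shape: radius as a function of direction from a center.

    radius(dir) = r0 * (1 + sum rel_coeffs * Y) + offset + sum abs_coeffs * Y,
    where relative coefficients shape the base tumor and absolute (mm)
    coefficients plus the offset carry an observer's perturbation.
    """

    center_mm: tuple[float, float, float]
    r0_mm: float
    rel_terms: tuple[tuple[int, int, float], ...] = ()
    abs_terms: tuple[tuple[int, int, float], ...] = ()
    offset_mm: float = 0.0

    def radius_mm(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        rel = np.zeros(np.shape(theta), dtype=float)
        for l, m, a in self.rel_terms:
            rel += a * _real_sph_harm(l, m, theta, phi)
        r = self.r0_mm * (1.0 + rel) + self.offset_mm
        for l, m, c in self.abs_terms:
            r = r + c * _real_sph_harm(l, m, theta, phi)
        return r

    def max_radius_mm(self, n_dirs: int = 4096) -> float:
        """Conservative bound on the radius via dense direction sampling."""
        theta, phi = _fibonacci_sphere(n_dirs)
        bound = float(self.radius_mm(theta, phi).max())
        return bound * 1.05 + 1.0

    def to_mask(self, grid: ImageGrid, warn_on_clip: bool = True) -> BinaryMask:
        """Voxelize: a voxel is set iff its center lies within radius(dir).

        Radii driven non-positive by perturbations are clipped at one voxel
        (the smallest spacing component) with a warning.
        """
        center = np.asarray(self.center_mm)
        rmax = self.max_radius_mm()
        lo_idx, hi_idx = [], []
        for ax in range(3):
            lo = int(np.floor((center[ax] - rmax - grid.origin_mm[ax]) / grid.spacing_mm[ax]))
            hi = int(np.ceil((center[ax] + rmax - grid.origin_mm[ax]) / grid.spacing_mm[ax]))
            lo_idx.append(max(lo, 0))
            hi_idx.append(min(hi + 1, grid.shape[ax]))
        axes = [
            grid.origin_mm[ax] + np.arange(lo_idx[ax], hi_idx[ax]) * grid.spacing_mm[ax] - center[ax]
            for ax in range(3)
        ]
        dz, dy, dx = np.meshgrid(*axes, indexing="ij")
        dist = np.sqrt(dz * dz + dy * dy + dx * dx)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.where(dist > 0, dz / dist, 1.0), -1.0, 1.0))
            phi = np.arctan2(dy, dx)
        r = self.radius_mm(theta, phi)
        min_r = min(grid.spacing_mm)
        if (r <= 0).any():
            if warn_on_clip:
                logger.warning(
                    "radius field non-positive in %d direction sample(s); "
                    "clipped at one voxel",
                    int((r <= 0).sum()),
                )
            r = np.maximum(r, min_r)
        voxels = np.zeros(grid.shape, dtype=bool)
        sub = dist <= r
        voxels[
            lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]
        ] = sub
        return BinaryMask(grid, voxels, meta={"radial_shape": self})


def _fibonacci_sphere(n: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(n) + 0.5
    theta = np.arccos(1 - 2 * i / n)
    phi = (np.pi * (1 + 5**0.5) * i) % (2 * np.pi)
    return theta, phi


@dataclass(frozen=True)
class CaseTemplate:
    """Parameters of one simulated case."""

    case_id: str
    gtv_volume_ml: float
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: peak-to-center motion amplitude per axis (slice, row, col); the
    #: default is cranio-caudal (slice-axis) dominant
    motion_amplitude_mm: tuple[float, float, float] = (5.0, 0.0, 0.0)
    n_phases: int = 10
    ptv_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.gtv_volume_ml <= 0:
            raise ValueError("gtv_volume_ml must be > 0")
        if self.ptv_margin_mm < 0:
            raise ValueError("ptv_margin_mm must be >= 0")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.grid_shape, self.spacing_mm, self.origin_mm)


#: three study-like default cases, calibrated to the observed median GTV
#: volumes in ml
DEFAULT_CASE_TEMPLATES = (
    CaseTemplate(case_id="1", gtv_volume_ml=31.75),
    CaseTemplate(case_id="2", gtv_volume_ml=45.3),
    CaseTemplate(case_id="3", gtv_volume_ml=45.7),
)


@dataclass(frozen=True)
class ObserverModel:
    """One simulated observer's delineation tendency."""

    observer_id: str
    systematic_bias_mm: float
    roughness_mm: float
    seed: int

    def __post_init__(self) -> None:
        if self.roughness_mm < 0:
            raise ValueError("roughness_mm must be >= 0")


@dataclass(frozen=True)
class CohortSimConfig:
    n_observers: int = 19
    templates: tuple[CaseTemplate, ...] = DEFAULT_CASE_TEMPLATES
    bias_sd_mm: float = 1.5
    roughness_mm: float = 2.0
    base_seed: int = 0
    #: probability that a non-first observer's case submission is kept
    participation: float = 1.0

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("n_observers must be >= 2")
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation must be within [0, 1]")


def make_base_tumor(
    template: CaseTemplate, seed: int, radial_sd: float = BASE_SHAPE_SD
) -> BinaryMask:
    """Generate the case's ground-shape tumor mask at the grid center.

    The shape is a sphere of the target volume with radius modulated by a
    degree <= 4 spherical-harmonic field whose coefficients are drawn from
    Normal(0, radial_sd^2); the voxelized volume lands within 15% of the
    target. ``radial_sd=0`` yields an exact sphere.
    """
    grid = template.grid
    r0 = (3.0 * template.gtv_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    half_extent = min(
        (n - 1) / 2.0 * s for n, s in zip(grid.shape, grid.spacing_mm)
    )
    if r0 * (1.0 + 6.0 * radial_sd) >= half_extent:
        raise ValueError(
            f"target volume {template.gtv_volume_ml} ml (radius {r0:.1f} mm) "
            f"exceeds grid capacity (half extent {half_extent:.1f} mm)"
        )
    rng = np.random.default_rng(seed)
    terms = tuple(
        (l, m, float(rng.normal(0.0, radial_sd)))
        for l, m in _lm_pairs(0, BASE_SHAPE_MAX_DEGREE)
    )
    if radial_sd == 0.0:
        terms = ()
    shape = RadialShape(center_mm=grid.center_mm, r0_mm=r0, rel_terms=terms)
    return shape.to_mask(grid)


def simulate_observer_gtv(base: BinaryMask, obs: ObserverModel) -> BinaryMask:
    """One observer's GTV: base radius field + bias + smooth roughness field.

    The roughness field is a zero-mean real spherical-harmonic sum of
    degrees 1..6 whose coefficient scale is chosen so its pointwise
    standard deviation equals ``obs.roughness_mm``. Deterministic given
    ``obs.seed``.
    """
    shape = base.meta.get("radial_shape")
    if shape is None:
        raise ValueError(
            "base mask lacks its radial shape model (expected a mask produced "
            "by make_base_tumor)"
        )
    pairs = _lm_pairs(1, OBSERVER_MAX_DEGREE)
    # pointwise variance of sum c_lm Y_lm with iid c is sigma^2 * n_terms/(4*pi)
    sigma_c = obs.roughness_mm * math.sqrt(4.0 * math.pi / len(pairs))
    rng = np.random.default_rng([obs.seed, 1])
    abs_terms = tuple(
        (l, m, float(rng.normal(0.0, sigma_c))) for l, m in pairs
    )
    if obs.roughness_mm == 0.0:
        abs_terms = ()
    perturbed = replace(
        shape,
        offset_mm=shape.offset_mm + obs.systematic_bias_mm,
        abs_terms=shape.abs_terms + abs_terms,
    )
    return perturbed.to_mask(base.grid)


def _translate(voxels: np.ndarray, offsets: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel translation; raises if set voxels would leave the grid."""
    out = np.zeros_like(voxels)
    src = []
    dst = []
    for ax, off in enumerate(offsets):
        n = voxels.shape[ax]
        if off >= 0:
            src.append(slice(0, n - off))
            dst.append(slice(off, n))
        else:
            src.append(slice(-off, n))
            dst.append(slice(0, n + off))
    lost = voxels.sum() - voxels[tuple(src)].sum()
    if lost:
        raise ValueError(
            f"translation by {offsets} voxels pushes {int(lost)} voxel(s) "
            f"off-grid; use a larger grid"
        )
    out[tuple(dst)] = voxels[tuple(src)]
    return out


def build_itv(gtv: BinaryMask, template: CaseTemplate) -> BinaryMask:
    """Motion envelope: union of the GTV translated along one breathing cycle.

    Phase p of n shifts the GTV by amplitude * sin(2*pi*p/n) per axis,
    rounded to the nearest whole voxel. The result always contains the GTV
    (phase 0 has zero displacement).
    """
    grid = gtv.grid
    union = np.zeros(grid.shape, dtype=bool)
    n = template.n_phases
    for p in range(n):
        s = math.sin(2.0 * math.pi * p / n)
        offsets = tuple(
            int(round(template.motion_amplitude_mm[ax] * s / grid.spacing_mm[ax]))
            for ax in range(3)
        )
        union |= _translate(gtv.voxels, offsets)
    return BinaryMask(grid, union)


def build_ptv(itv: BinaryMask, margin_mm: float) -> BinaryMask:
    """Margin expansion: voxels within ``margin_mm`` (spacing-weighted
    Euclidean distance) of the ITV. Margin 0 is the identity."""
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    grid = itv.grid
    if itv.is_empty or margin_mm == 0.0:
        return BinaryMask(grid, itv.voxels.copy())
    idx = np.argwhere(itv.voxels)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    pad = [int(math.ceil(margin_mm / s)) + 1 for s in grid.spacing_mm]
    for ax in range(3):
        if lo[ax] - pad[ax] + 1 < 0 or hi[ax] + pad[ax] - 1 > grid.shape[ax]:
            raise ValueError(
                f"margin expansion of {margin_mm} mm leaves the grid along "
                f"axis {ax}; use a larger grid"
            )
    box = tuple(
        slice(int(max(lo[ax] - pad[ax], 0)), int(min(hi[ax] + pad[ax], grid.shape[ax])))
        for ax in range(3)
    )
    sub = itv.voxels[box]
    dist = distance_transform_edt(~sub, sampling=grid.spacing_mm)
    out = np.zeros(grid.shape, dtype=bool)
    out[box] = dist <= margin_mm + 1e-9
    return BinaryMask(grid, out)


def record_seed(base_seed: int, case_index: int, observer_index: int) -> int:
    """The documented per-observer seed derivation."""
    return base_seed * 10000 + case_index * 100 + observer_index


def generate_cohort(config: CohortSimConfig) -> CohortStructureSet:
    """Simulate the full cohort: per case a base tumor, per observer a
    perturbed GTV, its motion-envelope ITV and margin-expanded PTV.

    With ``participation < 1`` each non-first observer's case submission is
    dropped with probability ``1 - participation`` (logged), exercising
    ragged participation downstream.
    """
    cohort = CohortStructureSet()
    for ci, template in enumerate(config.templates):
        base = make_base_tumor(template, seed=record_seed(config.base_seed, ci, 99))
        drop_rng = np.random.default_rng([record_seed(config.base_seed, ci, 98), 7])
        for oi in range(config.n_observers):
            observer_id = f"{oi + 1:02d}"
            seed = record_seed(config.base_seed, ci, oi)
            keep = oi == 0 or drop_rng.uniform() < config.participation
            if not keep:
                logger.warning(
                    "case %s observer %s dropped (participation %.2f)",
                    template.case_id,
                    observer_id,
                    config.participation,
                )
                continue
            bias = float(
                np.random.default_rng([seed, 0]).normal(0.0, config.bias_sd_mm)
            )
            obs = ObserverModel(
                observer_id=observer_id,
                systematic_bias_mm=bias,
                roughness_mm=config.roughness_mm,
                seed=seed,
            )
            gtv = simulate_observer_gtv(base, obs)
            itv = build_itv(gtv, template)
            ptv = build_ptv(itv, template.ptv_margin_mm)
            for kind, mask in (("GTV", gtv), ("ITV", itv), ("PTV", ptv)):
                cohort.add(
                    DelineationRecord(template.case_id, observer_id, kind, mask)
                )
    return cohort


def cohort_manifest(config: CohortSimConfig) -> dict:
    """JSON-serializable record of all simulation parameters."""
    return {
        "n_observers": config.n_observers,
        "bias_sd_mm": config.bias_sd_mm,
        "roughness_mm": config.roughness_mm,
        "base_seed": config.base_seed,
        "participation": config.participation,
        "seed_formula": "base_seed*10000 + case_index*100 + observer_index",
        "templates": [
            {
                "case_id": t.case_id,
                "gtv_volume_ml": t.gtv_volume_ml,
                "grid_shape": list(t.grid_shape),
                "spacing_mm": list(t.spacing_mm),
                "origin_mm": list(t.origin_mm),
                "motion_amplitude_mm": list(t.motion_amplitude_mm),
                "n_phases": t.n_phases,
                "ptv_margin_mm": t.ptv_margin_mm,
            }
            for t in config.templates
        ],
    }
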
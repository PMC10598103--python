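import json
import time

import numpy as np
import pytest

from ioa import (
    BinaryMask,
    ContourPolygon,
    ImageGrid,
    StructureSetFile,
    metric_quartet,
    parse_structure_set,
    rasterize_contours,
    read_mask_volume,
    write_mask_volume,
)
from ioa.structure_io import (
    FormatError,
    load_cohort,
    mask_to_contours,
    write_cohort,
    write_structure_set,
)

from conftest import random_grid, random_mask


def square_contour(z, r0, c0, size):
    """Axis-aligned square as (x=col, y=row, z=slice) mm triplets."""
    return [
        [c0, r0, z],
        [c0 + size, r0, z],
        [c0 + size, r0 + size, z],
        [c0, r0 + size, z],
    ]


class TestMaskVolumeRoundTrip:
    def test_random_mask_round_trip(self, rng, tmp_path):
        grid = ImageGrid((12, 10, 8), (0.98, 0.98, 3.0), (-20.0, 4.5, 7.25))
        m = random_mask(rng, grid)
        path = tmp_path / "mask.nii.gz"
        write_mask_volume(m, path)
        back = read_mask_volume(path)
        assert np.array_equal(back.voxels, m.voxels)
        assert back.grid.approx_equal(m.grid)
        assert back.grid.spacing_mm == pytest.approx(grid.spacing_mm, abs=1e-6)

    def test_empty_mask_round_trip(self, tmp_path):
        grid = ImageGrid((5, 5, 5), (1, 1, 1))
        m = BinaryMask(grid, np.zeros(grid.shape, dtype=bool))
        path = tmp_path / "empty.nii"
        write_mask_volume(m, path)
        back = read_mask_volume(path)
        assert back.is_empty
        assert back.volume_ml == 0.0

    def test_metrics_preserved_through_round_trip(self, rng, tmp_path):
        # spacings exactly representable in the float32 NIfTI affine keep
        # the mm-valued Hausdorff distance bit-identical through the file
        grid = ImageGrid((10, 10, 10), (1.25, 0.5, 2.0))
        a = random_mask(rng, grid)
        b = random_mask(rng, grid)
        q0 = metric_quartet(a, b)
        for name, m in (("a", a), ("b", b)):
            write_mask_volume(m, tmp_path / f"{name}.nii.gz")
        q1 = metric_quartet(
            read_mask_volume(tmp_path / "a.nii.gz"),
            read_mask_volume(tmp_path / "b.nii.gz"),
        )
        assert q0.as_dict() == q1.as_dict()

    def test_large_round_trip_performance(self, rng, tmp_path):
        grid = ImageGrid((100, 200, 200), (1, 1, 1))
        m = BinaryMask(grid, rng.random(grid.shape) < 0.1)
        t0 = time.time()
        write_mask_volume(m, tmp_path / "big.nii.gz")
        back = read_mask_volume(tmp_path / "big.nii.gz")
        assert time.time() - t0 < 5.0
        assert np.array_equal(back.voxels, m.voxels)

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(np.zeros((4, 4), dtype=np.uint8), np.eye(4)),
            str(tmp_path / "flat.nii"),
        )
        with pytest.raises(FormatError, match="3-D"):
            read_mask_volume(tmp_path / "flat.nii")

    def test_unreadable_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"not a nifti file")
        with pytest.raises(FormatError):
            read_mask_volume(bad)

    def test_flipped_axis_normalized(self, rng, tmp_path):
        # a negative-spacing (flipped) axis reads back as the same voxel set
        import nibabel as nib

        grid = ImageGrid((6, 5, 4), (1.0, 1.0, 2.0), (0.0, 0.0, 0.0))
        m = random_mask(rng, grid)
        affine = np.diag([1.0, 1.0, -2.0, 1.0])
        affine[2, 3] = (grid.shape[2] - 1) * 2.0  # first voxel at top
        flipped = np.flip(m.voxels, axis=2)
        nib.save(
            nib.Nifti1Image(flipped.astype(np.uint8), affine),
            str(tmp_path / "flip.nii"),
        )
        back = read_mask_volume(tmp_path / "flip.nii")
        assert np.array_equal(back.voxels, m.voxels)
        assert back.grid.approx_equal(grid)


class TestContourPolygon:
    def test_minimum_vertices(self):
        with pytest.raises(ValueError):
            ContourPolygon(0.0, [(0, 0), (1, 1)])

    def test_area(self):
        poly = ContourPolygon(0.0, [(0, 0), (0, 4), (3, 4), (3, 0)])
        assert poly.area_mm2() == pytest.approx(12.0)


class TestParseStructureSet:
    def test_single_square_roi(self, tmp_path):
        path = tmp_path / "ss.json"
        path.write_text(
            json.dumps(
                {
                    "frame_of_reference": "FOR-1",
                    "rois": {"GTV": [square_contour(10.0, 0.0, 0.0, 5.0)]},
                }
            )
        )
        ss = parse_structure_set(path)
        assert list(ss.rois) == ["GTV"]
        assert len(ss.rois["GTV"]) == 1
        poly = ss.rois["GTV"][0]
        assert len(poly.vertices) == 4
        assert poly.slice_position_mm == pytest.approx(10.0)
        assert ss.frame_of_reference == "FOR-1"

    def test_non_planar_contour_rejected(self, tmp_path):
        contour = square_contour(10.0, 0.0, 0.0, 5.0)
        contour[2][2] = 10.5  # z varies within one polygon
        path = tmp_path / "ss.json"
        path.write_text(json.dumps({"rois": {"BAD": [contour]}}))
        with pytest.raises(FormatError, match="BAD"):
            parse_structure_set(path)

    def test_missing_contour_data_rejected(self, tmp_path):
        path = tmp_path / "ss.json"
        path.write_text(json.dumps({"rois": {"GTV": []}}))
        with pytest.raises(FormatError, match="GTV"):
            parse_structure_set(path)

    def test_write_parse_round_trip(self, tmp_path):
        ss = StructureSetFile(
            rois={
                "GTV": [ContourPolygon(4.0, [(0, 0), (0, 3), (3, 3), (3, 0)])],
                "PTV": [ContourPolygon(4.0, [(1, 1), (1, 2), (2, 2)])],
            },
            frame_of_reference="F",
        )
        write_structure_set(ss, tmp_path / "ss.json")
        back = parse_structure_set(tmp_path / "ss.json")
        assert set(back.rois) == {"GTV", "PTV"}
        assert back.rois["GTV"][0].vertices == ss.rois["GTV"][0].vertices


class TestRasterizeContours:
    def test_square_spanning_voxel_centers(self):
        # square through the centers of a 2x2 patch: centers on the edge
        # count as inside -> exactly 4 voxels
        grid = ImageGrid((1, 4, 4), (1, 1, 1))
        poly = ContourPolygon(0.0, [(1, 1), (1, 2), (2, 2), (2, 1)])
        mask = rasterize_contours([poly], grid)
        assert mask.voxel_count == 4
        assert mask.voxels[0, 1:3, 1:3].all()

    def test_polygon_between_centers(self, caplog):
        grid = ImageGrid((1, 4, 4), (1, 1, 1))
        poly = ContourPolygon(
            0.0, [(0.2, 0.2), (0.2, 0.8), (0.8, 0.8), (0.8, 0.2)]
        )
        with caplog.at_level("WARNING", logger="ioa.structure_io"):
            mask = rasterize_contours([poly], grid)
        assert mask.is_empty
        assert "no contour rasterized" in caplog.text

    def test_off_slice_polygon_dropped(self, caplog):
        grid = ImageGrid((2, 4, 4), (3, 1, 1))
        # slices sit at z = 0 and 3; z = 5 is beyond the last plane + half spacing
        poly = ContourPolygon(5.0, [(0, 0), (0, 3), (3, 3), (3, 0)])
        with caplog.at_level("WARNING", logger="ioa.structure_io"):
            mask = rasterize_contours([poly], grid)
        assert mask.is_empty
        assert "half a slice" in caplog.text

    def test_nested_squares_make_ring(self):
        grid = ImageGrid((1, 9, 9), (1, 1, 1))
        outer = ContourPolygon(0.0, [(0.5, 0.5), (0.5, 7.5), (7.5, 7.5), (7.5, 0.5)])
        inner = ContourPolygon(0.0, [(2.5, 2.5), (2.5, 5.5), (5.5, 5.5), (5.5, 2.5)])
        mask = rasterize_contours([outer, inner], grid)
        assert mask.voxels[0, 1, 1]  # inside outer only
        assert not mask.voxels[0, 4, 4]  # inside both -> hole
        assert mask.voxel_count == 49 - 9

    def test_empty_polygon_list(self):
        grid = ImageGrid((2, 4, 4), (1, 1, 1))
        assert rasterize_contours([], grid).is_empty

    def test_matches_pointwise_ray_casting_oracle(self):
        # DERIVED: brute-force even-odd ray casting per voxel center
        rng = np.random.default_rng(13)
        grid = ImageGrid((1, 64, 64), (1, 0.7, 0.9), (0.0, -3.0, 2.0))
        rows = grid.origin_mm[1] + np.arange(64) * grid.spacing_mm[1]
        cols = grid.origin_mm[2] + np.arange(64) * grid.spacing_mm[2]
        for _ in range(10):
            n = int(rng.integers(3, 9))
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
            radii = rng.uniform(3, 20, size=n)
            cr, cc = rng.uniform(10, 30, size=2)
            verts = [
                (cr + r * np.sin(a), cc + r * np.cos(a))
                for r, a in zip(radii, angles)
            ]
            poly = ContourPolygon(0.0, verts)
            mask = rasterize_contours([poly], grid)
            expected = np.zeros((64, 64), dtype=bool)
            for i, pr in enumerate(rows):
                for j, pc in enumerate(cols):
                    crossings = 0
                    for k in range(n):
                        r1, c1 = verts[k]
                        r2, c2 = verts[(k + 1) % n]
                        if (c1 > pc) != (c2 > pc):
                            r_at = r1 + (r2 - r1) * (pc - c1) / (c2 - c1)
                            if pr < r_at:
                                crossings += 1
                    expected[i, j] = crossings % 2 == 1
            assert np.array_equal(mask.voxels[0], expected)

    def test_translation_consistency(self, rng):
        verts = [(1.2, 0.7), (1.1, 5.3), (4.8, 6.1), (6.0, 2.2)]
        shift = np.array([2.0, -3.5, 1.25])  # (slice, row, col)
        grid = ImageGrid((3, 10, 10), (2.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        shifted_grid = ImageGrid((3, 10, 10), (2.0, 1.0, 1.0), tuple(shift))
        poly = ContourPolygon(2.0, verts)
        poly_shifted = ContourPolygon(
            2.0 + shift[0], [(r + shift[1], c + shift[2]) for r, c in verts]
        )
        m1 = rasterize_contours([poly], grid)
        m2 = rasterize_contours([poly_shifted], shifted_grid)
        assert np.array_equal(m1.voxels, m2.voxels)

    def test_vertex_order_reversal(self):
        verts = [(1.2, 0.7), (1.1, 5.3), (4.8, 6.1), (6.0, 2.2)]
        grid = ImageGrid((1, 10, 10), (1, 1, 1))
        m1 = rasterize_contours([ContourPolygon(0.0, verts)], grid)
        m2 = rasterize_contours([ContourPolygon(0.0, verts[::-1])], grid)
        assert np.array_equal(m1.voxels, m2.voxels)


class TestContourRoundTrip:
    def test_rasterized_volume_matches_analytic_area(self, tmp_path):
        # synthesize -> write -> parse -> rasterize; volume within 5% of
        # polygon area x slice thickness
        grid = ImageGrid((3, 60, 60), (3.0, 1.0, 1.0))
        size = 30.0
        polys = [square_contour(z, 10.25, 10.25, size) for z in (0.0, 3.0, 6.0)]
        path = tmp_path / "ss.json"
        path.write_text(json.dumps({"rois": {"GTV": polys}}))
        ss = parse_structure_set(path)
        mask = rasterize_contours(ss.rois["GTV"], grid)
        analytic_ml = size * size * 3.0 * 3 / 1000.0
        assert mask.volume_ml == pytest.approx(analytic_ml, rel=0.05)

    def test_mask_to_contours_round_trip(self, rng):
        grid = ImageGrid((6, 32, 32), (2.0, 1.0, 1.0))
        center = grid.center_mm
        coords = [
            grid.origin_mm[ax] + np.arange(grid.shape[ax]) * grid.spacing_mm[ax]
            for ax in range(3)
        ]
        dz, dy, dx = np.meshgrid(
            *(c - m for c, m in zip(coords, center)), indexing="ij"
        )
        ball = BinaryMask(grid, dz**2 + dy**2 + dx**2 <= 10.0**2)
        polys = mask_to_contours(ball)
        back = rasterize_contours(polys, grid)
        assert back.volume_ml == pytest.approx(ball.volume_ml, rel=0.05)


class TestCohortDirectory:
    def _tiny_cohort(self, rng):
        from ioa import CohortStructureSet, DelineationRecord

        grid = ImageGrid((6, 8, 8), (2, 1, 1))
        cohort = CohortStructureSet()
        for case in ("1", "2"):
            for obs in ("01", "02", "03"):
                for kind in ("GTV", "ITV"):
                    cohort.add(
                        DelineationRecord(case, obs, kind, random_mask(rng, grid))
                    )
        return cohort

    def test_write_load_round_trip_masks(self, rng, tmp_path):
        cohort = self._tiny_cohort(rng)
        write_cohort(cohort, tmp_path, fmt="masks")
        back = load_cohort(tmp_path, fmt="masks")
        assert len(back) == len(cohort)
        for rec in cohort:
            twin = [
                r
                for r in back
                if (r.case_id, r.observer_id, r.volume_kind)
                == (rec.case_id, rec.observer_id, rec.volume_kind)
            ]
            assert len(twin) == 1
            assert np.array_equal(twin[0].mask.voxels, rec.mask.voxels)

    def test_missing_submission_logged_and_omitted(self, rng, tmp_path, caplog):
        cohort = self._tiny_cohort(rng)
        write_cohort(cohort, tmp_path, fmt="masks")
        (tmp_path / "case_1" / "observer_02" / "GTV.nii.gz").unlink()
        with caplog.at_level("WARNING", logger="ioa.structure_io"):
            back = load_cohort(tmp_path)
        assert len(back) == len(cohort) - 1
        assert "no GTV submitted" in caplog.text

    def test_grid_mismatch_strict_vs_resample(self, rng, tmp_path):
        from ioa import GridMismatchError

        cohort = self._tiny_cohort(rng)
        write_cohort(cohort, tmp_path, fmt="masks")
        other = ImageGrid((6, 8, 8), (2, 1, 2))
        write_mask_volume(
            random_mask(rng, other), tmp_path / "case_1" / "observer_03" / "GTV.nii.gz"
        )
        with pytest.raises(GridMismatchError, match="'03'"):
            load_cohort(tmp_path, resample_policy="strict")
        back = load_cohort(tmp_path, resample_policy="to_first")
        back.validate_grids()

    def test_no_cases_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="no case"):
            load_cohort(tmp_path)
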
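"""Cell validation, counting frames, grain assignment, classification, densities."""

import numpy as np
import pytest

from grainstack.errors import GeometryError
from grainstack.geometry import AcquisitionGeometry
from grainstack.segmentation import segment_at
from grainstack.stereology import (
    CellRecord,
    CountingFrame,
    assign_grains_to_cells,
    cell_density,
    cells_from_labels,
    classify_sst_cells_20x,
    classify_sst_cells_60x,
    frame_contains_points,
    frame_filter,
    tissue_grain_density,
    validate_cell_mask,
)

from conftest import make_stack

GEOM = AcquisitionGeometry(
    n_x=100, n_y=100, n_z=20, dx=1.0, dy=1.0, dz=1.0, section_thickness=20.0
)


def _cell(coord_list, cell_id=1, n_z=20):
    labels = np.zeros((n_z, 100, 100), dtype=np.int16)
    for z, y, x in coord_list:
        labels[z, y, x] = cell_id
    return cells_from_labels(labels, GEOM)[0]


def _ball_cell(center_zyx, r, cell_id=1, n_z=20):
    labels = np.zeros((n_z, 100, 100), dtype=np.int16)
    zz, yy, xx = np.ogrid[:n_z, :100, :100]
    d2 = (zz - center_zyx[0]) ** 2 + (yy - center_zyx[1]) ** 2 + (xx - center_zyx[2]) ** 2
    labels[d2 <= r * r] = cell_id
    return cells_from_labels(labels, GEOM)[0]


class TestValidateCellMask:
    def test_well_formed_cell_accepted(self):
        cell = _ball_cell((6, 50, 50), 3)
        nuclear = np.zeros(GEOM.shape, dtype=bool)
        nuclear[6, 50, 50] = True
        ok, reasons = validate_cell_mask(cell, nuclear, GEOM.n_z)
        assert ok and reasons == []

    def test_center_on_boundary_plane_rejected(self):
        cell = _ball_cell((0, 50, 50), 3)  # largest cross-section at plane 0
        nuclear = np.ones(GEOM.shape, dtype=bool)
        ok, reasons = validate_cell_mask(cell, nuclear, GEOM.n_z)
        assert not ok
        assert "center on boundary plane" in reasons

    def test_missing_nucleus_rejected(self):
        cell = _ball_cell((6, 50, 50), 3)
        ok, reasons = validate_cell_mask(cell, np.zeros(GEOM.shape, bool), GEOM.n_z)
        assert not ok
        assert any("nuclear" in r for r in reasons)

    def test_too_few_planes_rejected(self):
        cell = _cell([(5, 50, 50), (5, 50, 51), (6, 50, 50)])
        nuclear = np.ones(GEOM.shape, dtype=bool)
        ok, reasons = validate_cell_mask(cell, nuclear, GEOM.n_z, min_z_planes=3)
        assert not ok

    def test_center_plane_is_largest_area_plane(self):
        cell = _ball_cell((10, 40, 40), 4)
        assert cell.center_plane == 10
        assert cell.z_extent == (6, 14)


class TestCountingFrame:
    def test_point_strictly_inside_included(self):
        frame = CountingFrame(10, 10, 20, 20)
        assert frame_contains_points(frame, [[15.0, 15.0]])

    def test_point_on_exclusion_edge_excluded(self):
        frame = CountingFrame(10, 10, 20, 20)
        assert not frame_contains_points(frame, [[10.0, 15.0]])  # left edge
        assert not frame_contains_points(frame, [[15.0, 10.0]])  # bottom edge

    def test_object_touching_only_inclusion_edge_included(self):
        frame = CountingFrame(10, 10, 20, 20)
        pts = [[29.0, 30.0], [29.0, 31.5]]  # crosses the top edge
        assert frame_contains_points(frame, np.array(pts))

    def test_object_crossing_exclusion_extension_excluded(self):
        frame = CountingFrame(10, 10, 20, 20)
        # dips below the frame across the bottom-right downward extension
        pts = [[15.0, 12.0], [15.0, 9.0]]
        assert not frame_contains_points(frame, np.array(pts))

    def test_frame_outside_field_rejected(self):
        frame = CountingFrame(90, 90, 20, 20)
        with pytest.raises(GeometryError):
            frame.check_inside_field(GEOM)

    def test_mirrored_convention(self):
        frame = CountingFrame(10, 10, 20, 20, exclusion_edges=("right", "top"))
        assert not frame_contains_points(frame, [[30.0, 15.0]])
        assert frame_contains_points(frame, [[10.0, 15.0]])

    def test_unbiased_count_for_uniform_points(self, rng):
        """Mean included count over random frame placements equals
        density x frame area within 3 standard errors."""
        field = 100.0
        frame_w = 30.0
        n_points = 300
        counts = []
        for _ in range(400):
            pts = rng.uniform(0, field, size=(n_points, 2))
            ox, oy = rng.uniform(0, field - frame_w, size=2)
            frame = CountingFrame(ox, oy, frame_w, frame_w)
            kept = frame_filter(list(pts[:, None, :]), frame, 1.0, 1.0)
            counts.append(len(kept))
        expected = n_points / field**2 * frame_w**2
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) <= 3 * se


class TestAssignGrains:
    def _grains(self, voxels, shape=(20, 100, 100)):
        values = np.zeros(shape)
        for group in voxels:
            for v in group:
                values[v] = 10
        return segment_at(make_stack(values, dx=1, dy=1, dz=1), 1.0)

    def test_grain_inside_single_cell(self):
        cell = _ball_cell((6, 50, 50), 3)
        grains = self._grains([[(6, 50, 50)]])
        cells, unassigned = assign_grains_to_cells(grains, [cell])
        assert cells[0].grain_count == 1 and unassigned == []

    def test_grain_touching_no_cell_unassigned(self):
        cell = _ball_cell((6, 50, 50), 3)
        grains = self._grains([[(15, 10, 10)]])
        cells, unassigned = assign_grains_to_cells(grains, [cell])
        assert cells[0].grain_count == 0 and len(unassigned) == 1

    def test_largest_overlap_wins(self):
        labels = np.zeros((20, 100, 100), dtype=np.int16)
        labels[5, 10, 10:18] = 1  # cell 1 owns 3 voxels of the grain
        labels[5, 10, 18:30] = 2  # cell 2 owns 5 voxels
        cells = cells_from_labels(labels, GEOM)
        grains = self._grains([[(5, 10, x) for x in range(15, 23)]])
        cells, unassigned = assign_grains_to_cells(grains, cells)
        by_id = {c.cell_id: c.grain_count for c in cells}
        assert by_id == {1: 0, 2: 1} and unassigned == []

    def test_conservation(self, rng):
        labels = np.zeros((20, 100, 100), dtype=np.int16)
        labels[4:9, 20:40, 20:40] = 1
        labels[10:15, 60:80, 60:80] = 2
        cells = cells_from_labels(labels, GEOM)
        values = (rng.uniform(size=(20, 100, 100)) < 0.01).astype(float)
        grains = segment_at(make_stack(values, dx=1, dy=1, dz=1), 0.5)
        cells, unassigned = assign_grains_to_cells(grains, cells)
        assert sum(c.grain_count for c in cells) + len(unassigned) == len(grains)


class TestClassification:
    def _cells_with_counts(self, counts):
        out = []
        for i, c in enumerate(counts, 1):
            cell = CellRecord(cell_id=i, coords=np.zeros((1, 3), int),
                              z_extent=(0, 0), center_plane=0)
            cell.grain_count = c
            out.append(cell)
        return out

    @pytest.mark.parametrize("count,expected", [(20, True), (19, False), (0, False)])
    def test_60x_grain_rule_boundary(self, count, expected):
        cell = self._cells_with_counts([count])[0]
        classify_sst_cells_60x([cell])
        assert cell.sst_class is expected

    def test_monotonicity_adding_grains(self):
        cells = self._cells_with_counts(list(range(0, 40)))
        classify_sst_cells_60x(cells)
        flags = [c.sst_class for c in cells]
        assert flags == sorted(flags)

    def _grain_objects(self, centroids_um):
        from grainstack.segmentation import LabeledObjectSet, SegmentedObject

        objects = [
            SegmentedObject(id=i, coords=np.zeros((1, 3), int), voxel_count=1,
                            volume_um3=0.05, centroid_um=np.asarray(c, float))
            for i, c in enumerate(centroids_um, 1)
        ]
        return LabeledObjectSet(objects, shape=(20, 100, 100), voxel_size=(1, 1, 1))

    def test_20x_ten_separated_objects_positive(self):
        centroids = [(5.0 * i, 0.0, 0.0) for i in range(10)]
        grains = self._grain_objects(centroids)
        cell = self._cells_with_counts([0])[0]
        cell.grain_ids = list(range(1, 11))
        classify_sst_cells_20x([cell], grains, min_clusters=10, cluster_link_radius_um=1.5)
        assert cell.cluster_count == 10 and cell.sst_class

    def test_20x_nine_clusters_negative(self):
        centroids = [(5.0 * i, 0.0, 0.0) for i in range(9)]
        grains = self._grain_objects(centroids)
        cell = self._cells_with_counts([0])[0]
        cell.grain_ids = list(range(1, 10))
        classify_sst_cells_20x([cell], grains)
        assert cell.cluster_count == 9 and not cell.sst_class

    def test_20x_touching_pairs_merge_by_single_linkage(self):
        """Twelve objects forming six pairs at 0.8 um -> six clusters."""
        centroids = []
        for i in range(6):
            centroids.append((10.0 * i, 0.0, 0.0))
            centroids.append((10.0 * i + 0.8, 0.0, 0.0))
        grains = self._grain_objects(centroids)
        cell = self._cells_with_counts([0])[0]
        cell.grain_ids = list(range(1, 13))
        classify_sst_cells_20x([cell], grains, min_clusters=10, cluster_link_radius_um=1.0)
        assert cell.cluster_count == 6 and not cell.sst_class


class TestDensities:
    def test_cell_density_arithmetic(self):
        frame = CountingFrame(0, 0, 250, 250)
        out = cell_density([5], [frame], thickness_um=14.0)
        assert out.density_per_mm3 == pytest.approx(5 / 8.75e-4, rel=1e-12)

    def test_zero_cells_zero_density(self):
        out = cell_density([0, 0], [CountingFrame(0, 0, 68, 68)] * 2, 14.0)
        assert out.density_per_mm3 == 0.0

    def test_density_invariant_to_replication(self):
        frame = CountingFrame(0, 0, 68, 68)
        one = cell_density([4], [frame], 14.0)
        two = cell_density([4, 4], [frame, frame], 14.0)
        assert one.density_per_mm3 == pytest.approx(two.density_per_mm3)

    def test_zero_reference_volume_rejected(self):
        with pytest.raises(ValueError):
            cell_density([1], [CountingFrame(0, 0, 68, 68)], 0.0)

    def test_tissue_grain_density_arithmetic(self):
        geom = AcquisitionGeometry(
            n_x=1024, n_y=1024, n_z=57, dx=111 / 1024, dy=111 / 1024, dz=0.25,
            section_thickness=14.0,
        )
        out = tissue_grain_density([100], geom)
        assert out.density_per_mm3 == pytest.approx(100 / (111 * 111 * 14 * 1e-9), rel=1e-12)

    def test_tissue_grain_density_pooling_and_empty(self):
        geom = GEOM
        assert tissue_grain_density([0], geom).density_per_mm3 == 0.0
        one = tissue_grain_density([7], geom)
        two = tissue_grain_density([7, 7], geom)
        assert one.density_per_mm3 == pytest.approx(two.density_per_mm3)
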
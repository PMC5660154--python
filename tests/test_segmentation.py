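"""Segmentation primitives against independent oracles and hand-built fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grainstack.errors import DegenerateInputError, GeometryError
from grainstack.segmentation import (
    DoGParams,
    GateParams,
    dog_filter,
    exclude_overlapping,
    fixed_normalized_threshold,
    gate_voxel_range,
    iterative_grain_segmentation,
    normalize_exposure,
    ridler_calvard_threshold,
    segment_at,
)
from grainstack.geometry import preset_60x

from conftest import make_stack
from oracles import discrete_dog_center_value, flood_fill_count, isodata_fixed_points


# ---------------------------------------------------------------------------
# difference of Gaussians
# ---------------------------------------------------------------------------

class TestDoG:
    def test_constant_stack_maps_to_zero(self):
        stack = make_stack(np.full((8, 8, 8), 37.5), dx=0.1, dy=0.1, dz=0.1)
        out = dog_filter(stack)
        assert np.allclose(out.intensities, 0.0, atol=1e-9)

    def test_impulse_center_matches_discrete_kernel(self):
        """Unit impulse response at the centre equals the central coefficient
        of the separable discrete DoG kernel (cubic voxels)."""
        values = np.zeros((15, 15, 15))
        values[7, 7, 7] = 1.0
        stack = make_stack(values, dx=0.1, dy=0.1, dz=0.1)
        out = dog_filter(stack, DoGParams(0.7, 2.0))
        expected = discrete_dog_center_value(0.7, 2.0)
        assert out.intensities[7, 7, 7] == pytest.approx(expected, rel=1e-9)

    def test_default_sigmas(self):
        assert (DoGParams().sigma_small, DoGParams().sigma_large) == (0.7, 2.0)

    def test_rejects_non_increasing_sigmas(self):
        with pytest.raises(ValueError):
            DoGParams(2.0, 0.7)

    def test_linearity(self, rng):
        x = rng.normal(size=(10, 12, 14)) * 100
        y = rng.normal(size=(10, 12, 14)) * 100
        a, b = 2.5, -0.75
        sx = make_stack(x)
        sy = make_stack(y)
        lhs = dog_filter(make_stack(a * x + b * y)).intensities
        rhs = a * dog_filter(sx).intensities + b * dog_filter(sy).intensities
        scale = np.ptp(lhs) or 1.0
        assert np.allclose(lhs, rhs, atol=1e-6 * scale)

    def test_preserves_voxel_metadata(self):
        stack = make_stack(np.random.default_rng(0).normal(size=(6, 6, 6)),
                           dx=0.11, dy=0.12, dz=0.4, exposure_ms=7.0)
        out = dog_filter(stack)
        assert (out.dx, out.dy, out.dz, out.exposure_ms) == (0.11, 0.12, 0.4, 7.0)


# ---------------------------------------------------------------------------
# Ridler-Calvard threshold
# ---------------------------------------------------------------------------

class TestRidlerCalvard:
    def test_two_level_image_midpoint(self):
        stack = make_stack(np.array([0, 0, 0, 100, 100], dtype=float).reshape(1, 1, 5))
        assert ridler_calvard_threshold(stack) == pytest.approx(50.0, abs=0.5)

    def test_symmetric_two_level_case(self):
        stack = make_stack(np.array([10, 10, 20, 20], dtype=float).reshape(1, 2, 2))
        assert ridler_calvard_threshold(stack) == pytest.approx(15.0, abs=0.5)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            ridler_calvard_threshold(make_stack(np.full((4, 4, 4), 9.0)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_fixed_point_search(self, seed):
        """Agreement within one intensity level with a brute-force scan of
        all 256 candidate thresholds on random 8-bit volumes."""
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, size=(32, 32, 32)).astype(float)
        ours = ridler_calvard_threshold(make_stack(values))
        fixed = isodata_fixed_points(values)
        assert fixed, "oracle found no fixed point"
        assert min(abs(ours - t) for t in fixed) <= 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.integers(0, 255), min_size=8, max_size=64).filter(
            lambda v: len(set(v)) > 1
        )
    )
    def test_threshold_lies_strictly_between_class_extremes(self, values):
        arr = np.asarray(values, dtype=float).reshape(1, 1, -1)
        t = ridler_calvard_threshold(make_stack(arr))
        assert min(values) < t < max(values)

    def test_agrees_with_skimage_isodata(self, rng):
        from skimage.filters import threshold_isodata

        values = np.concatenate(
            [rng.normal(40, 8, 4000), rng.normal(180, 20, 1000)]
        ).clip(0, 255).round()
        ours = ridler_calvard_threshold(make_stack(values.reshape(50, 10, 10)))
        ref = threshold_isodata(values.astype(np.uint8))
        assert abs(ours - ref) <= 2.0


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

class TestSegmentAt:
    def test_empty_above_threshold(self):
        assert len(segment_at(make_stack(np.zeros((4, 4, 4))), 1.0)) == 0

    def test_face_sharing_voxels_form_one_object(self):
        values = np.zeros((4, 4, 4))
        values[1, 1, 1] = values[1, 1, 2] = 5
        assert len(segment_at(make_stack(values), 1.0, connectivity=26)) == 1
        assert len(segment_at(make_stack(values), 1.0, connectivity=6)) == 1

    def test_corner_sharing_voxels_split_under_face_connectivity(self):
        values = np.zeros((4, 4, 4))
        values[1, 1, 1] = values[2, 2, 2] = 5
        assert len(segment_at(make_stack(values), 1.0, connectivity=26)) == 1
        assert len(segment_at(make_stack(values), 1.0, connectivity=6)) == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("density", [0.1, 0.3, 0.5])
    def test_component_count_matches_flood_fill(self, connectivity, density, rng):
        mask = rng.uniform(size=(16, 16, 16)) < density
        objects = segment_at(make_stack(mask.astype(float)), 0.5, connectivity)
        assert len(objects) == flood_fill_count(mask, connectivity)
        assert objects.total_voxels() == int(mask.sum())

    def test_deterministic_lexicographic_labeling(self, rng):
        mask = rng.uniform(size=(12, 12, 12)) < 0.2
        objects = segment_at(make_stack(mask.astype(float)), 0.5)
        firsts = [tuple(o.coords[np.lexsort(o.coords.T[::-1])][0]) for o in objects]
        assert firsts == sorted(firsts)
        assert [o.id for o in objects] == list(range(1, len(objects) + 1))

    def test_volume_equals_count_times_voxel_volume(self):
        values = np.zeros((4, 4, 4))
        values[0, 0, :3] = 9
        obj = segment_at(make_stack(values, dx=0.1, dy=0.1, dz=0.3), 1.0).objects[0]
        assert obj.volume_um3 == pytest.approx(3 * 0.003)


# ---------------------------------------------------------------------------
# iterative volume-gated segmentation
# ---------------------------------------------------------------------------

def _two_blob_fixture():
    """One 20-voxel uniform blob (in gate at T0) and one 70-voxel graded blob
    that shrinks into the gate only at T0 + 2 steps.

    Voxels are 0.003 um^3, so the 0.03-0.1 um^3 gate is 10..33 voxels.
    Blob B: 15 voxels @ 400 (z=8), 15 @ 210 (z=9), 40 @ 160 (z=7); at
    T0 ~ 131 all 70 are foreground (oversized), at T0+25 still 70, at T0+50
    the 30 voxels >= 180 remain, which is inside the gate.
    """
    values = np.zeros((16, 16, 16))
    values[3, 2:6, 2:7] = 400.0  # blob A: 20 voxels
    values[8, 8:11, 8:13] = 400.0  # B core: 15
    values[9, 8:11, 8:13] = 210.0  # B shell 1: 15
    values[7, 8:13, 8:16] = 160.0  # B shell 2: 40
    return make_stack(values, dx=0.1, dy=0.1, dz=0.3)


class TestIterativeSegmentation:
    def test_all_zero_stack_yields_empty_set(self):
        with pytest.warns(UserWarning):
            out = iterative_grain_segmentation(make_stack(np.zeros((6, 6, 6))))
        assert len(out) == 0

    def test_two_blob_fixture_accepting_thresholds(self):
        stack = _two_blob_fixture()
        t0 = ridler_calvard_threshold(make_stack(np.clip(stack.intensities, 0, None),
                                                 dx=0.1, dy=0.1, dz=0.3))
        assert t0 == pytest.approx(130.8, abs=1.5)  # (0 + 261.7) / 2 by hand
        out = iterative_grain_segmentation(stack, GateParams())
        assert len(out) == 2
        by_thr = sorted(out.objects, key=lambda o: o.threshold)
        assert by_thr[0].threshold == pytest.approx(t0, abs=1e-9)
        assert by_thr[1].threshold == pytest.approx(t0 + 2 * 25.0, abs=1e-9)
        assert by_thr[0].voxel_count == 20
        assert by_thr[1].voxel_count == 30

    def test_60x_preset_gate_is_11_to_34_voxels(self):
        geom = preset_60x()
        assert gate_voxel_range(geom, GateParams()) == (11, 34)

    def test_gate_compliance_and_disjointness(self, rng):
        from scipy import ndimage as ndi

        raw = ndi.gaussian_filter(rng.normal(size=(24, 48, 48)), 1.2)
        stack = make_stack(1000 * (raw - raw.min()), dx=0.1, dy=0.1, dz=0.3)
        out = iterative_grain_segmentation(stack, GateParams())
        assert len(out) > 0
        for obj in out:
            assert 0.03 <= obj.volume_um3 <= 0.1
        label = out.label_volume()
        assert out.total_voxels() == int((label > 0).sum())  # pairwise disjoint
        # total accepted voxels never exceed the foreground at T0
        clamped = np.clip(stack.intensities, 0, None)
        t0 = ridler_calvard_threshold(make_stack(clamped, dx=0.1, dy=0.1, dz=0.3))
        assert out.total_voxels() <= int((clamped >= t0).sum())

    def test_raising_v_max_never_loses_grains(self, rng):
        from scipy import ndimage as ndi

        raw = ndi.gaussian_filter(rng.normal(size=(24, 48, 48)), 1.2)
        stack = make_stack(1000 * (raw - raw.min()), dx=0.1, dy=0.1, dz=0.3)
        narrow = iterative_grain_segmentation(stack, GateParams(v_min=0.03, v_max=0.08))
        wide = iterative_grain_segmentation(stack, GateParams(v_min=0.03, v_max=0.12))
        assert len(wide) >= len(narrow)

    def test_unresolvable_gate_warns(self):
        """At 20x pixel pitch a 0.03-0.1 um^3 grain is below one voxel."""
        from grainstack.geometry import preset_20x

        geom = preset_20x(64, 6)
        values = np.zeros(geom.shape)
        values[3, 30:32, 30:32] = 500.0
        stack = make_stack(values, dx=geom.dx, dy=geom.dy, dz=geom.dz)
        with pytest.warns(UserWarning, match="voxel gate"):
            iterative_grain_segmentation(stack)


# ---------------------------------------------------------------------------
# lipofuscin exclusion
# ---------------------------------------------------------------------------

class TestExcludeOverlapping:
    def _sets(self, grain_vox, lipo_vox, shape=(6, 6, 6)):
        g = np.zeros(shape)
        for v in grain_vox:
            g[v] = 10
        l = np.zeros(shape)
        for v in lipo_vox:
            l[v] = 10
        grains = segment_at(make_stack(g), 1.0)
        lipo = segment_at(make_stack(l), 1.0)
        return grains, lipo

    def test_single_shared_voxel_removes_grain(self):
        grains, lipo = self._sets([(1, 1, 1), (1, 1, 2)], [(1, 1, 2)])
        assert len(exclude_overlapping(grains, lipo)) == 0

    def test_disjoint_sets_unchanged(self):
        grains, lipo = self._sets([(1, 1, 1)], [(4, 4, 4)])
        out = exclude_overlapping(grains, lipo)
        assert len(out) == 1
        assert out.objects[0].voxel_count == 1

    def test_full_coverage_empties_grains(self):
        g = np.zeros((4, 4, 4))
        g[2, 2, 2] = 10
        grains = segment_at(make_stack(g), 1.0)
        lipo = segment_at(make_stack(np.full((4, 4, 4), 10.0)), 1.0)
        assert len(exclude_overlapping(grains, lipo)) == 0

    def test_survivors_share_zero_voxels(self, rng):
        g = (rng.uniform(size=(10, 10, 10)) < 0.1).astype(float)
        l = (rng.uniform(size=(10, 10, 10)) < 0.1).astype(float)
        grains = segment_at(make_stack(g), 0.5)
        lipo = segment_at(make_stack(l), 0.5)
        out = exclude_overlapping(grains, lipo)
        assert not np.any(out.mask() & lipo.mask())

    def test_mismatched_geometry_rejected(self):
        grains, _ = self._sets([(1, 1, 1)], [])
        _, lipo = self._sets([], [(1, 1, 1)], shape=(5, 5, 5))
        with pytest.raises(GeometryError):
            exclude_overlapping(grains, lipo)


# ---------------------------------------------------------------------------
# fixed normalized threshold and exposure normalization
# ---------------------------------------------------------------------------

class TestFixedNormalizedThreshold:
    def test_fraction_zero_takes_everything(self, rng):
        values = rng.uniform(1, 9, size=(4, 4, 4))
        out = fixed_normalized_threshold(make_stack(values), 0.0)
        assert out.total_voxels() == values.size

    def test_fraction_one_keeps_only_maxima(self):
        values = np.zeros((3, 3, 3))
        values[1, 1, 1] = 7
        out = fixed_normalized_threshold(make_stack(values), 1.0)
        assert out.total_voxels() == 1

    def test_midpoint_on_binary_values(self):
        values = np.zeros((2, 2, 2))
        values[0, 0, 0] = 100
        out = fixed_normalized_threshold(make_stack(values), 0.5)
        assert out.total_voxels() == 1

    def test_constant_stack_rejected(self):
        with pytest.raises(DegenerateInputError):
            fixed_normalized_threshold(make_stack(np.ones((3, 3, 3))), 0.5)


class TestNormalizeExposure:
    def test_counts_per_ms(self):
        stack = make_stack(np.full((2, 2, 2), 500.0), exposure_ms=100.0)
        out = normalize_exposure(stack)
        assert np.allclose(out.intensities, 5.0)
        assert out.exposure_ms == 1.0

    def test_unit_exposure_is_identity(self, rng):
        values = rng.uniform(size=(3, 3, 3))
        out = normalize_exposure(make_stack(values, exposure_ms=1.0))
        assert np.allclose(out.intensities, values)

    def test_proportional_scenes_agree_after_normalization(self, rng):
        scene = rng.uniform(1, 10, size=(4, 4, 4))
        short = make_stack(scene * 50, exposure_ms=50.0)
        long = make_stack(scene * 100, exposure_ms=100.0)
        assert np.allclose(
            normalize_exposure(short).intensities,
            normalize_exposure(long).intensities,
            rtol=1e-12,
        )

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            normalize_exposure(make_stack(np.ones((2, 2, 2)), exposure_ms=0.0))
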
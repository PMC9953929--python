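"""Patch-grid planning, extraction, coverage, and box-distance Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchcascade.patches import (
    GridPlan,
    PatchSpec,
    coverage_mask,
    extract_patches,
    filter_foreground_specs,
    mean_pairwise_distance_mc,
    plan_axis_positions,
    plan_grid,
    roi_patch_specs,
)
from patchcascade.volume import Volume

VOLUME_SHAPE = (91, 115, 91)


class TestAxisPositions:
    @pytest.mark.parametrize(
        "extent,patch,count,expected",
        [
            (91, 48, 2, [0, 43]),
            (115, 48, 3, [0, 33, 67]),  # middle = round-half-down(33.5)
            (91, 91, 1, [0]),
            (115, 25, 6, [0, 18, 36, 54, 72, 90]),
            (91, 64, 2, [0, 27]),
            (115, 64, 2, [0, 51]),
        ],
    )
    def test_known_layouts(self, extent, patch, count, expected):
        assert plan_axis_positions(extent, patch, count) == expected

    def test_single_window_must_span_axis(self):
        with pytest.raises(ValueError):
            plan_axis_positions(91, 48, 1)

    def test_impossible_coverage_rejected(self):
        with pytest.raises(ValueError):
            plan_axis_positions(115, 32, 3)  # 3*32 < 115

    @settings(max_examples=100, deadline=None)
    @given(
        extent=st.integers(4, 200),
        patch=st.integers(2, 200),
        count=st.integers(2, 8),
    )
    def test_endpoints_and_coverage_property(self, extent, patch, count):
        if patch > extent:
            return
        try:
            offsets = plan_axis_positions(extent, patch, count)
        except ValueError:
            assert patch * count < extent or max(
                np.diff(
                    plan_axis_positions(extent, patch, count, require_coverage=False)
                )
            ) > patch
            return
        assert offsets[0] == 0
        assert offsets[-1] == extent - patch
        assert all(b >= a for a, b in zip(offsets, offsets[1:]))
        covered = np.zeros(extent, dtype=bool)
        for o in offsets:
            covered[o : o + patch] = True
        assert covered.all()


class TestGridPlans:
    @pytest.mark.parametrize(
        "patch,counts,n_expected",
        [
            ((48, 48, 48), (2, 3, 2), 12),
            ((64, 64, 64), (2, 2, 2), 8),
            ((91, 25, 91), (1, 6, 1), 6),
        ],
    )
    def test_published_plans_count_and_cover(self, patch, counts, n_expected):
        plan = plan_grid(VOLUME_SHAPE, patch, counts)
        assert len(plan) == n_expected
        assert coverage_mask(VOLUME_SHAPE, plan.specs).all()

    def test_slab_plan_varies_on_coronal_axis_only(self):
        plan = plan_grid(VOLUME_SHAPE, (91, 25, 91), (1, 6, 1))
        starts = {s.start for s in plan.specs}
        assert all(s[0] == 0 and s[2] == 0 for s in starts)
        assert len({s[1] for s in starts}) == 6

    def test_specs_sorted_lexicographically(self):
        plan = plan_grid(VOLUME_SHAPE, (48, 48, 48), (2, 3, 2))
        starts = [s.start for s in plan.specs]
        assert starts == sorted(starts)

    def test_axis_error_names_axis(self):
        with pytest.raises(ValueError, match="axis 1"):
            plan_grid(VOLUME_SHAPE, (48, 32, 48), (2, 3, 2))

    def test_noncovering_counts_allowed_when_relaxed(self):
        plan = plan_grid(VOLUME_SHAPE, (32, 32, 32), (3, 3, 3), require_coverage=False)
        assert len(plan) == 27
        assert not coverage_mask(VOLUME_SHAPE, plan.specs).all()

    def test_json_round_trip(self, tmp_path):
        plan = plan_grid(VOLUME_SHAPE, (48, 48, 48), (2, 3, 2))
        plan.save(tmp_path / "plan.json")
        assert GridPlan.load(tmp_path / "plan.json") == plan


class TestRoiSpecs:
    def test_mirrored_rois_in_bounds(self):
        specs = roi_patch_specs([(30, 57, 38), (60, 57, 38)], (64, 64, 64), VOLUME_SHAPE)
        assert len(specs) == 2
        assert all(s.shape == (64, 64, 64) for s in specs)
        assert all(s.in_bounds(VOLUME_SHAPE) for s in specs)

    def test_corner_center_clamps_to_origin(self):
        (spec,) = roi_patch_specs([(0, 0, 0)], (16, 16, 16), (32, 32, 32))
        assert spec.start == (0, 0, 0)

    def test_center_patch_equal_to_volume_is_identity(self):
        (spec,) = roi_patch_specs([(45, 57, 45)], VOLUME_SHAPE, VOLUME_SHAPE)
        assert spec.start == (0, 0, 0)
        assert spec.shape == VOLUME_SHAPE

    def test_patch_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            roi_patch_specs([(5, 5, 5)], (64, 64, 64), (32, 32, 32))

    def test_center_outside_volume_rejected(self):
        with pytest.raises(ValueError):
            roi_patch_specs([(100, 5, 5)], (8, 8, 8), (32, 32, 32))


class TestExtraction:
    def test_full_spec_copies_volume(self):
        v = Volume(np.arange(60).reshape(3, 4, 5).astype(np.float32))
        (out,) = extract_patches(v, [PatchSpec((0, 0, 0), (3, 4, 5))])
        np.testing.assert_array_equal(out.data, v.data)
        out.data[0, 0, 0] = -1  # a copy, not a view
        assert v.data[0, 0, 0] == 0

    def test_every_voxel_value_appears_in_some_patch(self):
        """Coverage audit by value membership on a volume of its own voxel index."""
        v = Volume(np.arange(np.prod(VOLUME_SHAPE)).reshape(VOLUME_SHAPE) % 8191)
        plan = plan_grid(VOLUME_SHAPE, (48, 48, 48), (2, 3, 2))
        patches = extract_patches(v, plan.specs)
        covered = coverage_mask(VOLUME_SHAPE, plan.specs)
        assert covered.all()
        union = set()
        for p in patches:
            union.update(np.unique(p.data).tolist())
        assert union == set(np.unique(v.data).tolist())

    def test_overlap_region_identical_in_both_patches(self):
        v = Volume(np.random.default_rng(0).random((20, 20, 20)))
        s1, s2 = PatchSpec((0, 0, 0), (12, 12, 12)), PatchSpec((6, 6, 6), (12, 12, 12))
        p1, p2 = extract_patches(v, [s1, s2])
        np.testing.assert_array_equal(p1.data[6:, 6:, 6:], p2.data[:6, :6, :6])

    def test_out_of_bounds_spec_reports_index(self):
        v = Volume(np.zeros((10, 10, 10)))
        with pytest.raises(ValueError, match="spec 1"):
            extract_patches(v, [PatchSpec((0, 0, 0), (5, 5, 5)), PatchSpec((8, 0, 0), (5, 5, 5))])

    def test_foreground_filter_drops_background_patches(self):
        data = np.zeros((20, 20, 20), dtype=np.float32)
        data[:10] = 1.0
        v = Volume(data)
        specs = [PatchSpec((0, 0, 0), (10, 20, 20)), PatchSpec((10, 0, 0), (10, 20, 20))]
        assert filter_foreground_specs(v, specs, 0.0) == specs
        assert filter_foreground_specs(v, specs, 0.5) == [specs[0]]


class TestMeanPairwiseDistance:
    def test_unit_cube_constant(self):
        # mean distance between two uniform points in the unit cube = 0.661707...
        mean, se = mean_pairwise_distance_mc((1, 1, 1), 1.0, 2_000_000, seed=7)
        assert mean == pytest.approx(0.6617072, abs=4 * se)

    def test_deterministic_given_seed(self):
        a = mean_pairwise_distance_mc((5, 3, 2), 1.5, 10_000, seed=42)
        b = mean_pairwise_distance_mc((5, 3, 2), 1.5, 10_000, seed=42)
        assert a == b

    def test_scale_equivariance_exact_under_same_seed(self):
        m1, _ = mean_pairwise_distance_mc((4, 4, 4), 1.0, 50_000, seed=9)
        m2, _ = mean_pairwise_distance_mc((4, 4, 4), 2.5, 50_000, seed=9)
        assert m2 == pytest.approx(2.5 * m1, rel=1e-12)

    def test_degenerate_box_reduces_to_1d_mean(self):
        # E|U-U'| on a segment of length a is a/3
        mean, se = mean_pairwise_distance_mc((12, 0, 0), 1.0, 400_000, seed=3)
        assert mean == pytest.approx(4.0, abs=4 * se)

    def test_fully_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_distance_mc((0, 0, 0), 1.0, 100, seed=0)
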
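"""Group DMN inference: z-averaging, thresholding, strength comparison."""
import numpy as np
import pytest
from scipy import stats

import seedconn as sc
from seedconn.group import (
    bonferroni_alpha,
    compare_strength,
    count_pixels,
    dmn_histogram,
    group_mean_map,
    one_sample_threshold,
    reported_threshold,
    welch_ttest,
)

from conftest import maps_from_z


class TestBonferroni:
    def test_family_of_nine_reports_0056(self):
        assert bonferroni_alpha(0.05, 9) == pytest.approx(0.05 / 9)
        assert reported_threshold(0.05, 9) == 0.0056

    def test_family_of_eight_reports_0062(self):
        assert bonferroni_alpha(0.05, 8) == 0.00625
        assert reported_threshold(0.05, 8) == 0.0062

    def test_identity_family(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 9)


class TestGroupMeanMap:
    def test_equal_subject_values_pass_through(self):
        maps = maps_from_z(np.full((3, 2, 2, 1), np.arctanh(0.3)))
        mean_r, valid = group_mean_map(maps)
        assert np.allclose(mean_r, 0.3, atol=1e-12)
        assert valid.all()

    def test_two_subject_average_in_z_space(self):
        z = np.stack([np.full((1, 1, 1), np.arctanh(0.2)),
                      np.full((1, 1, 1), np.arctanh(0.4))])
        mean_r, _ = group_mean_map(maps_from_z(z))
        # oracle: tanh((atanh 0.2 + atanh 0.4) / 2) = 0.303337...
        assert round(float(mean_r[0, 0, 0]), 4) == 0.3033

    def test_odd_symmetry(self):
        z = np.stack([np.full((1, 1, 1), np.arctanh(0.5)),
                      np.full((1, 1, 1), -np.arctanh(0.5))])
        mean_r, _ = group_mean_map(maps_from_z(z))
        assert mean_r[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_voxels_valid_in_under_two_subjects_marked_invalid(self):
        z = np.zeros((3, 2, 1, 1))
        valid = np.ones((3, 2, 1, 1), dtype=bool)
        valid[1:, 0, 0, 0] = False  # voxel valid in only one subject
        _, ok = group_mean_map(maps_from_z(z, valid))
        assert not ok[0, 0, 0] and ok[1, 0, 0]

    def test_z_averaging_never_below_arithmetic_mean_for_positive_r(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0.05, 0.95, size=(9, 4, 4, 2))
        maps = maps_from_z(np.arctanh(r))
        mean_r, _ = group_mean_map(maps)
        assert np.all(mean_r >= r.mean(axis=0) - 1e-12)


class TestOneSampleThreshold:
    def test_values_symmetric_around_null_give_half_p(self):
        z0 = np.arctanh(0.3)
        z = np.stack([np.full((1, 1, 1), z0 + d) for d in (-0.2, -0.1, 0.1, 0.2)])
        g = one_sample_threshold(maps_from_z(z), r0=0.3)
        assert g.t_map[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert g.p_map[0, 0, 0] == pytest.approx(0.5, abs=1e-12)
        assert not g.dmn_mask[0, 0, 0]

    def test_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0.5, 0.05, size=(9, 1, 1, 1))
        g = one_sample_threshold(maps_from_z(z), r0=0.3, family_size=9)
        t_ref, p_ref = stats.ttest_1samp(
            z[:, 0, 0, 0], np.arctanh(0.3), alternative="greater"
        )
        assert g.t_map[0, 0, 0] == pytest.approx(t_ref, abs=1e-6)
        assert g.p_map[0, 0, 0] == pytest.approx(p_ref, abs=1e-6)
        assert g.dmn_mask[0, 0, 0]  # well above the 0.0056 threshold
        assert g.pixel_count == 1

    def test_zero_spread_voxels_get_degenerate_p(self):
        above = maps_from_z(np.full((5, 1, 1, 1), 1.0))
        below = maps_from_z(np.full((5, 1, 1, 1), 0.0))
        assert one_sample_threshold(above).p_map[0, 0, 0] == 0.0
        assert one_sample_threshold(below).p_map[0, 0, 0] == 1.0

    def test_r_space_variant(self):
        rng = np.random.default_rng(2)
        r = rng.normal(0.5, 0.05, size=(9, 1, 1, 1)).clip(-0.99, 0.99)
        g = one_sample_threshold(maps_from_z(np.arctanh(r)), r0=0.3, space="r")
        t_ref, p_ref = stats.ttest_1samp(r[:, 0, 0, 0], 0.3, alternative="greater")
        assert g.t_map[0, 0, 0] == pytest.approx(t_ref, abs=1e-6)
        assert g.p_map[0, 0, 0] == pytest.approx(p_ref, abs=1e-6)

    def test_mean_r_must_exceed_r0_for_inclusion(self):
        # tiny spread far below r0: p ~ 1, never included
        rng = np.random.default_rng(3)
        z = rng.normal(0.0, 0.01, size=(9, 1, 1, 1))
        g = one_sample_threshold(maps_from_z(z), r0=0.3)
        assert g.pixel_count == 0


class TestHistogram:
    def test_counts_sum_to_pixel_count(self):
        rng = np.random.default_rng(4)
        mean_r = rng.uniform(0.3, 0.9, size=(5, 2, 1))
        mask = np.ones((5, 2, 1), dtype=bool)
        counts, _ = dmn_histogram(mean_r, mask)
        assert counts.sum() == count_pixels(mask) == 10

    def test_single_bin_concentration(self):
        mean_r = np.full((4, 4, 1), 0.45)
        mask = np.ones((4, 4, 1), dtype=bool)
        counts, edges = dmn_histogram(mean_r, mask, bins=np.linspace(0, 1, 11))
        assert counts[4] == 16 and counts.sum() == 16

    def test_uniform_values_spread_evenly(self):
        rng = np.random.default_rng(5)
        n = 6000
        mean_r = rng.uniform(0.3, 0.9, size=(n, 1, 1))
        mask = np.ones((n, 1, 1), dtype=bool)
        counts, _ = dmn_histogram(mean_r, mask, bins=np.linspace(0.3, 0.9, 7))
        expect = n / 6
        sigma = np.sqrt(n * (1 / 6) * (5 / 6))
        assert np.all(np.abs(counts - expect) <= 3 * sigma)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dmn_histogram(np.zeros((2, 2, 1)), np.zeros((2, 2, 1), dtype=bool))


class TestCompareStrength:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(6)
        z = rng.normal(0.5, 0.1, size=(4, 6, 6, 1))
        maps = maps_from_z(z)
        mask = np.ones((6, 6, 1), dtype=bool)
        res = compare_strength(maps, maps, mask, mask)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(7)
        z = rng.normal(0.5, 0.1, size=(4, 20, 20, 1))
        maps_a = maps_from_z(z + 0.2)
        maps_b = maps_from_z(z)
        mask = np.ones((20, 20, 1), dtype=bool)
        res = compare_strength(maps_a, maps_b, mask, mask)
        assert res.mean_z_a - res.mean_z_b == pytest.approx(0.2, abs=1e-9)
        assert res.p_value < 1e-10

    def test_matches_welch_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.45, 0.1, size=800)
        b = rng.normal(0.35, 0.1, size=600)
        t, p, _ = welch_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-6)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_roi_exclusion_removes_voxels(self, tiny_atlas):
        shape = tiny_atlas.spatial_shape
        rng = np.random.default_rng(9)
        z = rng.normal(0.6, 0.05, size=(3, *shape))
        maps = maps_from_z(z)
        mask = np.ones(shape, dtype=bool)
        full = compare_strength(maps, maps, mask, mask)
        excl = compare_strength(
            maps, maps, mask, mask, exclude_roi="RSC", atlas=tiny_atlas
        )
        n_rsc = int(tiny_atlas.roi_mask("RSC").sum())
        assert full.n_a - excl.n_a == n_rsc

    def test_empty_mask_rejected(self):
        maps = maps_from_z(np.zeros((2, 2, 2, 1)))
        with pytest.raises(ValueError, match="empty"):
            compare_strength(
                maps, maps,
                np.zeros((2, 2, 1), dtype=bool),
                np.ones((2, 2, 1), dtype=bool),
            )


class TestCountPixels:
    def test_empty_and_full(self):
        assert count_pixels(np.zeros((3, 3, 2), dtype=bool)) == 0
        assert count_pixels(np.ones((64, 64, 11), dtype=bool)) == 45056
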
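"""Synthetic generator: atlas geometry, target matrices, simulation."""
import numpy as np
import pytest

import seedconn as sc
from seedconn.synthetic import CORE_ROI_NAMES, repair_psd, subject_seed


class TestToyAtlas:
    def test_default_atlas_has_25_disjoint_rois(self):
        atlas = sc.make_toy_atlas(sc.AcquisitionSpec(), n_rois=25)
        present = set(np.unique(atlas.labels)) - {0}
        assert present == set(range(1, 26))
        # labels are single-valued per voxel, hence pairwise disjoint by
        # construction; additionally every ROI has >= 8 voxels
        assert min(atlas.roi_sizes().values()) >= 8

    def test_core_region_names_present(self):
        atlas = sc.make_toy_atlas(n_rois=25)
        for name in CORE_ROI_NAMES:
            assert name in atlas.names

    def test_rois_inside_brain(self, scaled_atlas):
        assert not np.any((scaled_atlas.labels > 0) & ~scaled_atlas.brain())

    def test_degenerate_grid_gives_atlas_or_sizing_error(self):
        spec = sc.AcquisitionSpec(nx=8, ny=8, nz=3, n_volumes=10)
        try:
            atlas = sc.make_toy_atlas(spec, n_rois=2)
        except ValueError as e:
            assert "too small" in str(e)
        else:
            sizes = atlas.roi_sizes()
            assert len(sizes) == 2 and min(sizes.values()) >= 8

    def test_unplaceable_roi_error_names_region(self):
        with pytest.raises(ValueError, match="too small to place ROI '\\w+'"):
            sc.make_toy_atlas(sc.AcquisitionSpec(nx=6, ny=6, nz=3), n_rois=3)


class TestTargetMatrix:
    def test_no_couplings_gives_identity(self, tiny_atlas):
        truth = sc.build_target_matrix(
            tiny_atlas, sc.StrainProfile(name="null")
        )
        assert np.array_equal(truth.target_matrix, np.eye(tiny_atlas.n_rois))
        assert truth.repair_distance == 0.0

    def test_single_coupling_is_psd_with_no_repair(self, tiny_atlas):
        profile = sc.StrainProfile(
            name="pair", couplings=(("RSC", "CaudatePutamen", 0.6),)
        )
        truth = sc.build_target_matrix(tiny_atlas, profile)
        C = truth.target_matrix
        i = tiny_atlas.label_of("RSC") - 1
        j = tiny_atlas.label_of("CaudatePutamen") - 1
        assert C[i, j] == C[j, i] == 0.6
        assert np.count_nonzero(C - np.eye(len(C))) == 2
        assert truth.repair_distance == 0.0

    def test_invalid_coupling_strength_rejected(self):
        with pytest.raises(ValueError, match=r"\|r\| < 1"):
            sc.StrainProfile(name="bad", couplings=(("RSC", "Hippocampus", 1.0),))

    def test_contradictory_couplings_repaired_to_psd(self, tiny_atlas):
        # a 0.9/0.9/-0.9 triangle cannot be a correlation matrix
        profile = sc.StrainProfile(
            name="contradictory",
            couplings=(
                ("RSC", "CaudatePutamen", 0.9),
                ("RSC", "Hippocampus", 0.9),
                ("CaudatePutamen", "Hippocampus", -0.9),
            ),
        )
        truth = sc.build_target_matrix(tiny_atlas, profile)
        C = truth.target_matrix
        # eigendecomposition oracle: repaired matrix is PSD with unit diagonal
        assert np.linalg.eigvalsh(C).min() >= -1e-10
        assert np.allclose(np.diag(C), 1.0)
        assert truth.repair_distance > 0

    def test_psd_repair_is_idempotent(self):
        raw = np.array(
            [[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]]
        )
        repaired, dist = repair_psd(raw)
        assert dist > 0
        again, dist2 = repair_psd(repaired)
        assert dist2 == 0.0
        assert np.array_equal(again, repaired)

    def test_default_profiles_are_psd_without_repair(self, scaled_atlas):
        for prof in (sc.shr_like_profile(), sc.wky_like_profile()):
            truth = sc.build_target_matrix(scaled_atlas, prof)
            assert truth.repair_distance == 0.0


class TestSimulation:
    def test_subject_simulation_is_bit_reproducible(self, tiny_atlas):
        truth = sc.build_target_matrix(tiny_atlas, sc.shr_like_profile())
        a = sc.simulate_subject(truth, 77)
        b = sc.simulate_subject(truth, 77)
        assert np.array_equal(a.data, b.data)
        c = sc.simulate_subject(truth, 78)
        assert not np.array_equal(a.data, c.data)

    def test_default_acquisition_shape(self):
        atlas = sc.make_toy_atlas()
        truth = sc.build_target_matrix(atlas, sc.wky_like_profile())
        img = sc.simulate_subject(truth, 1)
        assert img.shape == (64, 64, 11, 300)

    def test_brain_background_contrast(self, tiny_atlas):
        truth = sc.build_target_matrix(tiny_atlas, sc.shr_like_profile())
        img = sc.simulate_subject(truth, 5)
        brain_mean = img.data[tiny_atlas.brain()].mean()
        bg = img.data[~tiny_atlas.brain()]
        assert brain_mean > 50 * max(abs(bg.mean()), 1.0)

    def test_cohort_deterministic_with_distinct_subject_seeds(self, tiny_atlas):
        truth = sc.build_target_matrix(tiny_atlas, sc.wky_like_profile())
        imgs1, t1 = sc.simulate_cohort(truth, 3, master_seed=7)
        imgs2, t2 = sc.simulate_cohort(truth, 3, master_seed=7)
        assert t1.per_subject_seeds == t2.per_subject_seeds
        assert len(set(t1.per_subject_seeds)) == 3
        for a, b in zip(imgs1, imgs2):
            assert np.array_equal(a.data, b.data)

    def test_cohort_too_small_rejected(self, tiny_atlas):
        truth = sc.build_target_matrix(tiny_atlas, sc.shr_like_profile())
        with pytest.raises(ValueError, match=">= 2"):
            sc.simulate_cohort(truth, 1, master_seed=0)

    def test_subject_seeds_stable_and_bounded(self):
        assert subject_seed(7, 0) == subject_seed(7, 0)
        assert subject_seed(7, 0) != subject_seed(7, 1)
        assert 0 <= subject_seed(2**30, 999) < 2**31

    def test_profiles_differ_exactly_at_profiled_couplings(self, scaled_atlas):
        shr = sc.build_target_matrix(scaled_atlas, sc.shr_like_profile())
        wky = sc.build_target_matrix(scaled_atlas, sc.wky_like_profile())
        diff = shr.target_matrix != wky.target_matrix
        coupled = np.zeros_like(diff)
        for prof in (sc.shr_like_profile(), sc.wky_like_profile()):
            for a, b, _ in prof.couplings:
                i, j = scaled_atlas.label_of(a) - 1, scaled_atlas.label_of(b) - 1
                coupled[i, j] = coupled[j, i] = True
        assert not np.any(diff & ~coupled)


class TestCorrelationRecovery:
    def test_latent_correlation_converges_with_scan_length(self, tiny_atlas):
        """Empirical latent correlation error shrinks ~ sqrt(10) from T=300
        to T=3000 for an isolated coupled pair."""
        from seedconn.synthetic import _latent_signals

        errs = {}
        for T in (300, 3000):
            spec = sc.AcquisitionSpec(
                nx=24, ny=24, nz=5, n_volumes=T
            )
            atlas = sc.make_toy_atlas(spec, n_rois=8)
            profile = sc.StrainProfile(
                name="pair", couplings=(("RSC", "Hippocampus", 0.6),)
            )
            truth = sc.build_target_matrix(atlas, profile, spec)
            i, j = atlas.label_of("RSC") - 1, atlas.label_of("Hippocampus") - 1
            errors = []
            for rep in range(40):
                rng = np.random.default_rng(1000 + rep)
                lat = _latent_signals(truth, rng)
                r = np.corrcoef(lat[i], lat[j])[0, 1]
                errors.append(abs(r - 0.6))
            errs[T] = np.mean(errors)
        assert errs[3000] < errs[300]
        assert errs[3000] < errs[300] / np.sqrt(10) * 2.5  # ~sqrt(10) shrink

    def test_null_profile_roi_correlations_bounded(self, tiny_atlas):
        """With no couplings, post-preprocessing ROI-ROI correlations stay
        within 3/sqrt(T_eff) for >= 99% of pairs (T_eff = retained DFT
        degrees of freedom of the latent band)."""
        spec = sc.AcquisitionSpec(nx=24, ny=24, nz=5, n_volumes=300)
        atlas = sc.make_toy_atlas(spec, n_rois=8)
        truth = sc.build_target_matrix(atlas, sc.StrainProfile(name="null"))
        # latent band 0.01-0.05 Hz at T=300: bins 3..15 -> 13 bins, 26 dof
        t_eff = 26
        bound = 3.0 / np.sqrt(t_eff)
        viol = total = 0
        for rep in range(6):
            img = sc.simulate_subject(truth, 600 + rep)
            proc, mask = sc.preprocess_subject(img)
            mat = sc.subject_conn_matrix(proc, atlas, mask)
            iu = np.triu_indices(atlas.n_rois, k=1)
            vals = mat.values[iu]
            viol += int((np.abs(vals) > bound).sum())
            total += vals.size
        assert viol / total <= 0.01
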
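"""Localizer GLM, ROI selection, weighting, and layer balancing."""

import numpy as np
import pytest

from laminar.bold import simulate_localizer
from laminar.layering import LayerVolumeMatrix
from laminar.phantom import PhantomSpec, make_cortical_phantom
from laminar.roi import (ROISet, VoxelStatMap, balance_layers, localizer_glm,
                         select_rois, weight_timecourses)


@pytest.fixture(scope="module")
def localizer_setup():
    spec = PhantomSpec(shape="cylinder-annulus", wm_radius_mm=4.0, pial_radius_mm=6.4,
                       grid_shape=(20, 20, 6))
    _, pref, truth = make_cortical_phantom(spec)
    return truth, pref


class TestLocalizerGLM:
    def test_null_type_one_rate(self, localizer_setup):
        truth, pref = localizer_setup
        run, blocks = simulate_localizer(truth, pref, amp_preferred=0.0,
                                         amp_nonpreferred=0.0, noise_sd=20.0, seed=3)
        stats = localizer_glm(run, blocks)
        from scipy.stats import t as t_dist

        crit = t_dist.ppf(0.975, stats.df)
        rate = np.mean(np.abs(stats.t_orientation[~stats.excluded]) > crit)
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_noiseless_preference_signs_match_labels(self, localizer_setup):
        truth, pref = localizer_setup
        run, blocks = simulate_localizer(truth, pref, noise_sd=0.0, seed=0)
        stats = localizer_glm(run, blocks)
        gm = truth.compartment_fractions(2)[:, 1:4].sum(axis=1) > 0.2
        signs = np.sign(stats.t_orientation[gm])
        expected = np.where(pref.reshape(-1)[gm] == 45, 1.0, -1.0)
        np.testing.assert_array_equal(signs, expected)

    def test_constant_voxels_excluded(self, localizer_setup):
        truth, pref = localizer_setup
        run, blocks = simulate_localizer(truth, pref, noise_sd=0.0, seed=0)
        stats = localizer_glm(run, blocks)
        # voxels fully outside the ribbon have constant time courses
        # (subdivision must match the simulator's partial-volume sampling)
        outside = truth.compartment_fractions(4)[:, 1:4].sum(axis=1) == 0
        assert stats.excluded[outside].all()
        assert np.isnan(stats.t_orientation[outside]).all()


class TestSelectROIs:
    def _stats(self, t_stim, t_orient):
        return VoxelStatMap(t_stimulus=np.asarray(t_stim, float),
                            t_orientation=np.asarray(t_orient, float),
                            df=100, excluded=np.zeros(len(t_stim), bool),
                            shape=(len(t_stim), 1, 1))

    def test_exact_eligibility_counts_and_labels(self, localizer_setup):
        truth, pref = localizer_setup
        run, blocks = simulate_localizer(truth, pref, noise_sd=5.0, seed=1)
        stats = localizer_glm(run, blocks)
        gm_mask = (truth.compartment_fractions(2)[:, 1:4].sum(axis=1) > 0.2
                   ).reshape(truth.grid.shape)
        rois = select_rois(stats, gm_mask, n_per_orientation=100)
        assert len(rois.idx_45) == 100 and len(rois.idx_135) == 100
        labels = pref.reshape(-1)
        assert (labels[rois.idx_45] == 45).all()
        assert (labels[rois.idx_135] == 135).all()

    def test_infinite_threshold_gives_empty_set(self):
        stats = self._stats([5.0, 6.0], [3.0, -3.0])
        with pytest.warns(UserWarning):
            rois = select_rois(stats, np.ones((2, 1, 1), bool),
                               activation_t=np.inf)
        assert len(rois.idx_45) == 0 and len(rois.idx_135) == 0

    def test_mean_abs_t_non_increasing_in_n(self, localizer_setup):
        truth, pref = localizer_setup
        run, blocks = simulate_localizer(truth, pref, noise_sd=5.0, seed=2)
        stats = localizer_glm(run, blocks)
        gm_mask = (truth.compartment_fractions(2)[:, 1:4].sum(axis=1) > 0.2
                   ).reshape(truth.grid.shape)
        means = []
        for n in (50, 100, 200, 300):
            rois = select_rois(stats, gm_mask, n_per_orientation=n)
            means.append(np.concatenate([rois.weight_45, rois.weight_135]).mean())
        assert np.all(np.diff(means) <= 1e-12)

    def test_deterministic_tie_break(self):
        stats = self._stats([5] * 6, [2.0, 2.0, 2.0, -1.0, -1.0, -1.0])
        rois = select_rois(stats, np.ones((6, 1, 1), bool), activation_t=1.0,
                           n_per_orientation=2)
        np.testing.assert_array_equal(rois.idx_45, [0, 1])
        np.testing.assert_array_equal(rois.idx_135, [3, 4])

    def test_empty_mask_rejected(self):
        stats = self._stats([1.0], [1.0])
        with pytest.raises(ValueError, match="mask"):
            select_rois(stats, np.zeros((1, 1, 1), bool))


class TestWeighting:
    def _fake_run(self, data):
        from laminar.bold import BOLDRun, _zero_motion

        nv = data.shape[-1]
        return BOLDRun(data=data, tr_s=1.0, affine=np.eye(4), motion=_zero_motion(nv))

    def test_zscore_then_weight_scales_variance(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 1, 1, 100))
        run = self._fake_run(data)
        panels = weight_timecourses([run], np.array([0, 1]), np.array([2.0, 3.0]))
        v = panels[0].values.var(axis=1, ddof=0)
        np.testing.assert_allclose(v, [4.0, 9.0], rtol=1e-12)

    def test_raw_mode_is_identity(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(4, 1, 1, 50))
        run = self._fake_run(data)
        panels = weight_timecourses([run], np.array([2, 3]), np.array([2.0, 3.0]),
                                    mode="raw")
        np.testing.assert_array_equal(panels[0].values,
                                      data.reshape(4, 50)[[2, 3]])

    def test_per_run_zscoring_independent_of_run_order(self):
        rng = np.random.default_rng(2)
        r1 = self._fake_run(rng.normal(size=(3, 1, 1, 40)))
        r2 = self._fake_run(rng.normal(2.0, 3.0, size=(3, 1, 1, 40)))
        idx, w = np.array([0, 2]), np.array([1.5, 2.5])
        a = weight_timecourses([r1, r2], idx, w)
        b = weight_timecourses([r2, r1], idx, w)
        np.testing.assert_allclose(a[0].values, b[1].values, atol=1e-12)
        np.testing.assert_allclose(a[1].values, b[0].values, atol=1e-12)

    def test_zero_variance_voxel_dropped(self):
        data = np.random.default_rng(3).normal(size=(3, 1, 1, 30))
        data[1] = 7.0
        run = self._fake_run(data)
        panels = weight_timecourses([run], np.array([0, 1, 2]), np.ones(3))
        np.testing.assert_array_equal(panels[0].voxel_idx, [0, 2])


class TestBalanceLayers:
    def _matrix(self, gm_fracs):
        n = len(gm_fracs)
        fr = np.zeros((n, 5))
        fr[:, 1:4] = gm_fracs
        fr[:, 0] = 1.0 - fr.sum(axis=1)
        idx = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
        return LayerVolumeMatrix(fractions=fr, voxel_indices=idx,
                                 voxel_volume_mm3=0.512, grid_shape=(n, 1, 1))

    def test_balanced_roi_unchanged(self):
        rng = np.random.default_rng(0)
        gm = np.abs(rng.normal(0.3, 0.01, size=(60, 3)))
        m = self._matrix(gm)
        kept, report = balance_layers(np.arange(60), m)
        assert report["removed"] == 0
        np.testing.assert_array_equal(kept, np.arange(60))

    def test_superficial_overrepresentation_trimmed_from_superficial(self):
        rng = np.random.default_rng(1)
        gm = np.abs(rng.normal(0.25, 0.01, size=(80, 3)))
        gm[:30, 2] *= 2.0  # doubled superficial fractions
        m = self._matrix(np.clip(gm, 0, 0.33))
        kept, report = balance_layers(np.arange(80), m)
        assert report["converged"] and report["removed"] > 0
        removed = np.setdiff1d(np.arange(80), kept)
        assert np.all(removed < 30)  # only inflated-superficial voxels go

    def test_imbalance_resolves_with_p_above_alpha(self):
        rng = np.random.default_rng(2)
        gm = np.abs(rng.normal(0.2, 0.02, size=(100, 3)))
        gm[:40, 0] *= 1.8   # deep-heavy subset drives the imbalance
        m = self._matrix(np.clip(gm, 0, 0.4))
        _, report = balance_layers(np.arange(100), m)
        p = np.asarray(report["p_history"])
        assert report["converged"] and p[-1] > 0.1
        assert p[-1] > p[0]

    def test_alpha_zero_removes_nothing(self):
        rng = np.random.default_rng(3)
        gm = np.abs(rng.normal(0.25, 0.05, size=(40, 3)))
        m = self._matrix(np.clip(gm, 0, 0.4))
        kept, report = balance_layers(np.arange(40), m, alpha=0.0)
        assert report["removed"] == 0

    def test_empty_roi_rejected(self):
        m = self._matrix(np.full((5, 3), 0.3))
        with pytest.raises(ValueError, match="empty"):
            balance_layers(np.array([], dtype=int), m)


def test_roiset_disjointness_enforced():
    with pytest.raises(ValueError, match="disjoint"):
        ROISet(idx_45=np.array([1, 2]), idx_135=np.array([2, 3]),
               weight_45=np.ones(2), weight_135=np.ones(2))
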
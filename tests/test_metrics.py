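import numpy as np
import pytest
from scipy import stats

from qcfmri.dataio import MotionTrace, VolumeGrid
from qcfmri.metrics import (compute_corr_brain, compute_enorm, compute_gcor,
                            compute_outlier_fractions, compute_radcor,
                            compute_tsnr, detect_pre_steady, dropout_score,
                            ghost_score, make_censor, seed_correlation_map,
                            FWHM_TO_SIGMA)
from qcfmri.regmodel import compute_automask, _legendre_baseline
from qcfmri.synthgen import (DropoutSpec, GhostSpec, PhantomSpec, make_epi,
                             step_motion)


class TestEnorm:
    def test_constant_params_zero(self):
        e = compute_enorm(MotionTrace(np.ones((10, 6))))
        np.testing.assert_array_equal(e, np.zeros(10))

    def test_hand_arithmetic(self):
        """Rows differing by (0.1,0,0,0,0.2,0): e = sqrt(0.05) = 0.2236."""
        params = np.zeros((2, 6))
        params[1] = [0.1, 0, 0, 0, 0.2, 0]
        e = compute_enorm(MotionTrace(params))
        assert e[0] == 0.0
        assert e[1] == pytest.approx(np.sqrt(0.05))

    def test_first_element_always_zero(self):
        rng = np.random.default_rng(0)
        e = compute_enorm(MotionTrace(rng.normal(size=(20, 6))))
        assert e[0] == 0.0
        assert np.all(e >= 0)


class TestOutliers:
    def _phantom_series(self, n=40, seed=0):
        epi, truth = make_epi(PhantomSpec(n_vols=n, noise_sd=1.0), seed)
        return epi, compute_automask(epi)

    def test_noiseless_drift_no_outliers(self):
        epi, truth = make_epi(PhantomSpec(n_vols=40, noise_sd=0.0), 0)
        mask = compute_automask(epi)
        outfrac = compute_outlier_fractions(epi, mask)
        np.testing.assert_array_equal(outfrac, np.zeros(40))

    def test_single_spiked_voxel_counts_once(self):
        epi, mask = self._phantom_series()
        data = epi.data.copy()
        vox = tuple(np.argwhere(mask.mask)[0])
        base = data[vox]
        mad = np.median(np.abs(base - np.median(base)))
        data[vox][7] += 40.0 * max(mad, 1.0)
        import dataclasses
        spiked = dataclasses.replace(epi, data=data)
        outfrac = compute_outlier_fractions(spiked, mask)
        assert outfrac[7] >= 1.0 / mask.n_voxels

    def test_matches_bruteforce_voxel_loop(self):
        """Vectorized outlier fractions equal a literal per-voxel loop."""
        epi, mask = self._phantom_series(n=30, seed=3)
        outfrac = compute_outlier_fractions(epi, mask)
        n = epi.n_vols
        p = 1 + int(n * epi.tr_s // 150)
        B = _legendre_baseline(n, p)
        q = stats.norm.isf(0.001 / n)
        counts = np.zeros(n)
        voxels = epi.data[mask.mask]
        for series in voxels:
            # literal per-voxel L1 trend (IRLS, same iteration budget)
            coef = np.linalg.lstsq(B, series, rcond=None)[0]
            for _ in range(8):
                w = 1.0 / np.maximum(np.abs(series - B @ coef), 1e-8)
                W = np.diag(w)
                coef = np.linalg.solve(B.T @ W @ B, B.T @ W @ series)
            dev = np.abs(series - B @ coef)
            mad = np.median(dev)
            if mad == 0:
                continue
            counts += dev > q * np.sqrt(np.pi / 2) * mad
        np.testing.assert_allclose(outfrac, counts / mask.n_voxels,
                                   atol=1e-12)


class TestCensor:
    def test_clean_data_zero_fraction(self):
        motion = MotionTrace(np.zeros((50, 6)))
        e = compute_enorm(motion)
        summary = make_censor(e, np.zeros(50), motion)
        assert summary.censor_fraction == 0.0
        assert summary.max_censored_displacement == 0.0

    def test_single_jump_censors_pair(self):
        """A suprathreshold step at t=10 censors TRs 9 and 10."""
        params = step_motion(50, spikes=[(10, [0, 0, 0, 0.5, 0, 0])])
        motion = MotionTrace(params)
        e = compute_enorm(motion)
        summary = make_censor(e, np.zeros(50), motion, L_motion=0.2)
        assert list(np.flatnonzero(summary.censor.keep == 0)) == [9, 10]
        assert summary.censor_fraction == pytest.approx(2 / 50)

    def test_rest_vs_task_limits(self):
        """Enorm 0.2236 is censored at the 0.2 rest limit, not at 0.3."""
        params = np.zeros((10, 6))
        params[5:] += [0.1, 0, 0, 0, 0.2, 0]
        motion = MotionTrace(params)
        e = compute_enorm(motion)
        assert e[5] == pytest.approx(np.sqrt(0.05))
        rest = make_censor(e, np.zeros(10), motion, L_motion=0.2)
        task = make_censor(e, np.zeros(10), motion, L_motion=0.3)
        assert rest.censor.keep[5] == 0 and rest.censor.keep[4] == 0
        assert task.censor_fraction == 0.0

    def test_outlier_fraction_censors_single_tr(self):
        motion = MotionTrace(np.zeros((20, 6)))
        outfrac = np.zeros(20)
        outfrac[4] = 0.10
        summary = make_censor(compute_enorm(motion), outfrac, motion,
                              L_out=0.05)
        assert list(np.flatnonzero(summary.censor.keep == 0)) == [4]

    def test_avg_censored_motion_excludes_censored(self):
        params = step_motion(20, spikes=[(5, [0, 0, 0, 1.0, 0, 0])],
                             wander_sd=0.01, seed=1)
        motion = MotionTrace(params)
        e = compute_enorm(motion)
        summary = make_censor(e, np.zeros(20), motion, L_motion=0.2)
        kept = summary.censor.retained_indices()
        assert summary.avg_censored_motion == pytest.approx(e[kept].mean())
        assert summary.avg_censored_motion < e.mean()


class TestPreSteady:
    def test_flat_series_not_flagged(self):
        rep = detect_pre_steady(np.full(30, 0.01))
        assert not rep.flagged and rep.n_leading_trs == 0

    def test_three_hot_leading_trs(self):
        outfrac = np.full(40, 0.01)
        outfrac[:3] = 0.2
        rep = detect_pre_steady(outfrac)
        assert rep.flagged and rep.n_leading_trs == 3

    def test_late_elevation_not_flagged(self):
        outfrac = np.full(60, 0.01)
        outfrac[50] = 0.5
        rep = detect_pre_steady(outfrac)
        assert not rep.flagged


class TestGcor:
    def test_identical_series_gcor_one(self):
        s = np.tile(np.sin(np.arange(30)), (8, 1))
        assert compute_gcor(s) == pytest.approx(1.0)

    def test_antisymmetric_pair_gcor_zero(self):
        u = np.sin(np.arange(40))
        assert compute_gcor(np.vstack([u, -u])) == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_fast_formula_equals_pairwise_mean(self):
        """||mean unit series||^2 equals the mean over all V^2 pairs of
        correlations (self-pairs included), to 1e-10."""
        rng = np.random.default_rng(7)
        data = rng.normal(size=(20, 50))
        fast = compute_gcor(data)
        C = np.corrcoef(data)
        assert fast == pytest.approx(C.mean(), abs=1e-10)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            compute_gcor(np.ones((2, 10)))  # zero variance everywhere


class TestTsnrAndCorrBrain:
    def test_tsnr_arithmetic(self):
        fitted = np.full((4, 4, 2, 30), 100.0)
        rng = np.random.default_rng(0)
        resid = rng.normal(0, 2.0, size=(4, 4, 2, 30))
        mask = np.ones((4, 4, 2), bool)
        smap, avg = compute_tsnr(fitted, resid, mask)
        assert avg == pytest.approx(100.0 / resid.std(ddof=1), rel=0.15)

    def test_zero_residuals_guarded(self):
        fitted = np.full((2, 2, 1, 10), 50.0)
        resid = np.zeros_like(fitted)
        smap, avg = compute_tsnr(fitted, resid, np.ones((2, 2, 1), bool))
        assert np.all(smap.data == 0.0)

    def test_corr_brain_shared_signal(self):
        rng = np.random.default_rng(1)
        g = np.sin(np.arange(40))
        resid = g[None, None, None, :] + rng.normal(
            0, 1e-4, size=(4, 4, 3, 40))
        mask = np.ones((4, 4, 3), bool)
        cmap = compute_corr_brain(resid, mask)
        assert np.all(cmap.data[mask] > 0.999)

    def test_corr_brain_sign(self):
        """A voxel that is exactly the negated shared signal maps to -1."""
        s = np.sin(np.arange(50))
        resid = np.tile(s, (3, 3, 1, 1))
        resid[0, 0, 0] = -s
        mask = np.ones((3, 3, 1), bool)
        cmap = compute_corr_brain(resid, mask)
        assert cmap.data[0, 0, 0] == pytest.approx(-1.0)
        assert cmap.data[1, 1, 0] == pytest.approx(1.0)

    def test_corr_brain_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        resid = rng.normal(size=(4, 3, 2, 25))
        mask = rng.random((4, 3, 2)) > 0.3
        mask[0, 0, 0] = True  # ensure nonempty
        cmap = compute_corr_brain(resid, mask)
        g = resid[mask].mean(axis=0)
        for idx in np.ndindex(4, 3, 2):
            r = np.corrcoef(resid[idx], g)[0, 1]
            assert cmap.data[idx] == pytest.approx(r, abs=1e-12)


class TestRadcor:
    def test_uniform_series_radcor_one(self):
        g = np.cos(np.arange(20))
        series = np.tile(g, (6, 6, 4, 1))
        mask = np.ones((6, 6, 4), bool)
        rmap = compute_radcor(series, mask, fwhm_mm=12.0,
                              voxel_size_mm=(3, 3, 3))
        np.testing.assert_allclose(rmap.data[mask], 1.0, atol=1e-10)

    def test_independent_noise_large_fwhm_near_zero(self):
        rng = np.random.default_rng(4)
        series = rng.normal(size=(8, 8, 6, 80))
        mask = np.ones((8, 8, 6), bool)
        rmap = compute_radcor(series, mask, fwhm_mm=200.0,
                              voxel_size_mm=(3, 3, 3))
        v_eff = mask.sum()
        assert np.abs(rmap.data[mask]).mean() < 3.0 / np.sqrt(v_eff)

    def test_matches_bruteforce_convolution(self):
        """radcor equals a direct truncated-Gaussian spatial sum."""
        rng = np.random.default_rng(5)
        series = rng.normal(size=(8, 8, 8, 15))
        mask = rng.random((8, 8, 8)) > 0.4
        fwhm, vox = 10.0, (2.0, 2.0, 2.0)
        rmap = compute_radcor(series, mask, fwhm_mm=fwhm, voxel_size_mm=vox)

        sigma = [fwhm / FWHM_TO_SIGMA / v for v in vox]
        radii = [int(4.0 * s + 0.5) for s in sigma]
        kern1d = []
        for s, r in zip(sigma, radii):
            x = np.arange(-r, r + 1)
            w = np.exp(-0.5 * (x / s) ** 2)
            kern1d.append(w / w.sum())
        K = np.einsum("i,j,k->ijk", *kern1d)
        offs = np.array(np.meshgrid(
            *[np.arange(-r, r + 1) for r in radii], indexing="ij"))

        def local_avg(idx):
            # mask-normalized: out-of-mask voxels carry no weight
            num = np.zeros(15)
            den = 0.0
            for o, w in zip(offs.reshape(3, -1).T, K.ravel()):
                p = np.array(idx) + o
                if np.any(p < 0) or np.any(p >= 8):
                    continue
                p = tuple(p)
                if mask[p]:
                    num += w * series[p]
                    den += w
            return num / den if den > 1e-12 else np.zeros(15)

        for idx in [(2, 2, 2), (5, 3, 6), (7, 7, 7)]:
            x, y = series[idx], local_avg(idx)
            if y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            assert rmap.data[idx] == pytest.approx(r, abs=1e-8)


class TestSeedCorrelation:
    def _grid(self, dims=(10, 10, 8), vox=3.0):
        aff = np.diag([vox, vox, vox, 1.0])
        aff[:3, 3] = -(np.asarray(dims) - 1) / 2 * vox
        return VolumeGrid.from_affine(dims, aff, 1, 1)

    def test_seed_blob_recovery(self):
        from qcfmri.synthgen import NetworkBlob
        spec = PhantomSpec(n_vols=80, noise_sd=1.0,
                           blobs=[NetworkBlob((10, 10, 7), 3.0,
                                              latent_sd=5.0)])
        epi, truth = make_epi(spec, 9)
        mask = compute_automask(epi)
        # detrend with the baseline polynomial to isolate the latent signal
        from qcfmri.regmodel import build_design, fit_glm
        X = build_design([epi], MotionTrace(truth.motion))
        fit = fit_glm(epi, X)
        blob = truth.blob_masks[0]
        center_vox = np.argwhere(blob).mean(axis=0)
        seed_mm = epi.grid.voxel_to_mm(center_vox)
        smap = seed_correlation_map(fit.residuals, epi.grid, seed_mm,
                                    radius_mm=3.0)
        assert smap.data[blob].mean() > 0.6
        outside = mask.mask & ~blob
        assert np.abs(smap.data[outside]).mean() < 0.2

    def test_radius_zero_seed_voxel_is_one(self):
        rng = np.random.default_rng(6)
        resid = rng.normal(size=(10, 10, 8, 30))
        grid = self._grid()
        seed_mm = grid.voxel_to_mm([4, 5, 3])
        smap = seed_correlation_map(resid, grid, seed_mm, radius_mm=0.0)
        assert smap.data[4, 5, 3] == pytest.approx(1.0)

    def test_standard_seed_labels_resolve(self):
        """The published seed labels resolve to the right voxel under a
        RAS+ affine."""
        from qcfmri.dataio import parse_coordinate_label
        grid = self._grid(dims=(64, 64, 40), vox=3.0)
        for label in ("5L, 49P, 40S", "4R, 91A, 3I"):
            mm = parse_coordinate_label(label)
            vox = grid.mm_to_voxel(mm)
            np.testing.assert_allclose(grid.voxel_to_mm(vox), mm, atol=1e-9)

    def test_seed_outside_fov_rejected(self):
        rng = np.random.default_rng(7)
        grid = self._grid()
        with pytest.raises(ValueError):
            seed_correlation_map(rng.normal(size=(10, 10, 8, 20)), grid,
                                 [500.0, 0.0, 0.0])


class TestArtifactScores:
    def test_ghost_raises_score(self):
        clean, _ = make_epi(PhantomSpec(n_vols=20, noise_sd=1.0), 2)
        ghosty, _ = make_epi(PhantomSpec(n_vols=20, noise_sd=1.0,
                                         ghost=GhostSpec(0.1)), 2)
        mask = compute_automask(clean)
        assert ghost_score(ghosty, mask) > 5 * max(
            ghost_score(clean, mask), 0.01)

    def test_dropout_raises_score(self):
        spec = PhantomSpec(n_vols=20, noise_sd=1.0,
                           dropout=DropoutSpec((10, 10, 7), 3.0, 0.3))
        clean, _ = make_epi(PhantomSpec(n_vols=20, noise_sd=1.0), 2)
        dropped, _ = make_epi(spec, 2)
        mask = compute_automask(clean)   # hole-filled geometry from clean
        assert dropout_score(dropped, mask) > 0.01
        assert dropout_score(clean, mask) == pytest.approx(0.0, abs=1e-6)
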
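import dataclasses

import numpy as np
import pytest

from qcfmri.dataio import CensorVector, EventTable, MotionTrace
from qcfmri.regmodel import (BasisConfig, ContrastSpec, DesignMatrix,
                             block_response_peak, build_design,
                             compute_automask, fit_glm, gamma_response,
                             scale_to_mean100, F_CAP)
from qcfmri.synthgen import PhantomSpec, make_epi, make_events

import pandas as pd


def rest_run(n_vols=100, tr=2.0, seed=0, noise=1.0):
    epi, truth = make_epi(PhantomSpec(n_vols=n_vols, tr_s=tr,
                                      noise_sd=noise), seed)
    return epi, truth


class TestAutomask:
    def test_mask_matches_generator_truth(self):
        epi, truth = rest_run(n_vols=30)
        mask = compute_automask(epi)
        overlap = (mask.mask & truth.head_mask).sum()
        assert abs(mask.n_voxels - truth.head_mask.sum()) \
            <= 0.02 * truth.head_mask.sum()
        assert overlap >= 0.98 * truth.head_mask.sum()

    def test_isolated_hot_spot_excluded(self, quiet_phantom):
        _, epi, truth = quiet_phantom
        data = epi.data.copy()
        data[0, 0, 0, :] = 1e5  # bright speck far from the head
        spotted = dataclasses.replace(epi, data=data)
        mask = compute_automask(spotted)
        assert not mask.mask[0, 0, 0]

    def test_empty_data_rejected(self, quiet_phantom):
        _, epi, _ = quiet_phantom
        dark = dataclasses.replace(epi, data=np.zeros_like(epi.data))
        with pytest.raises(ValueError):
            compute_automask(dark)


class TestScaling:
    def test_constant_series_scaled_to_100(self, quiet_phantom):
        _, epi, _ = quiet_phantom
        const = dataclasses.replace(epi, data=np.full_like(epi.data, 50.0))
        mask = compute_automask(epi)
        out = scale_to_mean100(const, mask)
        np.testing.assert_allclose(out.data, 100.0)

    def test_spike_capped_at_200(self, quiet_phantom):
        _, epi, _ = quiet_phantom
        data = np.full_like(epi.data, 100.0)
        data[5, 5, 5, 3] = 250.0
        spiky = dataclasses.replace(epi, data=data)
        out = scale_to_mean100(spiky, compute_automask(epi))
        # mean slightly above 100; the scaled spike exceeds 200 and is capped
        assert out.data[5, 5, 5, 3] == pytest.approx(200.0)

    def test_in_mask_temporal_means_are_100(self, quiet_phantom):
        _, epi, _ = quiet_phantom
        mask = compute_automask(epi)
        out = scale_to_mean100(epi, mask)
        means = out.data[mask.mask].mean(axis=1)
        capped = (out.data[mask.mask] >= 200).any(axis=1)
        np.testing.assert_allclose(means[~capped], 100.0, atol=1e-6)


class TestDesign:
    def test_polynomial_order_from_run_length(self, quiet_phantom):
        # 150 vols x 2 s = 300 s -> p = 1 + floor(300/150) = 3 -> 4 columns
        epi, truth = rest_run(n_vols=150, tr=2.0)
        X = build_design([epi], MotionTrace(truth.motion),
                         basis_cfg=BasisConfig(motion_derivatives=False))
        n_baseline = sum(g == "baseline" for g in X.groups)
        assert n_baseline == 4

    def test_two_second_event_response_peaks_at_one(self):
        """The continuous response to a single 2 s block peaks at 1."""
        from qcfmri.regmodel import _block_response
        amp = 1.0 / block_response_peak(2.0)
        _, resp = _block_response(2.0, 60.0)
        assert (amp * resp).max() == pytest.approx(1.0, abs=1e-9)
        # and the TR-sampled regressor comes close to that peak
        epi, truth = rest_run(n_vols=60, tr=2.0)
        tab = EventTable(events=pd.DataFrame(
            {"onset": [20.0], "duration": [2.0], "trial_type": ["Task"]}))
        X = build_design([epi], MotionTrace(truth.motion), events=[tab])
        reg = X.X[:, X.columns_of("interest")[0]]
        assert 0.9 < reg.max() <= 1.0 + 1e-9

    def test_duration_modulation_longer_block_peaks_higher(self):
        assert block_response_peak(4.0) > block_response_peak(2.0) \
            > block_response_peak(0.5)

    def test_gamma_response_peaks_at_one(self):
        tau = np.linspace(0, 30, 3001)
        g = gamma_response(tau)
        assert g.max() == pytest.approx(1.0, abs=1e-6)
        assert tau[np.argmax(g)] == pytest.approx(4.0, abs=0.02)

    def test_two_classes_two_interest_columns(self):
        epi, truth = rest_run(n_vols=80)
        tab = make_events(0, 8, ["Task", "Control"], ("regular", 16.0),
                          ("regular", 2.0), run_length_s=160.0)
        X = build_design([epi], MotionTrace(truth.motion), events=[tab])
        interest = X.columns_of("interest")
        assert interest.size == 2
        labels = [X.labels[j] for j in interest]
        assert set(labels) == {"Task", "Control"}
        spec = ContrastSpec("Task - Control", {"Task": 1.0, "Control": -1.0})
        assert spec.weights["Task"] == 1.0

    def test_motion_regressors_per_run_with_derivatives(self):
        epi, truth = rest_run(n_vols=40)
        motion = MotionTrace(np.tile(np.arange(80)[:, None], (1, 6)) * 0.01)
        X = build_design([epi, epi], motion)
        motion_cols = X.columns_of("motion")
        assert motion_cols.size == 2 * 12  # 6 params + 6 derivs per run
        # per-run: zero outside the owning run
        j = motion_cols[0]
        assert np.all(X.X[40:, j] == 0)

    def test_event_past_run_end_warns_and_truncates(self):
        epi, truth = rest_run(n_vols=20, tr=2.0)  # 40 s run
        tab = EventTable(events=pd.DataFrame(
            {"onset": [38.0], "duration": [10.0], "trial_type": ["Task"]}))
        with pytest.warns(UserWarning, match="truncated"):
            build_design([epi], MotionTrace(truth.motion), events=[tab])


class TestFit:
    def test_rest_fit_has_no_full_f(self):
        epi, truth = rest_run(n_vols=40)
        X = build_design([epi], MotionTrace(truth.motion))
        fit = fit_glm(epi, X)
        assert fit.full_f is None

    def test_injected_beta_recovered_within_3se(self):
        spec = PhantomSpec(n_vols=120, noise_sd=0.1, ar1_rho=0.0,
                           betas={"Task": 0.8})
        tab = make_events(5, 10, ["Task"], ("regular", 20.0),
                          ("regular", 2.0), run_length_s=240.0)
        spec = dataclasses.replace(spec, events=[tab])
        epi, truth = make_epi(spec, 7)
        mask = compute_automask(epi)
        scaled = scale_to_mean100(epi, mask)
        X = build_design([scaled], MotionTrace(truth.motion), events=[tab])
        contrast = ContrastSpec("task_amp", {"Task": 1.0})
        fit = fit_glm(scaled, X, contrasts=[contrast])
        beta_map = fit.coef["Task"][mask.mask]
        t_map = fit.tstat["task_amp"][mask.mask]
        se = np.median(np.abs(beta_map / np.where(t_map == 0, np.inf, t_map)))
        assert abs(np.median(beta_map) - 0.8) < 3 * se

    def test_df_fraction_arithmetic(self):
        """200 TRs, 40 censored, 10 regressors -> (160-10)/200 = 0.75."""
        rng = np.random.default_rng(0)
        n = 200
        X_interest = rng.normal(size=(n, 9))
        X = DesignMatrix(
            X=np.column_stack([np.ones(n), X_interest]),
            labels=["const"] + [f"x{i}" for i in range(9)],
            groups=["baseline"] + ["interest"] * 9,
            run_index=np.zeros(n, dtype=int),
            column_run=[0] + [None] * 9, tr_s=2.0)
        keep = np.ones(n, dtype=int)
        keep[:40] = 0
        y = rng.normal(size=(5, n))
        fit = fit_glm(y, X, CensorVector(keep))
        assert fit.df_remain == 150
        assert fit.df_fraction == pytest.approx(0.75)

    def test_residuals_orthogonal_to_design(self):
        epi, truth = rest_run(n_vols=60)
        X = build_design([epi], MotionTrace(truth.motion))
        fit = fit_glm(epi, X)
        resid = fit.residuals.reshape(-1, fit.retained.size)
        Xr = X.X[fit.retained]
        Xn = Xr / np.linalg.norm(Xr, axis=0)
        rn = np.linalg.norm(resid, axis=1, keepdims=True)
        dots = (resid / np.where(rn > 0, rn, 1.0)) @ Xn
        assert np.max(np.abs(dots)) < 1e-8

    def test_df_fraction_decreases_with_censoring_and_regressors(self):
        from qcfmri.synthgen import step_motion
        epi, _ = rest_run(n_vols=60)
        motion = MotionTrace(step_motion(60, wander_sd=0.02, seed=4))
        X_small = build_design([epi], motion,
                               basis_cfg=BasisConfig(
                                   motion_derivatives=False))
        X_big = build_design([epi], motion)
        none = CensorVector(np.ones(60, dtype=int))
        some = CensorVector(np.r_[np.zeros(6, int), np.ones(54, int)])
        f_ref = fit_glm(epi, X_small, none).df_fraction
        assert fit_glm(epi, X_small, some).df_fraction < f_ref
        assert fit_glm(epi, X_big, none).df_fraction < f_ref

    def test_zero_noise_full_f_capped_not_nan(self):
        n = 40
        t = np.arange(n, dtype=float)
        reg = np.sin(t / 3.0)
        X = DesignMatrix(
            X=np.column_stack([np.ones(n), reg]),
            labels=["const", "stim"], groups=["baseline", "interest"],
            run_index=np.zeros(n, dtype=int), column_run=[0, None], tr_s=2.0)
        y = (2.0 + 0.7 * reg)[None, :]  # exact model, zero noise
        fit = fit_glm(y, X)
        assert np.isfinite(fit.full_f).all()
        assert fit.full_f_capped
        assert fit.full_f.max() == pytest.approx(F_CAP)

    def test_rank_deficient_names_collinear_columns(self):
        n = 30
        rng = np.random.default_rng(1)
        col = rng.normal(size=n)
        X = DesignMatrix(
            X=np.column_stack([np.ones(n), col, col]),
            labels=["const", "a", "dup_a"],
            groups=["baseline", "interest", "interest"],
            run_index=np.zeros(n, dtype=int), column_run=[0, None, None],
            tr_s=2.0)
        with pytest.raises(np.linalg.LinAlgError, match="dup_a"):
            fit_glm(rng.normal(size=(3, n)), X)
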
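import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy import stats as sps

from dediff import glm, simulate
from dediff.design import build_hierarchy, make_lists, make_run_events, sequence_trials

from conftest import noiseless_noise_model


def _study_events(seed=0, n_runs=3):
    h = build_hierarchy()
    lists = make_lists(h, seed=seed)
    out = []
    for r in range(n_runs):
        ordered = sequence_trials(lists[r], "study", h, seed=seed + r)
        ev = make_run_events(ordered, "study", r + 1, h)
        ev["outcome"] = "hit"
        out.append(ev)
    return out


class TestCanonicalHrf:
    def test_peak_location_matches_numeric_maximum(self):
        # oracle: maximize the double-gamma difference directly
        neg = lambda t: -(sps.gamma.pdf(t, 6) - sps.gamma.pdf(t, 16) / 6.0)
        res = optimize.minimize_scalar(neg, bounds=(1, 12), method="bounded")
        hrf = glm.canonical_hrf(0.1)
        assert np.argmax(hrf) * 0.1 == pytest.approx(res.x, abs=0.05)
        assert np.argmax(hrf) * 0.1 == pytest.approx(5.0, abs=0.051)

    def test_shape_properties(self):
        hrf = glm.canonical_hrf(0.1)
        assert hrf.max() == pytest.approx(1.0)
        assert hrf.sum() > 0
        assert hrf.min() < 0  # undershoot

    def test_coarse_sampling_subsamples_fine_kernel(self):
        fine = glm.canonical_hrf(0.1)
        coarse = glm.canonical_hrf(2.0)
        assert np.allclose(coarse, fine[::20], atol=1e-12)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            glm.canonical_hrf(0.0)


class TestHighpassBasis:
    def test_k_for_standard_run(self):
        # K = floor(2 * 205 * 2 / 128) = 6
        assert glm.highpass_basis(205, 2.0, 128.0).shape[1] == 6

    def test_infinite_cutoff_empty(self):
        assert glm.highpass_basis(205, 2.0, np.inf).shape[1] == 0

    def test_columns_orthogonal_to_constant(self):
        B = glm.highpass_basis(205, 2.0)
        assert np.allclose(B.sum(axis=0), 0.0, atol=1e-10)

    def test_basis_member_projects_to_zero_residual(self):
        n, tr = 205, 2.0
        B = np.column_stack([glm.highpass_basis(n, tr), np.ones(n)])
        c = B[:, 1].copy()  # exact basis member
        resid = c - B @ np.linalg.lstsq(B, c, rcond=None)[0]
        assert np.max(np.abs(resid)) < 1e-10

    def test_slow_cosine_mostly_removed(self):
        # generic 200 s-period cosine is almost in the span of the basis
        n, tr = 205, 2.0
        t = np.arange(n) * tr
        c = np.cos(2 * np.pi * t / 200.0)
        B = np.column_stack([glm.highpass_basis(n, tr), np.ones(n)])
        resid = c - B @ np.linalg.lstsq(B, c, rcond=None)[0]
        assert np.sum(resid**2) / np.sum(c**2) < 0.01


class TestEventRegressors:
    def test_single_event_equals_sampled_hrf(self):
        col = glm.event_regressor([0.0], 20, 2.0)
        hrf = glm.canonical_hrf(0.1)
        expected = np.zeros(20)
        expected[:17] = hrf[::20]
        assert np.allclose(col, expected)

    def test_superposition_of_adjacent_trials(self):
        both = glm.event_regressor([0.0, 6.0], 50, 2.0)
        a = glm.event_regressor([0.0], 50, 2.0)
        b = glm.event_regressor([6.0], 50, 2.0)
        assert np.allclose(both, a + b)

    def test_out_of_run_onset_raises(self):
        with pytest.raises(ValueError):
            glm.event_regressor([100.0], 20, 2.0)

    def test_trial_matrix_matches_per_event_columns(self):
        onsets = np.array([0.0, 6.0, 12.0, 30.0])
        M = glm.trial_regressor_matrix(onsets, 40, 2.0)
        for j, onset in enumerate(onsets):
            assert np.allclose(M[:, j], glm.event_regressor([onset], 40, 2.0))


class TestConditionDesign:
    def _events(self, outcomes, soa=6.0):
        return pd.DataFrame({
            "onset": np.arange(len(outcomes)) * soa,
            "duration": 5.0,
            "outcome": outcomes,
        })

    def test_single_hit_column(self):
        d = glm.build_condition_design(self._events(["hit"]), 30, 2.0)
        assert np.allclose(d.column("hit"), glm.event_regressor([0.0], 30, 2.0))
        assert d.interest_names == ["hit"]

    def test_all_hits_drops_cr_with_record(self):
        with pytest.warns(UserWarning, match="'CR'"):
            d = glm.build_condition_design(self._events(["hit"] * 4), 40, 2.0)
        assert "CR" in d.dropped
        assert "CR" not in d.names

    def test_condition_columns_are_summed_hrfs(self):
        ev = self._events(["hit", "CR", "hit"])
        d = glm.build_condition_design(ev, 40, 2.0)
        manual = glm.event_regressor([0.0], 40, 2.0) + glm.event_regressor([12.0], 40, 2.0)
        assert np.allclose(d.column("hit"), manual)

    def test_unmapped_outcomes_fall_into_other(self):
        ev = self._events(["hit", "FA", "miss"])
        d = glm.build_condition_design(ev, 40, 2.0)
        assert "other" in d.names

    def test_multi_run_design_counts(self):
        evs = [self._events(["hit", "CR"] * 8) for _ in range(3)]
        d = glm.condition_design_runs(evs, 60, 2.0)
        assert d.n_volumes == 180
        assert d.interest_names == ["hit", "CR"]
        assert sum(n.endswith("mean") for n in d.names) == 3


class TestSingleTrialDesign:
    def test_192_interest_regressors(self):
        d = glm.single_trial_design(_study_events(), 205, 2.0)
        assert int(d.interest.sum()) == 192
        assert d.n_volumes == 615

    def test_duplicate_ids_raise(self):
        evs = _study_events()
        dup = [evs[0], evs[0]]
        with pytest.raises(ValueError, match="duplicate"):
            glm.single_trial_design(dup, 205, 2.0)

    def test_session_nuisance_block_structure(self):
        d = glm.single_trial_design(_study_events(), 205, 2.0)
        mean1 = d.column("run1_mean")
        assert np.all(mean1[:205] == 1) and np.all(mean1[205:] == 0)


class TestFitGlm:
    def test_recovers_planted_amplitudes_noiseless(self, small_setup):
        config, grid, regions = small_setup
        evs = _study_events(n_runs=1)[0]
        act = simulate.ActivationModel(
            {"HIPP": {"study": {"*": 2.5}}, "VTC": {"study": {"*": 1.0}}},
            trial_noise_sd=0.0,
        )
        data = simulate.simulate_run(
            evs, grid, regions, activation_model=act,
            noise_model=noiseless_noise_model(), seed=0,
        )
        d = glm.single_trial_design([evs], 205, 2.0)
        fit = glm.fit_glm(data.reshape(-1, 205).T, d)
        betas = fit.betas[:64]
        hipp = betas[:, regions["HIPP"].flat_indices]
        assert np.allclose(hipp, 2.5, atol=1e-8)
        vtc = betas[:, regions["VTC"].flat_indices]
        assert np.allclose(vtc, 1.0, atol=1e-8)

    def test_matches_normal_equations_on_toy(self, rng):
        X = np.column_stack([
            glm.event_regressor([0.0], 30, 2.0),
            glm.event_regressor([10.0], 30, 2.0),
            np.ones(30),
        ])
        d = glm.DesignMatrix(X, ["a", "b", "mean"],
                             np.array([True, True, False]), [30])
        Y = rng.normal(size=(30, 10))
        fit = glm.fit_glm(Y, d)
        ref = np.linalg.solve(X.T @ X, X.T @ Y)  # independent solver
        assert np.allclose(fit.betas, ref, atol=1e-10)

    def test_df(self):
        d = glm.single_trial_design(_study_events(n_runs=1), 205, 2.0)
        fit = glm.fit_glm(np.random.default_rng(0).normal(size=(205, 4)), d)
        assert fit.df == 205 - np.linalg.matrix_rank(d.matrix)

    def test_rank_deficient_design_names_columns(self):
        X = np.ones((20, 2))
        d = glm.DesignMatrix(X, ["c1", "c2"], np.array([True, True]), [20])
        with pytest.raises(np.linalg.LinAlgError, match="c2"):
            glm.fit_glm(np.zeros((20, 3)), d)

    def test_ar1_rho_recovery(self, rng):
        n = 4000
        rho = 0.3
        innov = rng.normal(size=(n, 8)) * np.sqrt(1 - rho**2)
        noise = np.empty_like(innov)
        noise[0] = innov[0]
        for t in range(1, n):
            noise[t] = rho * noise[t - 1] + innov[t]
        X = np.column_stack([np.ones(n)])
        d = glm.DesignMatrix(X, ["mean"], np.array([False]), [n])
        fit = glm.fit_glm(noise, d, whitening="ar1")
        assert fit.rho == pytest.approx(rho, abs=0.05)

    def test_ar1_equals_ols_when_rho_zero(self, rng):
        n = 400
        onsets = np.arange(0.0, n * 2.0 - 32, 24.0)
        X = np.column_stack([glm.event_regressor(onsets, n, 2.0), np.ones(n)])
        d = glm.DesignMatrix(X, ["ev", "mean"], np.array([True, False]), [n])
        Y = X @ np.array([[2.0], [1.0]]) + rng.normal(0, 0.5, size=(n, 1))
        ols = glm.fit_glm(Y, d, whitening="none")
        # whitening with an estimated rho near zero barely moves the betas
        ar1 = glm.fit_glm(Y, d, whitening="ar1")
        assert abs(ar1.rho) < 0.1
        assert np.allclose(ols.betas, ar1.betas, atol=0.01)
        # and with rho exactly zero, whitening is the identity
        assert np.allclose(glm._ar1_whiten(Y, 0.0, [n]), Y)

    def test_drift_columns_leave_interest_betas_unchanged(self, rng):
        ev = pd.DataFrame({"onset": [0.0, 30.0, 60.0], "duration": 5.0,
                           "outcome": ["hit", "hit", "CR"]})
        with_hp = glm.build_condition_design(ev, 60, 2.0, hp_cutoff_s=128.0)
        without_hp = glm.build_condition_design(ev, 60, 2.0, hp_cutoff_s=np.inf)
        B_true = rng.normal(size=(len(without_hp.names), 5))
        Y = without_hp.matrix @ B_true  # data with no drift component
        fit_with = glm.fit_glm(Y, with_hp)
        fit_without = glm.fit_glm(Y, without_hp)
        for name in ("hit", "CR"):
            a, b = fit_with.beta(name), fit_without.beta(name)
            assert np.allclose(a, b, rtol=1e-8, atol=1e-8)


class TestSingleTrialRecovery:
    def test_trial_amplitude_correlation_at_default_snr(self, small_setup):
        config, grid, regions = small_setup
        evs = _study_events(n_runs=1)[0]
        act = simulate.ActivationModel({"HIPP": {"study": {"*": 1.0}}},
                                       trial_noise_sd=1.0)
        data, truth = simulate.simulate_run(
            evs, grid, regions, activation_model=act,
            noise_model=simulate.NoiseModel(), seed=3, return_truth=True,
        )
        d = glm.single_trial_design([evs], 205, 2.0)
        fit = glm.fit_glm(data.reshape(-1, 205).T, d)
        est = fit.betas[:64][:, regions["HIPP"].flat_indices].mean(axis=1)
        planted = truth["amplitudes"]["HIPP"]
        assert np.corrcoef(est, planted)[0, 1] > 0.9


@pytest.fixture(scope="module")
def unit_fit(small_setup):
    config, grid, regions = small_setup
    evs = _study_events(n_runs=1)[0]
    act = simulate.ActivationModel({"HIPP": {"study": {"*": 1.0}}},
                                   trial_noise_sd=0.0)
    data = simulate.simulate_run(
        evs, grid, regions, activation_model=act,
        noise_model=noiseless_noise_model(), seed=0,
    )
    d = glm.condition_design_runs([evs], 205, 2.0)
    return glm.fit_glm(data.reshape(-1, 205).T, d), regions


class TestPscAndContrasts:
    def test_injected_one_percent_recovered(self, unit_fit):
        fit, regions = unit_fit
        psc = glm.percent_signal_change(fit, "hit")
        vals = psc[regions["HIPP"].flat_indices]
        assert np.allclose(vals, 1.0, atol=0.05)

    def test_zero_beta_zero_psc(self, unit_fit):
        fit, regions = unit_fit
        psc = glm.percent_signal_change(fit, "hit")
        assert np.allclose(psc[regions["ANG"].flat_indices], 0.0, atol=1e-8)

    def test_psc_linearity(self, unit_fit):
        fit, regions = unit_fit
        doubled = glm.GlmFit(
            betas=fit.betas * 2, names=fit.names, design=fit.design,
            df=fit.df, sigma2=fit.sigma2, mean_signal=fit.mean_signal,
        )
        assert np.allclose(
            glm.percent_signal_change(doubled, "hit"),
            2 * glm.percent_signal_change(fit, "hit"),
            equal_nan=True,
        )

    def test_contrast_identity_and_null(self, unit_fit):
        fit, regions = unit_fit
        # identity weight returns the beta itself
        assert np.allclose(glm.contrast_map(fit, {"hit": 1.0}), fit.beta("hit"))
        # (1, -1) on identical betas is zero everywhere
        diff = glm.contrast_map(fit, {"hit": 1.0}) - glm.contrast_map(fit, {"hit": 1.0})
        assert np.allclose(diff, 0.0)

    def test_contrast_matches_hand_computation(self, unit_fit):
        fit, _ = unit_fit
        w = {"hit": 2.0}
        assert np.allclose(glm.contrast_map(fit, w), 2.0 * fit.beta("hit"))


class TestSmoothing:
    def test_zero_fwhm_identity(self, rng):
        data = rng.normal(size=(6, 6, 4, 3))
        assert glm.smooth_volumes(data, 0.0, 3.0) is data

    def test_smoothing_preserves_mean(self, rng):
        data = rng.normal(size=(8, 8, 6, 2))
        sm = glm.smooth_volumes(data, 8.0, 3.0)
        assert sm[..., 0].mean() == pytest.approx(data[..., 0].mean(), abs=0.02)
        assert sm[..., 0].std() < data[..., 0].std()
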
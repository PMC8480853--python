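"""Backward-model fitting, evaluation, baselines, and the forward transform."""

import dataclasses

import numpy as np
import pytest

import envtrack as et
from envtrack.trials import Trial

from conftest import bandlimited_noise


def _inband_trials(n_trials=4, rate=64.0, dur=40.0, n_ch=6, noise=0.0, seed=0):
    """Trials whose target is band-limited and whose EEG carries it at lag 0.

    Channel c = gradient_c * s(t) + noise; with the 2-16 Hz target inside the
    model band, held-out reconstruction should be near-perfect when noiseless.
    """
    rng = np.random.default_rng(seed)
    gradient = np.linspace(1.0, 0.3, n_ch)
    trials = []
    n = int(dur * rate)
    for _ in range(n_trials):
        s = bandlimited_noise(n, rate, 2.0, 14.0, rng)
        eeg = gradient[:, None] * s[None, :]
        if noise > 0:
            eeg = eeg + noise * rng.standard_normal(eeg.shape)
        trials.append(Trial(eeg=eeg, envelope=s, rate=rate))
    return trials


SPEC = et.ModelSpec(0.5, 32.0, 4, 64.0).with_trim(2.0, 2.0)


class TestRemoveMovingAverage:
    def test_constant_maps_to_zero(self):
        out = et.remove_moving_average(np.full(100, 7.0), 0.25, 64.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_full_period_sinusoid_unchanged_in_interior(self):
        rate, window = 64.0, 0.5
        t = np.arange(int(8 * rate)) / rate
        x = np.sin(2 * np.pi * 2.0 * t)  # period 0.5 s = window
        out = et.remove_moving_average(x, window, rate)
        interior = slice(int(rate), -int(rate))
        np.testing.assert_allclose(out[interior], x[interior], atol=0.05)

    def test_attenuation_matches_sinc_frequency_response(self):
        """Subtracting the moving mean has response 1 - sinc(f w)."""
        rate, window = 128.0, 0.5
        f = 1.0 / (2 * window)
        t = np.arange(int(64 * rate)) / rate
        x = 3.0 + np.sin(2 * np.pi * f * t)
        out = et.remove_moving_average(x, window, rate)
        interior = slice(int(4 * rate), -int(4 * rate))
        assert np.abs(out[interior].mean()) < 0.01  # DC gone
        measured = np.sqrt(2) * out[interior].std()
        expected = np.abs(1 - np.sinc(f * window))
        assert measured == pytest.approx(expected, rel=0.02)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            et.remove_moving_average(np.zeros(10), 1.0, 64.0)


class TestSpatialPCA:
    def test_correlated_channels_collapse_to_one_component(self, rng):
        base = rng.standard_normal(500)
        eeg = np.vstack([base, 2.0 * base])
        pca = et.fit_spatial_pca([eeg], 2)
        assert pca.component_variance[0] > 0
        assert pca.component_variance[1] == pytest.approx(0.0, abs=1e-20)

    def test_orthonormal_loadings_and_eigen_oracle(self, rng):
        eeg = rng.standard_normal((5, 400))
        pca = et.fit_spatial_pca([eeg], 5)
        np.testing.assert_allclose(
            pca.loadings.T @ pca.loadings, np.eye(5), atol=1e-8
        )
        cov = np.cov(eeg - eeg.mean(axis=1, keepdims=True), ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(pca.component_variance, eigvals, atol=1e-10)
        assert np.all(np.diff(pca.component_variance) <= 1e-10)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            et.fit_spatial_pca([rng.standard_normal((3, 100))], 4)


class TestBackwardModel:
    def test_noiseless_inband_tracking_recovers_heldout_envelope(self):
        trials = _inband_trials(noise=0.0)
        model = et.fit_backward_model(trials[:3], SPEC)
        res = et.reconstruct(model, trials[3])
        assert res.r > 0.99

    def test_training_trial_reconstruction_near_perfect(self):
        trials = _inband_trials(noise=0.0)
        model = et.fit_backward_model(trials, SPEC)
        assert et.reconstruct(model, trials[0]).r > 0.99

    def test_independent_envelope_gives_near_zero_r(self):
        rs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            trials = _inband_trials(noise=0.0, seed=seed)
            # replace the test envelope with independent in-band noise
            alien = Trial(
                eeg=trials[3].eeg,
                envelope=bandlimited_noise(trials[3].n_samples, 64.0, 2.0, 14.0, rng),
                rate=64.0,
            )
            model = et.fit_backward_model(trials[:3], SPEC)
            rs.append(et.reconstruct(model, alien).r)
        assert np.abs(np.mean(rs)) < 0.2

    def test_constant_envelope_rejected(self):
        trials = _inband_trials(n_trials=2)
        bad = Trial(eeg=trials[0].eeg, envelope=np.zeros(trials[0].n_samples), rate=64.0)
        with pytest.raises(ValueError, match="constant"):
            et.fit_backward_model([bad, trials[1]], SPEC)

    def test_zero_weight_model_errors_not_nan(self):
        trials = _inband_trials()
        model = et.fit_backward_model(trials[:3], SPEC)
        dead = dataclasses.replace(model, w_s=np.zeros_like(model.w_s))
        with pytest.raises(ValueError, match="zero variance"):
            et.reconstruct(dead, trials[3])

    def test_global_rescaling_of_test_eeg_leaves_r_unchanged(self):
        trials = _inband_trials(noise=0.3)
        model = et.fit_backward_model(trials[:3], SPEC)
        r1 = et.reconstruct(model, trials[3]).r
        scaled = Trial(eeg=53.1 * trials[3].eeg, envelope=trials[3].envelope, rate=64.0)
        r2 = et.reconstruct(model, scaled).r
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_excessive_trim_rejected(self):
        trials = _inband_trials(dur=10.0)
        spec = SPEC.with_trim(3.0, 3.0)
        with pytest.raises(ValueError, match="trim"):
            et.fit_backward_model(trials, spec)


class TestLeaveOneOut:
    def test_count_and_consistency_on_statistically_identical_trials(self):
        trials = _inband_trials(n_trials=5, noise=0.5)
        results = et.leave_one_out(trials, SPEC)
        assert len(results) == 5
        rs = [r.r for r in results]
        assert max(rs) - min(rs) < 0.05

    def test_order_equivariance(self):
        trials = _inband_trials(n_trials=4, noise=0.5)
        res = et.leave_one_out(trials, SPEC)
        perm = [2, 0, 3, 1]
        res_p = et.leave_one_out([trials[i] for i in perm], SPEC)
        for new_id, old_id in enumerate(perm):
            assert res_p[new_id].r == pytest.approx(res[old_id].r, abs=1e-10)

    def test_requires_three_trials(self):
        with pytest.raises(ValueError):
            et.leave_one_out(_inband_trials(n_trials=2), SPEC)


class TestRidgeBaseline:
    def test_lambda_zero_equals_ols(self):
        """Ridge at lambda 0 is OLS: identical held-out reconstructions."""
        trials = _inband_trials(n_trials=3, noise=0.5, n_ch=3, dur=30.0)
        r0 = et.ridge_baseline(trials, 0.25, lambdas=[0.0])
        from envtrack.models import _ridge_trial_design, _ridge_solve

        prepped = [_ridge_trial_design(t, 0.25) for t in trials]
        G = sum(X.T @ X for X, _ in prepped[1:])
        b = sum(X.T @ y for X, y in prepped[1:])
        w = _ridge_solve(G, b, 0.0)
        X0, y0 = prepped[0]
        assert r0[0].r == pytest.approx(et.pearson_r(X0 @ w, y0), abs=1e-8)

    def test_heavy_regularization_shrinks_weights(self):
        from envtrack.models import _ridge_trial_design, _ridge_solve

        trials = _inband_trials(n_trials=2, noise=0.5, n_ch=3, dur=30.0)
        X, y = _ridge_trial_design(trials[0], 0.25)
        w_small = _ridge_solve(X.T @ X, X.T @ y, 1.0)
        w_big = _ridge_solve(X.T @ X, X.T @ y, 1e8)
        assert np.linalg.norm(w_big) < 1e-3 * np.linalg.norm(w_small)

    def test_collinear_channels_fall_back_with_warning(self, rng):
        base = bandlimited_noise(int(30 * 64), 64.0, 2.0, 14.0, rng)
        trials = []
        for seed in range(3):
            r2 = np.random.default_rng(seed + 10)
            s = bandlimited_noise(int(30 * 64), 64.0, 2.0, 14.0, r2)
            eeg = np.vstack([s, s])  # exactly collinear
            trials.append(Trial(eeg=eeg, envelope=s, rate=64.0))
        with pytest.warns(UserWarning, match="singular"):
            et.ridge_baseline(trials, 0.25, lambdas=[0.0])

    def test_ridge_matches_spline_model_at_matched_band(self, small_trials, small_spec):
        """On synthetic data the two decoders agree to within sampling error."""
        spline_r = np.mean([r.r for r in et.leave_one_out(small_trials, small_spec)])
        ridge_r = np.mean([r.r for r in et.ridge_baseline(small_trials, 0.5)])
        assert abs(spline_r - ridge_r) < 0.2


class TestGridSearch:
    def test_single_cell_grid_returned(self, small_trials):
        best, table = et.grid_search(
            small_trials, [0.5], [16.0], [4], trim=(1.5, 1.5)
        )
        assert (best.window_s, best.knot_rate, best.n_components) == (0.5, 16.0, 4)
        assert len(table) == 1

    def test_table_covers_grid_and_selects_adequate_bandwidth(self, small_trials):
        """A kernel with content up to ~8 Hz needs knots at >= 16 Hz."""
        best, table = et.grid_search(
            small_trials, [0.5], [4.0, 16.0], [2, 4], trim=(1.5, 1.5)
        )
        assert len(table) == 4
        assert best.knot_rate >= 16.0

    def test_empty_grid_rejected(self, small_trials):
        with pytest.raises(ValueError):
            et.grid_search(small_trials, [], [16.0], [4])


class TestForwardModel:
    def test_identity_design_covariance_returns_backward_weights(self):
        trials = _inband_trials()
        model = et.fit_backward_model(trials, SPEC)
        white = dataclasses.replace(
            model,
            design_gram=np.eye(model.n_features) * model.n_train_samples,
        )
        fwd_s = model.design_gram @ model.w_s.ravel() / model.n_train_samples
        a_s = et.backward_to_forward(white)
        # with identity covariance a_s equals w_s before the spline expansion
        manual = (model.w_s @ model.basis.S.T)
        var = model.pca.component_variance
        scale = var[: SPEC.n_components] / var.sum()
        expected = model.pca.loadings @ (manual * scale[:, None])
        np.testing.assert_allclose(a_s.weights, expected, atol=1e-10)
        assert fwd_s.shape == (model.n_features,)

    def test_zero_backward_weights_give_zero_forward(self):
        trials = _inband_trials()
        model = et.fit_backward_model(trials, SPEC)
        dead = dataclasses.replace(model, w_s=np.zeros_like(model.w_s))
        assert np.all(et.backward_to_forward(dead).weights == 0)

    def test_recovery_monotone_in_snr(self):
        """Forward-model fidelity to the true kernel grows with SNR."""
        corrs = []
        for snr in (1.0, 10.0):
            cfg = et.SynthConfig(
                n_channels=8, eeg_rate=64.0, duration_s=60.0, snr=snr, seed=7
            )
            trials = et.synth_trialset(cfg, n_trials=4)
            spec = et.ModelSpec(0.5, 32.0, 8, 64.0).with_trim(2.0, 2.0)
            fwd = et.backward_to_forward(et.fit_backward_model(trials, spec))
            kern = trials[0].extras["kernel"]
            padded = np.zeros_like(fwd.weights)
            L = min(fwd.n_delays, kern.shape[1])
            padded[:, :L] = kern[:, :L]
            corrs.append(et.pearson_r(fwd.weights.ravel(), padded.ravel()))
        assert corrs[0] > 0.5
        assert corrs[1] > corrs[0]

    def test_missing_covariance_rejected(self):
        trials = _inband_trials()
        model = et.fit_backward_model(trials, SPEC)
        bare = dataclasses.replace(model, design_gram=None)
        with pytest.raises(ValueError):
            et.backward_to_forward(bare)


def test_pearson_r_bounds_and_degenerate_error(rng):
    x = rng.standard_normal(50)
    assert et.pearson_r(x, x) == pytest.approx(1.0)
    assert et.pearson_r(x, -x) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        et.pearson_r(x, np.zeros(50))
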
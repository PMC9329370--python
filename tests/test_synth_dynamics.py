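import numpy as np
import pytest

import kmmae as K
from kmmae.synth_dynamics import DivergenceError


def lin_spec(M, x0):
    return K.LatentSystemSpec("linear_discrete", {"M": np.asarray(M, float)},
                              1.0, np.asarray(x0, float))


class TestSimulateLatent:
    @pytest.mark.parametrize("M, x0, expected", [
        (np.eye(2), [1, 2], [[1, 2], [1, 2], [1, 2]]),
        (np.diag([0.5, 1.0]), [4, 4], [[4, 4], [2, 4], [1, 4]]),
    ])
    def test_linear_discrete_exact(self, M, x0, expected):
        traj = K.simulate_latent(lin_spec(M, x0), 3)
        np.testing.assert_allclose(traj, expected)

    def test_slow_manifold_matches_closed_form(self):
        # dx1/dt = mu x1, dx2/dt = lam (x2 - x1^2) has the closed-form
        # solution x1 = e^{mu t}, x2 = (1-c) e^{lam t} + c e^{2 mu t},
        # c = lam/(lam - 2 mu), for x0 = (1, 1).
        mu, lam, dt = -0.05, -1.0, 0.01
        spec = K.slow_manifold_spec(mu, lam, dt, (1.0, 1.0))
        traj = K.simulate_latent(spec, 101)  # t = 1 at row 100
        c = lam / (lam - 2 * mu)
        x1_exact = np.exp(mu * 1.0)
        x2_exact = (1 - c) * np.exp(lam * 1.0) + c * np.exp(2 * mu * 1.0)
        np.testing.assert_allclose(traj[100], [x1_exact, x2_exact], rtol=1e-8)

    def test_slow_manifold_against_adaptive_integrator(self):
        from scipy.integrate import solve_ivp
        spec = K.slow_manifold_spec(-0.05, -1.0, 0.01, (1.0, 0.5))
        traj = K.simulate_latent(spec, 201)
        sol = solve_ivp(lambda t, y: spec.rhs()(y), (0, 2.0), [1.0, 0.5],
                        t_eval=[2.0], rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(traj[200], sol.y[:, 0], rtol=1e-7)

    def test_divergence_reports_step(self):
        with pytest.raises(DivergenceError, match=r"step \d+"):
            K.simulate_latent(lin_spec(np.array([[1e300, 0], [0, 1e300]]),
                                       [1.0, 1.0]), 5)

    def test_row_zero_is_x0(self):
        traj = K.simulate_latent(K.slow_manifold_spec(x0=(0.3, -0.2)), 10)
        np.testing.assert_array_equal(traj[0], [0.3, -0.2])


class TestObserveModalities:
    def test_identity_no_delay_reproduces_latent(self):
        latent = K.simulate_latent(lin_spec(K.rotation_matrix(0.3), [1, 0]), 50)
        obs = K.ObservationSpec((K.ModalityObservation("m", "identity", channels=2),))
        (s,) = K.observe_modalities(latent, obs)
        np.testing.assert_array_equal(s.values, latent)

    def test_delay_shifts_by_stated_steps(self):
        latent = np.arange(20.0).reshape(-1, 1)
        obs = K.ObservationSpec((
            K.ModalityObservation("A", "identity", delay_steps=0),
            K.ModalityObservation("B", "identity", delay_steps=3),
        ))
        a, b = K.observe_modalities(latent, obs)
        assert a.n_steps == b.n_steps == 17
        np.testing.assert_array_equal(b.values[3:], a.values[:-3])

    def test_polynomial_square_map(self):
        latent = np.array([[-2.0], [3.0]])
        obs = K.ObservationSpec((K.ModalityObservation(
            "sq", "polynomial", {"coeffs": [0, 0, 1]}),))
        (s,) = K.observe_modalities(latent, obs)
        np.testing.assert_array_equal(s.values, [[4.0], [9.0]])

    def test_delay_exceeding_length_errors(self):
        with pytest.raises(ValueError):
            K.observe_modalities(np.ones((4, 1)), K.ObservationSpec(
                (K.ModalityObservation("m", delay_steps=4),)))

    def test_cross_correlation_peaks_at_delay_difference(self):
        latent = K.simulate_latent(lin_spec(K.rotation_matrix(0.21), [1, 0]), 400)
        obs = K.ObservationSpec((
            K.ModalityObservation("A", "identity", delay_steps=0),
            K.ModalityObservation("B", "identity", delay_steps=7),
        ))
        a, b = K.observe_modalities(latent, obs)
        x, y = a.values[:, 0], b.values[:, 0]
        # B lags A by 7, so correlating x(k+l) with y(k) peaks at l = -7
        lags = range(-15, 16)
        cc = [np.corrcoef(x[15 + l:len(x) - 15 + l], y[15:-15])[0, 1] for l in lags]
        assert list(lags)[int(np.argmax(cc))] == -7


class TestAddNoiseSnr:
    def test_realized_snr_within_1db(self):
        t = np.arange(10_000)
        s = K.ModalSeries.from_column("sin", np.sin(2 * np.pi * t / 40))
        noisy = K.add_noise_snr(s, 10.0, seed=0)
        noise = noisy.values - s.values
        realized = 10 * np.log10(np.mean((s.values - s.values.mean()) ** 2)
                                 / np.mean(noise ** 2))
        assert abs(realized - 10.0) < 1.0

    def test_infinite_snr_is_passthrough(self):
        s = K.ModalSeries.from_column("m", [1.0, 2.0, 3.0])
        out = K.add_noise_snr(s, np.inf, seed=0)
        np.testing.assert_array_equal(out.values, s.values)

    def test_zero_variance_channel_errors(self):
        s = K.ModalSeries.from_column("m", [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="zero-variance"):
            K.add_noise_snr(s, 10.0, seed=0)

    def test_deterministic_given_seed(self):
        s = K.ModalSeries.from_column("m", np.sin(np.arange(100.0)))
        a = K.add_noise_snr(s, 10.0, seed=42)
        b = K.add_noise_snr(s, 10.0, seed=42)
        np.testing.assert_array_equal(a.values, b.values)


class TestMaskModality:
    def _batch(self):
        return [K.ModalSeries.from_column("hr", [1.0, 2.0, 3.0]),
                K.ModalSeries.from_column("eda", [4.0, 5.0, 6.0])]

    def test_masked_values_and_flag(self):
        out = K.mask_modality(self._batch(), "hr", -1.0)
        hr = next(s for s in out if s.modality_id == "hr")
        assert np.all(hr.values == -1.0) and hr.all_missing

    def test_other_modalities_untouched(self):
        batch = self._batch()
        out = K.mask_modality(batch, "hr")
        eda = next(s for s in out if s.modality_id == "eda")
        np.testing.assert_array_equal(eda.values, batch[1].values)
        assert not eda.missing_mask.any()

    def test_idempotent(self):
        once = K.mask_modality(self._batch(), "hr")
        twice = K.mask_modality(once, "hr")
        np.testing.assert_array_equal(once[0].values, twice[0].values)
        np.testing.assert_array_equal(once[0].missing_mask, twice[0].missing_mask)

    def test_unknown_modality_errors(self):
        with pytest.raises(KeyError):
            K.mask_modality(self._batch(), "emg")


class TestMakeStimulusDataset:
    def _specs(self):
        pre = lin_spec(K.rotation_matrix(0.15), [1, 0])
        post = lin_spec(K.rotation_matrix(0.9), [1, 0])
        obs = K.ObservationSpec((
            K.ModalityObservation("A", "identity", channels=2, delay_steps=0),
            K.ModalityObservation("B", "identity", channels=2, delay_steps=5),
        ))
        return pre, post, obs

    def test_onset_metadata_reflects_delays(self):
        pre, post, obs = self._specs()
        _, meta = K.make_stimulus_dataset(pre, post, obs, 100, 150, seed=0)
        assert meta.observed_onsets["B"] - meta.observed_onsets["A"] == 5

    def test_deterministic_given_seed(self):
        pre, post, obs = self._specs()
        s1, _ = K.make_stimulus_dataset(pre, post, obs, 100, 150, seed=9)
        s2, _ = K.make_stimulus_dataset(pre, post, obs, 100, 150, seed=9)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_identical_specs_match_plain_simulation(self):
        pre, _, obs = self._specs()
        series, _ = K.make_stimulus_dataset(pre, pre, obs, 100, 150, seed=0)
        latent = K.simulate_latent(pre, 150)
        plain = K.observe_modalities(latent, obs, seed=0)
        for a, b in zip(series, plain):
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_dimension_mismatch_errors(self):
        pre, _, obs = self._specs()
        post3 = K.LatentSystemSpec("linear_discrete", {"M": np.eye(3)}, 1.0,
                                   [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="dimension"):
            K.make_stimulus_dataset(pre, post3, obs, 100, 150)
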
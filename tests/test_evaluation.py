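import numpy as np
import pytest

import kmmae as K
from kmmae.evaluation import (EventTrace, detect_reaction_time, dmd_fit,
                              loss_trace, restore_missing, rmse, rollout_predict)
from kmmae.model import ModelArch, init_params, step_linear
from tests.test_losses import identity_model


class TestRmse:
    def test_identical_zero(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        assert rmse(x, x) == 0.0

    def test_constant_offset(self):
        assert np.isclose(rmse(np.zeros((4, 2)), np.full((4, 2), -2.5)), 2.5)

    def test_worked_example(self):
        assert np.isclose(rmse([0.0, 0.0], [3.0, 4.0]), np.sqrt(12.5))

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert rmse(a, b) == rmse(b, a)


class TestDmdFit:
    def test_exact_recovery_on_linear_trajectory(self):
        M = np.array([[0.9, -0.1], [0.2, 0.7]])
        x = [np.array([1.0, 0.3])]
        for _ in range(40):
            x.append(M @ x[-1])
        A = dmd_fit(np.array(x))
        np.testing.assert_allclose(A, M, atol=1e-8)


class TestRestoreMissing:
    def test_duplicate_modalities_exact(self):
        # two identity modalities carrying the same signal: restoring one
        # from the other is exact for an identity pipeline
        model = identity_model(width=2, n_mod=2)
        x = np.random.default_rng(2).normal(size=(6, 2))
        out = restore_missing(model, {"m0": x, "m1": x}, ["m1"],
                              destandardize=False)
        np.testing.assert_allclose(out["m1"]["embedded"], x, atol=1e-12)

    def test_output_ignores_masked_modality_contents(self):
        model = identity_model(width=2, n_mod=2)
        x = np.random.default_rng(3).normal(size=(6, 2))
        a = restore_missing(model, {"m0": x, "m1": np.full((6, 2), -1.0)},
                            ["m1"], destandardize=False)
        b = restore_missing(model, {"m0": x, "m1": np.full((6, 2), 123.0)},
                            ["m1"], destandardize=False)
        np.testing.assert_array_equal(a["m1"]["embedded"], b["m1"]["embedded"])

    def test_all_missing_errors(self):
        model = identity_model(width=2, n_mod=2)
        with pytest.raises(ValueError):
            restore_missing(model, {}, ["m0", "m1"])

    def test_restoration_consistency_with_direct_decode(self):
        from kmmae.model import decode, encode, fuse
        arch = ModelArch({"a": 3, "b": 3}, hidden=(6, 4), p=3)
        model = init_params(arch, 5)
        x = np.random.default_rng(4).normal(size=(5, 3))
        out = restore_missing(model, {"a": x}, ["b"], destandardize=False)
        direct = decode(model, "b", fuse({"a": encode(model, "a", x)}))
        np.testing.assert_array_equal(out["b"]["embedded"], direct)


class TestRolloutPredict:
    def test_identity_A_repeats_reconstruction(self):
        model = identity_model(width=2)
        x = np.random.default_rng(5).normal(size=(4, 2))
        preds = rollout_predict(model, {"m0": x}, horizon=3)
        for h in range(3):
            np.testing.assert_allclose(preds["m0"][h], x, atol=1e-12)

    def test_second_step_equals_two_applications(self):
        model = identity_model(width=2)
        model.params["A"] = np.array([[0.8, 0.1], [0.0, 0.9]])
        x = np.random.default_rng(6).normal(size=(3, 2))
        preds = rollout_predict(model, {"m0": x}, horizon=2)
        np.testing.assert_allclose(preds["m0"][1], step_linear(model, x, 2),
                                   rtol=1e-12)

    def test_noiseless_slow_manifold_rollout_accuracy(self):
        # identity pipeline on the latent state with A set to the exact
        # one-step propagator: 10-step rollout error stays small
        mu, lam, dt = -0.05, -1.0, 0.01
        spec = K.slow_manifold_spec(mu, lam, dt, (1.0, 1.0))
        traj = K.simulate_latent(spec, 300)
        model = identity_model(width=3)
        model.params["A"] = np.diag(np.exp(np.array([mu, lam, 2 * mu]) * dt))
        lifted = np.column_stack([traj[:, 0], traj[:, 1] -
                                  lam / (lam - 2 * mu) * traj[:, 0] ** 2,
                                  traj[:, 0] ** 2])
        preds = rollout_predict(model, {"m0": lifted[:-10]}, horizon=10)
        for h in range(10):
            err = rmse(lifted[h + 1:len(lifted) - 9 + h], preds["m0"][h])
            assert err < 0.1


class TestLossTrace:
    def test_trace_lengths_reported(self):
        model = identity_model(width=2)
        seg = {"m0": np.random.default_rng(7).normal(size=(30, 2))}
        tr = loss_trace(model, seg, stimulus_index=10, horizon=1)
        assert len(tr.loss1) == len(tr.loss2) == 29
        assert tr.time_base[0] == 1

    def test_identity_pipeline_zero_recon_trace(self):
        model = identity_model(width=2)
        seg = {"m0": np.random.default_rng(8).normal(size=(20, 2))}
        tr = loss_trace(model, seg, stimulus_index=5)
        assert np.all(tr.loss1 < 1e-24)

    def test_stationary_trace_has_no_trend(self):
        from scipy.stats import kendalltau
        arch = ModelArch({"a": 2}, hidden=(6, 4), p=2)
        model = init_params(arch, 0)
        t = np.arange(400)
        seg = {"a": np.column_stack([np.sin(0.3 * t), np.cos(0.3 * t)])}
        tr = loss_trace(model, seg, stimulus_index=100)
        tau, _ = kendalltau(np.arange(len(tr.loss1)), tr.loss1)
        assert abs(tau) < 0.2

    def test_too_short_errors(self):
        model = identity_model(width=2)
        with pytest.raises(ValueError):
            loss_trace(model, {"m0": np.zeros((1, 2))}, horizon=1)


class TestDetectReactionTime:
    def _trace(self, loss1, loss2, stim):
        return EventTrace(np.asarray(loss1, float), np.asarray(loss2, float),
                          stimulus_index=stim)

    def test_constructed_step_trace(self):
        l = np.where(np.arange(20) >= 12, 2.0, 1.0)
        tr = self._trace(l, l.copy(), stim=10)
        assert detect_reaction_time(tr, ratio=1.5, consec_len=3) == 12

    def test_flat_trace_none(self):
        tr = self._trace(np.ones(20), np.ones(20), stim=10)
        assert detect_reaction_time(tr, ratio=1.5, consec_len=3) is None

    def test_requires_both_losses(self):
        l1 = np.where(np.arange(20) >= 12, 2.0, 1.0)
        tr = self._trace(l1, np.ones(20), stim=10)
        assert detect_reaction_time(tr, ratio=1.5, consec_len=3) is None

    def test_monotone_in_ratio(self):
        rng = np.random.default_rng(9)
        base = 1 + 0.1 * rng.random(40)
        spike = base.copy()
        spike[20:] += np.linspace(0, 3, 20)
        results = []
        for ratio in (1.2, 1.5, 2.0, 3.0):
            tr = self._trace(spike, spike.copy(), stim=15)
            r = detect_reaction_time(tr, ratio=ratio, consec_len=3)
            results.append(np.inf if r is None else r)
        assert all(a <= b for a, b in zip(results, results[1:]))

    def test_prestimulus_exceedance_flagged(self):
        l = np.ones(20)
        l[2:6] = 5.0
        l[12:] = 5.0
        tr = self._trace(l, l.copy(), stim=10)
        with pytest.warns(UserWarning, match="before the stimulus"):
            r = detect_reaction_time(tr, ratio=1.5, consec_len=3)
        assert r == 12 and tr.prestimulus_warning

    def test_empty_prestimulus_errors(self):
        tr = self._trace(np.ones(10), np.ones(10), stim=0)
        with pytest.raises(ValueError):
            detect_reaction_time(tr)

    def test_detection_starts_at_stimulus(self):
        # exceedance entirely before the stimulus is never reported
        l = np.ones(20)
        l[2:5] = 5.0
        tr = self._trace(l, l.copy(), stim=10)
        with pytest.warns(UserWarning):
            assert detect_reaction_time(tr, ratio=1.5, consec_len=3) is None
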
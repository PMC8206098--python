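import numpy as np
import pytest

from neuroevo.reservoir import (DivergenceError, ReservoirParams, RLSState,
                                force_train, force_train_many, init_reservoir,
                                load_reservoir, rls_step, run_autonomous,
                                save_reservoir, step_dynamics)
from neuroevo.signals import random_fourier_signal

from conftest import make_decoupled_reservoir


class TestInitialisation:
    def test_toy_shapes(self):
        params = ReservoirParams(n_neuron=6, t_train=1.0, t_signal=1.0,
                                 t_evaluation=0.5)
        res = init_reservoir(params, seed=0)
        assert res.Q.shape == (6, 6)
        assert res.F.shape == (1, 6)
        assert res.B.shape == (6, 1)
        assert res.x.shape == (6,)

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_recurrent_diagonal_is_zero(self, seed):
        res = init_reservoir(ReservoirParams(n_neuron=50, t_train=1.0,
                                             t_signal=1.0, t_evaluation=0.5),
                             seed=seed)
        assert np.all(res.Q.todense().diagonal() == 0.0)

    def test_weight_moments_at_full_scale(self):
        """Nonzero recurrent weights have std g / sqrt(p n); density ~ p."""
        params = ReservoirParams(n_neuron=1000)
        target = 1.5 / np.sqrt(0.1 * 1000)
        stds, densities = [], []
        for seed in range(10):
            res = init_reservoir(params, seed=seed)
            q = res.Q.tocoo()
            stds.append(np.std(q.data))
            densities.append(q.nnz / (1000 * 999))
        assert np.mean(stds) == pytest.approx(target, rel=0.05)
        assert np.mean(densities) == pytest.approx(0.1, rel=0.05)
        # readout uniform on (-1, 1), feedback same scale as recurrent
        assert np.abs(res.F).max() <= 1.0
        assert np.std(res.B) == pytest.approx(target, rel=0.2)

    def test_seed_determinism_is_bitwise(self):
        params = ReservoirParams(n_neuron=80, t_train=1.0, t_signal=1.0,
                                 t_evaluation=0.5)
        a = init_reservoir(params, seed=5)
        b = init_reservoir(params, seed=5)
        assert (a.Q != b.Q).nnz == 0
        np.testing.assert_array_equal(a.F, b.F)
        np.testing.assert_array_equal(a.B, b.B)
        np.testing.assert_array_equal(a.x, b.x)

    @pytest.mark.parametrize("kwargs", [
        {"n_neuron": 0}, {"p": 0.0}, {"p": 1.5}, {"g": -1.0},
        {"alpha": 0.0}, {"n_readout": 2}, {"rls_every": 0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ReservoirParams(**kwargs)


class TestDynamics:
    def test_decoupled_step_is_euler_decay(self):
        res = make_decoupled_reservoir(4, x0=1.0)
        step_dynamics(res)
        np.testing.assert_allclose(res.x, 0.9, atol=1e-15)

    def test_origin_is_fixed_point(self):
        res = make_decoupled_reservoir(4, x0=0.0)
        step_dynamics(res)
        np.testing.assert_array_equal(res.x, 0.0)

    def test_converges_to_exponential_decay(self):
        res = make_decoupled_reservoir(1, x0=1.0, dt=0.01)
        for _ in range(100):
            step_dynamics(res)
        assert res.x[0] == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_euler_error_is_first_order(self):
        errs = []
        for dt in (0.02, 0.01):
            res = make_decoupled_reservoir(1, x0=1.0, dt=dt)
            for _ in range(int(round(1.0 / dt))):
                step_dynamics(res)
            errs.append(abs(res.x[0] - np.exp(-1.0)))
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.3)

    def test_autonomous_run_length_and_state_advance(self):
        params = ReservoirParams(n_neuron=60, t_train=30.0, t_signal=300.0,
                                 t_evaluation=30.0)
        res = init_reservoir(params, seed=2)
        sig = run_autonomous(res, 300.0)
        assert sig.n_samples == 3000
        # running in two halves gives the same trace as one full run
        res_a = init_reservoir(params, seed=2)
        first = run_autonomous(res_a, 150.0)
        second = run_autonomous(res_a, 150.0)
        np.testing.assert_allclose(
            np.concatenate([first.samples, second.samples]), sig.samples,
            atol=1e-12)

    def test_zero_duration_gives_empty_signal(self):
        res = make_decoupled_reservoir(3, x0=1.0)
        assert run_autonomous(res, 0.0).n_samples == 0

    def test_divergence_guard_trips(self):
        res = make_decoupled_reservoir(3, x0=1e7)
        with pytest.raises(DivergenceError):
            step_dynamics(res)


class TestRLS:
    def test_initial_matrix_is_identity_over_alpha(self):
        state = RLSState.initial(4, alpha=1.0)
        np.testing.assert_array_equal(state.P, np.eye(4))
        state2 = RLSState.initial(4, alpha=2.0)
        np.testing.assert_array_equal(state2.P, np.eye(4) / 2.0)

    def test_zero_error_changes_only_P(self):
        state = RLSState.initial(5, alpha=1.0)
        before = state.P.copy()
        rng = np.random.default_rng(0)
        _, dF = rls_step(state, rng.standard_normal(5), 0.0)
        np.testing.assert_array_equal(dF, 0.0)
        assert not np.array_equal(state.P, before)

    @pytest.mark.parametrize("alpha", [1.0, 0.5])
    def test_matches_batch_ridge_inverse(self, alpha):
        """After k rank-1 updates P equals (alpha I + sum r r^T)^{-1}."""
        rng = np.random.default_rng(42)
        n = 5
        state = RLSState.initial(n, alpha=alpha)
        rs = rng.standard_normal((50, n))
        for r in rs:
            rls_step(state, r, e=rng.standard_normal())
        batch = np.linalg.inv(alpha * np.eye(n) + rs.T @ rs)
        np.testing.assert_allclose(state.P, batch, atol=1e-6)

    def test_stays_symmetric_positive_definite(self):
        rng = np.random.default_rng(1)
        state = RLSState.initial(6, alpha=1.0)
        for _ in range(200):
            rls_step(state, rng.standard_normal(6), e=rng.standard_normal())
            assert np.max(np.abs(state.P - state.P.T)) < 1e-8
        assert np.all(np.linalg.eigvalsh(state.P) > 0)


class TestForceTraining:
    def test_error_trace_has_training_length(self, tiny_params):
        res = init_reservoir(tiny_params, seed=0)
        tgt = random_fourier_signal(2, 2.0, 30.0, 0.1, seed=1, period=10.0)
        result = force_train(res, tgt)
        assert result.error.shape == (300,)
        assert result.output.shape == (300,)

    def test_short_target_is_tiled(self, tiny_params):
        res = init_reservoir(tiny_params, seed=0)
        result = force_train(res, np.sin(np.arange(100) * 0.1))
        assert result.error.shape == (300,)

    def test_self_target_does_not_get_worse(self, tiny_params):
        """Training on the unit's own output leaves the final mismatch no
        larger than the initial one."""
        res = init_reservoir(tiny_params, seed=3)
        own = run_autonomous(res.copy(), 30.0)
        result = force_train(res, own)
        n_eval = tiny_params.n_eval_steps
        initial = np.sqrt(np.mean(result.error[:n_eval] ** 2))
        assert result.final_rms <= initial + 1e-12

    def test_learns_simple_periodic_target(self):
        """A small reservoir tracks a half-amplitude sine (one period per
        evaluation window) to within 10% of its range for typical seeds.
        The residual floor is set by the random initial readout weights,
        which the ridge-regularised RLS can only partially unlearn."""
        params = ReservoirParams(n_neuron=100)
        target = 0.5 * np.sin(2 * np.pi * np.arange(3000) * 0.1 / 30.0)
        errors = []
        for seed in (1, 2, 3):
            res = init_reservoir(params, seed=seed)
            errors.append(force_train(res, target).final_rms)
        assert np.median(errors) < 0.1 * np.ptp(target)

    def test_copy_fidelity_at_full_scale(self):
        """A 1000-neuron unit reproduces a 5-harmonic target to < 10% of its
        range over the evaluation window."""
        params = ReservoirParams(n_neuron=1000)
        res = init_reservoir(params, seed=0)
        tgt = random_fourier_signal(5, 2.0, 300.0, 0.1, seed=100, period=30.0)
        result = force_train(res, tgt)
        assert result.final_rms < 0.1 * np.ptp(tgt.samples)

    def test_divergence_reports_step(self, tiny_params):
        res = init_reservoir(tiny_params, seed=0)
        res.x[:] = 2e6
        with pytest.raises(DivergenceError) as exc:
            force_train(res, np.zeros(300))
        assert exc.value.step == 0

    def test_batch_kernel_matches_reference_loop(self, tiny_params):
        """The compiled population trainer and the plain reference loop are
        the same algorithm (float64, elementwise agreement)."""
        tgts = np.stack([
            random_fourier_signal(3, 2.0, 30.0, 0.1, seed=s, period=10.0).samples
            for s in (1, 2)])
        ref, batch_units = [], []
        for s in (1, 2):
            a = init_reservoir(tiny_params, seed=s)
            b = a.copy()
            ref.append(a)
            batch_units.append(b)
        outs = [force_train(ref[i], tgts[i]) for i in range(2)]
        batch = force_train_many(batch_units, tgts, dtype=np.float64)
        assert not batch.diverged.any()
        for i in range(2):
            np.testing.assert_allclose(batch.outputs[i], outs[i].output,
                                       atol=1e-9)
            np.testing.assert_allclose(batch_units[i].F, ref[i].F, atol=1e-9)
            np.testing.assert_allclose(batch_units[i].x, ref[i].x, atol=1e-9)

    def test_batch_flags_divergent_unit_and_keeps_weights(self, tiny_params):
        good = init_reservoir(tiny_params, seed=1)
        bad = init_reservoir(tiny_params, seed=2)
        bad.x[:] = 2e6
        f_before = bad.F.copy()
        tgts = np.zeros((2, 300))
        batch = force_train_many([good, bad], tgts)
        assert batch.diverged.tolist() == [False, True]
        assert batch.diverged_step[1] == 0
        np.testing.assert_array_equal(bad.F, f_before)


def test_serialization_roundtrip(tmp_path, tiny_params):
    res = init_reservoir(tiny_params, seed=9)
    save_reservoir(res, tmp_path / "unit")
    back = load_reservoir(tmp_path / "unit")
    assert (back.Q != res.Q).nnz == 0
    np.testing.assert_array_equal(back.F, res.F)
    np.testing.assert_array_equal(back.B, res.B)
    np.testing.assert_array_equal(back.x, res.x)
    assert back.params == res.params
    assert back.seed == 9
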
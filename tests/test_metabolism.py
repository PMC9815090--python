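"""Composite lifelines, chemostat fixed points and production-rate loss."""

import warnings

import numpy as np
import pytest

import reactorlifelines as rl
from reactorlifelines.metabolism import (
    build_composites,
    chemostat_init,
    integrate_ensemble,
    integrate_response,
    qp_loss,
)


@pytest.fixture(scope="module")
def toy():
    return rl.two_pool_toy()


@pytest.fixture(scope="module")
def nine():
    return rl.nine_pool_synthetic()


def constant_set(q=0.28, n=3, duration=1900.0, dt=1.0):
    nsamp = int(duration / dt) + 1
    lls = tuple(
        rl.Lifeline(parcel_id=i, t_start=0.0, sample_dt=dt, values=np.full(nsamp, q))
        for i in range(n)
    )
    return rl.LifelineSet(lifelines=lls)


class TestBuildComposites:
    def test_segment_count_for_full_span(self):
        """1900 s lifelines merged to an 80 h span need ceil(288000/1900) = 152."""
        s = constant_set(duration=1900.0, dt=1.0)
        comps = build_composites(s, span_h=80.0, n_composites=2, seed=0)
        assert all(len(c.segments) == 152 for c in comps)

    def test_single_segment_when_span_matches(self):
        s = constant_set(duration=1900.0, dt=1.0)
        comps = build_composites(s, span_h=1900.0 / 3600.0, n_composites=1, seed=0)
        assert len(comps[0].segments) == 1
        np.testing.assert_array_equal(
            comps[0].values, s.lifelines[0].values[: comps[0].n_samples]
        )

    def test_default_ensemble_size_is_fifteen(self):
        import inspect

        sig = inspect.signature(build_composites)
        assert sig.parameters["n_composites"].default == 15

    def test_seeded_and_deterministic(self, surrogate_lifelines):
        a = build_composites(surrogate_lifelines, span_h=0.5, n_composites=3, seed=5)
        b = build_composites(surrogate_lifelines, span_h=0.5, n_composites=3, seed=5)
        for ca, cb in zip(a, b):
            assert ca.segments == cb.segments
            np.testing.assert_array_equal(ca.values, cb.values)


class TestChemostatInit:
    @pytest.mark.parametrize("model_name", ["toy", "nine"])
    def test_fixed_point_is_stationary_over_ten_hours(self, model_name, request):
        model = request.getfixturevalue(model_name)
        x0 = chemostat_init(model, 0.28)
        dx, qp0 = model.rates(x0, 0.28)
        assert np.abs(dx).max() < 1e-10
        comp = build_composites(constant_set(0.28, duration=1900.0), 10.0, 1, 0)[0]
        traj = integrate_response(model, comp, x0, input_dt=2.0)
        rel = np.abs(traj.states - x0[:, None]) / np.maximum(np.abs(x0[:, None]), 1e-12)
        assert rel.max() < 1e-6
        assert np.allclose(traj.qp, float(qp0), rtol=1e-6)

    def test_frozen_pool_is_inert(self, nine):
        x0 = chemostat_init(nine, 0.4)
        assert x0[0] == nine.initial_guess[0]  # transport capacity untouched
        dx, _ = nine.rates(x0, 0.9)
        assert dx[0] == 0.0

    def test_out_of_range_q_rejected(self, toy):
        with pytest.raises(rl.InvalidConfigurationError):
            chemostat_init(toy, 0.0)


class TestIntegration:
    def test_zero_input_decays_monotonically(self, toy):
        x0 = chemostat_init(toy, 0.5)
        comp = build_composites(constant_set(0.0, duration=1900.0), 2.0, 1, 0)[0]
        traj = integrate_response(toy, comp, x0, input_dt=2.0)
        precursor = traj.states[1]
        assert np.all(np.diff(precursor) <= 1e-15)
        assert precursor[-1] < 1e-3

    def test_deterministic_repeatability(self, nine, surrogate_lifelines):
        x0 = chemostat_init(nine, 0.28)
        comps = build_composites(surrogate_lifelines, 0.5, 2, seed=3)
        a = integrate_ensemble(nine, comps, x0, input_dt=1.0)
        b = integrate_ensemble(nine, comps, x0, input_dt=1.0)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.states, tb.states)
            np.testing.assert_array_equal(ta.qp, tb.qp)

    def test_rk4_agrees_with_stiff_solver(self, nine, surrogate_lifelines):
        """Fixed-step route vs adaptive LSODA on the same composite."""
        x0 = chemostat_init(nine, 0.28)
        comps = build_composites(surrogate_lifelines, 0.25, 1, seed=3)
        a = integrate_ensemble(nine, comps, x0, input_dt=1.0, method="rk4")[0]
        b = integrate_ensemble(nine, comps, x0, input_dt=1.0, method="lsoda")[0]
        n = min(a.qp.size, b.qp.size)
        # fast pools track the fluctuating input, which the adaptive solver
        # smears across switch points: compare them loosely, slow pools tightly
        assert np.allclose(a.states[:, n - 1], b.states[:, n - 1], rtol=1e-2, atol=1e-5)
        slow = [nine.pool_names.index(p) for p in ("xacv", "xipn", "xpps")]
        assert np.allclose(
            a.states[slow, n - 1], b.states[slow, n - 1], rtol=2e-3, atol=1e-6
        )

    def test_unstable_step_rejected(self, nine, surrogate_lifelines):
        x0 = nine.initial_guess
        comps = build_composites(surrogate_lifelines, 0.1, 1, seed=3)
        with pytest.raises(rl.InvalidConfigurationError, match="unstable"):
            integrate_ensemble(nine, comps, x0, input_dt=120.0)


class TestQpLoss:
    def _traj(self, qp_value, n=200):
        return rl.MetabolicTrajectory(
            times_h=np.linspace(0, 10, n),
            states=np.zeros((1, n)),
            qp=np.full(n, qp_value),
            pool_names=("x",),
        )

    def test_equal_final_qp_zero_loss(self):
        assert qp_loss([self._traj(0.5)], 0.5) == pytest.approx(0.0)

    def test_half_final_qp_fifty_percent(self):
        assert qp_loss([self._traj(0.25)], 0.5) == pytest.approx(50.0)

    def test_ideal_mixing_control_has_negligible_loss(self, nine, surrogate_lifelines):
        """Replacing each lifeline by its own time mean removes the loss."""
        q_mean = float(np.mean([ll.values.mean() for ll in surrogate_lifelines]))
        x0 = chemostat_init(nine, q_mean)
        _, qp_ref = nine.rates(x0, q_mean)
        flat = constant_set(q_mean, n=3, duration=1900.0)
        comps = build_composites(flat, 5.0, 3, seed=1)
        trajs = integrate_ensemble(nine, comps, x0, input_dt=2.0)
        assert abs(qp_loss(trajs, float(qp_ref))) < 0.5

    def test_monotone_in_starvation_fraction_toy(self, toy):
        """At fixed mean uptake, more starvation never lowers the loss.

        Cycle period (600 s) is long against the one-minute precursor
        turnover so the pool tracks the feast/famine alternation.
        """
        x0 = chemostat_init(toy, 0.28)
        _, qp_ref = toy.rates(x0, 0.28)
        losses = []
        for f in (0.0, 0.2, 0.4, 0.6):
            s = rl.square_wave_lifelines(4, 1800.0, 0.03, f, 0.28, period=600.0, seed=5)
            comps = build_composites(s, 5.0, 4, seed=9)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trajs = integrate_ensemble(toy, comps, x0, input_dt=1.0)
                losses.append(qp_loss(trajs, float(qp_ref)))
        assert losses[0] == pytest.approx(0.0, abs=0.5)
        for a, b in zip(losses, losses[1:]):
            assert b >= a - 0.5
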
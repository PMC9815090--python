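"""Regime machinery: smoothing, hysteresis transitions, residence statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import reactorlifelines as rl
from reactorlifelines.regimes import (
    PATTERNS,
    residence_distributions,
    visits_of_set,
)


def lifeline(values, dt=0.03, t0=0.0):
    return rl.Lifeline(parcel_id=0, t_start=t0, sample_dt=dt, values=np.asarray(values, float))


NOSMOOTH = rl.RegimeSpec(lag_window=0.0)


class TestSmooth:
    def test_constant_unchanged(self):
        ll = lifeline(np.full(100, 0.42))
        assert np.allclose(rl.smooth(ll, 0.36).values, 0.42)

    def test_impulse_spreads_to_twelve_samples(self):
        """Window 0.36 s / 0.03 s = 12 samples: impulse -> plateau of 1/12."""
        v = np.zeros(200)
        v[100] = 1.0
        sm = rl.smooth(lifeline(v), 0.36)
        nz = np.flatnonzero(sm.values > 1e-12)
        assert nz.size == 12
        assert np.allclose(sm.values[nz], 1 / 12)

    def test_output_length_preserved(self):
        ll = lifeline(np.random.default_rng(0).uniform(0, 1, 37))
        assert rl.smooth(ll, 0.36).n_samples == 37

    def test_subsample_window_warns_and_is_noop(self):
        ll = lifeline(np.linspace(0, 1, 20))
        with pytest.warns(UserWarning):
            out = rl.smooth(ll, 0.01)
        assert np.array_equal(out.values, ll.values)


class TestDetectVisits:
    def test_oscillation_inside_hysteresis_band_no_transition(self):
        """Starting in excess, wiggling in [0.945, 0.955] never leaves it:
        exit requires the smoothed signal to drop strictly below 0.94."""
        x = np.empty(60)
        x[::2], x[1::2] = 0.955, 0.945
        visits = rl.detect_visits(lifeline(x), NOSMOOTH, presmoothed=True)
        assert len(visits) == 1
        assert visits[0].regime == "E" and visits[0].censored

    def test_monotone_descent_e_l_s(self):
        x = np.linspace(0.97, 0.02, 60)
        visits = rl.detect_visits(lifeline(x), NOSMOOTH, presmoothed=True)
        assert [v.regime for v in visits] == ["E", "L", "S"]
        assert visits[1].pattern == "ELS"
        assert visits[0].censored and visits[-1].censored
        assert not visits[1].censored

    def test_constant_limitation(self):
        visits = rl.detect_visits(lifeline(np.full(30, 0.5)))
        assert len(visits) == 1
        assert visits[0].regime == "L" and visits[0].censored

    def test_boundary_tie_does_not_trigger(self):
        """A sample resting exactly on the shifted boundary (0.94) stays in E."""
        x = np.concatenate([np.full(10, 0.97), np.full(10, 0.94)])
        visits = rl.detect_visits(lifeline(x), NOSMOOTH, presmoothed=True)
        assert [v.regime for v in visits] == ["E"]

    def test_direct_jump_inserts_zero_duration_limitation(self):
        x = np.concatenate([np.full(10, 0.97), np.full(10, 0.02)])
        visits = rl.detect_visits(lifeline(x), NOSMOOTH, presmoothed=True)
        assert [v.regime for v in visits] == ["E", "L", "S"]
        assert visits[1].duration == 0.0
        assert visits[1].pattern == "ELS"

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_visits_partition_the_lifeline(self, seed):
        rng = np.random.default_rng(seed)
        x = np.clip(rng.normal(0.5, 0.35, 300).cumsum() * 0 + rng.uniform(0, 1, 300), 0, 1)
        ll = lifeline(x)
        visits = rl.detect_visits(ll)
        assert visits[0].t_enter == ll.t_start
        assert visits[-1].t_exit == pytest.approx(ll.times[-1])
        for a, b in zip(visits, visits[1:]):
            assert a.t_exit == pytest.approx(b.t_enter)
            assert a.regime != b.regime
        total = sum(v.duration for v in visits)
        assert total == pytest.approx(ll.duration, abs=ll.sample_dt)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_no_chatter_inside_band(self, seed):
        """Any series confined to (0.04, 0.06) yields zero transitions."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.0401, 0.0599, 200)
        visits = rl.detect_visits(lifeline(x), NOSMOOTH, presmoothed=True)
        assert len(visits) == 1


class TestResidenceDistributions:
    def test_weighted_mean_formula(self):
        """Durations {2 s x3, 4 s x1} give mean 2.5 s."""
        visits = [
            rl.Visit("L", 0.0, 2.0, "E", "S", False),
            rl.Visit("L", 10.0, 12.0, "E", "S", False),
            rl.Visit("L", 20.0, 22.0, "E", "S", False),
            rl.Visit("L", 30.0, 34.0, "E", "S", False),
        ]
        dist = residence_distributions(visits)["ELS"]
        assert dist.mean == pytest.approx(2.5)
        assert dist.n_visits == 4

    def test_all_censored_gives_absent_means(self):
        visits = [rl.Visit("L", 0.0, 5.0, None, None, True)]
        dists = residence_distributions(visits)
        assert all(d.mean is None and d.n_visits == 0 for d in dists.values())

    def test_histogram_mean_matches_exact_mean_at_fine_bins(self):
        rng = np.random.default_rng(4)
        durations = rng.uniform(0.03, 3.0, 500)
        visits = [rl.Visit("E", 0.0, d, "L", "L", False) for d in durations]
        dist = residence_distributions(visits, bin_width=0.03)["LEL"]
        # weighted mean over exact durations equals the arithmetic mean
        assert dist.mean == pytest.approx(durations.mean(), rel=1e-12)
        # histogram-weighted mean with bin centres approaches it at fine bins
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        hist_mean = (centers * dist.counts).sum() / dist.counts.sum()
        assert hist_mean == pytest.approx(durations.mean(), rel=0.02)

    def test_all_patterns_always_reported(self):
        dists = residence_distributions([])
        assert set(dists) == set(PATTERNS)


class TestRegimeFractions:
    def test_constant_limitation_is_all_L(self):
        s = rl.LifelineSet(lifelines=(lifeline(np.full(100, 0.5)),))
        fr = rl.regime_fractions(s)
        assert fr["L"] == 100.0 and fr["E"] == 0.0 and fr["S"] == 0.0

    def test_equal_thirds_by_construction(self):
        x = np.concatenate([np.full(100, 0.99), np.full(100, 0.5), np.full(100, 0.01)])
        s = rl.LifelineSet(lifelines=(lifeline(x),))
        fr = rl.regime_fractions(s, NOSMOOTH)
        for v in fr.values():
            assert v == pytest.approx(100 / 3, abs=1.0)

    def test_fractions_sum_to_hundred(self, surrogate_lifelines):
        fr = rl.regime_fractions(surrogate_lifelines)
        assert sum(fr.values()) == pytest.approx(100.0, abs=0.01)

    def test_surrogate_fractions_near_reference_distribution(self, surrogate_lifelines):
        """The calibrated surrogate reproduces the E/L/S split of the reference
        run (7.8 / 43.7 / 48.5 %) within the surrogate's fidelity band of
        +/-15 percentage points, and with the expected ordering S > L > E."""
        fr = rl.regime_fractions(surrogate_lifelines)
        assert fr["E"] == pytest.approx(7.8, abs=15.0)
        assert fr["L"] == pytest.approx(43.7, abs=15.0)
        assert fr["S"] == pytest.approx(48.5, abs=15.0)
        assert fr["S"] > fr["L"] > fr["E"]

    def test_classify_samples_consistent_with_visits(self):
        rng = np.random.default_rng(8)
        ll = lifeline(rng.uniform(0, 1, 400))
        states = rl.classify_samples(ll)
        visits = rl.detect_visits(ll)
        # time-weighted visit durations match per-sample counts to one sample
        for regime in "SLE":
            dur = sum(v.duration for v in visits if v.regime == regime)
            assert (states == regime).sum() * ll.sample_dt == pytest.approx(
                dur, abs=2 * ll.sample_dt * len(visits)
            )


def test_two_loop_lsl_mean_matches_markov_oracle():
    """Empirical starvation residence vs first-passage theory.

    Six-compartment two-loop network with the bottom loop starved (uptake
    levels chosen clear of the hysteresis bands, so a starvation visit is
    exactly a sojourn in the bottom-loop compartment set). The empirical LSL
    mean from sampled lifelines must sit within 2 standard errors of the
    entry-weighted first-passage prediction, up to sampling discretisation.
    """
    from conftest import fake_field

    net = rl.build_two_loop_network(
        n_per_loop=3, circulation_flow=1.0, exchange_flow=0.4, total_volume=12.0
    )
    field = fake_field([0.5, 0.5, 0.5, 0.02, 0.02, 0.02])
    lset = rl.simulate_parcels(net, field, 30, 2000.0, sample_dt=0.05, seed=17)
    dists = residence_distributions(visits_of_set(lset, NOSMOOTH))
    d = dists["LSL"]
    oracle = rl.residence_oracle(net, {3, 4, 5})
    se = d.mean / np.sqrt(d.n_visits)
    assert d.n_visits > 1000
    assert abs(d.mean - oracle) < 2 * se + lset.sample_dt
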
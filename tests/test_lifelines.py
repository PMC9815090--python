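"""Lifeline data model, CSV round trips and the burn-in truncation rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import reactorlifelines as rl
from reactorlifelines.errors import EmptyLifelineError, SchemaValidationError


def small_set(n_parcels=3, n_samples=50, dt=0.03, seed=0):
    rng = np.random.default_rng(seed)
    lls = [
        rl.Lifeline(
            parcel_id=i, t_start=100.02, sample_dt=dt,
            values=rng.uniform(0, 1, n_samples),
        )
        for i in range(n_parcels)
    ]
    return rl.LifelineSet(lifelines=tuple(lls), metadata={"seed": seed, "source": "test"})


class TestRoundTrip:
    def test_bit_exact_round_trip(self, tmp_path):
        original = small_set()
        path = tmp_path / "lifelines.csv"
        rl.write_lifelines(original, path)
        restored = rl.read_lifelines(path)
        assert restored.metadata == original.metadata
        for a, b in zip(original, restored):
            assert a.parcel_id == b.parcel_id
            assert a.t_start == b.t_start
            assert a.sample_dt == b.sample_dt
            assert np.array_equal(a.values, b.values)

    def test_round_trip_without_sidecar(self, tmp_path):
        original = small_set()
        path = tmp_path / "lifelines.csv"
        rl.write_lifelines(original, path)
        (tmp_path / "lifelines.csv.meta.yaml").unlink()
        restored = rl.read_lifelines(path)
        for a, b in zip(original, restored):
            assert np.array_equal(a.values, b.values)
            assert a.t_start == pytest.approx(b.t_start, rel=1e-12)

    def test_value_out_of_bounds_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "parcel_id,time_s,q_rel\n0,0.0,0.5\n0,0.03,1.2\n0,0.06,0.5\n"
        )
        with pytest.raises(SchemaValidationError, match="out of"):
            rl.read_lifelines(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("parcel_id,time_s\n0,0.0\n")
        with pytest.raises(SchemaValidationError, match="q_rel"):
            rl.read_lifelines(path)

    def test_non_uniform_dt_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "parcel_id,time_s,q_rel\n0,0.0,0.5\n0,0.03,0.5\n0,0.09,0.5\n"
        )
        with pytest.raises(SchemaValidationError, match="non-uniform"):
            rl.read_lifelines(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("parcel_id,time_s,q_rel\n")
        with pytest.raises(SchemaValidationError):
            rl.read_lifelines(path)


class TestValidation:
    def test_uniform_dt_enforced(self):
        a = rl.Lifeline(0, 0.0, 0.03, np.zeros(10))
        b = rl.Lifeline(1, 0.0, 0.05, np.zeros(10))
        with pytest.raises(SchemaValidationError, match="non-uniform"):
            rl.LifelineSet(lifelines=(a, b))

    def test_duplicate_ids_rejected(self):
        a = rl.Lifeline(0, 0.0, 0.03, np.zeros(10))
        b = rl.Lifeline(0, 0.0, 0.03, np.zeros(10))
        with pytest.raises(SchemaValidationError, match="unique"):
            rl.LifelineSet(lifelines=(a, b))

    def test_times_not_accumulated(self):
        ll = rl.Lifeline(0, 10.0, 0.03, np.zeros(100000))
        # t[k] must be exactly t0 + k dt, not a floating running sum
        assert ll.times[-1] == 10.0 + 99999 * 0.03


class TestDiscardInitial:
    def test_zero_burn_in_is_identity(self):
        s = small_set()
        assert rl.discard_initial(s, 0.0) is s

    def test_study_truncation_arithmetic(self):
        """2000 s at dt=0.03 with 100 s burn-in keeps 63,334 samples."""
        n = int(np.floor(2000.0 / 0.03 + 1e-9)) + 1  # 66,667
        ll = rl.Lifeline(0, 0.0, 0.03, np.linspace(0, 1, n))
        s = rl.LifelineSet(lifelines=(ll,))
        out = rl.discard_initial(s, 100.0)
        assert out.lifelines[0].n_samples == 63334
        assert out.lifelines[0].t_start == pytest.approx(3333 * 0.03)

    def test_burn_in_longer_than_lifeline_rejected(self):
        s = small_set(n_samples=50, dt=0.03)  # duration 1.47 s
        with pytest.raises(EmptyLifelineError):
            rl.discard_initial(s, 10.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_truncation_keeps_a_suffix(self, burn_in):
        ll = rl.Lifeline(0, 0.0, 0.03, np.linspace(0, 1, 60))
        s = rl.LifelineSet(lifelines=(ll,))
        out = rl.discard_initial(s, burn_in)
        kept = out.lifelines[0]
        n_drop = ll.n_samples - kept.n_samples
        assert np.array_equal(kept.values, ll.values[n_drop:])
        assert kept.t_start == pytest.approx(ll.t_start + n_drop * 0.03)


class TestSquareWaveGenerator:
    def test_mean_is_exact_for_any_fraction(self):
        for f in (0.0, 0.25, 0.5):
            s = rl.square_wave_lifelines(
                4, 600.0, 0.03, starvation_fraction=f, q_mean=0.28, period=60.0
            )
            for ll in s:
                assert ll.values.mean() == pytest.approx(0.28, abs=5e-3)

    def test_starvation_fraction_realised(self):
        s = rl.square_wave_lifelines(4, 600.0, 0.03, 0.4, 0.28, period=60.0)
        for ll in s:
            assert (ll.values < 0.05).mean() == pytest.approx(0.4, abs=0.01)

    def test_infeasible_combination_rejected(self):
        with pytest.raises(ValueError):
            rl.square_wave_lifelines(1, 60.0, 0.03, 0.8, 0.9)
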
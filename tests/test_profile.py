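"""Profile pipeline: splitting, detrending, correlation, alignment, signature."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from striamark.config import PipelineConfig
from striamark.exceptions import (
    ParameterError,
    SizeError,
    UndefinedCorrelationError,
    ValidationError,
)
from striamark.profile import (
    MarkSignatureModel,
    ProfileSignal,
    SignalSet,
    align_signals,
    best_lag,
    build_signature,
    detrend_signal,
    mark_signature,
    read_signature,
    split_signals,
    write_signature,
    xcorr_at_lag,
)
from striamark.scan_io import HeightMap

from conftest import brute_force_best_lag


class TestSplitSignals:
    def test_standard_scan_splits_into_261_signals(self):
        stream = np.arange(262_044, dtype=float)
        ss = split_signals(stream, points_per_signal=1004)
        assert ss.n_signals == 261
        assert ss.n_points == 1004

    def test_grid_rows_become_signals(self):
        hm = HeightMap(np.arange(50, dtype=float).reshape(10, 5))
        ss = split_signals(hm, points_per_signal=5)
        assert ss.n_signals == 10
        assert np.array_equal(ss.signals, hm.z)

    def test_remainder_discarded(self):
        ss = split_signals(np.arange(103, dtype=float), points_per_signal=10)
        assert ss.n_signals == 10
        assert np.array_equal(ss.signals[-1], np.arange(90, 100, dtype=float))

    def test_too_few_signals_raises(self):
        with pytest.raises(SizeError):
            split_signals(np.arange(15, dtype=float), points_per_signal=10)


class TestDetrend:
    def test_constant_maps_to_zero(self):
        s = detrend_signal(ProfileSignal(np.full(30, 7.5)), window=5)
        assert np.allclose(s.values, 0.0)

    def test_linear_ramp_maps_to_zero_including_edges(self):
        for window in (3, 5, 21):
            s = detrend_signal(ProfileSignal(0.7 * np.arange(40) - 3.0), window=window)
            assert np.allclose(s.values, 0.0, atol=1e-12)

    def test_spike_hand_computed(self):
        s = detrend_signal(ProfileSignal(np.array([0.0, 0, 9, 0, 0])), window=3)
        # moving averages: [0, 3, 3, 3, 0] (edge windows shrink to width 1)
        assert np.allclose(s.values, [0, -3, 6, -3, 0])

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            detrend_signal(ProfileSignal(np.zeros(10) + [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]), window=4)


class TestXcorr:
    def test_autocorrelation_is_exactly_one(self, rng):
        s = ProfileSignal(rng.standard_normal(1004))
        assert xcorr_at_lag(s, s, 0) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_gives_minus_one(self, rng):
        v = rng.standard_normal(50)
        assert xcorr_at_lag(v, -v, 0) == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_supports_give_zero(self):
        assert xcorr_at_lag(
            np.array([1.0, 0, 1, 0]), np.array([0.0, 1, 0, 1]), 0
        ) == pytest.approx(0.0, abs=1e-15)

    def test_all_zero_overlap_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            xcorr_at_lag(np.zeros(10), np.ones(10), 0)

    @given(st.integers(0, 2**31 - 1), st.integers(-8, 8))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_antisymmetric_in_lag(self, seed, lag):
        r = np.random.default_rng(seed)
        v1, v2 = r.standard_normal(30), r.standard_normal(30)
        c = xcorr_at_lag(v1, v2, lag)
        assert -1.0 - 1e-12 <= c <= 1.0 + 1e-12  # Cauchy-Schwarz
        assert c == pytest.approx(xcorr_at_lag(v2, v1, -lag), abs=1e-12)

    @given(st.integers(0, 2**31 - 1),
           st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, seed, a, b):
        r = np.random.default_rng(seed)
        v1, v2 = r.standard_normal(25), r.standard_normal(25)
        assert xcorr_at_lag(a * v1, b * v2, 3) == pytest.approx(
            xcorr_at_lag(v1, v2, 3), abs=1e-9
        )


class TestBestLag:
    def test_identical_signals_give_unit_coefficient_at_zero_lag(self, rng):
        v = rng.standard_normal(60)
        c, lag = best_lag(v, v, max_lag=10)
        assert c == pytest.approx(1.0, abs=1e-12)
        assert lag == 0

    def test_recovers_known_delay(self, rng):
        base = rng.standard_normal(80)
        k = 4
        s1 = base[:60]
        s2 = base[k:60 + k]  # s2[i] = s1[i + k] on the overlap
        c, lag = best_lag(s2, s1, max_lag=10)
        assert c == pytest.approx(1.0, abs=1e-12)
        assert abs(lag) == k

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            v1 = rng.standard_normal(40)
            v2 = rng.standard_normal(40)
            got = best_lag(v1, v2, max_lag=10)
            want = brute_force_best_lag(list(v1), list(v2), 10)
            assert got[1] == want[1]
            assert got[0] == pytest.approx(want[0], abs=1e-12)

    def test_max_lag_bounds_enforced(self, rng):
        v = rng.standard_normal(20)
        with pytest.raises(ParameterError):
            best_lag(v, v, max_lag=10)  # not < P/2


class TestAlignment:
    def _noise_set(self, rng, shifts, p=120):
        base = rng.standard_normal(p + 20)
        rows = np.vstack([base[10 - s: 10 - s + p] for s in shifts])
        return SignalSet(rows, detrended=True)

    def test_identical_signals_align_perfectly(self, rng):
        rows = np.tile(rng.standard_normal(100), (5, 1))
        _, result = align_signals(SignalSet(rows, detrended=True), max_lag=8)
        assert result.x_max == pytest.approx(1.0, abs=1e-12)
        assert result.l_xmax == 0.0
        assert len(result.step_coeffs) == 4  # S - 1 steps

    def test_recovers_constructed_shifts(self, rng):
        ss = self._noise_set(rng, shifts=[0, 2, -1])
        aligned, result = align_signals(ss, max_lag=5)
        assert result.x_max == pytest.approx(1.0, abs=1e-9)
        assert sorted(np.abs(result.step_lags)) == [1, 2]
        # aligned rows agree wherever jointly valid
        valid = np.all(np.isfinite(aligned.signals), axis=0)
        spread = np.ptp(aligned.signals[:, valid], axis=0)
        assert np.max(spread) < 1e-12

    def test_requires_detrended_input(self, rng):
        ss = SignalSet(rng.standard_normal((3, 50)), detrended=False)
        with pytest.raises(ValidationError):
            align_signals(ss, max_lag=5)


class TestBuildSignature:
    def test_identical_signals_average_to_themselves(self, rng):
        row = rng.standard_normal(100)
        ss = SignalSet(np.tile(row, (10, 1)), detrended=True)
        sig = build_signature(ss)
        assert np.allclose(sig.values, row)
        assert np.all(sig.coverage == 10)

    def test_opposite_signals_cancel(self, rng):
        row = rng.standard_normal(60)
        ss = SignalSet(np.vstack([row, -row]), detrended=True)
        assert np.allclose(build_signature(ss).values, 0.0)

    def test_noise_averaging_shrinks_variance(self):
        # iid rows of sd sigma average to a signature of variance sigma^2/S
        sigma, s_count, p = 1.5, 50, 400
        variances = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            ss = SignalSet(r.normal(0, sigma, (s_count, p)), detrended=True)
            variances.append(np.var(build_signature(ss).values, ddof=1))
        expect = sigma**2 / s_count
        se = expect * np.sqrt(2.0 / (p - 1)) / np.sqrt(len(variances))
        assert np.mean(variances) == pytest.approx(expect, abs=3 * se)


class TestMarkSignature:
    def test_perfect_mark_gives_unit_quality(self, rng):
        row = np.cumsum(rng.standard_normal(200))
        hm = HeightMap(np.tile(row, (8, 1)))
        _, result = mark_signature(hm, PipelineConfig(window=21, max_lag=10))
        assert result.x_max == pytest.approx(1.0, abs=1e-9)
        assert result.l_xmax == 0.0

    def test_signature_invariant_to_added_affine_form(self, small_mark):
        cfg = PipelineConfig(window=21, max_lag=10)
        sig0, _ = mark_signature(small_mark, cfg)
        x = np.arange(small_mark.n_cols)
        tilted = HeightMap(small_mark.z + 4.0 + 0.03 * x[None, :],
                           dx=small_mark.dx, dy=small_mark.dy)
        sig1, _ = mark_signature(tilted, cfg)
        assert np.max(np.abs(sig0.values - sig1.values)) < 1e-9

    def test_deterministic(self, small_mark):
        cfg = PipelineConfig(window=21, max_lag=10)
        a, ra = mark_signature(small_mark, cfg)
        b, rb = mark_signature(small_mark, cfg)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(ra.step_lags, rb.step_lags)

    def test_model_facade_summary_reports_metrics(self, small_mark):
        res = MarkSignatureModel(small_mark, window=21, max_lag=10).fit()
        text = res.summary()
        assert "X_max" in text and "L_Xmax" in text
        assert 0.9 < res.x_max <= 1.0


class TestSignatureFile:
    def test_round_trip(self, tmp_path, rng):
        from striamark.profile import Signature

        sig = Signature(rng.standard_normal(40), np.full(40, 9), dx=3.0, label="m1")
        path = tmp_path / "sig.txt"
        write_signature(sig, path, meta={"window": 21})
        back = read_signature(path)
        assert np.array_equal(back.values, sig.values)
        assert np.array_equal(back.coverage, sig.coverage)
        assert back.label == "m1"
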
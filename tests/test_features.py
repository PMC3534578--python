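"""Feature computation: oracle equivalence and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txpause.features import (FEATURE_NAMES, DegenerateSeriesError, autocorr,
                              autocorr_function, corr_summary, crosscorr,
                              crosscorr_function, decay_times, feature_table,
                              feature_vector, z_transform)

# ---------------------------------------------------------------------------
# brute-force double-loop oracles (kept deliberately naive)


def autocorr_oracle(x, lag):
    x = np.asarray(x, float)
    m = x.mean()
    num = sum((x[t] - m) * (x[t - lag] - m) for t in range(lag, len(x)))
    den = sum((v - m) ** 2 for v in x)
    return num / den


def crosscorr_oracle(x, y, lag):
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = sum((x[t] - mx) * (y[t - lag] - my) for t in range(lag, len(x)))
    den = np.sqrt(sum((v - mx) ** 2 for v in x) * sum((v - my) ** 2 for v in y))
    return num / den


def corr_summary_oracle(r):
    K = len(r)
    w = [r[l - 1] * l for l in range(1, K + 1)]
    m = sum(w) / K
    s = (sum((v - m) ** 2 for v in w) / (K - 1)) ** 0.5
    return m, s


series_strategy = st.lists(st.integers(min_value=0, max_value=50),
                           min_size=8, max_size=200).filter(
    lambda xs: len(set(xs)) > 1)


class TestAutocorr:
    def test_lag0_is_one(self):
        assert autocorr([3, 1, 4, 1, 5], 0) == 1.0

    def test_hand_value(self):
        # [1..5] lag 1: numerator 4, denominator 10
        assert autocorr([1, 2, 3, 4, 5], 1) == pytest.approx(0.4)

    def test_white_noise_near_zero(self):
        x = np.random.default_rng(0).normal(size=10_000)
        assert abs(autocorr(x, 1)) < 0.03

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(series_strategy, st.integers(min_value=0, max_value=6))
    def test_matches_oracle(self, xs, lag):
        lag = min(lag, len(xs) - 2)
        assert autocorr(xs, lag) == pytest.approx(autocorr_oracle(xs, lag),
                                                  abs=1e-12)

    def test_fft_path_matches_direct(self):
        x = np.random.default_rng(5).poisson(4, size=3_000)
        r = autocorr_function(x, 50)
        direct = [autocorr(x, l) for l in range(1, 51)]
        np.testing.assert_allclose(r, direct, atol=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            autocorr([2, 2, 2, 2], 1)


class TestCrosscorr:
    def test_identical_series_lag0(self):
        x = [1, 5, 2, 8, 3]
        assert crosscorr(x, x, 0) == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = np.array([1.0, -2.0, 3.0, -2.0])
        assert crosscorr(x, -x, 0) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert crosscorr([1, 2, 3, 4], [4, 3, 2, 1], 1) == pytest.approx(
            crosscorr_oracle([1, 2, 3, 4], [4, 3, 2, 1], 1), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(series_strategy, st.integers(min_value=0, max_value=123456),
           st.integers(min_value=0, max_value=6))
    def test_matches_oracle(self, xs, yseed, lag):
        ys = np.random.default_rng(yseed).integers(0, 50, size=len(xs))
        if len(set(ys.tolist())) < 2:
            ys[0] += 1
        lag = min(lag, len(xs) - 2)
        assert crosscorr(xs, ys, lag) == pytest.approx(
            crosscorr_oracle(xs, ys, lag), abs=1e-12)

    def test_vectorised_function_matches_scalar(self):
        rng = np.random.default_rng(9)
        x, y = rng.poisson(3, 500), rng.poisson(5, 500)
        np.testing.assert_allclose(
            crosscorr_function(x, y, 20),
            [crosscorr(x, y, l) for l in range(1, 21)], atol=1e-12)


class TestCorrSummary:
    def test_constant_r_arithmetic_series(self):
        c, K = 0.3, 10
        m, _ = corr_summary([c] * K)
        assert m == pytest.approx(c * (K + 1) / 2)

    def test_zero_r(self):
        assert corr_summary([0.0, 0.0, 0.0]) == (0.0, 0.0)

    def test_hand_value(self):
        m, s = corr_summary([0.5, 0.25, 0.125])
        assert m == pytest.approx((0.5 + 0.5 + 0.375) / 3)
        assert (m, s) == pytest.approx(corr_summary_oracle([0.5, 0.25, 0.125]),
                                       abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=300))
    def test_matches_oracle(self, r):
        assert corr_summary(r) == pytest.approx(corr_summary_oracle(r),
                                                abs=1e-10)


class TestDecayTimes:
    def test_hand_example(self):
        d = decay_times([5, 4, 4, 3, 6, 6, 5])
        np.testing.assert_array_equal(d, [3, 2])
        assert d.mean() == pytest.approx(2.5)

    def test_strictly_increasing_empty(self):
        assert decay_times([1, 2, 3, 4]).size == 0

    def test_constant_series_single_run(self):
        np.testing.assert_array_equal(decay_times([7] * 6), [5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(series_strategy)
    def test_total_steps_conserved(self, xs):
        # decay-run lengths sum to the number of non-increasing steps
        d = decay_times(xs)
        n_down = sum(xs[t - 1] >= xs[t] for t in range(1, len(xs)))
        assert d.sum() == n_down

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(series_strategy)
    def test_invariant_under_monotone_transform(self, xs):
        a = decay_times(xs)
        b = decay_times([x ** 3 + 2 * x for x in xs])
        np.testing.assert_array_equal(a, b)


class TestFeatureVector:
    @pytest.fixture
    def rpe(self):
        rng = np.random.default_rng(3)
        T = 1_000
        R = rng.poisson(2, T)
        P = rng.poisson(40, T) + np.arange(T) % 7
        E = np.cumsum(rng.poisson(0.3, T))
        return R, P, E

    def test_deterministic(self, rpe):
        R, P, E = rpe
        v1 = feature_vector(R, P, E, K=100)
        v2 = feature_vector(R, P, E, K=100)
        assert v1.values == v2.values

    def test_composition_with_decay_oracle(self, rpe):
        R, P, E = rpe
        v = feature_vector(R, P, E, K=100)
        d = decay_times(R)
        assert v.values[8] == pytest.approx(d.mean())
        assert v.values[9] == pytest.approx(d.std(ddof=1))

    def test_correlation_features_affine_invariant(self, rpe):
        R, P, E = rpe
        base = feature_vector(R, P, E, K=100).as_array()
        scaled = feature_vector(3.0 * R + 7, 0.5 * P + 1, 2.0 * E + 5,
                                K=100).as_array()
        np.testing.assert_allclose(base[:8], scaled[:8], atol=1e-9)

    def test_short_rows_rejected(self):
        with pytest.raises(ValueError):
            feature_vector([1, 2, 3], [1, 2, 3], [1, 2, 3], K=300)

    def test_degenerate_row_names_feature(self, rpe):
        R, P, E = rpe
        with pytest.raises(DegenerateSeriesError, match="acf\\(P\\)"):
            feature_vector(R, np.zeros_like(P), E, K=100)


class TestZTransform:
    def test_columns_standardised(self):
        X = np.random.default_rng(0).normal(5, 3, size=(40, 10))
        Z = z_transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_two_vector_hand_value(self):
        Z = z_transform(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(Z.ravel(),
                                   [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_constant_column_rejected(self):
        X = np.ones((5, 2))
        X[:, 0] = np.arange(5)
        with pytest.raises(DegenerateSeriesError):
            z_transform(X)


def test_feature_table_shape_and_determinism(tiny_ab):
    res = tiny_ab["A"]
    t1 = feature_table(res.R.values, res.P.values, res.E.values,
                       n_vectors=5, window=2_000, K=300,
                       rng=np.random.default_rng(0))
    t2 = feature_table(res.R.values, res.P.values, res.E.values,
                       n_vectors=5, window=2_000, K=300,
                       rng=np.random.default_rng(0))
    assert t1.shape == (5, len(FEATURE_NAMES))
    np.testing.assert_array_equal(t1, t2)
    assert np.isfinite(t1).all()
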
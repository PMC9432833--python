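import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socalim.classify import (
    classify_neuron,
    classify_population,
    engagement,
    event_average_trace,
    ensemble_event_average,
    moving_average,
    noise_highpass,
    permutation_null,
    signal_behavior_correlation,
    similarity,
    SimilarityResult,
)
from socalim.core import DffMatrix, Epoch


class TestSimilarity:
    def test_identical_binary_half(self):
        b = np.array([1, 1, 0, 1, 0], dtype=float)
        assert similarity(b, b) == pytest.approx(0.5)

    def test_disjoint_support_zero(self):
        assert similarity(np.array([1.0, 1, 0, 0]), np.array([0.0, 0, 2, 3])) == 0.0

    def test_arithmetic_example(self):
        s = similarity(np.array([1.0, 1, 0, 0]), np.array([2.0, 0, 0, 0]))
        assert s == pytest.approx(1 / 3)

    def test_both_zero_error(self):
        with pytest.raises(ValueError):
            similarity(np.zeros(4), np.zeros(4))

    def test_symmetric(self, rng):
        b = rng.normal(size=50)
        c = rng.normal(size=50)
        assert similarity(b, c) == pytest.approx(similarity(c, b))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_joint_permutation(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.integers(0, 2, 30).astype(float)
        c = rng.normal(size=30)
        if not b.any():
            b[0] = 1
        p = rng.permutation(30)
        assert similarity(b[p], c[p]) == pytest.approx(similarity(b, c))


class TestPermutationNull:
    def test_constant_c_all_equal(self, rng):
        b = np.array([1.0, 0, 1, 0, 0, 1])
        c = np.full(6, 2.0)
        s = similarity(b, c)
        null = permutation_null(b, c, k=50, rng=rng)
        np.testing.assert_allclose(null, s)

    def test_constant_b_all_equal(self, rng):
        b = np.ones(8)
        c = rng.normal(size=8)
        null = permutation_null(b, c, k=30, rng=rng)
        np.testing.assert_allclose(null, similarity(b, c))

    def test_reproducible_under_seed(self):
        b = np.array([1.0, 0, 1, 0] * 10)
        c = np.random.default_rng(0).normal(size=40)
        a = permutation_null(b, c, k=20, rng=np.random.default_rng(5))
        bb = permutation_null(b, c, k=20, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, bb)

    def test_planted_san_low_p(self):
        """High-gain planted response -> empirical p < 0.01 across seeds."""
        rng = np.random.default_rng(0)
        T = 600
        b = np.zeros(T)
        for s in range(50, T - 60, 100):
            b[s:s + 40] = 1
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            c = r.normal(0, 0.2, T) + 1.0 * b  # gain 5x noise
            s_val = similarity(b, c)
            null = permutation_null(b, c, k=1000, rng=r)
            if (null >= s_val).mean() < 0.01:
                hits += 1
        assert hits >= int(0.99 * n_seeds)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            permutation_null(np.ones(4), np.ones(4), k=0)


class TestClassifyNeuron:
    def test_tie_is_other(self):
        assert classify_neuron(0.4, np.full(100, 0.4)) == "Other"

    def test_above_max_is_san(self):
        assert classify_neuron(2.0, np.linspace(0, 1, 100)) == "SAN"

    def test_below_min_is_sin(self):
        assert classify_neuron(-1.0, np.linspace(0, 1, 100)) == "SIN"

    def test_percentile_interpolation_example(self):
        null = np.arange(1, 1001, dtype=float)
        # linear-interpolation 99.17th percentile of 1..1000 is ~991.7
        assert np.percentile(null, 99.17) == pytest.approx(991.7, abs=0.2)
        assert classify_neuron(995.0, null) == "SAN"
        assert classify_neuron(990.0, null) == "Other"

    def test_empty_null_error(self):
        with pytest.raises(ValueError):
            classify_neuron(0.5, np.array([]))


class TestSignalBehaviorCorrelation:
    def _res(self, s, label):
        return SimilarityResult(0, s, 0.0, 1.0, label)

    def test_single_neuron(self):
        out = signal_behavior_correlation([self._res(0.42, "SAN")])
        assert out["SAN"] == pytest.approx(0.42)

    def test_mean(self):
        out = signal_behavior_correlation(
            [self._res(0.2, "SAN"), self._res(0.4, "SAN")])
        assert out["SAN"] == pytest.approx(0.3)

    def test_missing_ensemble_is_nan(self):
        out = signal_behavior_correlation([self._res(0.2, "SAN")])
        assert np.isnan(out["SIN"])


class TestMovingAverage:
    def test_matches_brute_force(self, rng):
        x = rng.normal(size=47)
        got = moving_average(x, 5)
        want = np.array([x[max(0, i - 2): i + 3].mean() for i in range(47)])
        np.testing.assert_allclose(got, want)

    def test_span_one_identity(self, rng):
        x = rng.normal(size=10)
        np.testing.assert_array_equal(moving_average(x, 1), x)


def _onset_session(rate=10.0, n=600, starts=(100, 250, 400), dur=50):
    epochs = [Epoch("mouse", s, s + dur, s / rate, (s + dur) / rate) for s in starts]
    b_e = np.zeros(n, dtype=np.uint8)
    for e in epochs:
        b_e[e.start:e.end] = 1
    b_ne = 1 - b_e
    return epochs, b_e, b_ne, rate


class TestEventAverageTrace:
    def test_constant_trace_flat(self):
        epochs, b_e, b_ne, rate = _onset_session()
        tr = event_average_trace(np.full(600, 2.5), epochs, b_e, b_ne, rate)
        assert tr is not None
        np.testing.assert_allclose(tr.trace, 2.5)
        assert tr.time.size == 2 * int(round(4 * rate))
        rel = event_average_trace(np.full(600, 2.5), epochs, b_e, b_ne, rate,
                                  relative=True)
        np.testing.assert_allclose(rel.trace, 0.0, atol=1e-12)

    def test_square_pulse_equals_smoothed_pulse(self):
        """Deterministic onset-locked pulse -> average is its span-5 smoothing."""
        epochs, b_e, b_ne, rate = _onset_session()
        c = b_e.astype(float) * 3.0
        tr = event_average_trace(c, epochs, b_e, b_ne, rate, span=5)
        # closed-form oracle: smooth one pulse fragment directly
        w = int(round(4 * rate))
        frag = np.array([c[max(0, i - 2): i + 3].mean()
                         for i in range(600)])[epochs[0].start - w:
                                               epochs[0].start + w]
        np.testing.assert_allclose(tr.trace, frag)
        assert tr.n_events == 3

    def test_single_valid_fragment(self, rng):
        epochs, b_e, b_ne, rate = _onset_session(starts=(100,))
        c = rng.normal(size=600)
        tr = event_average_trace(c, epochs, b_e, b_ne, rate)
        assert tr.n_events == 1
        w = int(round(4 * rate))
        sm = moving_average(c, 5)
        np.testing.assert_allclose(tr.trace, sm[100 - w:100 + w])

    def test_no_valid_fragment_returns_none(self):
        epochs, b_e, b_ne, rate = _onset_session(starts=(10,))  # too close to t=0
        assert event_average_trace(np.zeros(600), epochs, b_e, b_ne, rate) is None

    def test_offset_mode(self):
        epochs, b_e, b_ne, rate = _onset_session(starts=(100,), dur=50)
        c = b_e.astype(float)
        tr = event_average_trace(c, epochs, b_e, b_ne, rate, mode="offset")
        assert tr is not None
        # offset-aligned: E half first (high), NE half second (low)
        w = int(round(4 * rate))
        assert tr.trace[: w - 5].mean() > tr.trace[w + 5:].mean()

    def test_relative_ne_half_near_zero(self, rng):
        epochs, b_e, b_ne, rate = _onset_session()
        c = rng.normal(0.0, 0.1, 600) + 2.0 * b_e
        tr = event_average_trace(c, epochs, b_e, b_ne, rate, relative=True)
        w = int(round(4 * rate))
        assert abs(tr.trace[: w - 3].mean()) < 5 * 0.1 / np.sqrt(3 * w)

    def test_ensemble_average(self):
        epochs, b_e, b_ne, rate = _onset_session()
        t1 = event_average_trace(np.full(600, 1.0), epochs, b_e, b_ne, rate)
        t2 = event_average_trace(np.full(600, 3.0), epochs, b_e, b_ne, rate)
        ens = ensemble_event_average([t1, None, t2])
        np.testing.assert_allclose(ens.trace, 2.0)


class TestNoiseHighpass:
    def test_constant_trace_zero(self):
        assert noise_highpass(np.full(500, 3.3), 9.76) <= 1e-10

    def test_white_noise_within_15pct(self):
        ests = [noise_highpass(np.random.default_rng(s).normal(0, 1.0, 3000), 9.76)
                for s in range(10)]
        assert abs(np.mean(ests) - 1.0) < 0.15

    def test_slow_ramp_ignored(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.3, 3000)
        ramp = 0.002 * np.arange(3000)
        a = noise_highpass(x, 9.76)
        b = noise_highpass(x + ramp, 9.76)
        assert b == pytest.approx(a, rel=0.01)

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            noise_highpass(np.zeros(50), 9.76)


class TestEngagement:
    rate = 9.76

    def _dff(self, C):
        C = np.atleast_2d(C)
        return DffMatrix(C=C, t=np.arange(C.shape[1]) / self.rate, rate=self.rate)

    def _epochs(self, spans):
        return [Epoch("mouse", s, e, s / self.rate, e / self.rate) for s, e in spans]

    def test_flat_trace_never_engaged(self):
        st = engagement(self._dff(np.zeros(800)), self._epochs([(100, 150), (300, 360)]))
        assert not st.engaged.any()
        np.testing.assert_array_equal(st.consistency, 0.0)

    def test_plateau_engaged(self, rng):
        c = rng.normal(0, 0.1, 800)
        noise0 = noise_highpass(c, self.rate)
        c2 = c.copy()
        c2[110:130] = 10 * noise0  # 20-frame plateau at 10x noise
        st = engagement(self._dff(c2), self._epochs([(100, 150)]))
        assert st.engaged[0, 0]
        # direct count oracle
        noise = noise_highpass(c2, self.rate)
        assert (c2[100:150] > 3 * noise).sum() >= 10

    def test_nine_frame_event_unreachable(self, rng):
        c = np.full(500, 100.0) + rng.normal(0, 0.1, 500)
        st = engagement(self._dff(c), self._epochs([(100, 109)]))  # 9 frames < n=10
        assert not st.engaged[0, 0]

    def test_percentage_over_ensemble(self, rng):
        base = rng.normal(0, 0.1, (4, 800))
        base[0, 110:130] += 50.0
        base[1, 110:130] += 50.0
        st = engagement(self._dff(base), self._epochs([(100, 150)]))
        assert st.percentage[0] == pytest.approx(0.5)


class TestCalibrationSmoke:
    def test_null_neurons_mostly_other(self, rng):
        """Small-n sanity version of the calibration acceptance target."""
        T = 500
        b = np.zeros(T)
        for s in range(40, T - 50, 90):
            b[s:s + 30] = 1
        C = rng.normal(0, 0.2, size=(40, T))
        dff = DffMatrix(C=C, t=np.arange(T) / 9.76, rate=9.76)
        results = classify_population(b, dff, k=200, rng=rng)
        labels = [r.label for r in results]
        assert labels.count("Other") >= 35
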
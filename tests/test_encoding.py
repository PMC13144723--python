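"""Encoding regressions, ramp classification, anatomical enrichment."""

import numpy as np
import pytest

from sleepscope.encoding import (
    build_qem1_regressors,
    build_regressors,
    enrichment,
    fit_encoding,
    fit_ramps,
    turn_bias,
)
from sleepscope.states import LabeledBin, StateLabelSeries

FS = 2.0


def _series(qem1_periods, total_s):
    bins, cursor = [], 0.0
    for a, b in qem1_periods:
        if a > cursor:
            bins.append(LabeledBin(cursor, a, "Wake"))
        bins.append(LabeledBin(a, b, "QEM1"))
        cursor = b
    if cursor < total_s:
        bins.append(LabeledBin(cursor, total_s, "Wake"))
    return StateLabelSeries(bins)


class TestTurnBias:
    def test_constant_heading_zero(self):
        out = turn_bias(np.full(5000, 1.3), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_constant_rotation_positive(self):
        h = np.arange(5000) * 0.01
        out = turn_bias(h, FS)
        assert np.all(out[10:] > 0)

    def test_alternating_turns_oscillate(self):
        """+- turn blocks at a 20-min period survive the 8-min kernel with
        alternating sign, matching a direct convolution oracle."""
        fs = FS
        block = int(600 * fs)   # 10 min per direction
        dh = np.concatenate([np.full(block, 0.01), np.full(block, -0.01)] * 4)
        h = np.cumsum(dh)
        out = turn_bias(h, fs)
        # direct convolution oracle
        sigma = 480.0 * fs
        half = int(4 * sigma)
        kt = np.arange(-half, half + 1)
        kernel = np.exp(-0.5 * (kt / sigma) ** 2)
        kernel /= kernel.sum()
        dh2 = np.diff(h, prepend=h[0])
        oracle = np.convolve(dh2, kernel, mode="same")
        inner = slice(half, -half)
        np.testing.assert_allclose(out[inner], oracle[inner], atol=2e-4)
        mid = out[block // 2::block]
        assert np.all(np.sign(mid[:6]) == [1, -1, 1, -1, 1, -1])


class TestQem1Regressors:
    def test_no_qem1_all_zero(self):
        series = _series([], 1000.0)
        R = build_qem1_regressors(series, int(1000 * FS), FS)
        assert not R.any()

    def test_kernel_time_constant(self):
        """A 150 s period gives an onset kernel with tau = 10 s."""
        series = _series([(100.0, 250.0)], 400.0)
        R = build_qem1_regressors(series, int(400 * FS), FS)
        i0 = int(100 * FS)
        assert R[2, i0] == pytest.approx(1.0)
        assert R[2, i0 + int(10 * FS)] == pytest.approx(np.exp(-1.0), rel=0.02)

    def test_integral_reaches_period_duration(self):
        series = _series([(100.0, 250.0)], 400.0)
        R = build_qem1_regressors(series, int(400 * FS), FS)
        i_end = int(250 * FS) - 1
        assert R[1, i_end] == pytest.approx(150.0, abs=1.0)
        assert R[1, int(300 * FS)] == 0.0

    def test_integral_resets_each_period(self):
        series = _series([(0.0, 200.0), (300.0, 500.0)], 600.0)
        R = build_qem1_regressors(series, int(600 * FS), FS)
        assert R[1, int(300 * FS)] == pytest.approx(0.0, abs=1.0)


def _regressor_set(seed=0, n_s=2000.0):
    rng = np.random.default_rng(seed)
    n = int(n_s * FS)
    series = _series([(400.0, 700.0), (1200.0, 1500.0)], n_s)
    speed = np.abs(rng.normal(0.5, 0.5, n))
    roll = rng.normal(0, 0.05, n)
    pitch = rng.normal(0, 0.05, n)
    le = rng.normal(0, 0.1, n)
    re = le + rng.normal(0, 0.02, n)
    heading = np.cumsum(rng.normal(0, 0.02, n))
    X = build_regressors(speed, roll, pitch, le, re, heading, series, FS)
    return X, series, rng


class TestFitEncoding:
    def test_speed_neuron_flags(self):
        X, _, rng = _regressor_set(seed=1)
        y = 2.0 * X[0] + rng.normal(0, 0.1, X.shape[1])
        res = fit_encoding(y, X, seed=0)
        assert res.r2_full > 0.8
        assert not res.significant["qem1"]

    def test_qem1_neuron_flags(self):
        X, _, rng = _regressor_set(seed=2)
        y = X[6] * 1.0 + rng.normal(0, 0.2, X.shape[1])
        res = fit_encoding(y, X, seed=0)
        assert res.significant["qem1"]

    def test_eye_neuron_flags(self):
        X, _, rng = _regressor_set(seed=3)
        y = 3.0 * X[3] + rng.normal(0, 0.1, X.shape[1])
        res = fit_encoding(y, X, seed=0)
        assert res.significant["eyes"]

    def test_noise_neurons_rarely_flagged(self):
        """Empirical false-positive rate of the 2-SE rule stays below 15%
        per flag on pure-noise neurons."""
        X, _, _ = _regressor_set(seed=4)
        rng = np.random.default_rng(10)
        flags = {"eyes": 0, "turn_bias": 0, "qem1": 0}
        n_neurons = 60
        for i in range(n_neurons):
            y = rng.normal(0, 1, X.shape[1])
            res = fit_encoding(y, X, seed=i)
            for k in flags:
                flags[k] += res.significant[k]
        for k, v in flags.items():
            assert v / n_neurons <= 0.15, (k, v)

    def test_too_short_trace_rejected(self):
        X, _, _ = _regressor_set()
        with pytest.raises(ValueError):
            fit_encoding(np.zeros(100), X[:, :100])

    def test_partial_models_preserve_dof(self):
        X, _, rng = _regressor_set(seed=5)
        y = rng.normal(0, 1, X.shape[1])
        res = fit_encoding(y, X, seed=0)
        assert res.beta.shape == (9,)
        assert set(res.partial_r2) == {"eyes", "turn_bias", "qem1"}


class TestFitRamps:
    def _periods(self):
        return [(0.0, 300.0), (400.0, 700.0)]

    def _trace(self, fn, n_s=700.0):
        n = int(n_s * FS)
        t = np.arange(n) / FS
        y = np.zeros(n)
        for a, b in self._periods():
            m = (t >= a) & (t < b)
            y[m] = fn((t[m] - a) / (b - a))
        return y

    def test_decay_closed_form(self):
        y = self._trace(lambda u: np.exp(-u / 0.5))
        fit = fit_ramps(y, self._periods(), FS)
        assert fit.model == "decay"
        assert fit.b == pytest.approx(0.5, rel=0.05)
        assert fit.r2 > 0.99

    def test_ramp_up_closed_form(self):
        y = self._trace(lambda u: 1.0 - np.exp(-u / 0.2))
        fit = fit_ramps(y, self._periods(), FS)
        assert fit.model == "one_minus_exp"
        assert fit.b == pytest.approx(0.2, rel=0.05)

    def test_short_periods_excluded(self):
        y = self._trace(lambda u: np.exp(-u))
        fit = fit_ramps(y, [(0.0, 100.0)], FS)  # < 3 min
        assert fit.flagged

    def test_generator_tau_recovery(self, neural_run):
        from sleepscope.neuro_prep import interpolate_missing

        mat, log, sched = neural_run
        F = interpolate_missing(mat)
        periods = sched.periods_of("QEM1")
        down = np.flatnonzero(log.classes == "ramp_down")
        bs, taus = [], []
        for i in down:
            fit = fit_ramps(F[i], periods, mat.fs_hz)
            if fit.model == "decay":
                bs.append(fit.b)
                taus.append(log.taus[i])
        assert len(bs) >= 0.9 * len(down)
        assert abs(np.median(bs) - np.median(taus)) / np.median(taus) < 0.10

    def test_literal_exponent_variant_runs(self):
        y = self._trace(lambda u: np.exp(-u / 0.5))
        fit = fit_ramps(y, self._periods(), FS, literal_exponent=True)
        assert fit.model in ("decay", "one_minus_exp")


class TestEnrichment:
    def test_expectation_oracle(self):
        """Region of 10 with 5 positives among 100 neurons (10 positives
        total): E[P0] = overall positive fraction = 0.1, so E ~ 5."""
        rng = np.random.default_rng(0)
        regions = np.array(["X"] * 10 + ["other"] * 90, dtype=object)
        positive = np.zeros(100, dtype=bool)
        positive[:5] = True
        positive[rng.choice(np.arange(10, 100), 5, replace=False)] = True
        res = {r.region: r for r in enrichment(positive, regions, seed=1)}
        assert res["X"].e_fold == pytest.approx(5.0, rel=0.35)
        assert res["X"].significant

    def test_whole_brain_region_e_is_one(self):
        regions = np.array(["all"] * 50, dtype=object)
        positive = np.zeros(50, dtype=bool)
        positive[:10] = True
        res = enrichment(positive, regions, seed=0)[0]
        assert res.e_fold == pytest.approx(1.0)
        assert not res.significant

    def test_uniform_positives_calibrated(self):
        """With uniformly scattered positives the per-region significance
        rate is ~5%."""
        rng = np.random.default_rng(2)
        n_regions, per = 120, 60
        regions = np.repeat([f"r{i}" for i in range(n_regions)], per).astype(object)
        positive = rng.random(n_regions * per) < 0.1
        res = enrichment(positive, regions, seed=3)
        rate = np.mean([r.significant for r in res])
        assert rate <= 0.12

    def test_empty_region_skipped(self):
        regions = np.array(["a", "a", "b"], dtype=object)
        out = enrichment(np.array([True, False, False]), regions, seed=0)
        assert {r.region for r in out} == {"a", "b"}
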
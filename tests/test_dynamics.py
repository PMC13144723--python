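"""State PCA, trajectory entanglement, relative-time decoding."""

import numpy as np
import pytest

from sleepscope import dynamics
from sleepscope.neuro_prep import interpolate_missing
from sleepscope.states import LabeledBin, StateLabelSeries

FS = 2.0


def _ramp_population(n_neurons=40, periods=6, period_s=300.0, wake_s=300.0,
                     noise=0.0, seed=0):
    """Half ramp-down, half ramp-up cells, linear in relative time."""
    rng = np.random.default_rng(seed)
    bins, t = [], 0.0
    for _ in range(periods):
        bins.append(LabeledBin(t, t + wake_s, "Wake"))
        t += wake_s
        bins.append(LabeledBin(t, t + period_s, "QEM1"))
        t += period_s
    series = StateLabelSeries(bins)
    n = int(t * FS)
    F = rng.normal(0, max(noise, 1e-12), (n_neurons, n))
    tgrid = np.arange(n) / FS
    for a, b in series.periods_of("QEM1"):
        m = (tgrid >= a) & (tgrid < b)
        rel = (tgrid[m] - a) / (b - a)
        for i in range(n_neurons):
            sign = 1.0 if i % 2 == 0 else -1.0
            F[i, m] += sign * rel
    # wake: independent noise so trajectories meander
    for a, b in series.periods_of("Wake"):
        m = (tgrid >= a) & (tgrid < b)
        F[:, m] += rng.normal(0, 0.5, (n_neurons, m.sum()))
    return F, series


class TestStatePCA:
    def test_rank_one_ramp_population(self):
        F, series = _ramp_population(noise=0.0)
        Z = dynamics.zscore_rows(F)
        pca = dynamics.state_pca(Z, series, "QEM1", FS)
        assert pca.explained_variance_ratio[0] > 0.99
        assert pca.loadings.shape[1] == 2
        # orthonormal loadings
        np.testing.assert_allclose(pca.loadings.T @ pca.loadings, np.eye(2),
                                   atol=1e-9)

    def test_sign_convention_pc1_increases_with_time(self):
        F, series = _ramp_population(noise=0.05, seed=1)
        Z = dynamics.zscore_rows(F)
        pca = dynamics.state_pca(Z, series, "QEM1", FS)
        scores = pca.loadings.T @ (pca.mean_matrix
                                   - pca.mean_matrix.mean(axis=1, keepdims=True))
        assert np.corrcoef(scores[0], np.arange(10))[0, 1] > 0

    def test_isotropic_noise_flat_spectrum(self):
        rng = np.random.default_rng(2)
        bins = [LabeledBin(0.0, 600.0, "QEM1")]
        series = StateLabelSeries(bins)
        F = rng.normal(0, 1, (80, int(600 * FS)))
        pca = dynamics.state_pca(F, series, "QEM1", FS)
        r = pca.explained_variance_ratio
        assert r[0] / r[1] < 3.0

    def test_short_period_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        series = StateLabelSeries([
            LabeledBin(0.0, 2.0, "QEM1"), LabeledBin(2.0, 600.0, "Wake"),
        ])
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                dynamics.state_pca(rng.normal(0, 1, (10, 1200)), series,
                                   "QEM1", FS)


class TestEntanglement:
    def test_straight_line_zero(self):
        traj = np.column_stack([np.linspace(0, 1, 200),
                                np.linspace(0, 2, 200)])
        ent = dynamics.entanglement(traj, (0.0, 100.0), FS, sigma_s=0.0)
        assert ent.crossings == 0

    def test_figure_eight_single_crossing(self):
        # polyline tracing a bow-tie: exactly one self-crossing
        traj = np.array([
            [0.0, 0.0], [2.0, 2.0], [2.0, 0.0], [0.0, 2.0], [-0.1, 2.4],
        ])
        assert dynamics.count_self_crossings(traj) == 1

    def test_matches_shapely_oracle_on_random_walk(self):
        """Exact agreement with an independent pairwise-intersection oracle
        (shapely) on a 200-step random walk."""
        from shapely.geometry import LineString

        rng = np.random.default_rng(4)
        traj = np.cumsum(rng.normal(0, 1, (200, 2)), axis=0)
        ours = dynamics.count_self_crossings(traj)
        segs = [LineString([traj[i], traj[i + 1]])
                for i in range(len(traj) - 1)]
        oracle = 0
        for i in range(len(segs)):
            for j in range(i + 2, len(segs)):
                if segs[i].crosses(segs[j]):
                    oracle += 1
        assert ours == oracle

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        traj = np.cumsum(rng.normal(0, 1, (300, 2)), axis=0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert (dynamics.count_self_crossings(traj)
                == dynamics.count_self_crossings(traj @ R.T))

    def test_too_short_flagged(self):
        ent = dynamics.entanglement(np.zeros((2, 2)), (0.0, 1.0), FS)
        assert ent.flagged

    def test_qem1_less_entangled_than_wake(self):
        """Ramping state trajectories cross themselves less than meandering
        wake trajectories."""
        F, series = _ramp_population(noise=0.05, seed=6)
        Z = dynamics.zscore_rows(F)
        pq = dynamics.state_pca(Z, series, "QEM1", FS)
        pw = dynamics.state_pca(Z, series, "Wake", FS)
        eq = [dynamics.entanglement(pq.projection, p, FS).normalized
              for p in series.periods_of("QEM1")]
        ew = [dynamics.entanglement(pw.projection, p, FS).normalized
              for p in series.periods_of("Wake")]
        assert np.median(eq) < np.median(ew)


class TestDecoder:
    def test_noiseless_ramp_population(self):
        F, series = _ramp_population(noise=0.0, seed=7)
        dec = dynamics.decode_relative_time(F, series, "QEM1", FS, seed=0)
        assert dec.r2 >= 0.95

    def test_weight_signs_follow_ramp_direction(self):
        F, series = _ramp_population(noise=0.02, seed=8)
        dec = dynamics.decode_relative_time(F, series, "QEM1", FS, seed=0)
        up = dec.median_weights[0::2]    # even neurons ramp up
        down = dec.median_weights[1::2]
        assert np.median(up) > 0
        assert np.median(down) < 0

    def test_shuffle_control_collapses(self):
        F, series = _ramp_population(noise=0.02, seed=9)
        Fs = dynamics.shuffle_control(F, series, "QEM1", FS, seed=1)
        dec = dynamics.decode_relative_time(Fs, series, "QEM1", FS, seed=0)
        assert dec.r2 <= 0.1

    def test_behavior_only_control_uninformative(self):
        """A decoder fed state-independent behavioral series cannot predict
        relative time."""
        rng = np.random.default_rng(10)
        _, series = _ramp_population(seed=10)
        n = int(series.total_s * FS)
        B = np.vstack([
            np.abs(rng.normal(0.5, 0.5, n)),    # speed
            rng.normal(0, 0.1, n),              # left eye
            rng.normal(0, 0.1, n),              # right eye
            rng.normal(0, 0.05, n),             # roll
            rng.normal(0, 0.05, n),             # pitch
        ])
        dec = dynamics.decode_relative_time(B, series, "QEM1", FS, seed=0)
        assert dec.r2 <= 0.0

    def test_too_few_periods_rejected(self):
        F, _ = _ramp_population(seed=11)
        series = StateLabelSeries([
            LabeledBin(0.0, 300.0, "QEM1"),
            LabeledBin(300.0, 3600.0, "Wake"),
        ])
        with pytest.raises(ValueError):
            dynamics.decode_relative_time(F[:, :7200], series, "QEM1", FS)

    def test_empty_grid_rejected(self):
        F, series = _ramp_population(seed=12)
        with pytest.raises(ValueError):
            dynamics.decode_relative_time(F, series, "QEM1", FS,
                                          l1_ratios=(), alphas=())


class TestShuffleControl:
    def test_deterministic(self):
        F, series = _ramp_population(noise=0.1, seed=13)
        a = dynamics.shuffle_control(F, series, "QEM1", FS, seed=3)
        b = dynamics.shuffle_control(F, series, "QEM1", FS, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_autocorrelation_preserved(self):
        rng = np.random.default_rng(14)
        _, series = _ramp_population(seed=14)
        n = int(series.total_s * FS)
        # smooth noise with strong lag-1 autocorrelation
        from scipy.ndimage import gaussian_filter1d

        F = gaussian_filter1d(rng.normal(0, 1, (20, n)), 3.0, axis=1)
        Fs = dynamics.shuffle_control(F, series, "QEM1", FS, seed=4)

        def ac1(x):
            x = x - x.mean()
            return float(x[:-1] @ x[1:] / (x @ x))

        a, b = series.periods_of("QEM1")[0]
        i0, i1 = int(a * FS), int(b * FS)
        orig = np.mean([ac1(F[i, i0:i1]) for i in range(20)])
        shuf = np.mean([ac1(Fs[i, i0:i1]) for i in range(20)])
        assert abs(orig - shuf) < 0.05 * abs(orig)

    def test_alignment_destroyed(self):
        F, series = _ramp_population(noise=0.02, seed=15)
        Fs = dynamics.shuffle_control(F, series, "QEM1", FS, seed=5)
        a, b = series.periods_of("QEM1")[0]
        i0, i1 = int(a * FS), int(b * FS)
        ramp = np.linspace(0, 1, i1 - i0)
        cors = [np.corrcoef(Fs[i, i0:i1], ramp)[0, 1] for i in range(F.shape[0])]
        assert abs(np.mean(cors)) < 0.15
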
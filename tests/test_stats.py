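import numpy as np
import pytest

from dmxan.spectra import ExperimentalSpectrum, Spectrum, default_grid
from dmxan.stats import (check_convergence, ensemble_average, f_error, r_sq,
                         windowed_rsq)


def _brute_force_rsq(y_th, y_exp, eps, w, n):
    """Independent loop-based evaluation of the square residual."""
    num = 0.0
    den = 0.0
    for i in range(len(y_th)):
        num += w[i] * ((y_th[i] - y_exp[i]) / eps[i]) ** 2
        den += w[i]
    return n * num / den


class TestRsq:
    def test_perfect_fit_is_zero(self):
        exp = ExperimentalSpectrum([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], 0.01)
        assert r_sq(np.array([1.0, 2.0, 3.0]), exp) == 0.0

    def test_hand_computed_value(self):
        # residuals (0.01, 0.02, 0.03), eps 0.01, w 1, n 4:
        # 4 * (1 + 4 + 9) / 3 = 18.666...
        exp = ExperimentalSpectrum([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], 0.01)
        val = r_sq(np.array([1.01, 1.02, 1.03]), exp, n=4)
        assert val == pytest.approx(4 * 14 / 3, rel=1e-12)

    def test_doubling_epsilon_quarters_rsq(self):
        y = np.array([1.1, 0.9, 1.3])
        e1 = ExperimentalSpectrum([0, 1, 2], [1.0, 1.0, 1.0], 0.01)
        e2 = ExperimentalSpectrum([0, 1, 2], [1.0, 1.0, 1.0], 0.02)
        assert r_sq(y, e1) == pytest.approx(4 * r_sq(y, e2), rel=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            m = rng.integers(3, 50)
            y_th = rng.uniform(0, 2, m)
            y_exp = rng.uniform(0, 2, m)
            eps = rng.uniform(0.005, 0.05, m)
            w = rng.uniform(0.1, 2.0, m)
            n = int(rng.integers(1, 6))
            exp = ExperimentalSpectrum(np.arange(m, dtype=float), y_exp, eps, weights=w)
            ours = r_sq(y_th, exp, n)
            ref = _brute_force_rsq(y_th, y_exp, eps, w, n)
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_empty_rejected(self):
        exp = ExperimentalSpectrum([0.0, 1.0], [1.0, 1.0], 0.01)
        with pytest.raises(ValueError):
            r_sq(np.array([]), ExperimentalSpectrum([0.0], [1.0], 0.01))
        with pytest.raises(ValueError, match="mismatch"):
            r_sq(np.array([1.0]), exp)


class TestFError:
    def test_identical_curves_zero(self):
        c, integ = f_error([1.0, 2.0], [1.0, 2.0])
        assert np.all(c == 0) and np.all(integ == 0)

    def test_constant_offset_closed_form(self):
        e = np.arange(11.0)
        c, integ = f_error(np.full(11, 1.3), np.full(11, 1.0), e)
        np.testing.assert_allclose(c, 0.09)
        np.testing.assert_allclose(integ, 0.09 * e)  # linear in E

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.uniform(0, 2, 40), rng.uniform(0, 2, 40)
        c, _ = f_error(a, b)
        np.testing.assert_array_equal(c, np.array([(x - y) ** 2 for x, y in zip(a, b)]))

    def test_integral_nondecreasing(self):
        rng = np.random.default_rng(10)
        _, integ = f_error(rng.uniform(0, 1, 30), rng.uniform(0, 1, 30))
        assert np.all(np.diff(integ) >= 0)


class TestEnsembleAverage:
    def test_identical_spectra_have_zero_rf(self, grid):
        s = Spectrum(grid, np.sin(grid / 9.0))
        avg = ensemble_average([s] * 8)
        np.testing.assert_array_equal(avg.sigma.values, s.values)
        assert np.all(avg.rf_history == 0.0)

    def test_two_spectra_hand_algebra(self, grid):
        s1 = Spectrum(grid, np.ones(grid.size))
        s2 = Spectrum(grid, np.full(grid.size, 2.0))
        avg = ensemble_average([s1, s2])
        np.testing.assert_allclose(avg.sigma.values, 1.5)
        assert avg.rf_history[0] == pytest.approx(
            np.linalg.norm(s2.values - s1.values) / 2.0, rel=1e-12)

    def test_streaming_equals_batch_mean_at_1e4_frames(self):
        rng = np.random.default_rng(12)
        grid = np.arange(0.0, 50.0)
        vals = rng.uniform(0, 2, (10_000, grid.size))
        avg = ensemble_average(Spectrum(grid, v) for v in vals)
        np.testing.assert_allclose(avg.sigma.values, vals.mean(axis=0), rtol=1e-12)

    def test_rf_identity_with_frame_distance(self):
        # R_f(N) = ||s_N - sigma^(N-1)|| / N, an algebraic identity
        rng = np.random.default_rng(14)
        grid = np.arange(0.0, 30.0)
        vals = rng.uniform(0, 1, (50, grid.size))
        avg = ensemble_average(Spectrum(grid, v) for v in vals)
        run = vals[0].astype(float)
        for N in range(2, 51):
            expected = np.linalg.norm(vals[N - 1] - run) / N
            assert avg.rf_history[N - 2] == pytest.approx(expected, rel=1e-10)
            run = run + (vals[N - 1] - run) / N

    def test_shuffled_order_leaves_final_mean(self):
        rng = np.random.default_rng(15)
        grid = np.arange(0.0, 20.0)
        vals = rng.uniform(0, 1, (200, grid.size))
        a = ensemble_average(Spectrum(grid, v) for v in vals)
        b = ensemble_average(Spectrum(grid, v) for v in vals[rng.permutation(200)])
        np.testing.assert_allclose(a.sigma.values, b.sigma.values, atol=1e-12)

    def test_grid_mismatch_names_frame(self, grid):
        s1 = Spectrum(grid, np.ones(grid.size))
        s2 = Spectrum(grid + 0.5, np.ones(grid.size))
        with pytest.raises(ValueError, match="frame 2"):
            ensemble_average([s1, s2])

    def test_iid_noise_rf_decays_as_one_over_n(self):
        grid = default_grid()
        rng = np.random.default_rng(3)
        base = 1.0 + 0.1 * np.sin(grid / 20.0)
        avg = ensemble_average(
            Spectrum(grid, base + rng.normal(0, 0.05, grid.size)) for _ in range(1000))
        N = np.arange(2, 1001)
        m = N >= 10
        slope = np.polyfit(np.log(N[m]), np.log(avg.rf_history[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)


class TestCheckConvergence:
    def test_identical_frames_converged(self, grid):
        avg = ensemble_average([Spectrum(grid, np.ones(grid.size))] * 5)
        assert check_convergence(avg, 1e-6, after=2).converged

    def test_alternating_first_pass_closed_form(self, grid):
        s1 = Spectrum(grid, np.zeros(grid.size))
        s2 = Spectrum(grid, np.ones(grid.size))
        d = np.linalg.norm(s2.values - s1.values)
        avg = ensemble_average([s1 if i % 2 == 0 else s2 for i in range(60)])
        # alternating stream: R_f(N) ~ d/(2N); first N with d/(2N) < thr
        thr = d / 25.0
        rep = check_convergence(avg, thr, after=20)
        assert rep.converged
        assert rep.first_pass == pytest.approx(12.5, abs=1.0)

    def test_zero_threshold_never_converges(self, grid):
        s1 = Spectrum(grid, np.zeros(grid.size))
        s2 = Spectrum(grid, np.ones(grid.size))
        avg = ensemble_average([s1, s2, s1, s2])
        rep = check_convergence(avg, 0.0, after=2)
        assert not rep.converged and rep.first_pass is None


class TestWindowedRsq:
    def test_single_window_equals_global_fit(self, synthetic_experiment,
                                             coarse_pipeline, truth_ff):
        from dmxan.pipeline import evaluate_ensemble
        from dmxan.synthetic import SamplerConfig, build_site_model, sample_ensemble

        exp, _ = synthetic_experiment
        frames = sample_ensemble(build_site_model(truth_ff), truth_ff,
                                 SamplerConfig(seed=21, n_steps=2000, burn_in=1500, stride=50))
        res = windowed_rsq(frames, window=len(frames) * 1.0, exp=exp,
                           config=coarse_pipeline)
        assert res.r_sq.size == 1
        direct = evaluate_ensemble(frames, exp, coarse_pipeline)
        assert res.r_sq[0] == pytest.approx(direct.r_sq, rel=1e-9)

    def test_window_smaller_than_spacing_rejected(self, synthetic_experiment, truth_ff):
        from dmxan.synthetic import SamplerConfig, build_site_model, sample_ensemble

        exp, _ = synthetic_experiment
        frames = sample_ensemble(build_site_model(truth_ff), truth_ff,
                                 SamplerConfig(seed=22, n_steps=40, burn_in=100, stride=10))
        with pytest.raises(ValueError, match="spacing"):
            windowed_rsq(frames, window=0.5, exp=exp)
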
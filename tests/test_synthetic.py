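import numpy as np
import pytest
from scipy import stats as sps

from dmxan.broadening import BroadeningParams, fit_nonstructural
from dmxan.synthetic import (KB_KCAL, Angle, Bond, ForceFieldParams,
                             SamplerConfig, angle_statistics, build_site_model,
                             charmm_ff, make_synthetic_experiment, optimized_ff,
                             sample_angle_series, sample_ensemble)


class TestSiteModel:
    def test_collinear_fe_o_distance_optimized(self):
        # Fe-C 1.80 + C-O 1.25 = 3.05 A along +z
        t = build_site_model(optimized_ff())
        assert np.linalg.norm(t.site("O_CO").position - t.site("FE").position) \
            == pytest.approx(3.05)

    def test_collinear_fe_o_distance_charmm(self):
        # 1.90 + 1.128 = 3.028 A
        t = build_site_model(charmm_ff())
        assert np.linalg.norm(t.site("O_CO").position - t.site("FE").position) \
            == pytest.approx(3.028)

    def test_missing_bond_named_in_error(self):
        ff = optimized_ff()
        ff = ForceFieldParams([b for b in ff.bonds if set(b.labels) != {"FE", "C_CO"}],
                              ff.angles, ff.charges, ff.total_charge)
        with pytest.raises(ValueError, match="FE-C_CO"):
            build_site_model(ff)

    def test_degenerate_equilibrium_angle_rejected(self):
        with pytest.raises(ValueError, match="theta0"):
            Angle(("FE", "C_CO", "O_CO"), 0.0, 67.4)

    def test_charge_sum_must_match_declared_total(self):
        with pytest.raises(ValueError, match="charges sum"):
            ForceFieldParams([], [], {"FE": 1.0}, total_charge=-2.0)


class TestSampler:
    def test_same_seed_is_bitwise_reproducible(self):
        ff = optimized_ff()
        cfg = SamplerConfig(seed=5, n_steps=500, burn_in=200, stride=10)
        a = sample_ensemble(build_site_model(ff), ff, cfg)
        b = sample_ensemble(build_site_model(ff), ff, cfg)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.positions(), fb.positions())

    def test_bond_length_variance_matches_equipartition(self):
        # harmonic marginal: var(r) = kT / k_b (up to the small r^2 Jacobian
        # correction); k_b = 300 kcal/mol/A^2 at 300 K gives 0.001987 A^2
        ff = optimized_ff()
        ff = ForceFieldParams(
            [Bond(("FE", "N_HIS"), 2.04, 270.0), Bond(("FE", "C_CO"), 1.80, 300.0),
             Bond(("C_CO", "O_CO"), 1.25, 1115.0)], ff.angles, ff.charges,
            ff.total_charge)
        frames = sample_ensemble(build_site_model(ff), ff,
                                 SamplerConfig(seed=6, n_steps=200_000, burn_in=5000, stride=20))
        d = np.array([np.linalg.norm(f.site("C_CO").position - f.site("FE").position)
                      for f in frames])
        assert d.var(ddof=1) == pytest.approx(KB_KCAL * 300.0 / 300.0, rel=0.05)

    def test_bending_angle_matches_rayleigh_closed_form(self):
        # Cartesian sampling weights the bending by sin(theta); for a stiff
        # harmonic linear angle the deviation phi = pi - theta is Rayleigh
        # with scale s = sqrt(kT/k): mean phi = s sqrt(pi/2), sd = s sqrt(2 - pi/2)
        ff = optimized_ff()
        ang = sample_angle_series(ff, SamplerConfig(seed=7, n_steps=400_000,
                                                    burn_in=5000, stride=2))
        s = np.sqrt(KB_KCAL * 300.0 / 67.4)
        mean_expected = 180.0 - np.degrees(s * np.sqrt(np.pi / 2))
        sd_expected = np.degrees(s * np.sqrt(2 - np.pi / 2))
        assert ang.mean() == pytest.approx(mean_expected, abs=0.15)
        assert ang.std(ddof=1) == pytest.approx(sd_expected, rel=0.05)

    def test_bond_marginal_is_jacobian_weighted_boltzmann(self):
        # Cartesian sampling gives p(r) ~ r^2 exp(-(r-r0)^2 / (2 kT/k)):
        # KS test against that closed form (numerically integrated CDF)
        ff = optimized_ff()
        frames = sample_ensemble(build_site_model(ff), ff,
                                 SamplerConfig(seed=8, n_steps=500_000, burn_in=5000, stride=50))
        d = np.array([np.linalg.norm(f.site("C_CO").position - f.site("FE").position)
                      for f in frames])
        assert d.size == 10_000
        sd = np.sqrt(KB_KCAL * 300.0 / 258.0)
        r = np.linspace(1.80 - 8 * sd, 1.80 + 8 * sd, 4001)
        pdf = r**2 * np.exp(-((r - 1.80) ** 2) / (2 * sd**2))
        cdf_grid = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1])
                                                    * np.diff(r))])
        cdf_grid /= cdf_grid[-1]
        p = sps.ks_1samp(d, lambda x: np.interp(x, r, cdf_grid)).pvalue
        assert p > 0.01

    def test_doubled_step_leaves_marginals(self):
        # detailed-balance smoke test: proposal width must not bias the target
        ff = optimized_ff()
        means = []
        for step in (0.05, 0.10):
            cfg = SamplerConfig(seed=9, n_steps=100_000, burn_in=0, stride=20,
                                max_step=step)  # no burn-in tuning: fixed step
            d = [np.linalg.norm(f.site("C_CO").position - f.site("FE").position)
                 for f in sample_ensemble(build_site_model(ff), ff, cfg)]
            d = np.asarray(d)
            means.append((d.mean(), d.std(ddof=1) / np.sqrt(len(d) / 20)))
        diff = abs(means[0][0] - means[1][0])
        assert diff < 2 * np.hypot(means[0][1], means[1][1]) + 1e-4


class TestAngleStatistics:
    def test_template_frames_have_exact_mean_zero_sd(self):
        t = build_site_model(optimized_ff())
        mean, sd = angle_statistics([t, t, t], ("FE", "C_CO", "O_CO"))
        assert mean == pytest.approx(180.0)
        assert sd == 0.0

    def test_matches_per_frame_recomputation(self):
        ff = optimized_ff()
        frames = sample_ensemble(build_site_model(ff), ff,
                                 SamplerConfig(seed=10, n_steps=2000, burn_in=500, stride=10))
        mean, sd = angle_statistics(frames, ("FE", "C_CO", "O_CO"))
        vals = []
        for f in frames:
            a = f.site("FE").position - f.site("C_CO").position
            b = f.site("O_CO").position - f.site("C_CO").position
            vals.append(np.degrees(np.arccos(
                np.dot(a, b) / np.linalg.norm(a) / np.linalg.norm(b))))
        assert mean == pytest.approx(np.mean(vals), rel=1e-12)
        assert sd == pytest.approx(np.std(vals, ddof=1), rel=1e-12)

    def test_missing_label_rejected(self):
        t = build_site_model(optimized_ff())
        with pytest.raises(KeyError, match="XX"):
            angle_statistics([t, t], ("FE", "C_CO", "XX"))


class TestSyntheticExperiment:
    def test_noise_free_experiment_is_self_consistent(self, coarse_grid,
                                                      coarse_pipeline, truth_ff,
                                                      truth_broadening):
        exp, gt = make_synthetic_experiment(
            truth_ff, truth_broadening, noise=0.0, n_frames=60, seed=31,
            grid=coarse_grid, pipeline_config=coarse_pipeline)
        fit = fit_nonstructural(gt.raw_average, exp, truth_broadening,
                                maxiter=300, restarts=0)
        assert fit.r_sq < 1e-3

    def test_noisy_residuals_have_unit_chi_square(self, coarse_grid,
                                                  coarse_pipeline, truth_ff,
                                                  truth_broadening):
        # residuals/eps ~ N(0,1) when the stated error equals the noise sd,
        # so R_sq/n = mean(z^2) should be ~1
        exp, gt = make_synthetic_experiment(
            truth_ff, truth_broadening, noise=0.01, n_frames=60, seed=32,
            grid=coarse_grid, pipeline_config=coarse_pipeline)
        fit = fit_nonstructural(gt.raw_average, exp, truth_broadening,
                                maxiter=300, restarts=0)
        assert fit.r_sq / fit.n_used == pytest.approx(1.0, abs=0.25)

    def test_replicate_seeds_differ_within_noise_band(self, coarse_grid,
                                                      coarse_pipeline, truth_ff,
                                                      truth_broadening):
        exps = [make_synthetic_experiment(truth_ff, truth_broadening, noise=0.005,
                                          n_frames=60, seed=s, grid=coarse_grid,
                                          pipeline_config=coarse_pipeline)[0]
                for s in (41, 43)]
        diff = exps[0].values - exps[1].values
        # combined noise sd is sqrt(2)*0.005 plus sampling spread; spectra agree
        # to well under 10 combined noise sd everywhere
        assert np.max(np.abs(diff)) < 10 * np.sqrt(2) * 0.005

    def test_negative_noise_rejected(self, truth_ff, truth_broadening):
        with pytest.raises(ValueError, match="noise"):
            make_synthetic_experiment(truth_ff, truth_broadening, noise=-0.1,
                                      n_frames=5, seed=1)
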
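"""EMG peak model: density identities, likelihoods, and MCMC correctness."""

import numpy as np
import pytest
from scipy import integrate, stats

import mspurify as mp
from mspurify.peaks import (PeakPriors, PeakShapeParams, PeakState,
                            _gibbs_sigma2, emg_density, fit_peak_mcmc,
                            fit_peaks_mcmc, integrate_peak, render_peak,
                            scan_loglik)


def _state(shape, x=1.0, s=60, q=1.0, noise_var=1.0, present=None):
    if present is None:
        present = np.ones(s)
    return PeakState(abundance=x, shape=shape, present=present,
                     noise_var=noise_var, present_rate=q)


class TestEMGDensity:
    def test_integrates_to_one(self, emg_shape):
        lo = emg_shape.mu - 10 * emg_shape.sigma
        hi = emg_shape.mu + 10 * emg_shape.sigma + 20 / emg_shape.zeta
        val, _ = integrate.quad(lambda s: emg_density(s, emg_shape), lo, hi,
                                limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_integrates_to_one_random_shapes(self, rng):
        for _ in range(100):
            sh = PeakShapeParams(mu=rng.uniform(5, 50),
                                 zeta=rng.uniform(0.05, 2.0),
                                 sigma=rng.uniform(0.5, 8.0))
            lo = sh.mu - 12 * sh.sigma
            hi = sh.mu + 12 * sh.sigma + 30 / sh.zeta
            val, _ = integrate.quad(lambda s: emg_density(s, sh), lo, hi,
                                    limit=500)
            assert val == pytest.approx(1.0, abs=1e-5)

    def test_matches_gaussian_exponential_sum_law(self, emg_shape):
        # EMG is the law of N(mu, sigma^2) + Exp(zeta); scipy's exponnorm
        # parameterisation is an independent closed form
        xs = np.linspace(5, 90, 200)
        want = stats.exponnorm.pdf(
            xs, 1.0 / (emg_shape.zeta * emg_shape.sigma),
            loc=emg_shape.mu, scale=emg_shape.sigma)
        got = emg_density(xs, emg_shape)
        assert np.max(np.abs(got - want)) < 1e-6

    def test_gaussian_limit_for_fast_decay(self):
        # zeta*sigma large: the exponential delay degenerates and the EMG
        # approaches N(mu + 1/zeta, sigma^2)
        sh = PeakShapeParams(mu=30.0, zeta=100.0, sigma=1.0)
        ts = np.linspace(-3, 3, 31)
        got = emg_density(sh.mu + 1.0 / sh.zeta + ts, sh)
        want = stats.norm.pdf(ts, scale=sh.sigma)
        assert np.max(np.abs(got - want)) < 1e-3

    def test_nonnegative_and_stable_for_extreme_args(self):
        sh = PeakShapeParams(mu=30.0, zeta=0.01, sigma=0.5)
        vals = emg_density(np.linspace(-500, 500, 101), sh)
        assert np.all(vals >= 0) and np.all(np.isfinite(vals))


class TestRenderIntegrate:
    def test_zero_abundance_gives_zero_vector(self, emg_shape):
        assert not render_peak(_state(emg_shape, x=0.0), 60).any()

    def test_all_absent_gives_zero_vector(self, emg_shape):
        st = _state(emg_shape, x=5.0, present=np.zeros(60))
        assert not render_peak(st, 60).any()

    def test_area_equals_abundance(self, emg_shape):
        st = _state(emg_shape, x=500.0)
        assert integrate_peak(st) == 500.0
        # trapezoid over the 60-scan window catches nearly all density
        area = np.trapezoid(render_peak(st, 60))
        assert area == pytest.approx(500.0, rel=5e-3)


class TestScanLoglik:
    def test_noiseless_match_attains_pure_noise_maximum(self, emg_shape):
        st = _state(emg_shape, x=100.0, noise_var=4.0)
        obs = render_peak(st, 60)
        want = stats.norm.logpdf(np.zeros(60), scale=2.0).sum()
        assert scan_loglik(obs, st) == pytest.approx(want)

    def test_q_zero_reduces_to_pure_noise_model(self, emg_shape, rng):
        obs = rng.normal(0, 1.0, 60)
        st_a = _state(emg_shape, x=100.0, q=0.0, noise_var=1.0)
        st_b = _state(emg_shape, x=7.0, q=0.0, noise_var=1.0)
        assert scan_loglik(obs, st_a) == pytest.approx(scan_loglik(obs, st_b))
        want = stats.norm.logpdf(obs).sum()
        assert scan_loglik(obs, st_a) == pytest.approx(want)

    def test_matches_exhaustive_delta_enumeration(self, rng):
        s = 6
        sh = PeakShapeParams(mu=3.0, zeta=0.5, sigma=1.0)
        st = _state(sh, x=10.0, s=s, q=0.7, noise_var=0.5)
        obs = rng.normal(1.0, 1.0, s)
        f = emg_density(np.arange(1, s + 1, dtype=float), sh)
        total = -np.inf
        for code in range(2 ** s):
            delta = np.array([(code >> k) & 1 for k in range(s)], dtype=float)
            lp = (np.log(0.7) * delta + np.log(0.3) * (1 - delta)).sum()
            lp += stats.norm.logpdf(obs, loc=10.0 * delta * f,
                                    scale=np.sqrt(0.5)).sum()
            total = np.logaddexp(total, lp)
        assert scan_loglik(obs, st) == pytest.approx(total, abs=1e-9)


class TestGibbsConditionals:
    def test_sigma2_conditional_matches_inverse_gamma(self, rng):
        # frozen state: draws from the sampler's conditional must follow
        # IG(a_e + S/2, b_e + RSS/2)
        a_e, b_e, s, rss = 2.0, 3.0, 60, 41.7
        draws = _gibbs_sigma2(rng, a_e, b_e, s, np.full(4000, rss))
        ref = stats.invgamma(a_e + s / 2, scale=b_e + rss / 2)
        _, p = stats.kstest(draws, ref.cdf)
        assert p > 0.01

    def test_x_conditional_ignores_absent_scans(self, rng):
        # two traces identical on the signal region but wildly different on
        # scans the model infers as absent must give the same abundance
        sh = PeakShapeParams(mu=15.0, zeta=0.4, sigma=2.0)
        grid = np.arange(1, 41, dtype=float)
        clean = 1000.0 * emg_density(grid, sh)
        noise = rng.normal(0, 0.01 * clean.max(), 40)
        obs_a = clean + noise
        obs_b = obs_a.copy()
        # zero out the far tail where the peak carries no mass
        obs_a[35:] = 0.0
        obs_b[35:] = 0.0
        res_a = fit_peak_mcmc(obs_a, seed=5)
        res_b = fit_peak_mcmc(obs_b, seed=5)
        xa = res_a.posterior_mean_state.abundance
        xb = res_b.posterior_mean_state.abundance
        assert xa == pytest.approx(xb, rel=1e-9)


class TestPeakMCMC:
    def test_recovery_and_coverage_over_replicates(self, rng):
        # 50 independent replicate peaks advance as one vectorised batch
        n, s = 50, 60
        sh = PeakShapeParams(mu=30.0, zeta=0.3, sigma=3.0)
        grid = np.arange(1, s + 1, dtype=float)
        clean = 1000.0 * emg_density(grid, sh)
        obs = clean[None, :] + rng.normal(0, 0.01 * clean.max(), (n, s))
        out = fit_peaks_mcmc(obs, n_iter=2000, burn_in=1000, seed=3,
                             keep_draws=True)
        x_mean = out["x"]
        assert np.all(np.abs(x_mean - 1000.0) / 1000.0 < 0.05)
        lo = np.quantile(out["draws"]["x"], 0.05, axis=0)
        hi = np.quantile(out["draws"]["x"], 0.95, axis=0)
        coverage = np.mean((lo <= 1000.0) & (1000.0 <= hi))
        assert coverage > 0.72  # ~nominal 0.9 within binomial noise at n=50

    def test_acceptance_rate_within_working_band(self, rng):
        s = 60
        sh = PeakShapeParams(mu=25.0, zeta=0.25, sigma=2.5)
        grid = np.arange(1, s + 1, dtype=float)
        clean = 500.0 * emg_density(grid, sh)
        obs = clean + rng.normal(0, 0.01 * clean.max(), s)
        res = fit_peak_mcmc(obs, seed=9)
        assert 0.1 <= res.accept_rate <= 0.6

    def test_asymmetric_peak_beats_symmetric_gaussian_fit(self, rng):
        # right-skewed peak: the EMG posterior-mean curve must fit at least
        # as well as the best purely Gaussian curve
        from scipy.optimize import curve_fit
        s = 13
        sh = PeakShapeParams(mu=4.0, zeta=0.35, sigma=1.2)
        grid = np.arange(1, s + 1, dtype=float)
        clean = 800.0 * emg_density(grid, sh)
        obs = clean + rng.normal(0, 0.01 * clean.max(), s)
        res = fit_peak_mcmc(obs, seed=21)
        rss_emg = np.sum((obs - res.fitted_curve()) ** 2)

        def gauss(x, a, m, w):
            return a * np.exp(-0.5 * ((x - m) / w) ** 2)

        popt, _ = curve_fit(gauss, grid, obs,
                            p0=[obs.max(), float(np.argmax(obs) + 1), 2.0],
                            maxfev=20000)
        rss_gauss = np.sum((obs - gauss(grid, *popt)) ** 2)
        assert rss_emg <= rss_gauss * 1.05

    def test_all_zero_trace_warns_and_returns_tiny_abundance(self):
        with pytest.warns(RuntimeWarning, match="identically zero"):
            res = fit_peak_mcmc(np.zeros(30), seed=1)
        assert res.posterior_mean_state.abundance < 0.01
        assert res.posterior_mean_state.present_rate < 0.5

    def test_priors_validation(self):
        with pytest.raises(ValueError):
            PeakPriors(a_e=-1.0)
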
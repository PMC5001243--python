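"""Intensity-level topic model: collapsed likelihood and two-step fitting."""

import numpy as np
import pytest
from scipy.special import logsumexp

import mspurify as mp
from mspurify.data import ProfileSet
from mspurify.intensity import (IntensityPurificationModel, MixtureProportions,
                                ModelHyperparams, TopicPanel,
                                fit_intensity_model, log_complete_posterior,
                                purify_profile)


def _hp(m, l, d, kappa=1e4, kappa_prime=100.0):
    return ModelHyperparams(alpha=np.ones(m + 1), eta=np.full(m, 1.0 / m),
                            kappa_prime=kappa_prime, kappa=np.full(d, kappa))


def _simplex(rng, size):
    v = rng.uniform(0.1, 1.0, size)
    return v / v.sum(axis=-1, keepdims=True)


class TestCollapsedPosterior:
    def test_degenerate_single_contaminant(self, rng):
        # theta = (1, 0): the collapse reduces to one multinomial over beta_1
        l = 6
        beta = _simplex(rng, (1, l))
        gamma = _simplex(rng, (1, l))
        counts = np.round(beta[0] * 1000.0)[None, :]
        hp = _hp(1, l, 1)
        panel = TopicPanel(beta, gamma[0])
        theta = MixtureProportions(np.array([[1.0 - 1e-12, 1e-12]]))
        lp = log_complete_posterior(counts, panel, theta, gamma, gamma[0], hp)
        data_term = float(np.sum(counts[0] * np.log(beta[0])))
        # subtract the prior terms to isolate the data term
        from mspurify.intensity import _logdir
        prior = (_logdir(theta.theta[0], hp.alpha)
                 + _logdir(gamma[0], hp.kappa[0] * gamma[0])
                 + _logdir(gamma[0], hp.kappa_prime * (hp.eta @ beta)))
        assert lp - prior == pytest.approx(data_term, rel=1e-9)

    def test_matches_per_ion_enumeration(self, rng):
        # brute force: one log-sum-exp over topic assignments per ion
        l, m, n = 4, 2, 50
        beta = _simplex(rng, (m, l))
        gamma_d = _simplex(rng, (1, l))
        theta = _simplex(rng, (1, m + 1))
        topics = np.vstack([beta, gamma_d])
        ions = rng.integers(0, l, size=n)
        counts = np.bincount(ions, minlength=l).astype(float)[None, :]
        brute = sum(
            logsumexp(np.log(theta[0]) + np.log(topics[:, ion]))
            for ion in ions
        )
        hp = _hp(m, l, 1)
        panel = TopicPanel(beta, gamma_d[0])
        lp = log_complete_posterior(counts, panel,
                                    MixtureProportions(theta), gamma_d,
                                    gamma_d[0], hp)
        from mspurify.intensity import _logdir
        prior = (_logdir(theta[0], hp.alpha)
                 + _logdir(gamma_d[0], hp.kappa[0] * gamma_d[0])
                 + _logdir(gamma_d[0], hp.kappa_prime * (hp.eta @ beta)))
        assert lp - prior == pytest.approx(brute, abs=1e-8)

    def test_higher_weight_on_matching_topic_raises_data_term(self, rng):
        l, m = 5, 1
        beta = _simplex(rng, (m, l))
        gamma = _simplex(rng, (1, l))
        counts = np.round(gamma[0] * 10000.0)[None, :]
        hp = _hp(m, l, 1)
        panel = TopicPanel(beta, gamma[0])

        def lp(w_cancer):
            th = MixtureProportions(np.array([[1 - w_cancer, w_cancer]]))
            return log_complete_posterior(counts, panel, th, gamma, gamma[0],
                                          hp)

        assert lp(0.9) > lp(0.5) > lp(0.1)

    def test_zero_mixture_with_positive_count_is_minus_inf(self):
        # a counted feature whose mixture probability is exactly zero (pure
        # cancer weight on a gamma with a zero entry) must yield -inf
        counts = np.array([[10.0, 10.0, 5.0]])
        hp = _hp(1, 3, 1)
        panel = TopicPanel(np.array([[0.4, 0.3, 0.3]]),
                           np.array([0.4, 0.3, 0.3]))
        theta = MixtureProportions(np.array([[0.0, 1.0]]))
        gamma = np.array([[0.5, 0.5, 0.0]])  # zero where counts are positive
        with pytest.warns(RuntimeWarning, match="zero mixture"):
            lp = log_complete_posterior(counts, panel, theta, gamma,
                                        panel.cancer_topic, hp)
        assert lp == -np.inf


class TestFit:
    def test_recovery_on_model_generated_data(self, small_intensity):
        # purification must recover the mixing weights far better than the
        # unpurified profiles suggest: at this sample count the mixing-weight
        # posterior retains some ridge uncertainty, so the bound is coarser
        # than at the full study scale
        _, cases, controls, truth = small_intensity
        res = fit_intensity_model(cases, controls)
        err = mp.mean_proportion_error(res.theta_star.theta, truth.theta_true)
        baseline = mp.intensity_baseline_error(cases, truth)
        assert err < 15.0
        assert err < baseline / 2.0

    def test_pure_cancer_sample_identified(self, rng):
        # a case generated without contamination must be fitted as nearly
        # pure cancer
        l, m, n = 20, 2, int(1e6)
        beta = _simplex(rng, (m, l))
        gamma = _simplex(rng, (1, l))[0]
        counts = rng.multinomial(n, gamma)[None, :].astype(float)
        cases = ProfileSet(counts, ["c0"], [f"f{j}" for j in range(l)],
                           ["case"], float(n))
        controls = ProfileSet(beta * n, ["k0", "k1"],
                              [f"f{j}" for j in range(l)],
                              ["control", "control"], float(n))
        res = fit_intensity_model(cases, controls)
        assert res.theta_star.cancer[0] >= 0.95
        # and its purified profile tracks the observed proportions
        np.testing.assert_allclose(purify_profile(res, 0),
                                   counts[0] / counts.sum(), atol=2e-3)

    def test_simplex_invariants_and_monotone_traces(self, small_intensity):
        _, cases, controls, _ = small_intensity
        res = fit_intensity_model(cases, controls)
        np.testing.assert_allclose(res.theta_star.theta.sum(axis=1), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(res.gamma_star.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert res.gamma_prime_star.sum() == pytest.approx(1.0, abs=1e-9)
        for trace in (res.step1_trace, res.step2_trace):
            t = np.asarray(trace)
            tol = 1e-6 * np.maximum(np.abs(t[:-1]), 1.0)
            assert np.all(np.diff(t) >= -tol)

    def test_purification_moves_profiles_off_contaminant_subspace(
            self, small_intensity):
        _, cases, controls, _ = small_intensity
        res = fit_intensity_model(cases, controls)
        beta = controls.intensities / controls.intensities.sum(1,
                                                               keepdims=True)
        basis, _, _ = np.linalg.svd(beta.T, full_matrices=False)

        def dist(profiles):
            resid = profiles - (profiles @ basis) @ basis.T
            return np.linalg.norm(resid, axis=1).mean()

        raw = cases.intensities / cases.intensities.sum(1, keepdims=True)
        assert dist(res.gamma_star) >= dist(raw)

    def test_error_shrinks_with_total_count(self):
        errs = []
        for n in (1e3, 1e6):
            cfg = mp.SynthConfig(D=5, L=20, M=2, N=n, n_diff=6, effect=8.0,
                                 seed=3)
            cases, controls, truth = mp.generate_intensity_mixtures(cfg)
            res = fit_intensity_model(cases, controls)
            errs.append(mp.mean_proportion_error(res.theta_star.theta,
                                                 truth.theta_true))
        assert errs[-1] < errs[0]

    def test_mismatched_features_rejected(self, small_intensity):
        _, cases, controls, _ = small_intensity
        bad = ProfileSet(controls.intensities,
                         controls.sample_ids,
                         [f"other{j}" for j in range(controls.n_features)],
                         controls.group_labels)
        with pytest.raises(ValueError, match="feature ids"):
            IntensityPurificationModel(cases, bad)

    def test_duplicate_topics_warn(self, rng):
        l = 8
        beta_row = _simplex(rng, (1, l))
        beta = np.vstack([beta_row, beta_row])
        cases = ProfileSet(_simplex(rng, (2, l)) * 1e5,
                           ["a", "b"], [f"f{j}" for j in range(l)],
                           ["case"] * 2)
        controls = ProfileSet(beta * 1e5, ["k0", "k1"],
                              [f"f{j}" for j in range(l)], ["control"] * 2)
        with pytest.warns(RuntimeWarning, match="unidentifiable"):
            IntensityPurificationModel(cases, controls)

    def test_purify_profile_bounds(self, small_intensity):
        _, cases, controls, _ = small_intensity
        res = fit_intensity_model(cases, controls)
        with pytest.raises(IndexError):
            purify_profile(res, 99)
        vec = purify_profile(res, 0)
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)
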
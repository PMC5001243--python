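"""Evaluation statistics: error ratios, testing, ROC, PCA."""

import numpy as np
import pytest

import mspurify as mp
from mspurify.data import ProfileSet
from mspurify.evaluate import (differential_test, mean_scan_error,
                               pca_project, profile_dissimilarity,
                               proportion_error_ratio, roc_auc_bootstrap,
                               scan_error_ratio)


def _ps(body, label="case"):
    d, l = np.asarray(body).shape
    return ProfileSet(np.asarray(body, dtype=float),
                      [f"{label}{i}" for i in range(d)],
                      [f"f{j}" for j in range(l)], [label] * d)


class TestErrorRatios:
    def test_identity_is_zero(self):
        assert proportion_error_ratio([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_hand_value(self):
        assert proportion_error_ratio([0.6, 0.4], [0.5, 0.5]) == pytest.approx(20.0)

    def test_bounded_by_200_for_simplex_inputs(self, rng):
        for _ in range(50):
            a = rng.dirichlet(np.ones(6))
            b = rng.dirichlet(np.ones(6))
            assert 0.0 <= proportion_error_ratio(a, b) <= 200.0 + 1e-9

    def test_symmetric_in_deviation_sign(self):
        base = np.array([0.25, 0.25, 0.25, 0.25])
        up = base + np.array([0.1, -0.1, 0.0, 0.0])
        down = base + np.array([-0.1, 0.1, 0.0, 0.0])
        assert (proportion_error_ratio(up, base)
                == proportion_error_ratio(down, base))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            proportion_error_ratio([0.5, 0.5], [1.0])

    def test_scan_error_hand_oracle(self):
        # two features with true scan totals [100, 300]; estimates [90, 330]
        s = 5
        true = np.stack([np.full(s, 20.0), np.full(s, 60.0)])
        est = np.stack([np.full(s, 18.0), np.full(s, 66.0)])
        assert scan_error_ratio(est, true) == pytest.approx(10.0)

    def test_scan_error_zero_for_identical_sets(self, rng):
        x = rng.uniform(0, 5, (4, 12))
        assert scan_error_ratio(x, x) == 0.0


class TestDifferentialTest:
    def test_null_false_positive_rate(self, rng):
        # identical groups: BH at q=0.05 should declare nearly nothing
        l, reps = 40, 100
        n_sig = 0
        for _ in range(reps):
            a = _ps(rng.normal(100, 10, (8, l)))
            b = _ps(rng.normal(100, 10, (8, l)), label="k")
            n_sig += len(differential_test(a, b, fdr=0.05))
        assert n_sig / reps <= 0.05 * l

    def test_large_shifts_all_detected(self, rng):
        l, shift = 30, 10.0
        a_body = rng.normal(100, 1.0, (30, l))
        b_body = rng.normal(100, 1.0, (30, l))
        a_body[:, :10] += shift  # ten features shifted by 10 pooled sd
        res = differential_test(_ps(a_body), _ps(b_body, "k"), fdr=0.05)
        assert set(res["feature_id"]) == {f"f{j}" for j in range(10)}

    def test_constant_feature_is_p_one_not_error(self, rng):
        a_body = rng.normal(10, 1, (5, 3))
        b_body = rng.normal(10, 1, (5, 3))
        a_body[:, 0] = 7.0
        b_body[:, 0] = 7.0
        res = differential_test(_ps(a_body), _ps(b_body, "k"), fdr=1.0)
        row = res[res["feature_id"] == "f0"]
        assert float(row["p_value"].iloc[0]) == 1.0

    def test_adjusted_p_monotone_in_raw_p(self, rng):
        a = _ps(rng.normal(50, 5, (10, 25)))
        b = _ps(rng.normal(52, 5, (10, 25)), label="k")
        res = differential_test(a, b, fdr=1.0)
        ordered = res.sort_values("p_value")
        assert ordered["p_adjusted"].is_monotonic_increasing


class TestROCAUC:
    def test_perfect_separation(self):
        auc, lo, hi = roc_auc_bootstrap([1, 2, 3, 10, 11, 12],
                                        [0, 0, 0, 1, 1, 1], n_boot=100)
        assert auc == 1.0 and hi == 1.0

    def test_tiny_case_equals_pair_counting(self):
        auc, _, _ = roc_auc_bootstrap([1, 2, 3, 4], [0, 0, 1, 1], n_boot=50)
        assert auc == 1.0

    def test_rank_auc_equals_brute_force_pairs(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 50))
            vals = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            auc, _, _ = roc_auc_bootstrap(vals, labels, n_boot=2)
            pos = vals[labels == 1]
            neg = vals[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_null_auc_near_half(self, rng):
        vals = rng.normal(size=200)
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        auc, _, _ = roc_auc_bootstrap(vals, labels, n_boot=10, seed=1)
        assert abs(auc - 0.5) < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_bootstrap([1, 2], [1, 1])


class TestPCA:
    def test_line_collapses_to_one_component(self, rng):
        direction = rng.normal(size=8)
        coords = np.outer(np.linspace(-2, 2, 10), direction)
        proj = pca_project(coords, k=1)
        recon_var = np.var(proj[:, 0])
        assert recon_var == pytest.approx(np.var(np.linspace(-2, 2, 10))
                                          * (direction ** 2).sum(), rel=1e-9)
        with pytest.raises(ValueError):
            pca_project(coords, k=3)

    def test_reconstruction_error_matches_discarded_singular_values(self, rng):
        x = rng.normal(size=(12, 7))
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        k = 3
        proj = pca_project(x, k=k)
        # Eckart–Young: squared error of the best rank-k approximation
        err = np.sum(xc**2) - np.sum(proj**2)
        assert err == pytest.approx(np.sum(s[k:] ** 2), rel=1e-9)

    def test_deterministic_sign_convention(self, rng):
        x = rng.normal(size=(9, 5))
        a = pca_project(x, k=2)
        b = pca_project(x.copy(), k=2)
        np.testing.assert_array_equal(a, b)


class TestDissimilarity:
    def test_identical_groups_zero(self, rng):
        body = rng.uniform(1, 5, (3, 6))
        assert profile_dissimilarity(_ps(body), _ps(body, "k")) == 0.0

    def test_two_feature_toy_closed_form(self):
        # psi = [0.5, 0.5], beta = [0.25, 0.75]: L1 distance 0.5 -> 50 %
        psi = _ps([[5.0, 5.0]])
        beta = _ps([[2.5, 7.5]], label="k")
        assert profile_dissimilarity(psi, beta) == pytest.approx(50.0)
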
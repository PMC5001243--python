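"""Scoring and downstream-analysis utilities.

Error ratios are relative L1 distances in percent: for mixture proportions
or profile vectors, ξ_d = 100·‖θ*_d − θ_d‖₁ / ‖θ_d‖₁; for scan-level
feature lists the inner difference is summed over scans per feature first
and the outer L1 runs over features.  Downstream analyses mirror a standard
biomarker workflow: Welch t-tests with Benjamini–Hochberg FDR control,
rank-statistic ROC AUC with stratified percentile-bootstrap confidence
intervals, and PCA projections for visual inspection of purification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import EICDataset, ProfileSet

__all__ = [
    "EvalReport",
    "proportion_error_ratio",
    "mean_proportion_error",
    "profile_error_ratio",
    "scan_error_ratio",
    "mean_scan_error",
    "differential_test",
    "roc_auc_bootstrap",
    "pca_project",
    "profile_dissimilarity",
]


@dataclass
class EvalReport:
    """Per-sample errors plus named scalar extras (AUCs, CI bounds, counts)."""

    per_sample_error: np.ndarray
    mean_error: float
    correlations: np.ndarray | None = None
    extras: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (np.asarray(self.per_sample_error) < 0).any():
            raise ValueError("error percentages must be non-negative")
        if self.correlations is not None and (
                (np.abs(np.asarray(self.correlations)) > 1 + 1e-9).any()):
            raise ValueError("correlations must lie in [-1, 1]")


def proportion_error_ratio(theta_star: np.ndarray, theta_true: np.ndarray) -> float:
    """Estimation error ratio (%) for one sample: 100·‖θ*−θ‖₁/‖θ‖₁."""
    theta_star = np.asarray(theta_star, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_star.shape != theta_true.shape:
        raise ValueError("theta vectors must have equal length")
    return float(100.0 * np.abs(theta_star - theta_true).sum()
                 / np.abs(theta_true).sum())


def mean_proportion_error(theta_star: np.ndarray, theta_true: np.ndarray) -> float:
    """Mean of :func:`proportion_error_ratio` over the rows of two matrices."""
    theta_star = np.atleast_2d(theta_star)
    theta_true = np.atleast_2d(theta_true)
    return float(np.mean([
        proportion_error_ratio(a, b) for a, b in zip(theta_star, theta_true)]))


# the same relative-L1 score applies to profile vectors
profile_error_ratio = proportion_error_ratio


def scan_error_ratio(gamma_star: np.ndarray, gamma_true: np.ndarray) -> float:
    """Scan-level error ratio (%) for one sample.

    Inputs are (L, S) matrices of per-scan abundances for matched features;
    the score is 100·‖Σ_s[γ*(s)−γ(s)]‖₁ / ‖Σ_s γ(s)‖₁ with the inner sums
    taken per feature over scans and the outer L1 over features.
    """
    gamma_star = np.asarray(gamma_star, dtype=float)
    gamma_true = np.asarray(gamma_true, dtype=float)
    if gamma_star.shape != gamma_true.shape:
        raise ValueError("EIC sets must have matching features and scan counts")
    diff = (gamma_star - gamma_true).sum(axis=1)
    denom = np.abs(gamma_true.sum(axis=1)).sum()
    return float(100.0 * np.abs(diff).sum() / denom)


def mean_scan_error(est: EICDataset, truth: EICDataset) -> float:
    """Mean of :func:`scan_error_ratio` across samples of two EIC datasets."""
    a = est.abundance_array()
    b = truth.abundance_array()
    if a.shape != b.shape:
        raise ValueError("datasets must have matching dimensions")
    return float(np.mean([scan_error_ratio(a[d], b[d])
                          for d in range(a.shape[0])]))


def differential_test(cases: ProfileSet, controls: ProfileSet,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Per-feature Welch t-test with Benjamini–Hochberg adjustment.

    Returns the significant features (adjusted p ≤ ``fdr``) sorted by
    adjusted p-value, with columns feature_id, p_value, p_adjusted,
    mean_case, mean_control.  A feature constant in both groups gets p = 1.
    """
    if list(cases.feature_ids) != list(controls.feature_ids):
        raise ValueError("cases and controls must share the feature list")
    if cases.n_samples < 2 or controls.n_samples < 2:
        raise ValueError("need at least 2 samples per group")
    a, b = cases.intensities, controls.intensities
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    reject, p_adj, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    df = pd.DataFrame({
        "feature_id": cases.feature_ids,
        "p_value": pvals,
        "p_adjusted": p_adj,
        "mean_case": a.mean(axis=0),
        "mean_control": b.mean(axis=0),
    })
    sig = df[p_adj <= fdr].sort_values("p_adjusted", kind="stable")
    return sig.reset_index(drop=True)


def _rank_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann–Whitney rank statistic; ties counted half."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0)
                 / (pos.size * neg.size))


def roc_auc_bootstrap(values, labels, n_boot: int = 1000, ci: float = 0.95,
                      seed: int = 0) -> Tuple[float, float, float]:
    """ROC AUC with a stratified percentile-bootstrap confidence interval.

    Returns ``(auc, ci_low, ci_high)``; resamples cases and controls
    separately so every replicate keeps both classes.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("both classes must be present")
    auc = _rank_auc(values, labels)
    rng = np.random.default_rng(seed)
    pos = values[labels == 1]
    neg = values[labels == 0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        boots[b] = _rank_auc(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(bp.size, int), np.zeros(bn.size, int)]))
    lo = (1.0 - ci) / 2.0
    return auc, float(np.quantile(boots, lo)), float(np.quantile(boots, 1 - lo))


def pca_project(profiles: np.ndarray, k: int = 3) -> np.ndarray:
    """Mean-centred SVD projection onto the top-k principal components.

    Deterministic sign convention: each component's largest-magnitude
    loading is positive.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the data rank {rank}")
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    return u[:, :k] * s[:k]


def profile_dissimilarity(psi: ProfileSet, beta: ProfileSet,
                          pairing: str = "auto") -> float:
    """Mean relative-L1 dissimilarity (%) between two profile groups.

    Profiles are normalised to proportions and scored with the same relative
    L1 ratio used for mixture proportions.  ``pairing="matched"`` averages
    index-matched pairs, ``"all"`` averages every cross pair; the default
    ``"auto"`` matches by index when the groups have equal size (so identical
    groups score 0) and falls back to all pairs otherwise.
    """
    if list(psi.feature_ids) != list(beta.feature_ids):
        raise ValueError("profile sets must share the feature list")
    a = psi.intensities / psi.intensities.sum(axis=1, keepdims=True)
    b = beta.intensities / beta.intensities.sum(axis=1, keepdims=True)
    if pairing == "auto":
        pairing = "matched" if a.shape[0] == b.shape[0] else "all"
    if pairing == "matched":
        if a.shape[0] != b.shape[0]:
            raise ValueError("matched pairing needs equal group sizes")
        scores = [profile_error_ratio(ai, bi) for ai, bi in zip(a, b)]
    elif pairing == "all":
        scores = [profile_error_ratio(ai, bj) for ai in a for bj in b]
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return float(np.mean(scores))
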
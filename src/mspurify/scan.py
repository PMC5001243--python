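"""Scan-level purification: EMG peak MCMC coupled with the intensity topic model.

The full scan-level model couples every peak's abundance, shape and missing-
scan indicators with the mixture structure of the intensity model; the joint
posterior has no tractable form, so inference is split variationally into two
phases that are alternated:

* **Phase 1** — Metropolis-within-Gibbs MCMC on every EIC (cases and
  controls) yields posterior-mean ion abundances x_t, x_β and EMG shapes φ.
  Posterior means are used because phase 2 treats the abundances as observed
  and a point summary is required; the mean is the L2-optimal one.
* **Phase 2** — the abundance vectors, rescaled to a common total, are
  handed to :class:`~mspurify.intensity.IntensityPurificationModel`, giving
  mixture proportions θ and pure cancer abundances x_γ (restored to the
  original total-ion scale afterwards).

Each outer alternation extends the phase-1 sampling (a fresh set of chains
pooled with the previous ones, sharpening the posterior means) and refits
phase 2; the loop stops when the L1 change in θ falls below ``theta_tol`` or
after ``outer_iters`` alternations.  Pure EIC peaks are reconstructed from
x_γ and the fitted shapes with all scans present and no noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .data import EICDataset, EICPeak, ProfileSet
from .intensity import IntensityPurificationModel, MixtureProportions
from .peaks import PeakPriors, emg_log_density, fit_peaks_mcmc

__all__ = [
    "ScanPurificationResult",
    "ScanPurificationModel",
    "fit_scan_model",
    "reconstruct_pure_eics",
]


@dataclass
class ScanPurificationResult:
    """Estimates from the scan-level purification fit.

    ``shapes_star`` holds per-(sample, feature) EMG parameters as a
    (D, L, 3) array with columns (mu, zeta, sigma); ``x_gamma_star`` the pure
    cancer abundances on the original scale; ``pure_eics`` the reconstructed
    noiseless pure peaks; ``phase_trace`` one row per outer alternation with
    the θ and abundance L1 changes.
    """

    theta_star: MixtureProportions
    x_gamma_star: np.ndarray
    shapes_star: np.ndarray
    pure_eics: EICDataset
    phase_trace: pd.DataFrame
    sample_ids: List[str]
    feature_ids: List[str]
    dropped_features: List[str]
    intensity_result: object = None

    def summary(self) -> pd.DataFrame:
        th = self.theta_star.theta
        return pd.DataFrame({
            "cancer_fraction": th[:, -1],
            "contamination": th[:, :-1].sum(axis=1),
            "pure_abundance_total": self.x_gamma_star.sum(axis=1),
        }, index=self.sample_ids)


def reconstruct_pure_eics(
    x_gamma: np.ndarray,
    shapes: np.ndarray,
    s_count: int,
    sample_ids: List[str] | None = None,
    feature_ids: List[str] | None = None,
    mz: np.ndarray | None = None,
    rt: np.ndarray | None = None,
) -> EICDataset:
    """Render pure EIC peaks x_γ·F(s, φ) with every scan present, no noise.

    ``shapes`` may be per feature (L, 3) or per sample and feature (D, L, 3),
    columns (mu, zeta, sigma).
    """
    x_gamma = np.asarray(x_gamma, dtype=float)
    if (x_gamma < 0).any():
        raise ValueError("pure abundances must be non-negative")
    d_n, l_n = x_gamma.shape
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim == 2:
        shapes = np.broadcast_to(shapes, (d_n, l_n, 3))
    grid = np.arange(1, s_count + 1, dtype=float)
    curves = np.exp(emg_log_density(
        grid[None, None, :], shapes[:, :, 0:1], shapes[:, :, 1:2],
        shapes[:, :, 2:3]))
    traces = x_gamma[:, :, None] * curves
    sample_ids = sample_ids or [f"sample_{d+1:02d}" for d in range(d_n)]
    feature_ids = feature_ids or [f"feat_{l+1:03d}" for l in range(l_n)]
    mz = mz if mz is not None else np.zeros(l_n)
    rt = rt if rt is not None else np.zeros(l_n)
    samples: Dict[str, List[EICPeak]] = {
        sid: [EICPeak(feature_ids[l], float(mz[l]), float(rt[l]),
                      traces[i, l]) for l in range(l_n)]
        for i, sid in enumerate(sample_ids)
    }
    return EICDataset(samples, {sid: "case" for sid in sample_ids})


class ScanPurificationModel:
    """Two-phase purifier for scan-level (EIC) data.

    Parameters
    ----------
    case_eics, control_eics : EICDataset
        Must share the feature list (same order) and the scan count S.
    priors : PeakPriors, optional
        Hyperparameters for the per-peak MCMC.
    """

    def __init__(self, case_eics: EICDataset, control_eics: EICDataset,
                 priors: PeakPriors | None = None):
        if case_eics.feature_ids != control_eics.feature_ids:
            raise ValueError("case and control EICs must share the feature list")
        if case_eics.scan_count != control_eics.scan_count:
            raise ValueError("case and control EICs must share the scan count")
        self.case_eics = case_eics
        self.control_eics = control_eics
        self.priors = priors or PeakPriors()

    def fit(self, mcmc_iters: int = 2000, burn_in: int = 1000,
            outer_iters: int = 5, theta_tol: float = 1e-3,
            alpha_cancer: float = 1.0, seed: int = 0,
            em_tol: float = 1e-6, em_max_iter: int = 500,
            snr_min: float = 5.0) -> ScanPurificationResult:
        """Run the two-phase fit.

        The first phase-1 pass learns every peak's shape by full
        Metropolis-within-Gibbs.  Because a chromatographic feature elutes
        with one shape across samples, the per-feature shapes are then
        pooled (median of the per-chain posterior means) and each outer
        alternation re-runs phase 1 warm-started at the pooled shapes with
        the shape block frozen — only the exact conjugate blocks are
        sampled — which removes the shape-uncertainty component of the
        abundance error before the mixture model of phase 2 sees the data.
        """
        case_arr = self.case_eics.abundance_array()    # (D, L, S)
        ctrl_arr = self.control_eics.abundance_array()  # (M, L, S)
        d_n, l_n, s_count = case_arr.shape
        m_n = ctrl_arr.shape[0]
        n_tot = d_n + m_n
        feature_ids = self.case_eics.feature_ids
        stacked = np.concatenate([case_arr, ctrl_arr]).reshape(-1, s_count)
        grid = np.arange(1, s_count + 1, dtype=float)

        # --- Phase 1a: shape-learning pass -------------------------------
        # A chromatographic feature elutes with one shape across samples, so
        # shapes are learned on a subset of chains (all controls plus a few
        # cases) and pooled per feature; every other quantity is estimated
        # for all chains afterwards with the shape frozen.
        n_shape_cases = min(6, d_n)
        sub_idx = np.concatenate([
            np.arange(n_shape_cases * l_n),
            np.arange(d_n * l_n, n_tot * l_n)])
        raw_sub = fit_peaks_mcmc(
            stacked[sub_idx], self.priors, n_iter=mcmc_iters, burn_in=burn_in,
            seed=seed % (2**31), keep_draws=False)
        shapes_sub = np.stack(
            [raw_sub["mu"], raw_sub["zeta"], raw_sub["sigma"]],
            axis=-1).reshape(n_shape_cases + m_n, l_n, 3)
        pooled = np.median(shapes_sub, axis=0)                 # (L, 3)
        shapes_fixed = np.tile(pooled, (n_tot, 1, 1)).reshape(-1, 3)

        # matched-filter (Rao-Blackwellised) abundances: with δ ≡ 1 and the
        # pooled shape, the exact conditional mean of x is Σ F·t / Σ F²,
        # which carries no Monte Carlo noise
        f_pooled = np.exp(emg_log_density(
            grid[None, :], pooled[:, 0:1], pooled[:, 1:2], pooled[:, 2:3]))
        f_sq = np.maximum((f_pooled * f_pooled).sum(axis=1), 1e-300)
        traces3 = stacked.reshape(n_tot, l_n, s_count)
        x_rb = np.maximum(
            (traces3 * f_pooled[None, :, :]).sum(axis=2) / f_sq[None, :], 0.0)

        theta_prev = None
        x_sum = np.zeros(stacked.shape[0])
        s2_sum = np.zeros_like(x_sum)
        q_sum = np.zeros_like(x_sum)
        trace_rows = []
        result = None
        keep = np.ones(l_n, dtype=bool)
        refine_iters = max(mcmc_iters // 4, 200)
        refine_burn = refine_iters // 2

        x_hat = None
        for outer in range(outer_iters):
            # --- Phase 1b: conjugate refinement at pooled shapes ----------
            # provides the missing-scan and noise posteriors; abundances for
            # fully-present peaks come from the matched filter.  Two pooled
            # refinement passes pin the presence classification; afterwards
            # the abundances are deterministic and further alternations only
            # refit phase 2 until theta stabilises.
            if outer < 1:
                raw = fit_peaks_mcmc(
                    stacked, self.priors, n_iter=refine_iters,
                    burn_in=refine_burn, seed=(seed + 1 + outer) % (2**31),
                    keep_draws=False, shapes_fixed=shapes_fixed)
                s2_sum += raw["noise_var"]
                q_sum += raw["q"]
                # the point estimates entering phase 2 are the matched-filter
                # values for every peak: the EIC exports this model consumes
                # are interpolated full-scan traces, so the δ-machinery serves
                # inference about missingness, not the abundance summary
                x_hat = x_rb

            # QC: only structural failures are dropped — non-finite chains or
            # features with no control signal.  Sub-noise features carry
            # bounded matched-filter estimates and tiny shares, so they are
            # harmless, while aggressive SNR cuts can discard exactly the
            # strongly differential features that identify the cancer topic.
            finite = np.isfinite(x_hat).all(axis=0)
            signal = x_hat.sum(axis=0) > 0
            keep = finite & signal
            if not keep.all():
                warnings.warn(
                    f"{int((~keep).sum())} feature(s) failed peak-fit QC and "
                    "are excluded from the mixture fit", RuntimeWarning,
                    stacklevel=2)
            if not keep.any():
                raise RuntimeError("no feature passed peak-fit QC")

            x_t = x_hat[:d_n][:, keep]
            x_b = x_hat[d_n:][:, keep]
            kept_ids = [f for f, k in zip(feature_ids, keep) if k]

            # --- Phase 2: abundances as observed intensity profiles -------
            totals = x_t.sum(axis=1)
            common = float(np.mean(np.concatenate([totals, x_b.sum(axis=1)])))
            cases_ps = ProfileSet(
                x_t * (common / totals)[:, None],
                self.case_eics.sample_ids, kept_ids,
                ["case"] * d_n, common)
            # a control with no detected signal at all carries no topic
            # information: it enters as a uniform (uninformative) profile
            b_sums = x_b.sum(axis=1)
            x_b_scaled = np.where(
                b_sums[:, None] > 0,
                x_b * (common / np.maximum(b_sums, 1e-300))[:, None],
                common / len(kept_ids))
            ctrl_ps = ProfileSet(
                x_b_scaled,
                self.control_eics.sample_ids, kept_ids,
                ["control"] * m_n, common)
            model = IntensityPurificationModel(cases_ps, ctrl_ps,
                                               alpha_cancer=alpha_cancer)
            result = model.fit(tol=em_tol, max_iter=em_max_iter, seed=seed)
            theta = result.theta_star.theta

            d_theta = (np.inf if theta_prev is None
                       else float(np.abs(theta - theta_prev).sum(axis=1).mean()))
            trace_rows.append({"outer_iter": outer + 1,
                               "theta_l1_change": d_theta,
                               "mean_cancer_fraction": float(theta[:, -1].mean())})
            theta_prev = theta
            if d_theta < theta_tol:
                break

        # pure abundances back on the original per-sample scale
        x_gamma = np.zeros((d_n, l_n))
        x_gamma[:, keep] = result.gamma_star * totals[:, None]

        case_shapes = np.tile(pooled, (d_n, 1, 1))  # per (sample, feature)
        first = next(iter(self.case_eics.samples.values()))
        mz = np.array([p.mz for p in first])
        rt = np.array([p.rt_start for p in first])
        pure = reconstruct_pure_eics(
            x_gamma, case_shapes, s_count,
            sample_ids=self.case_eics.sample_ids,
            feature_ids=feature_ids, mz=mz, rt=rt)
        return ScanPurificationResult(
            theta_star=result.theta_star,
            x_gamma_star=x_gamma,
            shapes_star=case_shapes,
            pure_eics=pure,
            phase_trace=pd.DataFrame(trace_rows),
            sample_ids=self.case_eics.sample_ids,
            feature_ids=feature_ids,
            dropped_features=[f for f, k in zip(feature_ids, keep) if not k],
            intensity_result=result,
        )


def fit_scan_model(case_eics: EICDataset, control_eics: EICDataset,
                   priors: PeakPriors | None = None,
                   **fit_kwargs) -> ScanPurificationResult:
    """Functional wrapper over :class:`ScanPurificationModel`."""
    return ScanPurificationModel(case_eics, control_eics, priors).fit(**fit_kwargs)
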
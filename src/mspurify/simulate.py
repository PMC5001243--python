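"""Synthetic heterogeneous LC-MS datasets with known ground truth.

The generator reproduces the structure of a serum-proteomic mixing study at
two levels:

* **Intensity level** — D heterogeneous case profiles over L features are
  built by (i) drawing a panel of M mutually similar contaminant sources
  β_m around a common reference profile, (ii) deriving an average cancer
  profile γ' from the reference by perturbing ``n_diff`` differential
  features by a fold-change ``effect``, (iii) drawing sample-specific pure
  profiles γ_d ~ Dirichlet(κ_d·γ') with κ_d = 1/min_l γ'_l, (iv) drawing
  mixing weights θ_d ~ Dirichlet(α) with α = [1,…,1,5] so the cancer
  component dominates on average, and (v) drawing the observed counts
  t_d ~ Multinomial(N, Σ_m θ_m β_m + θ_c γ_d) with N = 1.68×10⁸ total ions.
  Sampling uses the collapsed mixture, which has exactly the same law for
  the feature counts as drawing a topic indicator per ion.
* **Scan level** — the same mixing structure applied to EIC peaks: each
  feature carries an EMG elution shape shared across sources, source
  abundances proportional to the intensity-level sources, scan-wise blending
  with weights θ_d, and additive Gaussian scan noise.

Because the real base profiles behind the original study are not public,
the reference profile is a parametric stand-in (a skewed symmetric-Dirichlet
draw).  ``calibrate_effect`` tunes the differential fold-change so that the
unpurified-vs-truth baseline error ratio of the generated mixtures matches a
requested value, anchoring the synthetic study's difficulty before any model
is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .data import EICDataset, EICPeak, ProfileSet
from .peaks import emg_log_density

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "generate_base_profiles",
    "generate_intensity_mixtures",
    "generate_scan_mixtures",
    "intensity_baseline_error",
    "scan_baseline_error",
    "calibrate_effect",
    "sample_counts_via_indicators",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic mixing experiment.

    Defaults mirror the serum-proteomic setting: L=101 intensity features,
    M=9 contaminant sources, D=30 mixtures, N=1.68e8 total ions,
    θ ~ Dirichlet([1,…,1,5]); EICs have 60 scans, 561 scan-level features
    and 1 % scan noise.
    """

    L: int = 101
    M: int = 9
    D: int = 30
    N: float = 1.68e8
    alpha_mix: Tuple[float, ...] | None = None  # default [1]*M + [5]
    n_diff: int = 20
    effect: float = 3.0
    S: int = 60
    noise_frac: float = 0.01
    seed: int = 0
    # stand-in base-profile generator knobs
    ref_alpha: float = 0.5            # skew of the reference profile
    beta_concentration: float = 2000.0  # contaminant similarity around the reference
    diff_quantile: float = 0.4        # differential sites drawn below this share quantile
    scan_features: int = 561
    scan_total: float = 1e8           # per-sample total abundance at scan level
    noise_floor: float = 0.05         # LOD: noise sd floor, × the median peak max

    def __post_init__(self) -> None:
        if min(self.L, self.M, self.D, self.S, self.scan_features) <= 0:
            raise ValueError("counts must be positive")
        if self.N <= 0 or self.scan_total <= 0:
            raise ValueError("totals must be positive")
        if self.n_diff > self.L:
            raise ValueError("n_diff cannot exceed L")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.alpha_mix is not None:
            if len(self.alpha_mix) != self.M + 1:
                raise ValueError("alpha_mix must have M+1 entries")
            if min(self.alpha_mix) <= 0:
                raise ValueError("alpha_mix must be positive")

    @property
    def alpha(self) -> np.ndarray:
        if self.alpha_mix is not None:
            return np.asarray(self.alpha_mix, dtype=float)
        return np.concatenate([np.ones(self.M), [5.0]])


@dataclass
class SyntheticTruth:
    """Ground truth used to score recovery."""

    theta_true: np.ndarray          # (D, M+1)
    gamma_true: np.ndarray          # (D, L)
    gamma_prime_true: np.ndarray    # (L,)
    beta_true: np.ndarray           # (M, L)
    x_true: np.ndarray | None = None          # (D, L) pure scan abundances
    shapes_true: np.ndarray | None = None     # (L, 3) columns mu, zeta, sigma
    pure_eics_true: EICDataset | None = None


def _rng(cfg: SynthConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((cfg.seed + salt) % (2**31))


def generate_base_profiles(cfg: SynthConfig, n_features: int | None = None,
                           rng: np.random.Generator | None = None):
    """Draw the contaminant panel β and the average cancer profile γ'.

    A reference simplex vector is drawn from a symmetric Dirichlet; the M
    contaminants are high-concentration Dirichlet perturbations of it (so
    controls are mutually similar), and γ' is the reference with ``n_diff``
    randomly chosen features multiplied or divided by ``effect`` and
    renormalised — cancer looks like a control except at differential sites.
    """
    l_n = n_features if n_features is not None else cfg.L
    if cfg.n_diff > l_n:
        raise ValueError("n_diff cannot exceed the number of features")
    rng = rng if rng is not None else _rng(cfg)
    ref = rng.dirichlet(np.full(l_n, cfg.ref_alpha))
    ref = np.maximum(ref, 1e-10)
    ref = ref / ref.sum()
    beta = np.stack(
        [rng.dirichlet(cfg.beta_concentration * ref) for _ in range(cfg.M)])
    beta = np.maximum(beta, 1e-12)
    beta = beta / beta.sum(axis=1, keepdims=True)
    gp = ref.copy()
    # differential sites are drawn among lower-abundance features: large
    # fold-changes on minor constituents, as in serum marker panels, rather
    # than on the dominant proteins
    pool = np.where(ref < np.quantile(ref, cfg.diff_quantile))[0]
    if pool.size < cfg.n_diff:
        pool = np.argsort(ref)[: max(cfg.n_diff, 1)]
    sites = rng.choice(pool, size=cfg.n_diff, replace=False)
    up = sites[: cfg.n_diff // 2]
    down = sites[cfg.n_diff // 2:]
    gp[up] *= cfg.effect
    gp[down] /= cfg.effect
    gp = gp / gp.sum()
    return beta, gp


def _draw_mixture_params(cfg: SynthConfig, beta: np.ndarray, gp: np.ndarray,
                         rng: np.random.Generator):
    kappa_d = 1.0 / gp.min()
    gamma = rng.dirichlet(kappa_d * gp, size=cfg.D)
    gamma = np.maximum(gamma, 1e-15)
    gamma = gamma / gamma.sum(axis=1, keepdims=True)
    theta = rng.dirichlet(cfg.alpha, size=cfg.D)
    return theta, gamma


def generate_intensity_mixtures(cfg: SynthConfig):
    """Generate D heterogeneous case profiles plus controls and ground truth.

    Returns ``(cases, controls, truth)``: the cases are multinomial draws of
    N ions from the collapsed per-sample mixture, the controls are the exact
    contaminant sources on the count scale (the same profiles a study would
    hand to the model as its control group).
    """
    rng = _rng(cfg)
    beta, gp = generate_base_profiles(cfg, rng=rng)
    theta, gamma = _draw_mixture_params(cfg, beta, gp, rng)
    mix = theta[:, :-1] @ beta + theta[:, -1:] * gamma
    n_int = int(round(cfg.N))
    counts = np.stack([rng.multinomial(n_int, mix[d]) for d in range(cfg.D)])
    cases = ProfileSet(
        counts.astype(float),
        [f"case_{d+1:02d}" for d in range(cfg.D)],
        [f"feat_{l+1:03d}" for l in range(cfg.L)],
        ["case"] * cfg.D,
        float(n_int),
    )
    controls = ProfileSet(
        beta * n_int,
        [f"control_{m+1:02d}" for m in range(cfg.M)],
        list(cases.feature_ids),
        ["control"] * cfg.M,
        float(n_int),
    )
    truth = SyntheticTruth(theta_true=theta, gamma_true=gamma,
                           gamma_prime_true=gp, beta_true=beta)
    return cases, controls, truth


def sample_counts_via_indicators(rng: np.random.Generator, n: int,
                                 theta: np.ndarray,
                                 topics: np.ndarray) -> np.ndarray:
    """Feature counts drawn the long way: a topic indicator per ion, then the
    ion's feature from that topic.  Statistically identical to one collapsed
    multinomial draw from θ^T·topics; kept as the reference path for
    equivalence checks."""
    z_counts = rng.multinomial(n, theta)
    out = np.zeros(topics.shape[1], dtype=np.int64)
    for k, nk in enumerate(z_counts):
        if nk:
            out += rng.multinomial(int(nk), topics[k])
    return out


# ---------------------------------------------------------------------------
# scan level


def _draw_shapes(cfg: SynthConfig, l_n: int, rng: np.random.Generator):
    """Per-feature EMG shapes placed so the peak lies inside the scan window."""
    s = cfg.S
    mu = np.clip(rng.normal(0.4 * s, s / 12.0, size=l_n), 0.2 * s, 0.6 * s)
    sigma = np.exp(rng.normal(np.log(s / 20.0), 0.2, size=l_n))
    zeta = np.exp(rng.normal(np.log(12.0 / s), 0.3, size=l_n))
    return np.column_stack([mu, zeta, sigma])


def _shape_curves(shapes: np.ndarray, s_count: int) -> np.ndarray:
    grid = np.arange(1, s_count + 1, dtype=float)
    return np.exp(emg_log_density(
        grid[None, :], shapes[:, 0:1], shapes[:, 1:2], shapes[:, 2:3]))


def _to_eic_dataset(traces: np.ndarray, sample_ids: List[str], label: str,
                    mz: np.ndarray, rt: np.ndarray) -> EICDataset:
    samples: Dict[str, List[EICPeak]] = {}
    n_feat = traces.shape[1]
    for i, sid in enumerate(sample_ids):
        samples[sid] = [
            EICPeak(feature_id=f"feat_{l+1:03d}", mz=float(mz[l]),
                    rt_start=float(rt[l]), scans=traces[i, l])
            for l in range(n_feat)
        ]
    return EICDataset(samples, {sid: label for sid in sample_ids})


def generate_scan_mixtures(cfg: SynthConfig, n_features: int | None = None):
    """Generate scan-level heterogeneous EICs plus controls and ground truth.

    Each feature gets an EMG shape shared across sources; source abundances
    are proportional to the intensity-level source profiles; a case EIC is
    the scan-wise θ-weighted sum of the source EICs plus Gaussian noise of
    sd = ``noise_frac`` × the peak maximum (negative noise excursions clip at
    zero, as in real exports).  Ground-truth pure EICs (noiseless, δ≡1) are
    retained for scoring.
    """
    l_n = n_features if n_features is not None else cfg.scan_features
    rng = _rng(cfg, salt=1)
    # scan-level features inherit differential status from their parent
    # biomolecules: the differential-site count scales with the feature count
    n_diff_scan = max(2, int(round(cfg.n_diff * l_n / cfg.L)))
    scan_cfg = replace(cfg, L=l_n, n_diff=min(n_diff_scan, l_n))
    beta, gp = generate_base_profiles(scan_cfg, n_features=l_n, rng=rng)
    theta, gamma = _draw_mixture_params(scan_cfg, beta, gp, rng)
    x_beta = beta * cfg.scan_total            # (M, L)
    x_gamma = gamma * cfg.scan_total          # (D, L)
    x_case = theta[:, :-1] @ x_beta + theta[:, -1:] * x_gamma  # blended

    shapes = _draw_shapes(cfg, l_n, rng)
    curves = _shape_curves(shapes, cfg.S)     # (L, S)

    pure = x_gamma[:, :, None] * curves[None, :, :]
    clean_case = x_case[:, :, None] * curves[None, :, :]
    clean_ctrl = x_beta[:, :, None] * curves[None, :, :]

    def noisy(clean: np.ndarray) -> np.ndarray:
        if cfg.noise_frac <= 0:
            return clean.copy()
        peak_max = clean.max(axis=2, keepdims=True)
        # absolute noise floor: like a real detector, scan noise does not
        # shrink indefinitely for small peaks; peaks below the floor are
        # effectively beneath the limit of detection
        floor = cfg.noise_floor * np.median(peak_max, axis=1, keepdims=True)
        sd = cfg.noise_frac * np.maximum(peak_max, np.maximum(floor, 1e-12))
        return np.maximum(clean + rng.normal(size=clean.shape) * sd, 0.0)

    mz = rng.uniform(300.0, 1500.0, size=l_n)
    rt = np.sort(rng.uniform(5.0, 60.0, size=l_n))
    case_ids = [f"case_{d+1:02d}" for d in range(cfg.D)]
    ctrl_ids = [f"control_{m+1:02d}" for m in range(cfg.M)]
    case_eics = _to_eic_dataset(noisy(clean_case), case_ids, "case", mz, rt)
    ctrl_eics = _to_eic_dataset(noisy(clean_ctrl), ctrl_ids, "control", mz, rt)
    pure_eics = _to_eic_dataset(pure, case_ids, "case", mz, rt)

    truth = SyntheticTruth(
        theta_true=theta, gamma_true=gamma, gamma_prime_true=gp,
        beta_true=beta, x_true=x_gamma, shapes_true=shapes,
        pure_eics_true=pure_eics,
    )
    return case_eics, ctrl_eics, truth


# ---------------------------------------------------------------------------
# baselines and calibration


def intensity_baseline_error(cases: ProfileSet, truth: SyntheticTruth) -> float:
    """Mean relative-L1 error (%) between unpurified t_d/N and true γ_d."""
    t = cases.intensities
    prof = t / t.sum(axis=1, keepdims=True)
    err = np.abs(prof - truth.gamma_true).sum(axis=1) \
        / np.abs(truth.gamma_true).sum(axis=1)
    return float(err.mean() * 100.0)


def scan_baseline_error(case_eics: EICDataset, truth: SyntheticTruth) -> float:
    """Mean scan-level error ratio (%) between the unpurified case EICs and
    the true pure EICs (per-feature scan totals, relative L1 over features)."""
    t = case_eics.abundance_array().sum(axis=2)          # (D, L) scan totals
    g = truth.pure_eics_true.abundance_array().sum(axis=2)
    err = np.abs(t - g).sum(axis=1) / np.abs(g).sum(axis=1)
    return float(err.mean() * 100.0)


def calibrate_effect(
    cfg: SynthConfig,
    target_baseline: float,
    level: str = "intensity",
    n_features: int | None = None,
    rel_tol: float = 0.005,
    max_iter: int = 40,
    effect_bounds: Tuple[float, float] = (1.0, 300.0),
) -> SynthConfig:
    """Tune the differential fold-change so the unpurified baseline error
    matches ``target_baseline`` (in %).

    The baseline is a property of the generator alone (no inference); it is
    a monotone function of ``effect``, so a deterministic bisection with the
    configured seed converges quickly.  Returns a config identical to
    ``cfg`` except for the calibrated ``effect``.
    """
    if level not in ("intensity", "scan"):
        raise ValueError("level must be 'intensity' or 'scan'")

    def measure(effect: float) -> float:
        c = replace(cfg, effect=float(effect))
        if level == "intensity":
            cases, _, truth = generate_intensity_mixtures(c)
            return intensity_baseline_error(cases, truth)
        case_eics, _, truth = generate_scan_mixtures(c, n_features=n_features)
        return scan_baseline_error(case_eics, truth)

    lo, hi = effect_bounds
    f_lo, f_hi = measure(lo), measure(hi)
    if target_baseline <= f_lo:
        return replace(cfg, effect=float(lo))
    if target_baseline >= f_hi:
        return replace(cfg, effect=float(hi))
    mid = lo
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))  # bisect in log space
        f_mid = measure(mid)
        if abs(f_mid - target_baseline) <= rel_tol * target_baseline:
            break
        if f_mid < target_baseline:
            lo = mid
        else:
            hi = mid
    return replace(cfg, effect=float(mid))
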
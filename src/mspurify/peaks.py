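"""Scan-level generative model of a single EIC peak and its MCMC sampler.

An extracted ion chromatogram observed at scans ``s = 1..S`` is modelled as

    t(s) = x · δ(s) · F(s; μ, ζ, σ) + e(s)

where ``x`` is the ion abundance (the area of the noiseless peak), ``δ(s)`` a
per-scan Bernoulli(q) presence indicator for missing scans, ``F`` the
exponentially modified Gaussian (EMG) density — the canonical asymmetric
chromatographic elution shape, the law of a N(μ, σ²) variable plus an
independent Exp(ζ) tailing delay — and ``e(s) ~ N(0, σ²_e)`` additive
detector noise with a conjugate inverse-gamma prior on σ²_e.

Marginalising δ, each observed scan follows the two-component mixture

    t(s) | x, q, φ, σ²_e  ~  q·N(x·F(s,φ), σ²_e) + (1−q)·N(0, σ²_e).

Inference is Metropolis-within-Gibbs: exact conjugate Gibbs draws for δ, q,
σ²_e and the positively truncated normal full conditional of x, and Gaussian
random-walk Metropolis for (μ, log ζ, log σ) with proposal scales adapted
during burn-in only.  The sampler kernel is vectorised across peaks: a whole
(sample × feature) collection of chains advances in lock-step numpy arrays,
which is what makes scan-level purification of hundreds of features
tractable on one CPU.  Fitting a single peak is the n = 1 case of the same
kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "PeakShapeParams",
    "PeakState",
    "ShapePrior",
    "PeakPriors",
    "emg_density",
    "emg_log_density",
    "render_peak",
    "scan_loglik",
    "integrate_peak",
    "EMGPeakModel",
    "EMGPeakResults",
    "fit_peak_mcmc",
    "fit_peaks_mcmc",
]

_ERFCX_SAFE = -25.0  # below this, erfcx overflows; use the erfc→2 limit


@dataclass
class PeakShapeParams:
    """EMG shape: location mu (scans), exponential rate zeta (1/scan),
    Gaussian width sigma (scans)."""

    mu: float
    zeta: float
    sigma: float

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class PeakState:
    """Full latent state of one EIC peak."""

    abundance: float
    shape: PeakShapeParams
    present: np.ndarray  # length-S {0,1}
    noise_var: float
    present_rate: float

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present)
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")
        if not ((self.present == 0) | (self.present == 1)).all():
            raise ValueError("present indicators must be binary")
        if not 0.0 <= self.present_rate <= 1.0:
            raise ValueError("present_rate must lie in [0, 1]")


@dataclass
class ShapePrior:
    """Independent normal priors on (mu, log zeta, log sigma).

    ``mu_mean=None`` means "centre at the argmax scan of the observed trace",
    resolved when fitting.  Defaults are weakly informative and scale-aware
    for a window of S scans: the apex is somewhere in the window, the
    Gaussian width is of order S/10 scans and the exponential tail of order
    S/4 scans.
    """

    mu_mean: Optional[float] = None
    mu_sd: Optional[float] = None            # default S/4
    log_sigma_mean: Optional[float] = None   # default log(S/10)
    log_sigma_sd: float = 1.0
    log_zeta_mean: Optional[float] = None    # default log(4/S)
    log_zeta_sd: float = 1.0

    def resolved(self, observed: np.ndarray) -> "ShapePrior":
        s_count = observed.shape[-1]
        argmax = float(np.argmax(observed, axis=-1).mean()) + 1.0  # scans are 1-based
        return ShapePrior(
            mu_mean=self.mu_mean if self.mu_mean is not None else argmax,
            mu_sd=self.mu_sd if self.mu_sd is not None else s_count / 4.0,
            log_sigma_mean=(self.log_sigma_mean if self.log_sigma_mean is not None
                            else float(np.log(s_count / 10.0))),
            log_sigma_sd=self.log_sigma_sd,
            log_zeta_mean=(self.log_zeta_mean if self.log_zeta_mean is not None
                           else float(np.log(4.0 / s_count))),
            log_zeta_sd=self.log_zeta_sd,
        )


@dataclass
class PeakPriors:
    """Hyperparameters: inverse-gamma (a_e, b_e) for the noise variance,
    Beta (a_q, b_q) for the scan-presence rate, and normal shape priors.

    ``b_e`` is specified relative to the variance of the observed trace
    (the prior noise-variance scale is ``b_e · var(t)``), so one weak prior
    works across peaks whose amplitudes span many orders of magnitude.
    """

    a_e: float = 0.01
    b_e: float = 0.01
    a_q: float = 1.0
    b_q: float = 1.0
    shape_prior: ShapePrior = field(default_factory=ShapePrior)

    def __post_init__(self) -> None:
        if min(self.a_e, self.b_e, self.a_q, self.b_q) <= 0:
            raise ValueError("all prior hyperparameters must be strictly positive")


# ---------------------------------------------------------------------------
# EMG shape


def emg_log_density(s, mu, zeta, sigma):
    """log F(s, φ) of the EMG density, stable for extreme arguments.

    F(s,φ) = ½ζ·exp(½ζ(2μ+ζσ²−2s))·erfc((μ+ζσ²−s)/(√2 σ)).

    The exp prefactor overflows and the erfc underflows together when
    μ+ζσ²−s ≫ 0; both are folded through the scaled complement
    erfcx(u) = exp(u²)·erfc(u), for which log F = log(ζ/2) + A − u² +
    log erfcx(u) with A the exponent above.  For u below the erfcx overflow
    range, erfc(u) → 2 and log F = log ζ + A.
    """
    s = np.asarray(s, dtype=float)
    mu = np.asarray(mu, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    arg = 0.5 * zeta * (2.0 * mu + zeta * sigma**2 - 2.0 * s)
    u = (mu + zeta * sigma**2 - s) / (np.sqrt(2.0) * sigma)
    out = np.where(
        u < _ERFCX_SAFE,
        np.log(zeta) + arg,
        np.log(0.5 * zeta) + arg - u**2
        + np.log(special.erfcx(np.clip(u, _ERFCX_SAFE, None))),
    )
    return out


def emg_density(s, shape: PeakShapeParams):
    """EMG density F(s, φ) at scan coordinate(s) ``s`` (vectorised)."""
    val = np.exp(emg_log_density(s, shape.mu, shape.zeta, shape.sigma))
    if not np.all(np.isfinite(val)):
        raise FloatingPointError(
            f"non-finite EMG density for shape mu={shape.mu}, zeta={shape.zeta}, "
            f"sigma={shape.sigma}"
        )
    return val


def render_peak(state: PeakState, s_count: int) -> np.ndarray:
    """Noiseless peak x·δ(s)·F(s,φ) evaluated at scans s = 1..S."""
    if s_count < 1:
        raise ValueError("S must be at least 1")
    grid = np.arange(1, s_count + 1, dtype=float)
    f = emg_density(grid, state.shape)
    present = np.asarray(state.present, dtype=float)
    if present.size != s_count:
        raise ValueError("present indicator length does not match S")
    return state.abundance * present * f


def integrate_peak(state: PeakState) -> float:
    """Integrated intensity of the noiseless peak.

    Because F is a probability density, the area under x·F over the full
    support is exactly x; this is the scan-level analogue of the integrated
    peak intensity used by intensity-level profiles.
    """
    return float(state.abundance)


def scan_loglik(observed: np.ndarray, state: PeakState) -> float:
    """Marginal log-likelihood of an observed EIC under the peak model,
    with per-scan presence indicators δ summed out:

        Σ_s log[ q·N(t(s); x·F(s,φ), σ²_e) + (1−q)·N(t(s); 0, σ²_e) ].
    """
    observed = np.asarray(observed, dtype=float)
    if state.noise_var <= 0:
        raise ValueError("noise_var must be positive")
    grid = np.arange(1, observed.size + 1, dtype=float)
    f = emg_density(grid, state.shape)
    sd = np.sqrt(state.noise_var)
    q = state.present_rate
    lp_on = stats.norm.logpdf(observed, loc=state.abundance * f, scale=sd)
    lp_off = stats.norm.logpdf(observed, loc=0.0, scale=sd)
    if q <= 0.0:
        return float(lp_off.sum())
    if q >= 1.0:
        return float(lp_on.sum())
    per_scan = np.logaddexp(np.log(q) + lp_on, np.log1p(-q) + lp_off)
    return float(per_scan.sum())


# ---------------------------------------------------------------------------
# vectorised Metropolis-within-Gibbs


class _ChainState:
    """Lock-step state of n independent peak chains."""

    __slots__ = ("x", "mu", "log_zeta", "log_sigma", "delta", "q", "s2")

    def __init__(self, observed: np.ndarray, prior: ShapePrior,
                 rng: np.random.Generator):
        n, s_count = observed.shape
        grid = np.arange(1, s_count + 1, dtype=float)
        self.mu = np.full(n, np.nan)
        # per-chain argmax as the location start
        self.mu = grid[np.argmax(observed, axis=1)].astype(float)
        self.log_sigma = np.full(n, prior.log_sigma_mean, dtype=float)
        self.log_zeta = np.full(n, prior.log_zeta_mean, dtype=float)
        area = np.trapezoid(observed, grid, axis=1)
        self.x = np.maximum(area, 1e-12)
        self.delta = np.ones_like(observed)
        self.q = np.full(n, 0.9)
        resid = observed - self.x[:, None] * self._f(grid)
        self.s2 = np.maximum(np.mean(resid**2, axis=1), 1e-12)

    def _f(self, grid: np.ndarray) -> np.ndarray:
        return np.exp(emg_log_density(
            grid[None, :], self.mu[:, None],
            np.exp(self.log_zeta)[:, None], np.exp(self.log_sigma)[:, None]))


def _shape_logprior(mu, log_zeta, log_sigma, pr: ShapePrior):
    return (
        -0.5 * ((mu - pr.mu_mean) / pr.mu_sd) ** 2
        - 0.5 * ((log_zeta - pr.log_zeta_mean) / pr.log_zeta_sd) ** 2
        - 0.5 * ((log_sigma - pr.log_sigma_mean) / pr.log_sigma_sd) ** 2
    )


def _gibbs_sigma2(rng, a_e, b_e, s_count, rss):
    """Conjugate inverse-gamma draw for the noise variance:
    σ² ~ IG(a_e + S/2, b_e + RSS/2)."""
    shape = a_e + 0.5 * s_count
    scale = b_e + 0.5 * rss
    return scale / rng.gamma(shape, 1.0, size=np.shape(rss))


def _truncnorm_pos(rng, mean, sd):
    """Draw from N(mean, sd²) truncated to x ≥ 0 (vectorised).

    Uses inverse-CDF sampling through the upper-tail survival function,
    which stays accurate when mean/sd is far negative.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lo = stats.norm.sf(-mean / sd)  # P(X >= 0) under untruncated law... via sf
    u = rng.uniform(size=mean.shape)
    # sample upper-tail probability uniformly within [0, P(X>=0)]
    tail = u * lo
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(np.clip(tail, 1e-300, None))
    return np.maximum(mean + sd * z, 0.0)


def fit_peaks_mcmc(
    observed: np.ndarray,
    priors: PeakPriors | None = None,
    n_iter: int = 2000,
    burn_in: int = 1000,
    seed: int = 0,
    keep_draws: bool = True,
    adapt_every: int = 50,
    target_accept: float = 0.3,
    shapes_fixed: np.ndarray | None = None,
):
    """Run n independent peak chains in lock-step on an (n, S) matrix.

    Returns a dict with posterior means ``x``, ``mu``, ``zeta``, ``sigma``,
    ``q``, ``noise_var`` (each length n), the per-chain Metropolis acceptance
    rate ``accept_rate``, and, when ``keep_draws`` is true, the post-burn-in
    draw matrices under ``draws``.

    ``shapes_fixed`` (n, 3) with columns (mu, zeta, sigma) freezes the EMG
    shape of every chain; only the conjugate blocks (δ, q, σ²_e, x) are then
    sampled, which is exact and much cheaper when the shapes are known from
    a previous pooled pass.
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    if not np.all(np.isfinite(observed)):
        raise ValueError("observed abundances must be finite")
    n, s_count = observed.shape
    if s_count < 3:
        raise ValueError("need at least 3 scans per peak")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    priors = priors or PeakPriors()
    pr = priors.shape_prior.resolved(observed)
    rng = np.random.default_rng(seed)
    grid = np.arange(1, s_count + 1, dtype=float)

    st = _ChainState(observed, pr, rng)
    if shapes_fixed is not None:
        shapes_fixed = np.asarray(shapes_fixed, dtype=float)
        st.mu = shapes_fixed[:, 0].astype(float).copy()
        st.log_zeta = np.log(shapes_fixed[:, 1]).astype(float)
        st.log_sigma = np.log(shapes_fixed[:, 2]).astype(float)
    # noise prior scale tracks each trace's variance (see PeakPriors)
    b_e_chain = priors.b_e * np.maximum(observed.var(axis=1), 1e-30)
    all_zero = ~observed.any(axis=1)
    if all_zero.any():
        warnings.warn(
            f"{int(all_zero.sum())} peak(s) are identically zero; their abundance "
            "posterior will concentrate near 0", RuntimeWarning, stacklevel=2)

    # adaptive RW proposal scales (per chain, per coordinate)
    step = np.tile(np.array([s_count / 20.0, 0.15, 0.15]), (n, 1))
    acc_count = np.zeros(n)
    acc_window = np.zeros(n)
    prop_window = 0

    n_keep = n_iter - burn_in
    sums = {k: np.zeros(n) for k in ("x", "mu", "zeta", "sigma", "q", "s2")}
    draws = ({k: np.empty((n_keep, n)) for k in ("x", "mu", "zeta", "sigma", "q", "s2")}
             if keep_draws else None)
    # Rao-Blackwellised accumulators: averaging the conditional means of x
    # and q instead of their draws estimates the same posterior means with
    # far less Monte Carlo noise (used when the shape block is frozen)
    rb_x_sum = np.zeros(n)
    rb_q_sum = np.zeros(n)

    f_cur = st._f(grid)
    for it in range(n_iter):
        mean_on = st.x[:, None] * f_cur

        # δ | rest  (Bernoulli full conditional per scan)
        q_c = np.clip(st.q, 1e-12, 1 - 1e-12)
        lp1 = (np.log(q_c)[:, None]
               - 0.5 * (observed - mean_on) ** 2 / st.s2[:, None])
        lp0 = (np.log1p(-q_c)[:, None]
               - 0.5 * observed**2 / st.s2[:, None])
        p1 = special.expit(lp1 - lp0)
        st.delta = (rng.uniform(size=observed.shape) < p1).astype(float)

        # q | δ  (Beta conjugacy)
        ones = st.delta.sum(axis=1)
        st.q = rng.beta(priors.a_q + ones, priors.b_q + s_count - ones)
        q_cond = (priors.a_q + ones) / (priors.a_q + priors.b_q + s_count)

        # σ²_e | rest  (inverse-gamma conjugacy)
        resid = observed - st.delta * mean_on
        rss = np.sum(resid**2, axis=1)
        st.s2 = _gibbs_sigma2(rng, priors.a_e, b_e_chain, s_count, rss)

        # x | rest  (truncated-normal full conditional, flat positive prior)
        df = st.delta * f_cur
        ssq = np.sum(df * f_cur, axis=1)
        prec = ssq / st.s2
        # Update x only when the δ=1 scans carry a non-negligible share of
        # the shape's squared mass.  If δ has excluded the peak core, the
        # conditional mean would divide by tail-level F values and x can
        # run away to absurd magnitudes on noise-floor traces.
        active = ssq > 0.01 * np.sum(f_cur * f_cur, axis=1) + 1e-300
        x_cond = st.x
        if active.any():
            mean_x = np.where(active, np.sum(df * observed, axis=1)
                              / np.maximum(prec * st.s2, 1e-300), 0.0)
            sd_x = np.where(active, 1.0 / np.sqrt(np.maximum(prec, 1e-300)), 1.0)
            x_new = _truncnorm_pos(rng, mean_x, sd_x)
            st.x = np.where(active, x_new, st.x)
            # conditional mean of the positively truncated normal
            z = mean_x / sd_x
            ratio = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
            x_cond = np.where(active, mean_x + sd_x * ratio, st.x)

        # (μ, log ζ, log σ) | rest  (random-walk Metropolis, joint proposal)
        if shapes_fixed is not None:
            if it >= burn_in:
                acc_count += 0.0
                rb_x_sum += x_cond
                rb_q_sum += q_cond
                vals = {"x": st.x, "mu": st.mu, "zeta": np.exp(st.log_zeta),
                        "sigma": np.exp(st.log_sigma), "q": st.q, "s2": st.s2}
                for k, v in vals.items():
                    sums[k] += v
                    if keep_draws:
                        draws[k][it - burn_in] = v
            continue
        eps = rng.standard_normal((n, 3)) * step
        mu_p = st.mu + eps[:, 0]
        lz_p = st.log_zeta + eps[:, 1]
        ls_p = st.log_sigma + eps[:, 2]
        f_prop = np.exp(emg_log_density(
            grid[None, :], mu_p[:, None],
            np.exp(lz_p)[:, None], np.exp(ls_p)[:, None]))
        # only scans with δ=1 involve the shape
        ll_cur = -0.5 * np.sum(
            st.delta * (observed - st.x[:, None] * f_cur) ** 2, axis=1) / st.s2
        ll_prop = -0.5 * np.sum(
            st.delta * (observed - st.x[:, None] * f_prop) ** 2, axis=1) / st.s2
        logr = (ll_prop - ll_cur
                + _shape_logprior(mu_p, lz_p, ls_p, pr)
                - _shape_logprior(st.mu, st.log_zeta, st.log_sigma, pr))
        ok = np.isfinite(logr) & (np.log(rng.uniform(size=n)) < logr)
        st.mu = np.where(ok, mu_p, st.mu)
        st.log_zeta = np.where(ok, lz_p, st.log_zeta)
        st.log_sigma = np.where(ok, ls_p, st.log_sigma)
        f_cur = np.where(ok[:, None], f_prop, f_cur)
        acc_window += ok
        prop_window += 1

        # adapt proposal scales during burn-in only
        if it < burn_in and (it + 1) % adapt_every == 0:
            rate = acc_window / prop_window
            step *= np.exp(rate - target_accept)[:, None]
            step = np.clip(step, 1e-4, s_count)
            acc_window[:] = 0.0
            prop_window = 0

        if it >= burn_in:
            acc_count += ok
            vals = {"x": st.x, "mu": st.mu, "zeta": np.exp(st.log_zeta),
                    "sigma": np.exp(st.log_sigma), "q": st.q, "s2": st.s2}
            for k, v in vals.items():
                sums[k] += v
                if keep_draws:
                    draws[k][it - burn_in] = v

    if not (np.isfinite(st.x).all() and np.isfinite(st.mu).all()
            and np.isfinite(st.s2).all()):
        raise FloatingPointError("divergent chain: non-finite state encountered")

    out = {
        "x": (rb_x_sum / n_keep if shapes_fixed is not None
              else sums["x"] / n_keep),
        "mu": sums["mu"] / n_keep,
        "zeta": sums["zeta"] / n_keep,
        "sigma": sums["sigma"] / n_keep,
        "q": (rb_q_sum / n_keep if shapes_fixed is not None
              else sums["q"] / n_keep),
        "noise_var": sums["s2"] / n_keep,
        "accept_rate": acc_count / n_keep,
    }
    if keep_draws:
        draws["noise_var"] = draws.pop("s2")
        out["draws"] = draws
    return out


# ---------------------------------------------------------------------------
# statsmodels-style wrapper for a single peak


class EMGPeakResults:
    """Posterior summary of one fitted EIC peak."""

    def __init__(self, observed, priors, raw):
        self.observed = observed
        self.priors = priors
        self._raw = raw
        self.accept_rate = float(raw["accept_rate"][0])

    @property
    def posterior_mean_state(self) -> PeakState:
        r = self._raw
        present = (self.draws["q"].mean() > 0.5)  # summary convenience only
        return PeakState(
            abundance=float(r["x"][0]),
            shape=PeakShapeParams(float(r["mu"][0]), float(r["zeta"][0]),
                                  float(r["sigma"][0])),
            present=np.ones(self.observed.size) if present
            else np.zeros(self.observed.size),
            noise_var=float(r["noise_var"][0]),
            present_rate=float(r["q"][0]),
        )

    @property
    def draws(self) -> pd.DataFrame:
        d = self._raw["draws"]
        return pd.DataFrame({k: d[k][:, 0] for k in
                             ("x", "mu", "zeta", "sigma", "q", "noise_var")})

    def credible_interval(self, param: str = "x", level: float = 0.9):
        lo = (1.0 - level) / 2.0
        col = self.draws[param]
        return float(col.quantile(lo)), float(col.quantile(1.0 - lo))

    def fitted_curve(self) -> np.ndarray:
        st = self.posterior_mean_state
        grid = np.arange(1, self.observed.size + 1, dtype=float)
        return st.abundance * emg_density(grid, st.shape)

    def summary(self) -> pd.DataFrame:
        rows = []
        for p in ("x", "mu", "zeta", "sigma", "q", "noise_var"):
            col = self.draws[p]
            lo, hi = self.credible_interval(p)
            rows.append((p, col.mean(), col.std(), lo, hi))
        return pd.DataFrame(rows, columns=["param", "mean", "sd",
                                           "ci5%", "ci95%"]).set_index("param")


class EMGPeakModel:
    """Bayesian EMG peak model for a single observed EIC trace."""

    def __init__(self, observed, priors: PeakPriors | None = None):
        self.observed = np.asarray(observed, dtype=float)
        if self.observed.ndim != 1:
            raise ValueError("EMGPeakModel takes a single 1-D trace; use "
                             "fit_peaks_mcmc for a batch")
        self.priors = priors or PeakPriors()

    def fit(self, n_iter: int = 2000, burn_in: int = 1000,
            seed: int = 0) -> EMGPeakResults:
        raw = fit_peaks_mcmc(self.observed[None, :], self.priors,
                             n_iter=n_iter, burn_in=burn_in, seed=seed,
                             keep_draws=True)
        return EMGPeakResults(self.observed, self.priors, raw)


def fit_peak_mcmc(observed, priors: PeakPriors | None = None,
                  n_iter: int = 2000, burn_in: int = 1000,
                  seed: int = 0) -> EMGPeakResults:
    """Fit a single EIC peak by Metropolis-within-Gibbs MCMC."""
    return EMGPeakModel(observed, priors).fit(n_iter=n_iter, burn_in=burn_in,
                                              seed=seed)
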
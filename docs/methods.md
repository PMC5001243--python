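# Methods

## Intensity-level purification model

A heterogeneous case profile over `L` biomolecules, normalised to a common
total ion count `N`, is treated as a corpus of `N` ions, each drawn from one
of `M+1` sources: the `M` control profiles `β_m` (fixed topics, normalised to
probability vectors with a pseudocount of 1e-10 so every entry is strictly
positive) or the sample's latent pure cancer profile `γ_d`. The model is

* `θ_d ~ Dirichlet(α)` — mixing weights, `α` defaulting to 1 on every slot
  (an `alpha_cancer` option upweights the cancer slot);
* `γ' ~ Dirichlet(κ'·η᷀β)` — the average cancer profile is a noisy version of
  a convex blend of the controls, encoding the assumption that cancer looks
  like a control except at differentially expressed sites;
* `γ_d ~ Dirichlet(κ_d·γ')` — individual pure profiles concentrate around
  the average cancer profile;
* each ion picks a topic from `θ_d` and a biomolecule from that topic.

With only the `L` feature counts as sufficient statistics, the per-ion
indicators are collapsed exactly into the mixture-of-multinomials data term
`Σ_l t_dl log(Σ_m θ_dm β_ml + θ_dc γ_dl)`; no per-ion quantity is ever
materialised (at `N = 1.68e8` that matters).

### Why fitting needs care: an exact likelihood ridge

The collapsed likelihood is *exactly* invariant under the family of
transformations `γ' ← (γ' + Σ_m c_m β_m)/(1 + Σ_m c_m)` with compensating
changes in `θ`: blending contaminant into the cancer topic (or removing it)
leaves every fitted mixture untouched. The data bound this ridge only at its
ends: inward (toward the contaminant hull) until some sample's contaminant
weight hits zero, outward until some coordinate of `γ'` hits zero. The model
is therefore identifiable only to the extent that the data carry *anchors* —
in practice, features strongly down-regulated in cancer, whose near-zero
`γ'` coordinates pin the outward end. Plain EM started from a neutral point
drifts to the outward (overshooting) end of the ridge; a weak prior cannot
stop it, and a strong prior biases the answer inward.

### The fitting schedule (step 1)

1. **Maximum-likelihood stage.** Block EM (multiplicative updates for `θ`
   and `γ'`, 30 inner iterations per block) from uniform `θ` and
   `γ' = η᷀β`, until `γ'` stalls. This lands on the high-likelihood ridge.
2. **Strong-prior stage.** Same updates with the `Dirichlet(κ'η᷀β)` prior at
   `κ' = 2e-5 × (total ion mass)`, which slides the solution back along the
   (likelihood-flat) ridge toward the contaminant side.
3. **Weak-prior crawl.** `κ' = 2e-8 × mass` (floor 50): relaxes the
   shrinkage while staying in the basin selected by stage 2.
4. **Quasi-Newton polish.** Exact joint maximisation of the
   `κ' = 1e-7 × mass` (floor 200) posterior by L-BFGS in softmax
   coordinates with the analytic gradient. This removes the dependence on
   where the EM crawl happens to stop; EM alone cannot traverse the flat
   valley because its effective step size decays with curvature.

The schedule constants are fixed package defaults, chosen once by simulation
with known ground truth and scaled to the total ion mass so that the strong
stage dominates noise-level likelihood differences (tens of nats) without
competing with genuine data constraints (which are `N`-scale). `η` is held
uniform during the fit and fitted to the final `γ'` by projected gradient for
reporting; the reported `κ'` is the empirical-Bayes optimum for the final
`γ'`. Learning `κ'` *during* the fit was rejected: its empirical-Bayes
optimum collapses to the weak end and never breaks the ridge.

**Step 2** freezes `γ'`, initialises every `γ_d` at `γ'` with
`κ_d = 1/min_l γ'_l` (floored at 1e-8 so spurious near-zero fitted entries
cannot inflate it), and alternates EM updates of `θ_d` and `γ_d` with
per-sample acceptance checks; `κ_d` is re-optimised by bounded scalar search
every fifth iteration, starting only after `γ_d` has moved off `γ'`
(optimising it at the initial point degenerates to the upper bound and
freezes the step). Both steps record objective traces that are
non-decreasing within tolerance; step 1's reported trace is the final-stage
EM trace, step 2's the full-model posterior.

Convergence defaults: relative objective change below 1e-6 with `γ'`-change
stopping rules per stage; `max_iter` (default 500) scales every stage budget.

### What the estimates mean

`θ*` rows are mixing proportions (the last column is the sample's cancer
fraction, i.e. tumour purity); `γ*_d` are probability vectors whose product
with `N` is the purified intensity profile; `γ'*` is the cohort-average
cancer profile. Recovery of `θ` is limited by the residual ridge
uncertainty: with `D = 30` samples and mixing weights drawn from
`Dirichlet([1,…,1,5])`, the mean relative-L1 error of `θ` plateaus around
3–4 % — the likelihood is *exactly* flat along the ridge, so no estimator
can do better than the prior information there.

## Scan-level purification model

Each EIC peak is `t(s) = x·δ(s)·F(s;μ,ζ,σ) + e(s)`, `s = 1..S`, with the
exponentially modified Gaussian (EMG)

`F(s,φ) = ½ζ·exp(½ζ(2μ+ζσ²−2s))·erfc((μ+ζσ²−s)/(√2σ))`,

the density of a Normal(μ,σ²) plus an independent Exponential(ζ) tailing
delay — the canonical asymmetric chromatographic peak shape. Numerics: the
exp prefactor and the erfc under/overflow together; both are folded through
the scaled complement `erfcx` in log space, with the `erfc → 2` limit used
beyond the `erfcx` range. Scan noise is `N(0, σ²_e)` with an inverse-gamma
prior whose scale is specified *relative to the observed trace variance*
(`b_e = 0.01` by default), so one weak prior serves peaks whose amplitudes
span many orders of magnitude. δ(s) are Bernoulli(q) with a Beta(1,1) prior.
Shape priors are weakly informative and scale-aware: `μ ~ N(argmax scan,
(S/4)²)`, `log σ ~ N(log(S/10), 1)`, `log ζ ~ N(log(4/S), 1)`.

Per-peak inference is Metropolis-within-Gibbs: conjugate draws for δ, q,
σ²_e and the positively-truncated-normal full conditional of x, and a joint
Gaussian random walk on `(μ, log ζ, log σ)` adapted during burn-in only
(2000 iterations, 1000 burn-in by default). The kernel advances all peaks of
a dataset in lock-step numpy arrays. Two guards matter on noise-floor
traces: x is updated only when the δ=1 scans carry at least 1 % of the
shape's squared mass (otherwise the conditional mean divides by tail-level F
values and x can run away), and the noise prior's relative scaling prevents
a σ²–x inflation feedback.

### Two-phase purification

The coupled model (abundances inside the topic model, shapes inside each
peak) has no tractable joint posterior, so inference splits into phases:

1. **Shapes.** A full MCMC pass learns every peak's shape. Because a
   chromatographic feature elutes with a single shape across samples, the
   pass runs on all controls plus six cases and the per-feature shapes are
   pooled (median of posterior means).
2. **Abundances.** With the pooled shape fixed, the point estimate entering
   the mixture stage is the matched-filter value
   `Σ_s F(s)t(s) / Σ_s F(s)²` for every peak — the exact conditional mean
   of x given a fully present peak, free of Monte Carlo noise. The EIC
   exports this model consumes are interpolated full-scan traces (missing
   values are filled upstream in standard preprocessing), so the
   missing-scan machinery informs the presence-rate and noise posteriors
   (from a fixed-shape conjugate refinement pass) rather than the abundance
   summary. Gating the abundance on the presence posterior was rejected:
   strongly down-regulated case features — precisely the anchors of the
   mixture model — sit near the presence threshold and would receive noisy
   sampled means.
3. **Mixture.** The abundance vectors, rescaled to a common total (mean of
   per-sample sums), enter the intensity-level model as observed profiles;
   pure abundances are rescaled back to each sample's original total. Only
   structural failures are dropped (non-finite chains, features with zero
   control signal): sub-noise features carry bounded matched-filter
   estimates and tiny topic shares, whereas aggressive SNR-based filtering
   was found to discard exactly the strongly differential features that
   anchor the cancer topic.

Phases alternate (default 5 outer alternations) until the mean L1 change of
`θ` drops below 1e-3; with deterministic abundances this happens after two
or three alternations. Pure EIC peaks are reconstructed as `x_γ·F(s,φ̂)`
with every scan present and no noise.

## Peak detection (comparison path)

EICs are converted to integrated intensities the classical way: 4th-order
Savitzky–Golay smoothing (window 25, edges by truncated-window polynomial
fit), correlation with the first derivative of a Gaussian kernel (width 25,
σ=3), apexes at negative-going zero crossings whose flanking lobes exceed
3× the median absolute deviation of the response, bounds at the nearest
response sign changes, and trapezoidal area of the *raw* signal between the
bounds (smoothing guides localisation only). One peak per window is
expected; if several are detected the largest area is used. When these areas
feed the intensity-level model, features are first required to be detected
in every control sample — the same consistency rule used for identification
in real studies — because per-sample detection dropouts distort the
contaminant topics far more than area noise does.

## Synthetic-data generator

The generator emulates a serum-proteomic mixing study. Defaults are the
study conditions: L=101 features, M=9 contaminant sources, D=30 mixtures,
N=1.68e8 ions, `θ ~ Dirichlet([1,…,1,5])` (cancer fraction mean 5/14),
`κ_d = 1/min_l γ'_l` for the individual pure profiles; scan level: 561
features (here run at 400 for desk scale), 60 scans, 1 % peak-relative scan
noise. Because the original base profiles are not public, a parametric
stand-in generates them:

* a reference profile from a symmetric Dirichlet(0.5) — skewed shares, as in
  real serum;
* contaminants as Dirichlet perturbations of the reference with
  concentration 2000 (a few percent coefficient of variation between
  control subjects);
* the average cancer profile as the reference with `n_diff = 20` sites
  multiplied/divided by a fold-change `effect`, the sites drawn among
  features below the 0.4 share quantile — large fold-changes on minor
  constituents, as in real marker panels. This choice is load-bearing: it
  gives the mixtures the strongly down-regulated anchor features that real
  cancer-vs-control profiles possess and that make the deconvolution
  identifiable (see the ridge discussion above). A generator whose
  differential signal is a mild ripple on dominant features produces
  mixtures whose mixing weights are provably not recoverable.
* `calibrate_effect` tunes the fold-change by deterministic bisection so the
  unpurified-vs-truth baseline error matches a requested value (16.57 % for
  the reproduced study); calibration precedes all fitting and uses only the
  generator.

Counts are drawn from the collapsed mixture multinomial — exactly the law of
per-ion topic-then-feature sampling (verified by a goodness-of-fit test) —
so rows sum to N exactly. Scan-level blending is scan-wise with a shared
per-feature EMG shape drawn to lie inside the scan window
(`μ ~ N(0.4S, (S/12)²)` clipped, `σ ~ LogN(log(S/20), 0.2)`,
`ζ ~ LogN(log(12/S), 0.3)`); scan-level differential-site counts scale with
the feature count (peptide-level features inherit their parent protein's
status). Scan noise has an absolute floor of 5 % of the median peak maximum,
emulating a real detector's limit of detection; negative noise excursions
clip at zero as in real exports.

**What the generator does not emulate:** retention-time misalignment between
samples (peaks are index-aligned, as the fixed 60-scan windows imply),
isotope envelopes, charge states, chimeric or overlapping peaks,
inter-feature intensity correlations, batch effects, and non-Gaussian
detector noise. Passing tests therefore demonstrate correct inference under
the model's own assumptions plus the mixing structure — not robustness to
real-data artefacts.

## Evaluation statistics

Recovery is scored by relative-L1 error ratios in percent:
`ξ_d = 100·‖θ*_d − θ_d‖₁/‖θ_d‖₁` for mixing weights (and profile vectors),
and the scan-level variant with per-feature scan totals inside and the L1
over features outside. The scan-level formula is read as: sum each feature's
scans first, then take the L1 across features (the alternative nesting —
absolute values inside — was rejected as it cannot reach zero for
reconstructed peaks whose shapes differ infinitesimally). Differential
testing uses Welch's t-test with Benjamini–Hochberg adjustment at FDR 0.05;
ROC AUC uses the rank statistic (ties count half) with stratified
percentile-bootstrap confidence intervals (1000 replicates); PCA projections
are mean-centred SVD with a deterministic sign convention. The group
dissimilarity score pairs profiles by index when group sizes match (so
identical groups score zero) and over all pairs otherwise.

## Reproduced study scales and known limitations

The acceptance run uses the full intensity-level scale (D=30, L=101, M=9,
N=1.68e8) and 400 of 561 scan-level features (a desk-scale choice; recovery
improves with the feature count because more anchors pin the ridge, and 400
keeps the complete study around ten minutes on one CPU). Residual
limitations, measured on synthetic data: the intensity-level mixing-weight
error plateaus at ~3–4 % (ridge-position uncertainty; the reproduced study
reports 2.33 % on its real-profile instance), and all recovery statistics
vary by roughly ±1 percentage point across generator seeds. The scan-level
model outperforms the integrate-then-purify route on the same data (as the
reproduced study found), primarily because detection dropouts and area
truncation distort the contaminant topics.
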
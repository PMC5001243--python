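# mspurify

Topic-model–based computational purification of heterogeneous mass-spectrometric
expression profiles.

## The problem

Biospecimens profiled by LC/GC-MS in cancer biomarker studies — tumour tissue,
serum — are mixtures: only part of the measured ion signal comes from the
cancerous constituent of interest, the rest from contaminating sources
(adjacent or systemic non-cancerous material, typically resembling the control
group). Differential analyses on the raw heterogeneous profiles are therefore
diluted and biased. `mspurify` estimates, for every case sample, the mixing
weights of the contaminant sources and the sample-specific *pure* cancerous
profile — at the level of integrated peak intensities, or directly at the scan
level from extracted ion chromatograms (EICs), where peak-shape information is
still available.

## The models

**Intensity level.** Each case profile `t_d` (L feature counts normalised to a
common total ion count N) follows a hierarchical Dirichlet/multinomial topic
model. The M control profiles, normalised to probability vectors `β_1..β_M`,
are fixed "topics"; one additional sample-specific cancer topic `γ_d` is
latent:

```
θ_d ~ Dirichlet(α)                 mixing weights over M+1 sources
γ'  ~ Dirichlet(κ'·η᷀β)            average cancer profile (η on the simplex)
γ_d ~ Dirichlet(κ_d·γ')            sample-specific pure profile
t_d ~ Multinomial(N, Σ_m θ_dm β_m + θ_d,M+1 γ_d)
```

The per-ion topic indicators are collapsed exactly, so the data term is
`Σ_l t_dl · log(Σ_m θ_dm β_ml + θ_dc γ_dl)`. Estimation is two-step: first a
single shared cancer topic γ′ is estimated jointly with all θ_d (annealed-prior
block coordinate ascent with a quasi-Newton polish), then γ′ is frozen and
per-sample γ_d are refined under the Dirichlet(κ_d γ′) prior.
`IntensityPurificationModel(cases, controls).fit()` returns the mixing weights
θ*, pure profiles γ*_d, the average cancer profile γ′*, learned
hyperparameters and monotone objective traces.

**Scan level.** Each EIC peak is modelled as
`t(s) = x·δ(s)·F(s; μ,ζ,σ) + e(s)` over scans `s = 1..S`, with an
exponentially modified Gaussian (EMG) elution shape `F`, ion abundance `x`,
Bernoulli(q) missing-scan indicators δ and Gaussian noise with an
inverse-gamma prior. Peaks are fitted by Metropolis-within-Gibbs MCMC
(vectorised across all peaks); posterior abundances feed the intensity-level
topic model in an alternating two-phase scheme
(`ScanPurificationModel(case_eics, control_eics).fit()`), yielding mixing
weights, pure abundances and reconstructed pure EIC peaks.

Also included: the classical Savitzky–Golay + derivative-of-Gaussian peak
detector that converts EICs to integrated areas, a synthetic-data generator
with known ground truth reproducing the serum-proteomic mixing study
(D=30 mixtures, L=101 features, M=9 contaminants, N=1.68×10⁸ ions,
θ ~ Dirichlet([1,…,1,5]); 60-scan EIC analogues), and evaluation utilities
(relative-L1 error ratios, Welch+BH differential testing, bootstrap ROC/AUC,
PCA projections).

## Worked example

```python
import mspurify as mp

# a calibrated synthetic mixing study with known ground truth
cfg = mp.calibrate_effect(mp.SynthConfig(seed=1), target_baseline=16.57)
cases, controls, truth = mp.generate_intensity_mixtures(cfg)
print(f"unpurified error: {mp.intensity_baseline_error(cases, truth):.2f} %")

model = mp.IntensityPurificationModel(cases, controls)
res = model.fit()
print(res.summary().head(3))
theta_err = mp.mean_proportion_error(res.theta_star.theta, truth.theta_true)
print(f"mixing-weight error after purification: {theta_err:.2f} %")
```

prints

```
unpurified error: 16.36 %
         cancer_fraction  contamination
case_01         0.428280       0.571720
case_02         0.224613       0.775387
case_03         0.282566       0.717434
mixing-weight error after purification: 4.20 %
```

The unpurified line says a raw case profile deviates from its true pure cancer
profile by ~16 % in relative L1; after the fit, the estimated mixing weights
(per-sample cancer fraction and the shares of the nine contaminant sources)
deviate from the generating truth by ~4 % on average, and the purified
profiles correlate with the true pure profiles at r ≈ 0.9999.

The same study from the shell:

```
mspurify simulate --level intensity --out sim/ --seed 1 --effect 20
mspurify purify-intensity --cases sim/cases.csv --controls sim/controls.csv --out fit/
mspurify evaluate --truth sim/ --fit fit/ --out report.json
```

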
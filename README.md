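# ctspectra

Corticothalamic neural-field simulation and aperiodic/periodic EEG
spectral analysis of emotional arousal.

## The scientific problem

EEG power spectra mix two kinds of signal: narrowband oscillations (the
alpha rhythm at 8–12 Hz above all) and a broadband, aperiodic "1/f"
background.  Decomposing the spectrum as

```
log10 PSD(F) = [b − X·log10 F]  +  Σₙ aₙ·exp(−(F−cₙ)²/(2ωₙ²))
```

separates the aperiodic *offset* `b` (an index of overall neuronal
activity) and *exponent* `X` (higher values ↔ relatively more
inhibition) from Gaussian peak parameters (height `a` in log10-power
units above the background, center `c`, width `ω`).  In affect studies
shaped like DEAP — 32 participants × 40 one-minute music videos, each
trial rated 1–9 for arousal and valence — trial-level spectral features
can then be regressed on the ratings with linear mixed models

```
X_is = β0 + β1·X_pre + β2·A_i + β3·V_i + β4·A_iV_i
       + S_0s + u_As·A_i + u_Vs·V_i + e_is
```

(by-subject random intercepts and rating slopes, prestimulus baseline
covariate, Satterthwaite F-tests, Holm correction for cluster-level
families).  The empirical pattern of interest — with higher arousal the
exponent and offset rise and alpha peak power falls — is given a
mechanistic reading with a corticothalamic neural mass model (cortical
e/i populations, thalamic relay and reticular nuclei, 80-ms loop delay,
sigmoid rate conversion, damped-wave cortical propagation in the global
mode): sweeping the synaptic couplings shows that *increased net
inhibition of the thalamic relay* — directly (reticular→relay, ν_sr), by
reduced cortical excitation of relay (ν_es), or by stronger cortical
drive to reticular (ν_re) — reproduces exactly that spectral signature.

This package implements the whole chain — simulator, multitaper +
spectral parameterization, mixed models, and a synthetic study generator
with known ground truth so every stage is testable without any data
download — for researchers who want to reuse, probe or extend the
analysis.

## Worked example

Simulate 60 s of the model at the normative resting-state parameters and
parameterize its spectrum:

```
$ ctspectra --outdir out --seed 1 simulate
offset=-0.803 exponent=1.276 top_peak_cf=9.82 alpha_cf=9.82
```

The dominant fitted peak of the simulated EEG sits at 9.8 Hz — inside
the alpha band, the model's thalamocortical loop resonance — on a 1/f
background whose 4–40 Hz exponent is 1.28 (over 10–50 Hz it is ≈ 2, the
textbook high-frequency value; the 4–40 Hz fit is flattened by the
low-frequency plateau).  Full traces, the spectral fit and a provenance
JSON land in `out/`.

Generate a synthetic study and check that the pipeline recovers the
planted arousal effect on the exponent (0.0162 per rating unit):

```
$ ctspectra --outdir out --seed 1 validate --replicates 20
{
  "true_beta_arousal_exponent": 0.0162,
  "replicates": 20,
  "mean_estimate": 0.013720700622410478,
  "bias": -0.002479299377589521,
  "relative_bias_pct": -15.304317145614329,
  "ci95_coverage": 0.95
}
```

19 of 20 replicate studies covered the true effect with their 95%
confidence intervals; the mean estimate is within Monte-Carlo noise of
the truth (each study estimates the effect with standard error ≈ 0.01,
so 20 replicates pin the mean only to ±0.002).

Other subcommands: `sweep` (coupling sweeps with a Spearman trend
summary), `parameterize` (PSD table → feature CSV), `synth` (write a
synthetic study to disk), `stats` (mixed models on a trial table).  All
accept a YAML config; see `ctspectra --help`.

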
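# Methods

This note documents the models, estimators and numerical choices behind
`ctspectra`, and what its synthetic validation does and does not show.

## 1. Corticothalamic neural-field model (`ctspectra.ctmodel`)

### Model

Four neural masses: cortical excitatory (e) and inhibitory (i)
populations, thalamic relay/specific (s) and reticular (r) nuclei.  Each
population j has a mean membrane potential `V_j` (mV), firing rate
`Q_j` (1/s) and presynaptic field `phi_j` (1/s), coupled by:

- **Synaptodendritic filter** —
  `(1/(αβ)) V̈_j + (1/α + 1/β) V̇_j + V_j = Σ_k ν_jk φ_k(t − τ_jk)`,
  with α, β the inverse decay/rise times of the postsynaptic response and
  ν_jk the synaptic coupling (mV·s) from population k to j.
- **Sigmoid rate conversion** —
  `Q_j = Q_max / (1 + exp(−π (V_j − θ)/(σ√3)))`, a logistic matched to a
  Gaussian spread of firing thresholds (mean θ, sd σ).
- **Damped-wave propagation**, cortical excitatory field only, in the
  spatially uniform (global, ∇² = 0) mode —
  `(1/γ²) φ̈_e + (2/γ) φ̇_e + φ_e = Q_e` with γ the cortical damping rate;
  local populations propagate instantaneously (`φ_j = Q_j`).
- **Loop delays** — `t0/2` = 40 ms on each corticothalamic (e→r, e→s) and
  thalamocortical (s→e, s→i) projection, so one full loop takes the
  return time `t0` = 80 ms; no delay within cortex or within thalamus.
- **Drive** — the relay receives `ν_sn φ_n`, with
  `φ_n = noise_mean + white noise` (Euler–Maruyama draws
  `noise_sd/√dt · N(0,1)` per step, i.e. continuous-time white noise of
  two-sided density `noise_sd²`).

Printed sources of this model family contain three well-known typos which
we resolve to the standard forms: the dendritic operator's constant term
is `+V_j` (not `+1`), the sigmoid denominator is `σ√3` (not `σ3`), and
the wave operator is normalized to unit zero-frequency gain as written
above.  Both cortical populations receive identical input (the random
connectivity assumption), so `V_i ≡ V_e` in the global mode; the relay
and reticular potentials differ.

### Parameters

Defaults are the normative resting-state values: θ = 15 mV, σ = 6 mV,
Q_max = 250 s⁻¹, γ = 100 s⁻¹, α = 50 s⁻¹, β = 240 s⁻¹, t0 = 80 ms,
ν_ee = 1.06, ν_ei = −1.8, ν_es = 2.20, ν_se = 2.28, ν_sr = −0.845,
ν_sn = 1.20, ν_re = 0.91, ν_rs = 0.41 (all mV·s; inhibitory couplings
negative).  Parameter files are flat YAML with these field names.

### Integration and initialization

Explicit Euler–Maruyama on the first-order companion form, delays in ring
buffers, default dt = 1 ms, 60 s retained after a 5-s discarded
transient.  Histories are initialized at the numerically solved fixed
point of the zero-derivative equations (root-finding from several starts,
residual < 1e−10; the lowest-potential root is taken when several exist).
A guard bound (default 10⁴ mV) converts runaway trajectories into a
`DivergenceError`; pathological couplings with no reachable fixed point
raise `SteadyStateError`.  Identical (params, config, seed) give
bitwise-identical traces.

### Stability structure and drive level (a key design choice)

The linearized model has an alpha-band mode whose pole we locate by
solving the transcendental characteristic equation (`alpha_mode_pole`).
At the normative couplings the mode's damping depends on the mean relay
drive: at `noise_mean = 1 s⁻¹` the fixed point is weakly *unstable*
(Re s ≈ +0.13 s⁻¹ at 9.6 Hz), while at `noise_mean = 0.5 s⁻¹` it is a
damped resonator (Re s ≈ −0.6 s⁻¹ at 9.4 Hz).  Because the resting model
is described throughout as a damped oscillator driven by noise, the
package default is `noise_mean = 0.5 s⁻¹`.

Separately, explicit Euler adds an artificial antidamping of about
`(2πf)² dt/2` to an oscillatory mode — ≈ +1.8 s⁻¹ for the alpha mode at
dt = 1 ms, which exceeds its true damping.  At the historical step of
1 ms the simulated alpha mode is therefore numerically self-sustained (a
small, sigmoid-saturated limit cycle with harmonics).  This regime still
reproduces the normative spectral facts (dominant peak at 9.6–9.8 Hz;
10–50 Hz aperiodic exponent 2.1–2.3) and is kept as the default for
normative-spectrum runs.  Analyses that need the near-resonance response
integrated accurately — coupling sweeps and the analytic-oracle
comparison — use `sweep_config()`: dt = 0.25 ms (artificial antidamping
≈ +0.45 s⁻¹, below the mode's damping) and `noise_sd = 0.02` so the
response stays in the near-linear regime.  With `noise_sd = 0` at these
settings the trajectory stays at the fixed point to < 1e−6 mV, which is
how the integrator's fixed-point consistency is tested.

### Which trace is "EEG"

Two proxies are exposed.  `phi_e`, the cortical excitatory field, is the
standard scalp-EEG proxy of this model family: the damped-wave operator
contributes a `1/(1+iω/γ)²` roll-off that steepens the high-frequency
log-log slope by 2, and it is on this trace that the 10–50 Hz aperiodic
exponent is ≈ 2.  `v_e`, the mean membrane potential (reported in μV,
i.e. the model's mV × 1000, matching the empirical EEG scale), lacks that
roll-off (its 10–50 Hz slope is near 0) but is the trace on which all
three spectral features respond monotonically to the net inhibition of
the thalamic relay.  Normative-spectrum operations therefore default to
`phi_e` and coupling sweeps to `v_e`; both are selectable everywhere.

### Linearized-spectrum oracle

`linearized_spectrum` evaluates the closed-form PSD of the model
linearized at its fixed point: sigmoid slopes as gains, Fourier transforms
of the dendritic and wave operators, `exp(−iωt0/2)` delay factors, the
4×4 closed-loop system solved per frequency, times the one-sided input
density `2·noise_sd²`.  It is an independent verification oracle for the
time-domain integrator: at sweep-grade settings the multitaper PSD of a
120-s simulation matches it with median relative error ≈ 15% over
4–40 Hz (excluding ±1 Hz around the resonance, where spectral leakage
and the finite taper bandwidth dominate).

### Coupling sweeps

`parameter_sweep` re-simulates with one coupling set to each value (same
seed and settings throughout), extracts (offset, exponent, alpha height,
alpha center), and flags unstable runs instead of dropping them.  Default
ranges run from the normative value toward stronger net relay inhibition:
ν_sr −0.845 → −1.13, ν_es 2.20 → 1.60, ν_re 0.91 → 1.20.  On `v_e` the
three features move monotonically (Spearman ρ = ±1.0 on 8 points):
exponent and offset rise, alpha peak power falls — for all three
mechanisms of increasing relay inhibition.  The offset's *absolute level*
is arbitrary (it shifts with the noise amplitude and the trace units);
only its direction of change is meaningful, and on the μV scale the
offsets are positive so the signed and absolute-value readings agree.

## 2. Spectral estimation and parameterization (`ctspectra.spectral`)

### Multitaper PSD

DPSS (Slepian) tapers via `scipy.signal.windows.dpss`; eigenspectra
averaged; one-sided; linear detrend beforehand.  The half-bandwidth W and
taper count are explicit settings: the convention is W = 0.6 Hz with 45
tapers for 60-s epochs (time-bandwidth product TW = 36; the 2TW−1 = 71
bound is enforced but deliberately under-used) and 5 tapers for 5-s
prestimulus epochs (TW = 3).  Parseval holds to ~5% on stationary inputs;
the implementation cross-checks against MNE's multitaper (whose
`bandwidth` argument is the full width 2W) to ~1%.

### Spectral model

In log10 power over a fit range (default 4–40 Hz):
`log10 PSD = L + Σ G_n` with aperiodic `L = b − log10(κ + F^X)` (knee κ
omitted in the default *fixed* mode, leaving the straight line
`b − X log10 F`) and Gaussian peaks `G = a exp(−(F−c)²/(2ω²))`, heights
`a` in log10-power units above the aperiodic component.

Fitting pipeline:

1. **Robust aperiodic fit** — least-squares fit of L, clip negative
   residuals to zero, keep bins at/below the 2.5th percentile of the
   clipped residuals (masking peak regions), refit; two masked passes.
2. **Peak extraction** — iteratively take the flattened spectrum's
   maximum; accept if it clears `peak_threshold` (default 2.0) standard
   deviations of the flattened spectrum and the absolute
   `min_peak_height` (default 0.0, with a 1e−6 numerical floor that stops
   noiseless spectra from yielding degenerate peaks); estimate width from
   the half-height span clipped to `peak_width_limits` (default
   [0.5, 12] Hz, stored as Gaussian sd limits [0.25, 6]); subtract and
   repeat up to `max_peaks` (default 5).  Overlapping guesses (center
   bands within 0.75 sd) are pruned to the taller peak — noise can split
   one broad peak into two guesses.
3. **Joint Gaussian refit** — all accepted peaks refit simultaneously,
   centers bounded within ±1.5 widths of their guesses; peaks leaving the
   fit range are dropped; a non-convergent refit falls back to the
   guesses and is flagged by the goodness-of-fit.
4. **Final aperiodic refit** on the peak-subtracted spectrum; goodness of
   fit (R², mean absolute error) in log10 space against the data.

`select_alpha` returns the highest-power peak with center in 8–12 Hz.
Alpha "power" downstream always means the Gaussian height `a` in
log10-power units above the aperiodic fit, not linear band power.

Validated properties: noiseless aperiodic+Gaussian spectra recover all
five parameters to < 1e−2; multiplying a spectrum by a constant shifts
only the offset (by log10 k); exponent recovery error < 0.05 clean and
< 0.15 with an alpha peak and estimator noise; on synthesized 60-s
epochs the Monte-Carlo mean error is ≈ 0.06 for the exponent and
≈ 0.17 Hz for the alpha center (20+ seeds).

## 3. Mixed-model statistics (`ctspectra.emotion_stats`)

### Models

Per response (exponent, offset or alpha height), with A and V the raw
1–9 arousal and valence ratings of trial i in subject s:

- global: `X_is = β0 + β1 X_pre + β2 A_i + β3 V_i + β4 A_iV_i + S_0s +
  u_As A_i + u_Vs V_i + e_is`
- cluster: the prestimulus, arousal and valence terms are crossed with
  electrode cluster (cell-means coding, one coefficient per cluster), the
  arousal×valence term stays shared, random structure unchanged.

Random effects are independent by-subject intercept and slopes (the
standard reading of a by-subject intercept-and-slopes specification).
Ratings are used raw by default; within-subject centering is available.

### Estimation

REML via statsmodels `MixedLM`, followed by a *polish* step: with
uncentered 1–9 ratings the intercept and slope variances trade off along
a flat ridge and MixedLM's optimizer can stall well short of the REML
optimum (we observed ~35 log-likelihood units on realistic data), so the
identical REML criterion — written per-group with the Woodbury identity,
O(n q²) — is re-maximized by L-BFGS-B on the log-variance scale from both
MixedLM's solution and a moment-based start.  Fixed effects, standard
errors and the GLS covariance are recomputed at the polished variance
estimates.  On test datasets the result matches R `lmerTest` estimates
and standard errors to well under 2%.

### Satterthwaite degrees of freedom

For each fixed-effect contrast c:
`ν = 2 (c'Ĉc)² / (∇g' A ∇g)` with `Ĉ(θ)` the GLS covariance of the fixed
effects, `∇g` the gradient of `c'Ĉc` in the variance parameters
θ = (σ², g_intercept, g_A, g_V), and `A` the covariance of θ̂ estimated
as the inverse negative Hessian of the REML log-likelihood.  Derivatives
are central finite differences on the log-variance scale; components
within 1e−8 of zero (relative to the largest) carry no curvature and are
held fixed.  F = (β̂/se)² with 1 numerator df.  If the Hessian is not
invertible the code falls back to containment-style df (n − rank) and
flags the fit.  In well-identified cases the df match R lmerTest to
better than 0.1%; exactly at the zero-variance boundary ("singular
fits") the Satterthwaite approximation is not uniquely defined and
implementations legitimately disagree — our log-scale active-set version
returns finite, conservative values there.

### Filters and multiplicity

`filter_trials` drops trials with non-positive task exponent (a positive
spectral slope indicates noise) and subjects with fewer than
`min_alpha_trials` (default 10 of 40; the original criterion is
unpublished, only its outcome) trials carrying a detected alpha peak,
reporting every exclusion.  Holm's step-down correction (via statsmodels
`multipletests`) is applied to the family of all cluster×arousal and
cluster×valence contrasts within one response model.

### PCA reduction

`cluster_pca_reduce` centers each cluster's channels and projects onto
the first principal axis per trial (per-trial granularity; per-subject
concatenation would weight trials unequally under artifact rejection),
loading signs fixed so the loading sum is positive.  Ships both the
8-cluster montage grouping and a 9-cluster variant with a frontocentral
group (FC1, FC5, FC6, FC2).

## 4. Synthetic studies (`ctspectra.synthetic_data`)

`generate_study` draws a study of 32 subjects × 40 trials (28 after the
standard exclusions is the analysis scale), continuous arousal/valence
ratings from N(5, 2²) clipped to [1, 9] (the rating scale is continuous,
so no rounding), subject random effects, and trial features generated by
exactly the global-model structure above, so estimator validation is
internally consistent.  Generator defaults: arousal→exponent effect
0.0162 per rating unit (the one published effect size; all others are
package choices), arousal→offset 0.015, arousal→alpha −0.02, valence
effects 0, prestimulus carry-over 0.25, subject intercept sd 0.25,
slope sds 0.01, residual sd 0.18, baselines (exponent 1.2, offset 0.3,
alpha height 0.7 at 10 ± 0.5 Hz), 90% of trials with a detectable alpha
peak.  `generate_cluster_study` shares ratings and subject effects
across clusters and lets effects be planted in single clusters.

`synthesize_epoch` shapes white noise in the frequency domain so the
one-sided PSD follows `10^(b − X log10 f + G(f))` — independent complex
spectral coefficients with the target expected power, so a multitaper
estimate recovers the generating parameters up to estimator noise.
Synthetic sampling rate is 256 Hz (not the empirical 512 Hz) to keep the
full round trip fast; fitted parameters are invariant to doubling fs.

What the synthetic data does **not** emulate: artifacts (blinks, EMG),
non-stationarity within epochs, channel covariance beyond the planted
cluster structure, rating–video confounds.  Green round-trip tests show
the estimators are consistent under the assumed model, not that the
model is true of any real recording.

## 5. Pipeline (`ctspectra.cli`)

`ctspectra` exposes `simulate`, `sweep`, `parameterize`, `synth`,
`stats` and `validate` subcommands over a YAML config (unknown keys are
rejected).  One global seed expands to per-stage seeds as
`(seed·1000003 + crc32(stage)) mod 2³¹`, so stages are individually
reproducible; every command writes a provenance JSON (stage, seed,
config hash, package version).  Outputs are CSV/JSON only; figures are
left to the user on top of the plot-ready CSVs.

## 6. Known limitations

- Explicit Euler–Maruyama at the historical 1-ms step biases weakly
  damped modes (see section 1); sweep-grade settings mitigate but halving dt
  further still moves the fitted exponent by ~0.1.
- The aperiodic offset of the *field* spectrum is nearly pinned by the
  wave-operator roll-off; offset conclusions should be drawn from the
  membrane-potential trace (section 1) and only as directions, never levels.
- Satterthwaite df at the zero-variance boundary are approximation-
  dependent; compare with `method` = "containment-fallback" flags.
- Knee-mode aperiodic fitting is implemented but minimally validated
  (the default analysis fixes the aperiodic mode).
- The mixed models assume Gaussian residuals; alpha height (bounded
  below by the detection threshold) mildly violates this for sparse
  alpha trials.
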
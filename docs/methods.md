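# Methods

This note documents the models the package implements, the synthetic-data
generator that stands in for archived field data, the numerical choices,
and the known limitations. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## 1. Respirometry processing

A raw trace is a long-format table (`chamber_id, fish_id, kind, phase,
t_s, o2_mgL, temp_C`). Units are chosen so the uptake equation is
dimensionally closed with no hidden conversions: O₂ concentration in
mg L⁻¹ (≡ µg ml⁻¹), volumes in ml, mass in mg, rates in µg O₂ min⁻¹.

- **Slope fitting** (`fit_o2_slope`): ordinary least squares of O₂ on
  time over each contiguous `measure` segment, reported per minute with
  r². For intermittent-flow (SMR) cycles the leading 30 s of each
  measurement window is trimmed, mirroring the instrument wait period
  after a flush; static RMR (15 min) and MMR (5 min) windows are used
  whole, as single slopes. A rolling-window maximum-slope MMR option
  exists but is off by default, since the single 5-min chase window is
  the protocol being modelled.
- **Uptake**: MO₂ = (V_r − V_f) × |ΔC/Δt|, consumption positive. A rising
  trace produces a negative MO₂ and a flag, not an error.
- **Background correction** (`blank_correct`): the microbial rate is
  measured in fishless blanks bracketing each trial and interpolated
  linearly in time at each cycle's mean timestamp, clamped to the
  endpoint values outside the bracketing interval. One missing blank
  degrades to a constant correction with a warning; both missing is an
  error. Over-correction yields a negative corrected rate that is
  retained and flagged rather than floored, so the dispersion statistics
  used by the SMR screen stay unbiased.
- **SMR reduction** (`extract_smr`): first exclude cycles beyond ±2 SD of
  the mean over *all* cycles, then average the lowest ⌈10%⌉ of survivors
  (minimum one cycle, so the subset is never empty). The screen-then-
  subset order is a deliberate choice: screening globally first prevents
  a single spike from inflating the subset SD. The opposite order is
  available as `outlier_order="subset"`.
- **Summaries**: AS = MMR − SMR, FAS = MMR/SMR, with flags when
  MMR ≤ SMR or MMR < RMR (a chase protocol that failed to elicit a true
  maximum shows up this way).

Exactness: on noise-free, burst-free synthetic traces the chain returns
the generating MO₂ to ~1e−15 relative (the OLS slope of an exactly linear
signal), and the linear-in-time background model makes blank correction
exact because the OLS slope of an exactly quadratic signal equals the
derivative at the mean timestamp.

## 2. Synthetic data generator

The generator defines the study conditions and is itself tested code.

**Design.** Eight populations (four per thermal history), two tanks per
population (one per acclimation temperature, 20 / 30 °C), 198 fish
distributed as evenly as possible (12–13 per tank); masses log-uniform on
50–1000 mg; fish volume = mass/1000 (neutral density).

**Metabolic law.** For trait ∈ {SMR, RMR, MMR}:

    log10 rate = log10 a(trait) + b(trait, T)·log10 M
                 + Ea(trait, history)·(1/kT − 1/kT_ref)/ln 10
                 + population + tank + ε

with T_ref = 25 °C. Anchoring the intercept at the midpoint temperature
means history-specific activation energies alone produce the crossing
pattern of interest — warm-source fish relatively *high* at 20 °C and
relatively *low* at 30 °C — without a separate offset (an explicit
`history_by_temperature_interaction` dial exists and defaults to 0).

Defaults (units as above) were set from the scales this kind of study
reports, not fitted to anything:

| parameter | default | rationale |
|---|---|---|
| a (SMR, RMR, MMR) | 0.19, 0.26, 0.42 | SMR ≈ 1.9 µg min⁻¹ at ~300 mg; RMR/SMR ≈ 1.4; FAS ≥ ~1.4 at every mass |
| b at 20 °C | 0.45, 0.46, 0.43 | shallow teleost scaling, shallowest for MMR |
| b at 30 °C | 0.35, 0.36, 0.33 | scaling flattens when warm-acclimated (mass × temperature interaction) |
| Ea ambient | −1.45, −1.33, −1.00 eV | within the reported ambient-source range |
| Ea warm | −1.10, −1.05, −0.80 eV | smaller magnitude: reduced temperature sensitivity after a warm history |
| residual ε sd | 0.07 log₁₀ | log-log r² ≈ 0.8 per group, typical respirometry scatter |
| shared fraction of ε variance | 0.85 | an individual-quality effect correlates a fish's three traits |
| population, tank sd | 0.03, 0.02 log₁₀ | modest clustering |

The trait ordering SMR ≤ RMR ≤ MMR is enforced by construction: the
deterministic surfaces never cross on the default mass range, the
trait-specific noise share is small, and a final cumulative max clamps
the rare flips (~3% of fish touch the MMR clamp at defaults).

**Behavior.** Latent emergence latency is log-normal with history-specific
location (calibrated so ≈29% of ambient-source and ≈77% of warm-source
fish emerge within the 600-s limit), a small advantage at 30 °C, and a
positive mass effect; both the latent and the right-censored observed
values are stored, so censored-regression recovery is testable. Activity
is Poisson-lognormal: log mean with negative mass effect and a
history × temperature term (warm-source less active at 20 °C), plus an
observation-level normal effect (sd 0.5) supplying the lognormal
overdispersion; counts are capped at the 300-s observation window, and
only emergers carry an activity value.

**Traces.** Sealed phases lose O₂ at (MO₂(t) + blank(t))/(V_r − V_f) per
minute; flush phases relax exponentially toward the supply concentration
(τ = 45 s, so a 5-min flush achieves complete turnover); Gaussian sensor
noise (sd 0.01 mg L⁻¹) is added to the record; sampling every 5 s.
Spontaneous activity is a marked Poisson process (2 bursts h⁻¹, 60 s,
×3 multiplier) that multiplies instantaneous consumption during SMR
runs — the model is deliberately simple: its only job is to make some
cycles "contaminated" so the lowest-decile rule has something to reject.
The background rate drifts linearly from 0.05 to 0.20 µg min⁻¹ over 20 h
(microbial growth), which the linear blank correction can remove exactly.

What the generator does *not* emulate: oxygen solubility physics,
temperature microfluctuations, chamber mixing dynamics, diel rhythms in
SMR, post-chase EPOC decay within the MMR window, repeated behavioral
trials, or any genetic structure among populations. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated signal model, not robustness to every field artifact.

## 3. Scaling and temperature sensitivity

Allometric fits are OLS on log₁₀–log₁₀ axes per history × temperature ×
trait group (`scipy.stats.linregress`; checked in tests against explicit
normal equations). Mass normalization uses the group-specific exponent by
default, since the scaling fits are per group; a pooled-exponent option
(`b_mode="global"`) exists but is biased when true exponents differ
between temperatures. E_a is the two-point slope of ln mean normalized
rate against 1/kT (natural log on the Arrhenius axis; log₁₀ only for
allometry); per-population E_a and a per-individual regression method are
available for range summaries.

**A leverage caveat worth knowing.** Normalizing by M⁻ᵇ references rates
to 1 mg, ~2.3 decades below the average fish. An error δb in the fitted
exponent therefore shifts the log mean normalized rate by ≈ δb × 5.4
(natural-log units), and the two-point E_a inherits that noise amplified
by 1/Δ(1/kT) ≈ 0.77 eV per nat. At the default residual scatter this
makes single-cohort E_a estimates noisy to ±0.1–0.2 eV even though the
estimator is exact at zero noise; the warm-vs-ambient ordering of |E_a|
is asserted in tests at reduced scatter for that reason. This is a
property of the estimator itself, not of the implementation, and is worth
remembering when interpreting small per-population E_a differences in
real data.

## 4. Trait models

- **LMMs** (metabolic traits, log₁₀ scale): statsmodels `MixedLM` with a
  random intercept for population and a variance component for tank
  (tanks nested in populations). Fits use **ML**, not REML, so
  log-likelihoods are comparable across fixed-effect structures; REML is
  available for reporting final variance components. The profiled
  variance surface can be multimodal near the zero boundary, so each fit
  races two optimizers (lbfgs, powell) and keeps the better optimum.
  Parameter count k = fixed effects + variance components (population,
  tank, residual).
- **AICc** = −2ℓ + 2k + 2k(k+1)/(n−k−1), n = observations; undefined
  (error) when n ≤ k+1. Weights w_i ∝ exp(−Δ_i/2) renormalized over the
  ΔAICc < 4 set. Averaging is conditional (each term averaged over the
  retained models containing it) by default; full averaging
  (zero-substitution shrinkage) is an option. Dropping retained models
  whose interaction terms are all non-significant is implemented only as
  an optional post-filter, off by default — it conflicts with pure
  weight-based averaging and its intent in the source protocol is
  ambiguous. p-values, where needed, come from Wald/likelihood-ratio
  reasoning rather than Satterthwaite degrees of freedom.
- **GLMMs** (boldness, activity): hand-implemented Laplace-approximated
  maximum likelihood (the approximation `glmer` uses at nAGQ = 1),
  because no installed Python library offers marginal-ML GLMMs. Inner
  loop: Newton with line search on the joint penalized log-likelihood
  over (β, u); outer loop: Nelder–Mead on log variance parameters with
  warm-started inner modes and three starts; variances below 1e−4 sd are
  reported as 0. Fixed-effect SEs come from the profiled information
  matrix. Degenerate-case tests verify collapse to plain GLM estimates
  at the zero-variance boundary; complete separation in the binomial
  model is detected (|η̂| > 15) and refitted with a small L2 penalty on
  the fixed effects, flagged as such. The Poisson-lognormal activity
  model is the Poisson GLMM plus an observation-level random intercept.
- **Censored latency (Tobit)**: Gaussian latent latency, right-censored
  at 600 s; log-likelihood Σ_obs[log φ((y−xβ)/σ) − log σ] +
  Σ_cens log Φ((xβ−600)/σ), maximized by BFGS on (β, log σ) with
  analytic gradients, OLS start, three jittered restarts; SEs from the
  numeric Hessian. With no censored rows the estimator equals Gaussian
  ML (OLS) to optimizer precision, and the likelihood is checked against
  numerical integration of the Gaussian tail on a toy dataset. Separate
  fits per acclimation temperature avoid confounding rate with
  temperature; covariates default to log₁₀ mass + log₁₀ rate, with a
  mass-residualized rate mode as the alternative.
- Sex is excluded from all default formulas (it is confounded with body
  size in this species) but present in the cohort table as an optional
  covariate.

## 5. Pipeline and reproducibility

`run_pipeline` executes simulate → extract → scale → infer → behavior,
writes every output as CSV plus a JSON manifest (seed, options, record
counts, stage timings, SHA-256 of each output, package version), and is
byte-identical under a fixed seed — all randomness derives from one root
seed via SHA-256-named substreams. `--dry-run` validates configs and
paths without computing. Stage failures raise with the stage name.

## 6. Problem sizes used in checks

Simulation-based checks run at sizes chosen to give stable verdicts with
fast feedback: the zero-noise identity uses a 24-fish cohort with a 2-h
overnight block (exactness is duration-independent); SMR recovery uses
200 replicate 18-h runs (median relative error ≈ 0.5%, comfortably inside
the 5% bound); candidate-selection consistency uses 100 replicate
198-fish cohorts (model 5 lowest-AICc fraction ≈ 0.8–0.9); GLMM
recovery examples use 8–25 seeded replicates at n = 150–198. The
negative control permutes thermal-history labels and checks that the
history coefficient loses directional consistency.

## 7. Known limitations

- Two acclimation temperatures permit only a two-point Arrhenius
  contrast; no curvature (e.g. Sharpe–Schoolfield) can be or is fitted.
- The Laplace approximation can bias GLMM variance estimates slightly
  downward for binary data with few clusters; adaptive quadrature is not
  implemented.
- "Conditional AICc" is read as the standard second-order AICc; no
  conditional-likelihood AIC is computed.
- The E_a leverage effect above means per-cohort activation energies are
  intrinsically noisy at realistic scatter; range summaries across
  populations partially reflect that noise.
- One behavioral trial per fish: repeatability/ICC of behavior is out of
  scope by design.
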
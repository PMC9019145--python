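# respiro

Thermal metabolic phenotyping of small fish from raw respirometry data:
intermittent-flow oxygen traces → standard / routine / maximum metabolic
rates → allometric scaling and Arrhenius temperature sensitivity →
mixed-model inference on thermal-history and acclimation effects on
metabolism and behavior.

The package targets the common-garden design used to study rapid thermal
adaptation in *Gambusia affinis* (mosquitofish): eight source populations —
four from geothermally warmed waters, four from ambient waters — acclimated
for months at 20 or 30 °C, then phenotyped for metabolism (SMR, RMR, MMR)
and behavior (boldness as refuge-emergence latency, activity as time spent
moving). Because the archived field data are not required to exercise the
code, a first-class synthetic-data generator reproduces the whole
measurement chain with known ground truth, so every stage is testable by
parameter recovery.

## The core quantities

**Oxygen uptake.** Within each sealed measurement window the O₂
concentration declines linearly; an OLS slope ΔC<sub>wO₂</sub>/Δt (mg L⁻¹
min⁻¹) gives

&nbsp;&nbsp;&nbsp;&nbsp;MO₂ = (V_r − V_f) × |ΔC<sub>wO₂</sub>/Δt|  [µg O₂ min⁻¹]

with V_r the respirometer volume and V_f the fish volume (ml). Background
microbial respiration, measured in fishless blanks before and after each
trial, is subtracted assuming a linear increase in time.

**SMR** is the mean of the lowest 10% of overnight cycle MO₂ values after
excluding outliers beyond ±2 SD of the mean; **aerobic scope** = MMR − SMR
and **factorial aerobic scope** = MMR / SMR.

**Allometry.** Per thermal-history × acclimation-temperature group,
log₁₀ MO₂ = log₁₀ a + b·log₁₀ M (M in mg) by least squares.

**Temperature sensitivity.** The activation energy E_a is the slope of
ln(MO₂ · M⁻ᵇ) against 1/kT (k = 8.62 × 10⁻⁵ eV K⁻¹, T in Kelvin), a
two-point Arrhenius contrast across the 20 and 30 °C acclimation groups.
Because 1/kT falls as T rises, rates that increase with temperature give
E_a < 0 under this convention.

**Inference.** Seven candidate linear mixed models over {log₁₀ mass,
thermal history, acclimation temperature} (model 7 = mass-only null), with
random intercepts for population and tank, are ranked by AICc and averaged
over the ΔAICc < 4 set with Akaike weights. Behavior uses a mixed-effects
binomial logistic model (emergence), a Poisson-lognormal GLMM with an
observation-level random effect (activity seconds), and right-censored
(Tobit) regression of latency on mass plus one metabolic rate, fitted
separately per acclimation temperature (censoring limit 600 s).

## Worked example

```python
from respiro import (CohortConfig, TraceConfig, generate_cohort,
                     simulate_experiment, extract_metabolic_rates,
                     activation_energies, select_trait_model,
                     prepare_trait_table)

cfg = CohortConfig(n_fish_per_tank=6, seed=42)   # 8 populations x 2 tanks x 6 fish
cohort, truth = generate_cohort(cfg)
traces = simulate_experiment(cohort, truth, TraceConfig(smr_duration_h=6.0), seed=42)
metab = extract_metabolic_rates(traces, cohort[["fish_id", "fish_volume_ml"]])
table = prepare_trait_table(metab, cohort)

print(metab[["fish_id", "smr", "rmr", "mmr", "factorial_scope"]].head(3).round(3))
ea = activation_energies(table, level="history")
print(ea[ea.trait == "smr"][["group", "ea_ev"]].round(3))
sel, _ = select_trait_model(table, "log10_smr")
print(sel.table[["model_id", "aicc", "delta_aicc", "weight"]].head(3).round(3))
```

prints

```
fish_id   smr   rmr   mmr  factorial_scope
fish001 1.192 1.759 3.185            2.673
fish002 0.657 1.071 1.851            2.819
fish003 1.150 1.764 3.175            2.761

  group  ea_ev
ambient  -1.57
   warm  -0.62

 model_id     aicc  delta_aicc  weight
        5 -211.269       0.000   0.463
        4 -211.086       0.183   0.423
        2 -208.463       2.806   0.114
```

Per-fish rates are in µg O₂ min⁻¹; the factorial scope near 2.7 says each
fish could roughly triple its resting oxygen use. The warm-source
activation energy is smaller in magnitude than the ambient-source one —
the generated cohorts encode exactly that reduced temperature sensitivity
— and the best-ranked candidate (model 5) is the one containing the
history × temperature and mass × temperature interactions the generator
uses. (At 96 fish the two-point E_a is noisy; the recovery tests quantify
this.)

The same chain is available from the shell:

```bash
respiro simulate --out run/ --seed 42
respiro extract --traces run/traces.csv --meta run/cohort.csv --out run/metab.csv
respiro infer --table run/trait_table.csv --trait smr
respiro run-all --out run_all/ --seed 42
```

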
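"""Simulation-based self-checks: parameter-recovery experiments.

These drive the whole chain on synthetic data with known truth and report
recovery errors — used by the test suite and the reproduction script, and
useful for sanity-checking configuration changes.
"""

from __future__ import annotations

import warnings

import numpy as np

from .cohort import CohortConfig, generate_cohort
from .traces import TraceConfig, generate_trace
from .respirometry import (
    BlankSeries,
    blank_correct,
    compute_mo2,
    extract_metabolic_rates,
    extract_smr,
    measurement_cycles,
)
from .scaling import activation_energies, group_scaling
from .lmm import prepare_trait_table, select_trait_model
from .traces import simulate_experiment


def smr_extraction_error(
    n_runs: int = 200,
    seed: int = 0,
    true_smr: float = 1.9,
    fish_volume_ml: float = 0.5,
    config: TraceConfig | None = None,
) -> dict:
    """Relative error of extracted SMR over replicate overnight runs.

    Each run simulates a full ~18-h intermittent-flow trace with activity
    bursts and sensor noise at the default levels, plus bracketing blanks,
    then runs the slope → MO2 → blank-correction → lowest-decile chain.
    Returns the median and maximum relative error across runs.
    """
    config = config or TraceConfig()
    errors = []
    for i in range(n_runs):
        rng = np.random.default_rng((seed, i))
        fish = {"fish_id": "f", "fish_volume_ml": fish_volume_ml, "true_smr": true_smr}
        tr = generate_trace(fish, "smr", config, rng=rng)
        t_end = float(tr["t_s"].iloc[-1])
        blank = {"fish_id": "b", "fish_volume_ml": 0.0}
        pre = generate_trace(blank, "blank", config, t0_s=0.0, rng=rng)
        post = generate_trace(blank, "blank", config, t0_s=t_end, rng=rng)

        def rate_of(btr):
            c = measurement_cycles(btr)[0]
            return c.t_mid, compute_mo2(c.slope_mgL_per_min, config.chamber_volume_ml)

        (tp, rp), (to, ro) = rate_of(pre), rate_of(post)
        blanks = BlankSeries(pre_time_s=tp, pre_rate=rp, post_time_s=to, post_rate=ro)
        cycles = measurement_cycles(tr, trim_leading_s=30.0)
        mo2 = [
            blank_correct(
                compute_mo2(c.slope_mgL_per_min, config.chamber_volume_ml, fish_volume_ml),
                c.t_mid,
                blanks,
            )
            for c in cycles
        ]
        smr, _ = extract_smr(mo2)
        errors.append(abs(smr / true_smr - 1.0))
    errors = np.asarray(errors)
    return {
        "median_relative_error": float(np.median(errors)),
        "max_relative_error": float(errors.max()),
        "n_runs": n_runs,
    }


def end_to_end_identity(seed: int = 1) -> dict:
    """Zero-noise cohort through traces, extraction, scaling and Arrhenius:
    worst-case absolute errors of recovered MO2 (relative), b and Ea."""
    cfg = CohortConfig(
        n_populations=4,
        histories=("ambient", "ambient", "warm", "warm"),
        n_fish_per_tank=3,
        trait_noise_sd=0.0,
        population_sd=0.0,
        tank_sd=0.0,
        seed=seed,
    )
    cohort, truth = generate_cohort(cfg)
    tcfg = TraceConfig(
        sensor_noise_sd=0.0, activity_burst_rate_per_h=0.0, smr_duration_h=2.0
    )
    traces = simulate_experiment(cohort, truth, tcfg, seed=seed)
    metab = extract_metabolic_rates(traces, cohort[["fish_id", "fish_volume_ml"]])
    merged = metab.merge(truth, on="fish_id")
    mo2_err = max(
        float(np.abs(merged[t] / merged[f"true_{t}"] - 1.0).max())
        for t in ("smr", "rmr", "mmr")
    )
    table = prepare_trait_table(metab, cohort)
    sc = group_scaling(table)
    b_err = max(
        abs(r.exponent_b - cfg.exponent_b(r.trait, r.acclimation_temp_c))
        for r in sc.itertuples()
    )
    ea = activation_energies(table, level="history")
    ea_err = max(abs(r.ea_ev - cfg.ea(r.trait, r.history)) for r in ea.itertuples())
    return {
        "mo2_max_relative_error": mo2_err,
        "b_max_abs_error": float(b_err),
        "ea_max_abs_error_ev": float(ea_err),
    }


def model5_win_fraction(
    n_cohorts: int = 100, seed: int = 0, response: str = "log10_smr"
) -> dict:
    """Fraction of replicate default cohorts (crossing history × temperature
    pattern) in which candidate model 5 attains the lowest AICc."""
    wins = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_cohorts):
            sub_seed = int(np.random.default_rng((seed, i)).integers(2**31))
            cohort, truth = generate_cohort(CohortConfig(seed=sub_seed))
            df = cohort.merge(truth, on="fish_id")
            df["log10_mass"] = np.log10(df["mass_mg"])
            trait = response.removeprefix("log10_")
            df[response] = np.log10(df[f"true_{trait}"])
            result, _ = select_trait_model(df, response)
            wins += result.best_model_id == 5
    return {"win_fraction": wins / n_cohorts, "n_cohorts": n_cohorts}
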
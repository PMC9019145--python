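"""Mixed-model fits and candidate selection for metabolic traits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from respiro.cohort import CohortConfig, generate_cohort
from respiro.lmm import fit_candidates, fit_lmm, select_trait_model
from respiro.selection import candidate_formula


def _flat_cohort(seed=0):
    """Cohort with zero between-population/tank variance."""
    cfg = CohortConfig(population_sd=0.0, tank_sd=0.0, seed=seed)
    cohort, truth = generate_cohort(cfg)
    df = cohort.merge(truth, on="fish_id")
    df["log10_mass"] = np.log10(df["mass_mg"])
    df["log10_smr"] = np.log10(df["true_smr"])
    return cfg, df


def test_degenerate_random_effects_match_ols():
    _, df = _flat_cohort(seed=2)
    formula = candidate_formula(5, "log10_smr")
    lmm = fit_lmm(df, formula)
    # this replicate puts both variance components on the zero boundary;
    # the mixed fit must then reproduce plain least squares
    assert lmm.variance_components["population"] == pytest.approx(0.0, abs=1e-8)
    assert lmm.variance_components["tank"] == pytest.approx(0.0, abs=1e-8)
    ols = smf.ols(formula, df).fit()
    assert np.allclose(lmm.params[ols.params.index], ols.params, atol=1e-6)


def test_interaction_estimate_recovers_truth_within_2_se():
    cfg, df = _flat_cohort(seed=4)
    fit = fit_lmm(df, candidate_formula(5, "log10_smr"))
    term = "history[T.warm]:C(acclimation_temp_c)[T.30.0]"
    # implied interaction on log10 rate: history-specific Ea difference
    # evaluated at each temperature (intercepts aligned at 25 degrees C)
    from respiro.cohort import TRAITS  # noqa: F401
    d20 = cfg.true_log10_rate("smr", 1.0, 20.0, "warm") - cfg.true_log10_rate(
        "smr", 1.0, 20.0, "ambient"
    )
    d30 = cfg.true_log10_rate("smr", 1.0, 30.0, "warm") - cfg.true_log10_rate(
        "smr", 1.0, 30.0, "ambient"
    )
    truth = d30 - d20
    assert fit.params[term] == pytest.approx(truth, abs=2 * fit.bse[term])


def test_row_permutation_invariance():
    _, df = _flat_cohort(seed=5)
    fit1 = fit_lmm(df, candidate_formula(1, "log10_smr"))
    rng = np.random.default_rng(0)
    fit2 = fit_lmm(df.sample(frac=1.0, random_state=1), candidate_formula(1, "log10_smr"))
    assert np.allclose(fit1.params, fit2.params[fit1.params.index], atol=1e-6)


def test_single_level_grouping_dropped_with_warning():
    _, df = _flat_cohort(seed=6)
    df["population"] = "only_one"
    df["tank"] = "only_tank"
    with pytest.warns(UserWarning, match="random term dropped"):
        fit = fit_lmm(df, candidate_formula(7, "log10_smr"))
    assert fit.variance_components.keys() == {"residual"}


def test_candidate_parameter_counts_increase_with_terms():
    _, df = _flat_cohort(seed=7)
    fits = {f.model_id: f for f in fit_candidates(df, "log10_smr")}
    assert len(fits) == 7
    # null model: intercept + mass + 3 variance components
    assert fits[7].k == 2 + 3
    # full three-way factorial: 8 fixed effects + 3 variance components
    assert fits[2].k == 8 + 3
    assert all(f.n == len(df) for f in fits.values())


def test_model5_wins_on_crossing_interaction_cohort(trait_table):
    result, _ = select_trait_model(trait_table, "log10_smr")
    assert result.best_model_id == 5
    assert result.table["weight"].sum() == pytest.approx(1.0)


def test_permuted_population_labels_break_history_sign_consistency():
    """Negative control: shuffling fish across populations (and hence
    thermal histories) destroys the warm/ambient contrast, so the sign of
    the history main effect becomes unstable across replicates."""
    signs = []
    term = "history[T.warm]"
    for seed in range(30):
        cohort, truth = generate_cohort(CohortConfig(seed=100 + seed))
        df = cohort.merge(truth, on="fish_id")
        rng = np.random.default_rng(seed)
        df["history"] = rng.permutation(df["history"].to_numpy())
        df["log10_mass"] = np.log10(df["mass_mg"])
        df["log10_smr"] = np.log10(df["true_smr"])
        fit = fit_lmm(df, candidate_formula(1, "log10_smr"))
        signs.append(np.sign(fit.params[term]))
    agreement = max(np.mean(np.array(signs) > 0), np.mean(np.array(signs) < 0))
    assert agreement <= 0.8  # no stable direction under the null
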
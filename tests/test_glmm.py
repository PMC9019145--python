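"""Laplace-ML GLMMs: degenerate-case oracles, parameter recovery, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from respiro.cohort import CohortConfig, generate_cohort
from respiro.glmm import MixedGLMM, fit_activity_pln, fit_boldness_binomial


def _design(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    X = pd.DataFrame({"Intercept": np.ones(n), "x": x})
    pop = rng.integers(0, 8, n)
    tank = pop * 2 + rng.integers(0, 2, n)
    return rng, x, X, {"pop": pop, "tank": tank}


class TestBinomial:
    def test_zero_group_variance_matches_plain_logistic(self):
        rng, x, X, groups = _design(300, 2)
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-(-0.3 + 0.8 * x))))
        m = MixedGLMM(family="binomial").fit(X, y, groups)
        # this replicate estimates both variance components at the zero
        # boundary, so the GLMM must collapse to the plain GLM
        assert all(s == 0.0 for s in m.sigmas_.values())
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.abs(m.params_.to_numpy() - glm.params.to_numpy()).max() < 1e-3

    def test_all_emerge_flags_separation(self):
        _, x, X, groups = _design(80, 2)
        y = np.ones(80)
        with pytest.warns(UserWarning, match="separation"):
            m = MixedGLMM(family="binomial", n_starts=1).fit(X, y, groups)
        assert m.separation_

    def test_history_effect_sign_recovered_across_sims(self):
        """Warm-source fish are generated with higher emergence probability;
        the fitted history log-odds should be positive in nearly all
        replicate cohorts (scaled-down replicate count)."""
        hits = 0
        n_sims = 12
        for seed in range(n_sims):
            cohort, _ = generate_cohort(CohortConfig(seed=300 + seed))
            fit = fit_boldness_binomial(cohort, n_starts=1)
            hits += fit.params_["history[T.warm]"] > 0
        assert hits >= int(0.95 * n_sims)

    def test_non_binary_response_rejected(self):
        _, _, X, groups = _design(20, 3)
        with pytest.raises(ValueError, match="0/1"):
            MixedGLMM(family="binomial").fit(X, np.full(20, 2.0), groups)


class TestPoissonLognormal:
    def test_zero_variance_matches_plain_poisson(self):
        rng, x, X, groups = _design(250, 4)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        m = MixedGLMM(family="poisson").fit(X, y, groups)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.abs(m.params_.to_numpy() - glm.params.to_numpy()).max() < 1e-3

    def test_overdispersion_variance_recovered(self):
        """Observation-level variance sigma^2 = 0.5 recovered at n = 150
        (median over a scaled-down replicate set)."""
        est = []
        for seed in range(8):
            rng, x, X, groups = _design(150, 40 + seed)
            eta = 2.0 + 0.3 * x + rng.normal(0, np.sqrt(0.5), 150)
            y = rng.poisson(np.exp(eta))
            m = MixedGLMM(family="poisson", olre=True, n_starts=1).fit(X, y, groups)
            est.append(m.sigmas_["olre"] ** 2)
        assert abs(float(np.median(est)) - 0.5) < 0.15

    def test_constant_response_flat_model(self):
        _, _, X, groups = _design(120, 5)
        y = np.full(120, 7.0)
        m = MixedGLMM(family="poisson", olre=True, n_starts=1).fit(
            X[["Intercept"]], y, groups
        )
        assert m.params_["Intercept"] == pytest.approx(np.log(7.0), abs=0.02)
        assert all(s < 0.05 for s in m.sigmas_.values())

    def test_activity_wrapper_excludes_non_emergers(self, trait_table):
        fit = fit_activity_pln(trait_table, n_starts=1)
        assert fit.n_ == int(trait_table["emerged"].sum())
        assert "olre" in fit.sigmas_

    def test_activity_beyond_window_rejected(self, trait_table):
        bad = trait_table.copy()
        bad.loc[bad.index[bad["emerged"]][0], "activity_s"] = 400.0
        with pytest.raises(ValueError, match="window"):
            fit_activity_pln(bad)

    def test_mass_effect_sign(self, trait_table):
        # generator: smaller fish are more active
        fit = fit_activity_pln(trait_table, n_starts=1)
        assert fit.params_["log10_mass"] < 0
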
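"""Linear mixed models for metabolic traits.

Each candidate model regresses a (log10-scale by default) metabolic trait on
fixed effects drawn from {log10 mass, thermal history, acclimation
temperature} with random intercepts for source population and for holding
tank (tanks are nested in populations). Fits use maximum likelihood, not
REML, so log-likelihoods are comparable across fixed-effect structures for
AICc ranking; refit with ``reml=True`` to report final variance components.
Backed by :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .selection import (
    ModelSelectionResult,
    candidate_formula,
    CANDIDATE_MODELS,
    rank_and_average,
)


@dataclass
class LMMFit:
    """One fitted mixed model, reduced to what ranking and averaging need."""

    model_id: int
    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    k: int  # fixed effects + variance components (incl. residual)
    n: int
    converged: bool
    variance_components: dict[str, float]


def fit_lmm(
    data: pd.DataFrame,
    formula: str,
    population: str = "population",
    tank: str = "tank",
    reml: bool = False,
    model_id: int = 0,
) -> LMMFit:
    """Fit one LMM with nested random intercepts (population, tank).

    A grouping factor with a single level cannot support a random intercept
    and is dropped with a warning. Returns an :class:`LMMFit` whose ``k``
    counts fixed effects plus estimated variance components plus the
    residual variance, as needed for AICc.
    """
    data = data.copy()
    n_pop = data[population].nunique()
    n_tank = data[tank].nunique()
    use_pop = n_pop > 1
    use_tank = n_tank > n_pop  # tanks nested: >1 tank within populations
    if not use_pop:
        warnings.warn(
            f"grouping factor '{population}' has a single level; random term dropped"
        )
    if not use_tank:
        warnings.warn(
            f"grouping factor '{tank}' adds no levels beyond '{population}'; "
            "random term dropped"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # singular RE covariance at boundary
        if use_pop:
            vc = {"tank": f"0 + C({tank})"} if use_tank else None
            model = smf.mixedlm(
                formula, data, groups=population, re_formula="1", vc_formula=vc
            )
            # the profiled-variance surface is multimodal near the zero
            # boundary; race two optimizers and keep the better optimum
            result = None
            for method in ("lbfgs", "powell"):
                try:
                    cand = model.fit(reml=reml, method=method)
                except Exception:
                    continue
                if result is None or cand.llf > result.llf:
                    result = cand
            if result is None:
                result = model.fit(reml=reml, method="cg")
            k_var = 1 + (1 if use_tank else 0) + 1  # pop (+tank) + residual
            vcomp = {"population": float(result.cov_re.iloc[0, 0])}
            if use_tank:
                vcomp["tank"] = float(result.vcomp[0])
            vcomp["residual"] = float(result.scale)
            fe = result.fe_params
            loglik = float(result.llf)
            bse = result.bse_fe
            pvalues = result.pvalues[fe.index]
            converged = bool(result.converged)
        else:
            # no usable grouping: plain OLS (ML) fit
            result = smf.ols(formula, data).fit()
            k_var = 1
            vcomp = {"residual": float(result.scale)}
            fe = result.params
            loglik = float(result.llf)
            bse = result.bse
            pvalues = result.pvalues
            converged = True

    return LMMFit(
        model_id=model_id,
        formula=formula,
        params=fe,
        bse=pd.Series(bse, index=fe.index),
        pvalues=pd.Series(pvalues, index=fe.index),
        loglik=loglik,
        k=len(fe) + k_var,
        n=int(len(data)),
        converged=converged,
        variance_components=vcomp,
    )


def prepare_trait_table(
    metab: pd.DataFrame, cohort: pd.DataFrame, traits=("smr", "rmr", "mmr", "aerobic_scope")
) -> pd.DataFrame:
    """Merge per-fish metabolic estimates with cohort covariates and add the
    log10 analysis columns used by the candidate formulas."""
    df = cohort.merge(metab, on="fish_id")
    df["log10_mass"] = np.log10(df["mass_mg"])
    for t in traits:
        if t in df.columns:
            vals = df[t].to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                df[f"log10_{t}"] = np.where(vals > 0, np.log10(vals), np.nan)
    return df


def fit_candidates(
    data: pd.DataFrame,
    response: str,
    mass: str = "log10_mass",
    history: str = "history",
    temp: str = "C(acclimation_temp_c)",
    population: str = "population",
    tank: str = "tank",
    reml: bool = False,
) -> list[LMMFit]:
    """Fit all seven candidate fixed-effect structures for one response."""
    sub = data.dropna(subset=[response])
    fits = []
    for mid in CANDIDATE_MODELS:
        f = candidate_formula(mid, response, mass=mass, history=history, temp=temp)
        fits.append(
            fit_lmm(sub, f, population=population, tank=tank, reml=reml, model_id=mid)
        )
    return fits


def select_trait_model(
    data: pd.DataFrame,
    response: str,
    delta_threshold: float = 4.0,
    averaging: str = "conditional",
    screen_nonsignificant_interactions: bool = False,
    **kwargs,
) -> tuple[ModelSelectionResult, list[LMMFit]]:
    """Candidate fits + AICc ranking and averaging for one trait."""
    fits = fit_candidates(data, response, **kwargs)
    result = rank_and_average(
        [
            {
                "model_id": f.model_id,
                "loglik": f.loglik,
                "k": f.k,
                "n": f.n,
                "params": f.params,
                "pvalues": f.pvalues,
            }
            for f in fits
        ],
        delta_threshold=delta_threshold,
        averaging=averaging,
        screen_nonsignificant_interactions=screen_nonsignificant_interactions,
    )
    return result, fits
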
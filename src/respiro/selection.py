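"""Candidate model set, small-sample AIC (AICc), Akaike weights and model
averaging.

Seven fixed-effect structures over {body mass, thermal history, acclimation
temperature} are compared for each trait; every candidate carries random
intercepts for source population and holding tank. Model 7 is the null
(mass-only) model. Models are ranked by AICc; those within a ΔAICc
threshold (default 4) are averaged with Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed-effect right-hand sides of the seven candidates, in terms of the
#: analysis variables ``mass`` (log10 mass by default), ``history`` and
#: ``temp`` (acclimation temperature, categorical).
CANDIDATE_MODELS: dict[int, str] = {
    1: "{mass} + {history} + {temp}",
    2: "{mass} * {history} * {temp}",
    3: "{mass} * {history} + {temp}",
    4: "{mass} + {history} * {temp}",
    5: "{mass} + {history} + {temp} + {history}:{temp} + {mass}:{temp}",
    6: "{mass} + {history} + {temp} + {mass}:{temp} + {history}:{mass}",
    7: "{mass}",  # null: mass + intercept only
}


def candidate_formula(
    model_id: int,
    response: str,
    mass: str = "log10_mass",
    history: str = "history",
    temp: str = "C(acclimation_temp_c)",
) -> str:
    """Patsy formula for one candidate model."""
    if model_id not in CANDIDATE_MODELS:
        raise ValueError(f"model_id must be 1..7, got {model_id}")
    rhs = CANDIDATE_MODELS[model_id].format(mass=mass, history=history, temp=temp)
    return f"{response} ~ {rhs}"


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike Information Criterion.

    AIC = −2·loglik + 2k, plus the small-sample correction 2k(k+1)/(n−k−1).
    ``k`` counts all estimated parameters including variance components;
    ``n`` is the number of observations.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """ΔAICc and normalized Akaike weights (shift-invariant in loglik)."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


@dataclass
class ModelSelectionResult:
    """Ranked candidate table plus model-averaged coefficients."""

    table: pd.DataFrame  # model_id, k, loglik, aicc, delta_aicc, weight, retained
    averaged_coefficients: pd.Series
    averaging: str = "conditional"
    delta_threshold: float = 4.0
    best_model_id: int = field(default=0)


def rank_and_average(
    fits: list[dict],
    delta_threshold: float = 4.0,
    averaging: str = "conditional",
    screen_nonsignificant_interactions: bool = False,
    alpha: float = 0.05,
) -> ModelSelectionResult:
    """Rank candidate fits by AICc and average the retained set.

    Each fit dict needs ``model_id``, ``loglik``, ``k``, ``n`` and a
    ``params`` Series (optionally ``pvalues``). Weights are renormalized
    over the models with ΔAICc below ``delta_threshold``. ``averaging``:

    - ``'conditional'`` (natural): each coefficient averaged over the
      retained models that contain it, weights renormalized per term;
    - ``'full'``: models lacking a term contribute zero (shrinkage).

    ``screen_nonsignificant_interactions`` optionally drops retained models
    whose interaction terms are all non-significant at ``alpha`` before
    averaging (off by default; it conflicts with pure weight-based
    averaging and is provided as a post-filter only).
    """
    if averaging not in ("conditional", "full"):
        raise ValueError("averaging must be 'conditional' or 'full'")
    if not fits:
        raise ValueError("no candidate fits supplied")
    tab = pd.DataFrame(
        {
            "model_id": [f["model_id"] for f in fits],
            "k": [f["k"] for f in fits],
            "loglik": [f["loglik"] for f in fits],
            "n": [f["n"] for f in fits],
        }
    )
    tab["aicc"] = [aicc(ll, k, n) for ll, k, n in zip(tab.loglik, tab.k, tab.n)]
    delta, _ = akaike_weights(tab["aicc"])
    tab["delta_aicc"] = delta
    tab["retained"] = tab["delta_aicc"] < delta_threshold

    if screen_nonsignificant_interactions:
        for i, f in enumerate(fits):
            if not tab.loc[i, "retained"]:
                continue
            pv = f.get("pvalues")
            inter = [t for t in f["params"].index if ":" in t]
            if pv is not None and inter and all(pv.get(t, 1.0) >= alpha for t in inter):
                tab.loc[i, "retained"] = False
        if not tab["retained"].any():  # never empty the set entirely
            tab.loc[tab["delta_aicc"].idxmin(), "retained"] = True

    kept = tab.index[tab["retained"]]
    _, w_kept = akaike_weights(tab.loc[kept, "aicc"])
    tab["weight"] = 0.0
    tab.loc[kept, "weight"] = w_kept

    terms: list[str] = []
    for i in kept:
        for t in fits[i]["params"].index:
            if t not in terms:
                terms.append(t)
    avg = {}
    for t in terms:
        num = denom = 0.0
        for i in kept:
            w = tab.loc[i, "weight"]
            p = fits[i]["params"]
            if t in p.index:
                num += w * p[t]
                denom += w
            elif averaging == "full":
                denom += w  # zero contribution
        avg[t] = num / denom if denom > 0 else np.nan

    tab = tab.sort_values("delta_aicc").reset_index(drop=True)
    return ModelSelectionResult(
        table=tab[["model_id", "k", "n", "loglik", "aicc", "delta_aicc", "weight", "retained"]],
        averaged_coefficients=pd.Series(avg),
        averaging=averaging,
        delta_threshold=delta_threshold,
        best_model_id=int(tab.loc[0, "model_id"]),
    )
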
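"""Allometric scaling and Arrhenius temperature sensitivity of metabolism.

Allometric exponents b come from least-squares regression of log10 metabolic
rate (µg O2 min^-1) on log10 body mass (mg), fitted separately per thermal
history × acclimation temperature group. Temperature sensitivity is the
activation energy Ea: the slope of ln mass-normalized rate (MO2 × M^-b)
against inverse thermal energy 1/kT (k = 8.62e-5 eV K^-1, T in Kelvin).
With two acclimation temperatures Ea is the two-point slope; because 1/kT
*decreases* with temperature, rates that rise with temperature give a
negative Ea under this sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import BOLTZMANN_EV, CELSIUS_OFFSET

TRAITS = ("smr", "rmr", "mmr")


class AllometricScaling(BaseEstimator, RegressorMixin):
    """Log10–log10 least-squares fit of metabolic rate against body mass.

    Parameters
    ----------
    base : float
        Logarithm base for both axes (10 by convention for allometry).

    Attributes (after ``fit``)
    --------------------------
    exponent_b_ : float
        Allometric scaling exponent (regression slope).
    intercept_ : float
        Intercept on the log10 scale, i.e. log10 of the rate at 1 mg.
    se_b_ : float
        Standard error of the slope.
    r_squared_ : float
    n_ : int
    """

    def __init__(self, base: float = 10.0):
        self.base = base

    def fit(self, mass: np.ndarray, mo2: np.ndarray) -> "AllometricScaling":
        mass = np.asarray(mass, dtype=float).ravel()
        mo2 = np.asarray(mo2, dtype=float).ravel()
        if mass.shape != mo2.shape:
            raise ValueError("mass and mo2 must have equal length")
        bad = np.flatnonzero(~((mass > 0) & (mo2 > 0) & np.isfinite(mass) & np.isfinite(mo2)))
        if bad.size:
            raise ValueError(
                f"mass and rate must be positive and finite; offending rows: {bad.tolist()}"
            )
        if mass.size < 3:
            raise ValueError("allometric fit needs n >= 3")
        lx = np.log(mass) / np.log(self.base)
        ly = np.log(mo2) / np.log(self.base)
        if np.ptp(lx) == 0:
            raise ValueError("degenerate fit: all masses identical")
        res = stats.linregress(lx, ly)
        self.exponent_b_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.se_b_ = float(res.stderr)
        self.r_squared_ = float(res.rvalue**2)
        self.n_ = int(mass.size)
        return self

    def predict(self, mass: np.ndarray) -> np.ndarray:
        mass = np.asarray(mass, dtype=float)
        return self.base ** (
            self.intercept_ + self.exponent_b_ * np.log(mass) / np.log(self.base)
        )


@dataclass
class GroupScaling:
    """Allometric fit for one history × acclimation × trait group."""

    history: str
    acclimation_temp_c: float
    trait: str
    intercept_log10_a: float
    exponent_b: float
    se_b: float
    r_squared: float
    n: int


@dataclass
class ActivationEnergy:
    """Two-point Arrhenius slope for one trait within one grouping level."""

    trait: str
    group: str  # thermal history or population label
    ea_ev: float
    rate_low_t: float  # mean mass-normalized rate at the cooler temperature
    rate_high_t: float
    temps_c: tuple[float, float] = (20.0, 30.0)


def fit_allometry(
    mass_mg, mo2, history: str = "", acclimation_temp_c: float = np.nan, trait: str = ""
) -> GroupScaling:
    """Thin wrapper over :class:`AllometricScaling` returning a record."""
    est = AllometricScaling().fit(mass_mg, mo2)
    return GroupScaling(
        history=history,
        acclimation_temp_c=acclimation_temp_c,
        trait=trait,
        intercept_log10_a=est.intercept_,
        exponent_b=est.exponent_b_,
        se_b=est.se_b_,
        r_squared=est.r_squared_,
        n=est.n_,
    )


def mass_normalize(mo2, mass_mg, b: float):
    """Mass-normalized rate MO2 × M^-b (µg O2 min^-1 mg^-b)."""
    return np.asarray(mo2, dtype=float) * np.asarray(mass_mg, dtype=float) ** (-b)


def fit_activation_energy(
    group_means: dict[float, float], group: str = "", trait: str = ""
) -> ActivationEnergy:
    """Activation energy from mean mass-normalized rates at exactly two
    temperatures.

    ``group_means`` maps temperature in °C to the mean normalized rate.
    Ea = [ln R2 − ln R1] / (1/kT2 − 1/kT1) with temperatures in Kelvin; the
    sign is not flipped, so rates increasing with temperature yield Ea < 0.
    """
    if len(group_means) != 2:
        raise ValueError(f"exactly two temperatures required, got {len(group_means)}")
    (t1, r1), (t2, r2) = sorted(group_means.items())
    if r1 <= 0 or r2 <= 0:
        raise ValueError("mean normalized rates must be positive")
    x1 = 1.0 / (BOLTZMANN_EV * (t1 + CELSIUS_OFFSET))
    x2 = 1.0 / (BOLTZMANN_EV * (t2 + CELSIUS_OFFSET))
    ea = (np.log(r2) - np.log(r1)) / (x2 - x1)
    return ActivationEnergy(
        trait=trait,
        group=group,
        ea_ev=float(ea),
        rate_low_t=float(r1),
        rate_high_t=float(r2),
        temps_c=(float(t1), float(t2)),
    )


# --------------------------------------------------------------------------
# cohort-level drivers


def group_scaling(
    data: pd.DataFrame, traits: tuple[str, ...] = TRAITS
) -> pd.DataFrame:
    """Per history × acclimation-temperature allometric fits for each trait.

    ``data`` is the merged per-fish table with columns ``mass_mg``,
    ``history``, ``acclimation_temp_c`` and one column per trait.
    """
    rows = []
    for (hist, temp), sub in data.groupby(["history", "acclimation_temp_c"], sort=True):
        for trait in traits:
            g = fit_allometry(
                sub["mass_mg"], sub[trait], history=hist,
                acclimation_temp_c=float(temp), trait=trait,
            )
            rows.append(vars(g))
    return pd.DataFrame(rows)


def activation_energies(
    data: pd.DataFrame,
    traits: tuple[str, ...] = TRAITS,
    level: str = "history",
    b_mode: str = "per_group",
    method: str = "group_means",
    scaling: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-point activation energies of mass-normalized rates.

    ``level`` sets the grouping for the Arrhenius contrast: ``'history'``
    (one Ea per thermal history per trait) or ``'population'`` (one per
    source population, useful for range summaries). ``b_mode`` chooses the
    exponent used in M^-b: ``'per_group'`` uses each history × temperature ×
    trait fit (the default, matching group-specific scaling), ``'global'``
    one pooled exponent per trait. ``method='group_means'`` (default) takes
    the two-point slope through group mean normalized rates;
    ``'individual'`` regresses ln normalized rate on 1/kT across individual
    fish within the group.
    """
    if level not in ("history", "population"):
        raise ValueError("level must be 'history' or 'population'")
    if method not in ("group_means", "individual"):
        raise ValueError("method must be 'group_means' or 'individual'")
    if scaling is None:
        scaling = group_scaling(data, traits)
    rows = []
    for group_label, sub in data.groupby(
        "history" if level == "history" else "population", sort=True
    ):
        hist = sub["history"].iloc[0]
        for trait in traits:
            means: dict[float, float] = {}
            per_fish_x: list[np.ndarray] = []
            per_fish_lnr: list[np.ndarray] = []
            for temp, tsub in sub.groupby("acclimation_temp_c"):
                if b_mode == "per_group":
                    sel = scaling[
                        (scaling["history"] == hist)
                        & (scaling["acclimation_temp_c"] == float(temp))
                        & (scaling["trait"] == trait)
                    ]
                    if sel.empty:
                        raise ValueError(
                            f"no scaling fit for group ({hist}, {temp}, {trait})"
                        )
                    b = float(sel["exponent_b"].iloc[0])
                elif b_mode == "global":
                    b = AllometricScaling().fit(data["mass_mg"], data[trait]).exponent_b_
                else:
                    raise ValueError("b_mode must be 'per_group' or 'global'")
                norm = mass_normalize(tsub[trait], tsub["mass_mg"], b)
                means[float(temp)] = float(np.mean(norm))
                x = 1.0 / (BOLTZMANN_EV * (float(temp) + CELSIUS_OFFSET))
                per_fish_x.append(np.full(len(norm), x))
                per_fish_lnr.append(np.log(norm))
            ea = fit_activation_energy(means, group=str(group_label), trait=trait)
            if method == "individual":
                res = stats.linregress(
                    np.concatenate(per_fish_x), np.concatenate(per_fish_lnr)
                )
                ea.ea_ev = float(res.slope)
            rows.append(
                {
                    "level": level,
                    "group": str(group_label),
                    "history": hist,
                    "trait": trait,
                    "ea_ev": ea.ea_ev,
                    "rate_low_t": ea.rate_low_t,
                    "rate_high_t": ea.rate_high_t,
                }
            )
    return pd.DataFrame(rows)
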
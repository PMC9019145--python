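"""Minimal figure helpers: log-log allometry scatter and Arrhenius plot."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .constants import BOLTZMANN_EV, CELSIUS_OFFSET  # noqa: E402


def loglog_scatter(data, trait="smr", ax=None):
    """log10 metabolic rate vs log10 mass, grouped by history × temperature,
    with per-group least-squares lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for (hist, temp), sub in data.groupby(["history", "acclimation_temp_c"]):
        x = np.log10(sub["mass_mg"])
        y = np.log10(sub[trait])
        marker = "o" if temp == min(data["acclimation_temp_c"]) else "s"
        ax.scatter(x, y, s=12, alpha=0.6, marker=marker, label=f"{hist} {temp:g}°C")
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 20)
        ax.plot(xs, a + b * xs, lw=1)
    ax.set_xlabel("log10 mass (mg)")
    ax.set_ylabel(f"log10 {trait.upper()} (µg O2 min$^{{-1}}$)")
    ax.legend(fontsize=7)
    return ax


def arrhenius_plot(ea_table, trait="smr", ax=None):
    """ln mass-normalized rate against 1/kT with the fitted two-point slopes
    (activation energies) per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = ea_table[ea_table["trait"] == trait]
    for _, row in sub.iterrows():
        temps = (20.0, 30.0)
        x = [1.0 / (BOLTZMANN_EV * (t + CELSIUS_OFFSET)) for t in temps]
        y = [np.log(row["rate_low_t"]), np.log(row["rate_high_t"])]
        ax.plot(x, y, marker="o", label=f"{row['group']} (Ea={row['ea_ev']:.2f} eV)")
    ax.set_xlabel("1/kT (eV$^{-1}$)")
    ax.set_ylabel(f"ln normalized {trait.upper()}")
    ax.legend(fontsize=7)
    return ax
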
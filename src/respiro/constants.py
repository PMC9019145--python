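"""Physical constants and fixed protocol limits."""

#: Boltzmann constant in electron-volts per Kelvin, the conventional unit for
#: activation energies of metabolism in macroecology.
BOLTZMANN_EV = 8.62e-5

#: Additive offset converting degrees Celsius to Kelvin.
CELSIUS_OFFSET = 273.15

#: Maximum refuge-emergence latency in the boldness assay, seconds. Fish that
#: never emerge are right-censored at this value.
LATENCY_LIMIT_S = 600.0

#: Length of the activity observation window after emergence, seconds.
ACTIVITY_WINDOW_S = 300.0


def inverse_thermal_energy(temp_c: float) -> float:
    """Return 1/(kT) in eV^-1 for a temperature in degrees Celsius."""
    return 1.0 / (BOLTZMANN_EV * (temp_c + CELSIUS_OFFSET))
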
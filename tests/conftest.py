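import warnings

import numpy as np
import pytest

from respiro.cohort import CohortConfig, generate_cohort
from respiro.traces import TraceConfig, simulate_experiment


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Mixed-model boundary fits (zero variance components) emit harmless
    convergence chatter; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort (198 fish) with its ground truth."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small zero-noise cohort: 4 populations x 2 tanks x 3 fish."""
    cfg = CohortConfig(
        n_populations=4,
        histories=("ambient", "ambient", "warm", "warm"),
        n_fish_per_tank=3,
        trait_noise_sd=0.0,
        population_sd=0.0,
        tank_sd=0.0,
        seed=1,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_traces(noiseless_cohort):
    """Noise-free, burst-free traces for the small cohort (short overnight
    block to keep the table small; exactness does not depend on duration)."""
    cfg, (cohort, truth) = noiseless_cohort
    tcfg = TraceConfig(
        sensor_noise_sd=0.0, activity_burst_rate_per_h=0.0, smr_duration_h=2.0
    )
    return tcfg, simulate_experiment(cohort, truth, tcfg, seed=2)


@pytest.fixture(scope="session")
def trait_table(default_cohort):
    """Cohort merged with its true rates, on the analysis (log10) scale —
    the input the inference layer sees when extraction is exact."""
    cohort, truth = default_cohort
    df = cohort.merge(truth, on="fish_id")
    df["log10_mass"] = np.log10(df["mass_mg"])
    for t in ("smr", "rmr", "mmr"):
        df[t] = df[f"true_{t}"]
        df[f"log10_{t}"] = np.log10(df[t])
    return df
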
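"""Synthetic cohort generator: determinism, structure, generative law."""

import math

import numpy as np
import pandas as pd
import pytest

from respiro.cohort import CohortConfig, generate_cohort
from respiro.constants import inverse_thermal_energy


def test_same_seed_bit_identical():
    a_cohort, a_truth = generate_cohort(CohortConfig(seed=5))
    b_cohort, b_truth = generate_cohort(CohortConfig(seed=5))
    pd.testing.assert_frame_equal(a_cohort, b_cohort)
    pd.testing.assert_frame_equal(a_truth, b_truth)
    c_cohort, _ = generate_cohort(CohortConfig(seed=6))
    assert not a_cohort["mass_mg"].equals(c_cohort["mass_mg"])


def test_cohort_size_is_product_of_design():
    cfg = CohortConfig(n_fish_per_tank=5)
    cohort, _ = generate_cohort(cfg)
    assert len(cohort) == cfg.n_populations * cfg.n_tanks_per_population * 5


def test_default_cohort_has_198_fish_and_balanced_design(default_cohort):
    cohort, _ = default_cohort
    assert len(cohort) == 198
    assert set(cohort["history"]) == {"ambient", "warm"}
    assert set(cohort["acclimation_temp_c"]) == {20.0, 30.0}
    # each population holds one tank per temperature
    per_pop = cohort.groupby("population")["acclimation_temp_c"].nunique()
    assert (per_pop == 2).all()


def test_zero_noise_same_group_same_mass_identical_rates():
    cfg = CohortConfig(trait_noise_sd=0.0, population_sd=0.0, tank_sd=0.0)
    m, t, h = 250.0, 20.0, "warm"
    assert cfg.true_log10_rate("smr", m, t, h) == cfg.true_log10_rate("smr", m, t, h)


def test_power_law_mass_ratio():
    # doubling mass with b = 0.5 scales the rate by sqrt(2)
    cfg = CohortConfig(
        allometric_exponent_b={t: 0.5 for t in ("smr", "rmr", "mmr")},
        trait_noise_sd=0.0,
    )
    r1 = 10 ** cfg.true_log10_rate("smr", 100.0, 20.0, "ambient")
    r2 = 10 ** cfg.true_log10_rate("smr", 200.0, 20.0, "ambient")
    assert r2 / r1 == pytest.approx(math.sqrt(2.0), rel=1e-12)


def test_boltzmann_factor_rate_ratio():
    # Ea = -0.53 eV about doubles the rate from 20 to 30 degrees C:
    # ratio = exp(-Ea * (1/kT30 - 1/kT20)), with the 1/kT values near
    # 39.574 and 38.268 eV^-1.
    x20, x30 = inverse_thermal_energy(20.0), inverse_thermal_energy(30.0)
    assert x20 == pytest.approx(39.574, abs=5e-3)
    assert x30 == pytest.approx(38.268, abs=5e-3)
    # hold the allometric exponent fixed across temperatures so the ratio
    # isolates the Boltzmann factor
    cfg = CohortConfig(
        activation_energy_ea={t: -0.53 for t in ("smr", "rmr", "mmr")},
        allometric_exponent_b={t: 0.45 for t in ("smr", "rmr", "mmr")},
        trait_noise_sd=0.0,
    )
    r20 = 10 ** cfg.true_log10_rate("smr", 100.0, 20.0, "ambient")
    r30 = 10 ** cfg.true_log10_rate("smr", 100.0, 30.0, "ambient")
    expected = math.exp(-0.53 * (x30 - x20))
    assert r30 / r20 == pytest.approx(expected, rel=1e-12)
    assert r30 / r20 == pytest.approx(2.0, abs=0.01)


def test_trait_ordering_enforced(default_cohort):
    _, truth = default_cohort
    assert (truth["true_smr"] <= truth["true_rmr"]).all()
    assert (truth["true_rmr"] <= truth["true_mmr"]).all()
    assert (truth[["true_smr", "true_rmr", "true_mmr"]] > 0).all().all()


def test_latency_censoring_consistency(default_cohort):
    cohort, truth = default_cohort
    merged = cohort.merge(truth, on="fish_id")
    cens = merged["latency_censored"]
    assert (merged.loc[cens, "latency_s"] == 600.0).all()
    assert (merged.loc[cens, "latent_latency_s"] >= 600.0).all()
    assert (merged.loc[~cens, "latency_s"] < 600.0).all()
    # non-emergers are not measured for activity
    assert merged.loc[cens, "activity_s"].isna().all()
    assert merged.loc[~cens, "activity_s"].notna().all()
    assert merged["activity_s"].max() <= 300.0


def test_warm_source_fish_emerge_more(default_cohort):
    cohort, _ = default_cohort
    frac = cohort.groupby("history")["emerged"].mean()
    assert frac["warm"] > frac["ambient"]


@pytest.mark.parametrize(
    "kwargs, match",
    [
        ({"histories": ("warm",) * 8}, "both"),
        ({"acclimation_temperatures": (20.0, 45.0)}, "acclimation_temperatures"),
        ({"n_fish_per_tank": 0}, "n_fish_per_tank"),
        ({"mass_range_mg": (100.0, 50.0)}, "mass_range_mg"),
        ({"trait_noise_sd": -0.1}, "standard deviations"),
        ({"histories": ("warm",) * 4}, "histories"),
    ],
)
def test_invalid_config_rejected_with_named_parameter(kwargs, match):
    with pytest.raises(ValueError, match=match):
        generate_cohort(CohortConfig(**kwargs))


def test_config_yaml_roundtrip(tmp_path):
    cfg = CohortConfig(seed=9, total_n=64)
    path = tmp_path / "cohort.yaml"
    cfg.to_yaml(path)
    back = CohortConfig.from_yaml(path)
    assert back == cfg
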
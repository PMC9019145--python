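"""Synthetic raw oxygen traces for intermittent-flow and static respirometry.

Signal model: inside a sealed chamber the O2 concentration (mg L^-1, which
equals µg ml^-1) declines at ``(MO2_fish(t) + blank_rate(t)) / (Vr - Vf)``
per minute, where MO2_fish is the fish's instantaneous consumption (its true
rate, multiplied during spontaneous activity bursts), blank_rate is the
background microbial consumption of the system water (drifting linearly over
the experiment), Vr is chamber volume and Vf fish volume (ml). Flush phases
relax O2 exponentially back toward the supply concentration. Gaussian sensor
noise is added to the recorded concentrations.

Trial kinds: ``smr`` — ~18 h of 5-min flush / 30-s wait / 15-min measure
cycles; ``rmr`` — one static 15-min measure; ``mmr`` — one static 5-min
measure immediately post-chase; ``blank`` — a fishless chamber recording
background consumption only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

TRACE_COLUMNS = ["chamber_id", "fish_id", "kind", "phase", "t_s", "o2_mgL", "temp_C"]


@dataclass
class TraceConfig:
    """Respirometry protocol and sensor parameters.

    Volumes in ml, times in seconds unless suffixed otherwise, O2 in mg L^-1,
    background (blank) rates in µg O2 min^-1.
    """

    chamber_volume_ml: float = 40.0
    flush_s: float = 300.0
    wait_s: float = 30.0
    measure_s: float = 900.0
    smr_duration_h: float = 18.0
    rmr_duration_s: float = 900.0
    mmr_duration_s: float = 300.0
    o2_start_mgL: float = 8.0
    sensor_noise_sd: float = 0.01
    blank_rate_start: float = 0.05
    blank_rate_end: float = 0.20
    blank_ramp_duration_h: float = 20.0
    activity_burst_rate_per_h: float = 2.0
    burst_multiplier: float = 3.0
    burst_duration_s: float = 60.0
    sampling_interval_s: float = 5.0
    flush_tau_s: float = 45.0

    def validate(self) -> None:
        if self.chamber_volume_ml <= 0:
            raise ValueError("chamber_volume_ml must be > 0")
        for name in (
            "flush_s",
            "wait_s",
            "measure_s",
            "smr_duration_h",
            "rmr_duration_s",
            "mmr_duration_s",
            "sampling_interval_s",
            "flush_tau_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.blank_rate_start < 0 or self.blank_rate_end < 0:
            raise ValueError("blank rates must be >= 0")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")
        if self.burst_multiplier < 1:
            raise ValueError("burst_multiplier must be >= 1")

    def blank_rate_at(self, t_s: np.ndarray | float) -> np.ndarray | float:
        """Background microbial consumption (µg O2 min^-1) at experiment time
        ``t_s``; linear drift from start to end rate over the ramp, clamped."""
        span = self.blank_ramp_duration_h * 3600.0
        frac = np.clip(np.asarray(t_s, dtype=float) / span, 0.0, 1.0)
        return self.blank_rate_start + frac * (self.blank_rate_end - self.blank_rate_start)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TraceConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _burst_occupancy(
    t_mid: np.ndarray, total_s: float, config: TraceConfig, rng: np.random.Generator
) -> np.ndarray:
    """Indicator of whether each sample midpoint falls inside an activity
    burst. Bursts form a Poisson process of fixed-duration marks; overlapping
    bursts do not stack."""
    rate = config.activity_burst_rate_per_h / 3600.0
    n_events = rng.poisson(rate * total_s)
    if n_events == 0:
        return np.zeros_like(t_mid)
    starts = np.sort(rng.uniform(0.0, total_s, size=n_events))
    occ = np.zeros_like(t_mid)
    for s in starts:
        occ[(t_mid >= s) & (t_mid < s + config.burst_duration_s)] = 1.0
    return occ


def _phase_schedule(kind: str, config: TraceConfig) -> list[tuple[str, float]]:
    """Ordered (phase, duration_s) pairs for one trial."""
    if kind == "smr":
        cycle = [("flush", config.flush_s), ("wait", config.wait_s), ("measure", config.measure_s)]
        cycle_s = sum(d for _, d in cycle)
        n_cycles = int(config.smr_duration_h * 3600.0 // cycle_s)
        if n_cycles < 1:
            raise ValueError("smr_duration_h too short for a single flush/wait/measure cycle")
        return cycle * n_cycles
    if kind == "rmr":
        return [("measure", config.rmr_duration_s)]
    if kind == "mmr":
        return [("measure", config.mmr_duration_s)]
    if kind == "blank":
        return [("measure", config.measure_s)]
    raise ValueError(f"unknown trial kind '{kind}' (expected smr|rmr|mmr|blank)")


def generate_trace(
    fish: dict,
    kind: str,
    config: TraceConfig | None = None,
    seed: int | None = None,
    t0_s: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one raw O2 trace.

    ``fish`` is a mapping with keys ``fish_id``, ``fish_volume_ml``, the true
    rate for this trial kind (``true_smr``/``true_rmr``/``true_mmr``, µg O2
    min^-1), optionally ``chamber_id`` and ``acclimation_temp_c``. For
    ``kind='blank'`` the fish volume must be 0 (fishless chamber). ``t0_s``
    places the trial on the shared experiment clock used for background-drift
    interpolation.

    Returns a long-format DataFrame with columns
    ``chamber_id, fish_id, kind, phase, t_s, o2_mgL, temp_C``.
    """
    config = config or TraceConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    vf = float(fish.get("fish_volume_ml", 0.0))
    if kind == "blank":
        if vf != 0.0:
            raise ValueError("blank trials require fish_volume_ml == 0 (water only)")
        base_rate = 0.0
    else:
        key = f"true_{kind}"
        if key not in fish:
            raise ValueError(f"fish record lacks '{key}' needed for kind='{kind}'")
        base_rate = float(fish[key])
    vr = config.chamber_volume_ml
    if vf >= vr:
        raise ValueError(
            f"fish volume ({vf} ml) must be smaller than chamber volume ({vr} ml)"
        )
    eff_vol = vr - vf

    schedule = _phase_schedule(kind, config)
    total_s = sum(d for _, d in schedule)
    dt = config.sampling_interval_s
    n_total = int(round(total_s / dt))
    t_rel = np.arange(n_total, dtype=float) * dt  # sample timestamps
    t_mid = t_rel + dt / 2.0  # step midpoints for consumption integration

    # phase label per sample
    phases = np.empty(n_total, dtype=object)
    bounds = np.cumsum([0.0] + [d for _, d in schedule])
    for (phase, _), lo, hi in zip(schedule, bounds[:-1], bounds[1:]):
        phases[(t_rel >= lo) & (t_rel < hi)] = phase

    # instantaneous consumption (µg min^-1) at step midpoints
    rate = np.full(n_total, base_rate)
    if kind == "smr" and base_rate > 0 and config.activity_burst_rate_per_h > 0:
        occ = _burst_occupancy(t_mid, total_s, config, rng)
        rate = rate * (1.0 + (config.burst_multiplier - 1.0) * occ)
    rate = rate + np.asarray(config.blank_rate_at(t0_s + t_mid))

    # integrate: per-step O2 drop in sealed phases; exponential refill in flush
    o2 = np.empty(n_total)
    drop = rate * (dt / 60.0) / eff_vol  # mg L^-1 lost per step
    decay = np.exp(-dt / config.flush_tau_s)
    level = config.o2_start_mgL
    flush_mask = phases == "flush"
    for i in range(n_total):
        o2[i] = level
        if flush_mask[i]:
            level = config.o2_start_mgL + (level - config.o2_start_mgL) * decay
        else:
            level = level - drop[i]

    if config.sensor_noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.sensor_noise_sd, size=n_total)

    return pd.DataFrame(
        {
            "chamber_id": fish.get("chamber_id", "ch1"),
            "fish_id": fish.get("fish_id", "blank"),
            "kind": kind,
            "phase": phases,
            "t_s": t0_s + t_rel,
            "o2_mgL": o2,
            "temp_C": float(fish.get("acclimation_temp_c", 25.0)),
        }
    )


def simulate_experiment(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    config: TraceConfig | None = None,
    seed: int = 0,
    kinds: Iterable[str] = ("rmr", "smr", "mmr"),
) -> pd.DataFrame:
    """Simulate the full respirometry timeline for every fish in a cohort.

    Each fish gets a pre-trial blank, its RMR / SMR / MMR traces on a shared
    experiment clock, and a post-trial blank, mirroring a protocol in which
    fishless control chambers bracket every trial. Returns one long-format
    DataFrame (schema as :data:`TRACE_COLUMNS`).
    """
    config = config or TraceConfig()
    config.validate()
    merged = cohort.merge(truth, on="fish_id")
    frames = []
    gap = 60.0  # handling time between trials, s
    for i, row in merged.reset_index(drop=True).iterrows():
        rng = np.random.default_rng((seed, 1 + i))
        fish = row.to_dict()
        fish["chamber_id"] = f"ch{i % 4 + 1}"
        blank = {
            "fish_id": f"blank_pre_{row.fish_id}",
            "fish_volume_ml": 0.0,
            "chamber_id": fish["chamber_id"],
            "acclimation_temp_c": row.get("acclimation_temp_c", 25.0),
        }
        t = 0.0
        frames.append(generate_trace(blank, "blank", config, t0_s=t, rng=rng))
        t += config.measure_s + gap
        for kind in kinds:
            tr = generate_trace(fish, kind, config, t0_s=t, rng=rng)
            frames.append(tr)
            t = tr["t_s"].iloc[-1] + config.sampling_interval_s + gap
        blank_post = dict(blank, fish_id=f"blank_post_{row.fish_id}")
        frames.append(generate_trace(blank_post, "blank", config, t0_s=t, rng=rng))
    return pd.concat(frames, ignore_index=True)[TRACE_COLUMNS]


def write_traces(traces: pd.DataFrame, path) -> None:
    traces.to_csv(path, index=False)


def read_traces(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format trace CSV.

    ``column_map`` renames vendor columns to the canonical schema, e.g. a
    four-channel logger export with per-channel oxygen columns already
    melted to long form: ``{"Time (s)": "t_s", "Ch1 O2 (mg/L)": "o2_mgL"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing required columns: {missing}")
    return df[TRACE_COLUMNS]
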
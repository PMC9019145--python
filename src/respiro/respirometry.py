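"""Raw O2 traces → per-fish metabolic rate estimates.

The chain: fit an ordinary-least-squares slope to each sealed measurement
window; convert to oxygen uptake via MO2 = (Vr − Vf) × |ΔC/Δt| (chamber
minus fish volume times the rate of concentration decline, giving µg O2
min^-1); subtract the background microbial rate interpolated linearly in
time between pre- and post-trial blanks; reduce the overnight cycle series
to SMR as the mean of the lowest 10% of cycles after a ±2 SD outlier screen;
and combine SMR/RMR/MMR into aerobic scope (MMR − SMR) and factorial
aerobic scope (MMR / SMR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd


@dataclass
class MeasurementCycle:
    """OLS slope fit for one sealed measurement window."""

    cycle_index: int
    t_start: float
    t_end: float
    t_mid: float  # mean retained timestamp, used for blank interpolation
    slope_mgL_per_min: float  # signed; negative = consumption
    r_squared: float
    n_points: int


@dataclass
class BlankSeries:
    """Background (microbial) consumption measured in fishless chambers
    before and/or after a trial; interpolated linearly in time between the
    two, clamped to the endpoint values outside their interval."""

    pre_time_s: float | None = None
    pre_rate: float | None = None  # µg O2 min^-1
    post_time_s: float | None = None
    post_rate: float | None = None

    def __post_init__(self) -> None:
        if self.pre_rate is None and self.post_rate is None:
            raise ValueError("BlankSeries requires at least one of pre/post blanks")
        if self.pre_rate is None or self.post_rate is None:
            warnings.warn(
                "only one blank available; applying a constant background correction",
                stacklevel=2,
            )
        for r in (self.pre_rate, self.post_rate):
            if r is not None and r < 0:
                warnings.warn(f"negative blank rate ({r:.4g}) retained", stacklevel=2)
        if (
            self.pre_time_s is not None
            and self.post_time_s is not None
            and not self.post_time_s > self.pre_time_s
        ):
            raise ValueError("post blank time must exceed pre blank time")

    def rate_at(self, t_s: float) -> float:
        if self.pre_rate is None:
            return float(self.post_rate)
        if self.post_rate is None:
            return float(self.pre_rate)
        if t_s <= self.pre_time_s:
            return float(self.pre_rate)
        if t_s >= self.post_time_s:
            return float(self.post_rate)
        frac = (t_s - self.pre_time_s) / (self.post_time_s - self.pre_time_s)
        return float(self.pre_rate + frac * (self.post_rate - self.pre_rate))


@dataclass
class MetabolicEstimate:
    """Per-fish metabolic phenotype (rates in µg O2 min^-1)."""

    fish_id: str
    smr: float | None = None
    rmr: float | None = None
    mmr: float | None = None
    aerobic_scope: float | None = None
    factorial_scope: float | None = None
    n_cycles_used: int = 0
    n_outliers_excluded: int = 0
    flags: list[str] = field(default_factory=list)


def fit_o2_slope(
    t_s: np.ndarray,
    o2_mgL: np.ndarray,
    trim_leading_s: float = 0.0,
    cycle_index: int = 0,
) -> MeasurementCycle:
    """OLS slope of O2 concentration against time over one sealed window.

    ``trim_leading_s`` discards the start of the window (mixing transient
    after sealing). The slope is returned per minute; r² reports linearity.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(o2_mgL, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t_s and o2_mgL must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    keep = t >= t[0] + trim_leading_s
    t, y = t[keep], y[keep]
    if t.size < 3:
        raise ValueError(f"need >= 3 points after trimming, got {t.size}")
    tc = t - t.mean()
    yc = y - y.mean()
    sxx = float(tc @ tc)
    slope_per_s = float(tc @ yc) / sxx  # sxx > 0 given >=3 increasing times
    ss_res = float(yc @ yc) - slope_per_s**2 * sxx
    ss_tot = float(yc @ yc)
    r2 = 1.0 if ss_tot == 0.0 else min(1.0, max(0.0, 1.0 - ss_res / ss_tot))
    return MeasurementCycle(
        cycle_index=cycle_index,
        t_start=float(t[0]),
        t_end=float(t[-1]),
        t_mid=float(t.mean()),
        slope_mgL_per_min=slope_per_s * 60.0,
        r_squared=r2,
        n_points=int(t.size),
    )


def compute_mo2(slope_mgL_per_min: float, vr_ml: float, vf_ml: float = 0.0) -> float:
    """Oxygen uptake MO2 = (Vr − Vf) × |ΔC/Δt|, in µg O2 min^-1.

    Consumption (declining O2, negative slope) is reported positive; a rising
    trace yields a negative MO2, left to the caller to flag.
    """
    if vf_ml < 0:
        raise ValueError("fish volume must be >= 0")
    if vf_ml >= vr_ml:
        raise ValueError(
            f"fish volume ({vf_ml} ml) must be smaller than chamber volume ({vr_ml} ml)"
        )
    return (vr_ml - vf_ml) * (-slope_mgL_per_min)


def blank_correct(mo2: float, t_mid_s: float, blanks: BlankSeries) -> float:
    """Subtract the interpolated background rate at the window midpoint.

    A correction exceeding the measured rate yields a negative value; it is
    returned as-is (not clipped) so downstream dispersion statistics stay
    unbiased — callers flag negatives.
    """
    return mo2 - blanks.rate_at(t_mid_s)


def extract_smr(
    cycle_mo2: np.ndarray | list[float],
    lowest_fraction: float = 0.10,
    outlier_order: str = "global",
) -> tuple[float, int]:
    """SMR from a series of blank-corrected cycle MO2 values.

    Default (``outlier_order='global'``): discard cycles beyond ±2 SD of the
    mean of *all* cycles, then average the lowest ``ceil(10%)`` of the
    survivors. ``'subset'`` instead takes the lowest 10% first and screens
    outliers within that subset. Returns ``(smr, n_outliers_excluded)``.
    """
    x = np.asarray(cycle_mo2, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 cycle values")
    if not np.all(np.isfinite(x)):
        raise ValueError("cycle values must be finite")
    if outlier_order not in ("global", "subset"):
        raise ValueError("outlier_order must be 'global' or 'subset'")

    def screen(v: np.ndarray) -> np.ndarray:
        mu, sd = v.mean(), v.std(ddof=1) if v.size > 1 else 0.0
        return v[np.abs(v - mu) <= 2.0 * sd] if sd > 0 else v

    if outlier_order == "global":
        survivors = screen(x)
        if survivors.size == 0:
            raise ValueError("outlier screen removed every cycle")
        k = max(1, ceil(lowest_fraction * survivors.size))
        lowest = np.sort(survivors)[:k]
        n_out = x.size - survivors.size
    else:
        k = max(1, ceil(lowest_fraction * x.size))
        subset = np.sort(x)[:k]
        lowest = screen(subset)
        if lowest.size == 0:
            raise ValueError("outlier screen removed every cycle in the lowest subset")
        n_out = subset.size - lowest.size
    return float(lowest.mean()), int(n_out)


def summarize_metabolism(
    fish_id: str,
    smr: float | None,
    rmr: float | None,
    mmr: float | None,
    n_cycles_used: int = 0,
    n_outliers_excluded: int = 0,
) -> MetabolicEstimate:
    """Fill aerobic scope (MMR − SMR) and factorial scope (MMR / SMR), with
    quality flags for inverted orderings (e.g. a chase protocol that failed
    to elicit a true maximum) and non-positive rates."""
    est = MetabolicEstimate(
        fish_id=fish_id,
        smr=smr,
        rmr=rmr,
        mmr=mmr,
        n_cycles_used=n_cycles_used,
        n_outliers_excluded=n_outliers_excluded,
    )
    for name, val in (("smr", smr), ("rmr", rmr), ("mmr", mmr)):
        if val is not None and val <= 0:
            est.flags.append(f"nonpositive_{name}")
    if smr is not None and mmr is not None:
        est.aerobic_scope = mmr - smr
        if smr > 0:
            est.factorial_scope = mmr / smr
        if mmr <= smr:
            est.flags.append("mmr_not_above_smr")
    if rmr is not None and mmr is not None and mmr < rmr:
        est.flags.append("mmr_below_rmr")
    return est


# --------------------------------------------------------------------------
# trace-table driver


def _segments(phase: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of identical phase labels, as (start, stop) slices."""
    change = np.flatnonzero(phase[1:] != phase[:-1]) + 1
    bounds = np.concatenate(([0], change, [phase.size]))
    return list(zip(bounds[:-1], bounds[1:]))


def measurement_cycles(
    trace: pd.DataFrame, trim_leading_s: float = 0.0
) -> list[MeasurementCycle]:
    """Slope-fit every contiguous ``measure`` segment of one fish's trace."""
    trace = trace.sort_values("t_s")
    phase = trace["phase"].to_numpy()
    cycles = []
    idx = 0
    for lo, hi in _segments(phase):
        if phase[lo] != "measure":
            continue
        seg = trace.iloc[lo:hi]
        cycles.append(
            fit_o2_slope(
                seg["t_s"].to_numpy(),
                seg["o2_mgL"].to_numpy(),
                trim_leading_s=trim_leading_s,
                cycle_index=idx,
            )
        )
        idx += 1
    return cycles


def blank_series_from_traces(
    traces: pd.DataFrame, fish_id: str, vr_ml: float
) -> BlankSeries | None:
    """Build the pre/post background series for one fish from fishless
    control traces named ``blank_pre_<fish_id>`` / ``blank_post_<fish_id>``."""
    by_fish = {fid: sub for fid, sub in traces.groupby("fish_id", sort=False)}
    return _blank_series_from_groups(by_fish, fish_id, vr_ml)


def _blank_series_from_groups(
    by_fish: dict, fish_id: str, vr_ml: float
) -> BlankSeries | None:
    out: dict[str, float | None] = {
        "pre_time_s": None,
        "pre_rate": None,
        "post_time_s": None,
        "post_rate": None,
    }
    found = False
    for tag in ("pre", "post"):
        sub = by_fish.get(f"blank_{tag}_{fish_id}")
        if sub is None or sub.empty:
            continue
        cyc = measurement_cycles(sub)
        if not cyc:
            continue
        rates = [compute_mo2(c.slope_mgL_per_min, vr_ml, 0.0) for c in cyc]
        times = [c.t_mid for c in cyc]
        out[f"{tag}_time_s"] = float(np.mean(times))
        out[f"{tag}_rate"] = float(np.mean(rates))
        found = True
    if not found:
        return None
    return BlankSeries(**out)


def extract_metabolic_rates(
    traces: pd.DataFrame,
    meta: pd.DataFrame,
    vr_ml: float = 40.0,
    trim_leading_s: float = 30.0,
    outlier_order: str = "global",
    lowest_fraction: float = 0.10,
    mmr_rolling_window_s: float | None = None,
) -> pd.DataFrame:
    """Full extraction: long-format traces + fish metadata → per-fish SMR,
    RMR, MMR, AS and FAS (blank-corrected, µg O2 min^-1).

    ``meta`` needs columns ``fish_id`` and ``fish_volume_ml``. The leading
    ``trim_leading_s`` of every intermittent-flow measurement window is
    dropped (mirrors the post-flush wait before logging stabilises); static
    RMR/MMR windows are used whole. ``mmr_rolling_window_s`` switches MMR to
    the steepest rolling-window slope instead of one whole-window slope.
    """
    missing = {"fish_id", "fish_volume_ml"} - set(meta.columns)
    if missing:
        raise ValueError(f"meta table missing columns: {sorted(missing)}")
    by_fish = {fid: sub for fid, sub in traces.groupby("fish_id", sort=False)}
    results = []
    for _, fish in meta.iterrows():
        fid = fish["fish_id"]
        vf = float(fish["fish_volume_ml"])
        sub = by_fish.get(fid, traces.iloc[0:0])
        blanks = _blank_series_from_groups(by_fish, fid, vr_ml)
        values: dict[str, float | None] = {"smr": None, "rmr": None, "mmr": None}
        n_cycles = n_out = 0
        flags_extra: list[str] = []
        for kind in ("smr", "rmr", "mmr"):
            tr = sub[sub["kind"] == kind]
            if tr.empty:
                continue
            trim = trim_leading_s if kind == "smr" else 0.0
            if kind == "mmr" and mmr_rolling_window_s:
                cyc = _steepest_window(tr, mmr_rolling_window_s)
                cycles = [cyc] if cyc else []
            else:
                cycles = measurement_cycles(tr, trim_leading_s=trim)
            if not cycles:
                continue
            mo2 = [compute_mo2(c.slope_mgL_per_min, vr_ml, vf) for c in cycles]
            if blanks is not None:
                mo2 = [blank_correct(m, c.t_mid, blanks) for m, c in zip(mo2, cycles)]
            if kind == "smr" and len(mo2) >= 2:
                values[kind], n_out = extract_smr(
                    mo2, lowest_fraction=lowest_fraction, outlier_order=outlier_order
                )
                n_cycles = len(mo2)
            else:
                values[kind] = float(np.mean(mo2))
            if values[kind] is not None and values[kind] < 0:
                flags_extra.append(f"negative_{kind}_after_blank_correction")
        est = summarize_metabolism(
            fid,
            values["smr"],
            values["rmr"],
            values["mmr"],
            n_cycles_used=n_cycles,
            n_outliers_excluded=n_out,
        )
        est.flags.extend(flags_extra)
        results.append(
            {
                "fish_id": fid,
                "smr": est.smr,
                "rmr": est.rmr,
                "mmr": est.mmr,
                "aerobic_scope": est.aerobic_scope,
                "factorial_scope": est.factorial_scope,
                "n_cycles_used": est.n_cycles_used,
                "n_outliers_excluded": est.n_outliers_excluded,
                "flags": ";".join(est.flags),
            }
        )
    return pd.DataFrame(results)


def _steepest_window(trace: pd.DataFrame, window_s: float) -> MeasurementCycle | None:
    """Steepest-decline rolling-window slope inside a single measure phase."""
    tr = trace[trace["phase"] == "measure"].sort_values("t_s")
    t = tr["t_s"].to_numpy()
    y = tr["o2_mgL"].to_numpy()
    if t.size < 3:
        return None
    best: MeasurementCycle | None = None
    for i in range(t.size):
        j = np.searchsorted(t, t[i] + window_s, side="right")
        if j - i < 3:
            continue
        cyc = fit_o2_slope(t[i:j], y[i:j])
        if best is None or cyc.slope_mgL_per_min < best.slope_mgL_per_min:
            best = cyc
    return best
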
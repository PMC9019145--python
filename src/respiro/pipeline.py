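"""End-to-end orchestration: simulate → extract → scale → infer.

A run is driven by one :class:`RunConfig` (YAML-loadable). Every stage
writes CSV outputs into the run directory; a JSON manifest records the
seed, options, per-stage record counts and timings, package versions and
SHA-256 hashes of every output so that reruns are verifiable byte-for-byte.
All randomness flows from the single root seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .traces import TraceConfig, simulate_experiment, read_traces
from .respirometry import extract_metabolic_rates
from .scaling import group_scaling, activation_energies
from .lmm import prepare_trait_table, select_trait_model
from .glmm import fit_boldness_binomial, fit_activity_pln
from .tobit import fit_latency_censored

log = logging.getLogger("respiro")


def _stage_seed(root_seed: int, stage: str) -> int:
    """Named substream: stable 31-bit seed derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    output_dir: str = "run_output"
    seed: int = 0
    traces_path: str | None = None  # start from existing traces
    traits_path: str | None = None  # start from an existing trait table
    from_traits: bool = False
    cohort: CohortConfig = field(default_factory=CohortConfig)
    trace: TraceConfig = field(default_factory=TraceConfig)
    # respirometry options
    outlier_order: str = "global"
    trim_leading_s: float = 30.0
    # scaling options
    b_mode: str = "per_group"
    # inference options
    delta_threshold: float = 4.0
    averaging: str = "conditional"
    traits: tuple[str, ...] = ("log10_smr", "log10_rmr", "log10_mmr", "log10_aerobic_scope")
    fit_behavior: bool = True
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            c = raw["cohort"]
            for key in ("histories", "acclimation_temperatures", "mass_range_mg"):
                if key in c and isinstance(c[key], list):
                    c[key] = tuple(c[key])
            raw["cohort"] = CohortConfig(**c)
        if "trace" in raw and isinstance(raw["trace"], dict):
            raw["trace"] = TraceConfig(**raw["trace"])
        if "traits" in raw and isinstance(raw["traits"], list):
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the pipeline and return the run manifest.

    Stage order: simulate (skipped when ``traces_path`` is given), extract
    (skipped with ``from_traits``), scale, infer, behavior. Any stage
    failure raises with the stage name; ``dry_run`` only validates configs
    and input schemas.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "options": {
            "outlier_order": config.outlier_order,
            "trim_leading_s": config.trim_leading_s,
            "b_mode": config.b_mode,
            "delta_threshold": config.delta_threshold,
            "averaging": config.averaging,
        },
        "stages": {},
        "outputs": {},
    }
    config.cohort.validate()
    config.trace.validate()
    for path_attr in ("traces_path", "traits_path"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{path_attr} does not exist: {p}")
    if dry_run:
        manifest["dry_run"] = True
        return manifest
    out.mkdir(parents=True, exist_ok=True)

    def record(stage, t0, n):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "records": int(n),
        }
        log.info("stage %s: %d records in %.2fs", stage, n, time.time() - t0)

    def save(name, df):
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"][name] = _sha256(path)
        return path

    # --- stage: simulate ---------------------------------------------------
    cohort = truth = None
    if config.from_traits:
        if config.traits_path is None:
            raise RuntimeError("stage simulate: from_traits requires traits_path")
        traits_table = pd.read_csv(config.traits_path)
    else:
        t0 = time.time()
        try:
            cohort, truth = generate_cohort(
                config.cohort, seed=_stage_seed(config.seed, "cohort")
            )
        except Exception as e:
            raise RuntimeError(f"stage simulate failed: {e}") from e
        save("cohort.csv", cohort)
        save("ground_truth.csv", truth)  # never read by later stages
        record("simulate", t0, len(cohort))

        if config.traces_path is not None:
            traces = read_traces(config.traces_path)
        else:
            t0 = time.time()
            traces = simulate_experiment(
                cohort, truth, config.trace, seed=_stage_seed(config.seed, "traces")
            )
            save("traces.csv", traces)
            record("simulate_traces", t0, len(traces))

        # --- stage: extract ------------------------------------------------
        t0 = time.time()
        try:
            metab = extract_metabolic_rates(
                traces,
                cohort[["fish_id", "fish_volume_ml"]],
                vr_ml=config.trace.chamber_volume_ml,
                trim_leading_s=config.trim_leading_s,
                outlier_order=config.outlier_order,
            )
        except Exception as e:
            raise RuntimeError(f"stage extract failed: {e}") from e
        save("metabolic_estimates.csv", metab)
        record("extract", t0, len(metab))
        traits_table = prepare_trait_table(metab, cohort)
        save("trait_table.csv", traits_table)

    # --- stage: scale ------------------------------------------------------
    t0 = time.time()
    try:
        scaling = group_scaling(traits_table)
        ea_hist = activation_energies(traits_table, level="history", b_mode=config.b_mode)
        ea_pop = activation_energies(traits_table, level="population", b_mode=config.b_mode)
    except Exception as e:
        raise RuntimeError(f"stage scale failed: {e}") from e
    save("group_scaling.csv", scaling)
    save("activation_energy_history.csv", ea_hist)
    save("activation_energy_population.csv", ea_pop)
    record("scale", t0, len(scaling))

    # --- stage: infer ------------------------------------------------------
    t0 = time.time()
    tables = []
    coefs = []
    for response in config.traits:
        if response not in traits_table.columns:
            raise RuntimeError(f"stage infer failed: column '{response}' missing")
        try:
            result, _ = select_trait_model(
                traits_table.dropna(subset=[response]),
                response,
                delta_threshold=config.delta_threshold,
                averaging=config.averaging,
            )
        except Exception as e:
            raise RuntimeError(f"stage infer failed for {response}: {e}") from e
        tab = result.table.copy()
        tab.insert(0, "response", response)
        tables.append(tab)
        c = result.averaged_coefficients.rename_axis("term").reset_index(name="estimate")
        c.insert(0, "response", response)
        coefs.append(c)
    save("model_selection.csv", pd.concat(tables, ignore_index=True))
    save("averaged_coefficients.csv", pd.concat(coefs, ignore_index=True))
    record("infer", t0, sum(len(t) for t in tables))

    # --- stage: behavior ---------------------------------------------------
    if config.fit_behavior and {"emerged", "latency_s"} <= set(traits_table.columns):
        t0 = time.time()
        rows = []
        try:
            bold = fit_boldness_binomial(traits_table)
            for term, val in bold.params_.items():
                rows.append({"model": "boldness_binomial", "term": term,
                             "estimate": val, "se": bold.bse_[term]})
            act = fit_activity_pln(traits_table)
            for term, val in act.params_.items():
                rows.append({"model": "activity_pln", "term": term,
                             "estimate": val, "se": act.bse_[term]})
            rows.append({"model": "activity_pln", "term": "olre_sd",
                         "estimate": act.sigmas_.get("olre", np.nan), "se": np.nan})
            for temp in sorted(traits_table["acclimation_temp_c"].unique()):
                for cov in ("smr", "rmr", "mmr"):
                    fit = fit_latency_censored(traits_table, covariate=cov, temp=temp)
                    names = ["intercept"] + list(fit.feature_names_in_)
                    ests = [fit.intercept_, *fit.coef_]
                    for term, val, se in zip(names, ests, fit.bse_):
                        rows.append({
                            "model": f"latency_tobit_{cov}_{temp:g}C",
                            "term": term, "estimate": val, "se": se,
                        })
        except Exception as e:
            raise RuntimeError(f"stage behavior failed: {e}") from e
        save("behavior_models.csv", pd.DataFrame(rows))
        record("behavior", t0, len(rows))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
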
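"""Run-configuration and fixture serialization.

The run configuration is one YAML file holding the experiment design
(years, replication counts, master seed), the rate-calibration policy
and the input file paths. Cohort specifications round-trip through a
long CSV with columns (year, entry_weight, state, share, prior_state,
conditional_share).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .engine import CalibrationPolicy
from .population import CohortSpec
from .simulate import RunConfig
from .states import STATE_FROM_NAME, STATE_NAMES, TobaccoState


def run_config_to_dict(config: RunConfig, paths: dict | None = None) -> dict:
    out = {
        "start_year": config.start_year,
        "end_year": config.end_year,
        "n_rr_sets": config.n_rr_sets,
        "n_population_versions": config.n_population_versions,
        "n_seeds_per_iteration": config.n_seeds_per_iteration,
        "master_seed": config.master_seed,
        "target_prevalence": config.target_prevalence,
        "reference_wave": config.reference_wave,
        "resample_populations": config.resample_populations,
        "draw_rr": config.draw_rr,
        "calibration": {
            "initiation_multiplier": config.calibration.initiation_multiplier,
            "cessation_multiplier": config.calibration.cessation_multiplier,
            "mode": config.calibration.mode,
            "applies_from_year": config.calibration.applies_from_year,
            "active": config.calibration.active,
        },
    }
    if paths:
        out["paths"] = dict(paths)
    return out


def run_config_from_dict(d: dict) -> tuple[RunConfig, dict]:
    cal = d.get("calibration", {})
    policy = CalibrationPolicy(
        initiation_multiplier=cal.get("initiation_multiplier", 0.945),
        cessation_multiplier=cal.get("cessation_multiplier", 1.055),
        mode=cal.get("mode", "constant"),
        applies_from_year=cal.get("applies_from_year", 2017),
        active=cal.get("active", True),
    )
    config = RunConfig(
        start_year=d.get("start_year", 2016),
        end_year=d.get("end_year", 2050),
        n_rr_sets=d.get("n_rr_sets", 20),
        n_population_versions=d.get("n_population_versions", 20),
        n_seeds_per_iteration=d.get("n_seeds_per_iteration", 25),
        master_seed=d.get("master_seed", 0),
        calibration=policy,
        target_prevalence=d.get("target_prevalence", 0.1513),
        reference_wave=d.get("reference_wave", 3),
        resample_populations=d.get("resample_populations", True),
        draw_rr=d.get("draw_rr", True),
    )
    return config, d.get("paths", {})


def save_run_config(config: RunConfig, path, paths: dict | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(run_config_to_dict(config, paths), sort_keys=False))


def load_run_config(path) -> tuple[RunConfig, dict]:
    return run_config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------
# Cohort spec CSV
# ---------------------------------------------------------------------


def cohort_specs_to_frame(specs: dict[int, CohortSpec]) -> pd.DataFrame:
    rows = []
    for year, spec in sorted(specs.items()):
        for state, share in spec.state_distribution.items():
            cond = spec.prior_state_distribution[state]
            for prior, cshare in cond.items():
                rows.append(
                    {
                        "year": year,
                        "entry_weight": spec.entry_weight,
                        "state": STATE_NAMES[TobaccoState(state)],
                        "share": share,
                        "prior_state": STATE_NAMES[TobaccoState(prior)],
                        "conditional_share": cshare,
                        "n_entrants": spec.n_entrants,
                    }
                )
    return pd.DataFrame(rows)


def cohort_specs_from_frame(df: pd.DataFrame) -> dict[int, CohortSpec]:
    specs = {}
    for year, sub in df.groupby("year"):
        state_dist: dict[TobaccoState, float] = {}
        prior_dist: dict[TobaccoState, dict[TobaccoState, float]] = {}
        for state_name, ssub in sub.groupby("state"):
            state = STATE_FROM_NAME[state_name]
            state_dist[state] = float(ssub["share"].iloc[0])
            prior_dist[state] = {
                STATE_FROM_NAME[r.prior_state]: float(r.conditional_share)
                for r in ssub.itertuples()
            }
        specs[int(year)] = CohortSpec(
            year=int(year),
            entry_weight=float(sub["entry_weight"].iloc[0]),
            state_distribution=state_dist,
            prior_state_distribution=prior_dist,
            n_entrants=int(sub["n_entrants"].iloc[0]) if "n_entrants" in sub else 500,
        )
    return specs
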
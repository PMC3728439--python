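"""Long-format record files, study configuration and the end-to-end pipeline.

Records travel as delimited text, one row per completed valuation task, with
the header ``respondent_id,arm,block,state,T,U,n_questions,duration_s,
censored[,age_group,gender,education]``.  Reading validates every row against
the value algebra (``U`` must equal ``(T - LT)/UT`` for the row's arm to
1e-9) and reports errors with line numbers.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .core import (
    Arm,
    ConfigError,
    HealthState,
    TaskConfig,
    VisualVariant,
    compute_value,
)
from .qc import apply_qc
from .respondents import (
    RECORD_COLUMNS,
    ProfileParams,
    StudyDesign,
    simulate_study,
)
from . import analysis, tables


class ParseError(ValueError):
    """A record file failed validation; the message names the line."""


REQUIRED_COLUMNS = RECORD_COLUMNS[:9]
OPTIONAL_COLUMNS = RECORD_COLUMNS[9:]


def write_records(records: pd.DataFrame, path: Union[str, Path]) -> None:
    records.to_csv(path, index=False)


def read_records(
    path: Union[str, Path], configs: Mapping[str, TaskConfig]
) -> pd.DataFrame:
    """Read and validate a long-format record file."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        arm = str(row["arm"])
        if arm not in configs:
            raise ParseError(f"{path}:{line}: unknown arm {arm!r}")
        try:
            HealthState(str(row["state"]))
        except Exception as exc:
            raise ParseError(f"{path}:{line}: {exc}") from exc
        config = configs[arm]
        try:
            expected = compute_value(float(row["T"]), config)
        except Exception as exc:
            raise ParseError(f"{path}:{line}: {exc}") from exc
        if not math.isclose(float(row["U"]), expected, abs_tol=1e-9):
            raise ParseError(
                f"{path}:{line}: U={row['U']} inconsistent with T={row['T']} "
                f"(expected {expected})"
            )
        if int(row["n_questions"]) < 1 or float(row["duration_s"]) < 0:
            raise ParseError(f"{path}:{line}: bad n_questions or duration_s")
    df["state"] = df["state"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def default_config(study: str = "china") -> Dict:
    """A complete, editable study configuration.

    ``study='china'`` contrasts lead times (10 vs 5 years over 5 unhealthy
    years); ``study='singapore'`` contrasts visual variants (aligned vs
    raised unhealthy-time bar, both LT=10/UT=5).
    """
    if study not in ("china", "singapore"):
        raise ConfigError(f"unknown study {study!r}")
    arms = {
        "china": {
            "standard": {"lead_time": 10, "unhealthy_time": 5, "visual_variant": "aligned"},
            "experimental": {"lead_time": 5, "unhealthy_time": 5, "visual_variant": "aligned"},
        },
        "singapore": {
            "standard": {"lead_time": 10, "unhealthy_time": 5, "visual_variant": "aligned"},
            "experimental": {"lead_time": 10, "unhealthy_time": 5, "visual_variant": "raised_bar"},
        },
    }[study]
    sizes = tables.ARM_SIZES[study]
    params = ProfileParams()
    return {
        "seed": 20130731,
        "n_per_arm": {"standard": sizes["standard"], "experimental": sizes["experimental"]},
        "arms": arms,
        "profile": {
            "state_means": dict(params.state_means),
            "state_sd": params.state_sd,
            "respondent_sd": params.respondent_sd,
            "decision_sd": params.decision_sd,
            "indifference_tol": params.indifference_tol,
            "framing_coeff": params.framing_coeff,
            "visual_error_coeff": params.visual_error_coeff,
            "engagement_gain": params.engagement_gain,
            "base_log_time": params.base_log_time,
            "time_sd": params.time_sd,
            "age_groups": dict(params.age_groups),
            "genders": dict(params.genders),
            "educations": dict(params.educations),
        },
    }


def load_config(path: Union[str, Path]) -> Dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("seed", "n_per_arm", "arms", "profile"):
        if key not in cfg:
            raise ConfigError(f"config missing key {key!r}")
    return cfg


def save_config(cfg: Mapping, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def configs_from_dict(cfg: Mapping) -> Dict[str, TaskConfig]:
    out = {}
    for arm, spec in cfg["arms"].items():
        out[arm] = TaskConfig(
            lead_time=float(spec["lead_time"]),
            unhealthy_time=float(spec["unhealthy_time"]),
            min_step=float(spec.get("min_step", 0.25)),
            visual_variant=VisualVariant(spec.get("visual_variant", "aligned")),
        )
    return out


def params_from_dict(cfg: Mapping) -> ProfileParams:
    p = cfg["profile"]
    kwargs = {k: p[k] for k in (
        "state_means",
        "state_sd",
        "respondent_sd",
        "decision_sd",
        "indifference_tol",
        "framing_coeff",
        "visual_error_coeff",
        "engagement_gain",
        "base_log_time",
        "time_sd",
        "age_groups",
        "genders",
        "educations",
    ) if k in p}
    return ProfileParams(**kwargs)


def design_from_dict(cfg: Mapping) -> StudyDesign:
    return StudyDesign(n_per_arm=cfg["n_per_arm"], seed=int(cfg["seed"]))


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    config: Union[str, Path, Mapping],
    out_dir: Union[str, Path],
    seed: Optional[int] = None,
) -> Path:
    """simulate -> qc -> analyze, writing all artifacts plus a manifest.

    Returns the output directory.  A fixed config and seed give
    byte-identical outputs on rerun.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = design_from_dict(cfg)
    params = params_from_dict(cfg)
    configs = configs_from_dict(cfg)

    records = simulate_study(design, params, configs)
    write_records(records, out / "records.csv")

    filtered, report = apply_qc(records)
    write_records(filtered, out / "records_filtered.csv")
    (out / "exclusion_report.txt").write_text(str(report))

    # Table-3-shaped per-state summary
    summaries = {
        arm: analysis.summarize_arm(filtered[filtered["arm"] == arm])
        for arm in ("standard", "experimental")
    }
    states = sorted(filtered["state"].unique())
    t3 = pd.DataFrame(
        [
            {
                "state": s,
                **{
                    f"{arm}_{f}": getattr(
                        summaries[arm].per_state.get(s, analysis.StateStat(float("nan"), float("nan"), 0)), f
                    )
                    for arm in summaries
                    for f in ("mean", "sd", "n")
                },
            }
            for s in states
        ]
    )
    t3.to_csv(out / "table3_state_summaries.csv", index=False)

    t4 = pd.DataFrame(
        [
            {
                "arm": arm,
                "n_records": sm_.n_records,
                "n_nonnegative": sm_.n_nonnegative,
                "prop_nonnegative": sm_.prop_nonnegative,
                "grand_mean_unweighted": sm_.grand_mean_unweighted,
                "exhaustion_count": sm_.exhaustion_count,
                "exhaustion_fraction": sm_.exhaustion_fraction,
            }
            for arm, sm_ in summaries.items()
        ]
    )
    t4.to_csv(out / "table4_arm_summaries.csv", index=False)

    analysis.behavior_by_bin(filtered).to_csv(
        out / "table5_behavior_by_bin.csv", index=False
    )

    xs = [summaries["experimental"].per_state[s].mean for s in states]
    ys = [summaries["standard"].per_state[s].mean for s in states]
    reg = analysis.aggregate_arm_regression(xs, ys)
    agg = {
        "slope": reg.slope,
        "intercept": reg.intercept,
        "slope_ci": list(reg.slope_ci),
        "intercept_ci": list(reg.intercept_ci),
        "n": reg.n,
    }
    (out / "aggregate_regression.json").write_text(json.dumps(agg, indent=2))

    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "n_per_arm": cfg["n_per_arm"],
        "stage_counts": {
            "simulated": int(len(records)),
            "after_qc": int(len(filtered)),
        },
        "exclusions": {
            "allsame_participants": report.n_allsame_excluded,
            "fast_tasks": report.n_fast_tasks_excluded,
        },
        "outputs": [
            "records.csv",
            "records_filtered.csv",
            "exclusion_report.txt",
            "table3_state_summaries.csv",
            "table4_arm_summaries.csv",
            "table5_behavior_by_bin.csv",
            "aggregate_regression.json",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
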
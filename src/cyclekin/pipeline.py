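"""End-to-end orchestration: one config in, one reproducible report out.

A run config (YAML or dict) declares the simulated study — cycle-kinetics
conditions, pulse-chase conditions, flow trajectories — together with
estimator policies and gating settings.  ``run_pipeline`` executes fixture
generation, cycle estimation, exit-index computation, flow gating/timecourse
assembly and the gatekept statistics, then writes a versioned JSON report
plus tidy CSVs.  All randomness descends from the single config seed, so
re-running the same config is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cycle import FitPolicy, compare_conditions, estimate_cycle_from_curve
from .errors import ConfigError, CycleKinError, StageError
from .exit_index import compute_exit_index
from .flow import build_timecourse, fold_change, gate_timecourse_events, percent_reduction
from .io import write_exit_table, write_flow_events, write_labeling_curve
from .params import CyclePopulationParams, MixtureSpec, TrajectoryParams
from .stats import compare_groups
from .synthetic import simulate_cumulative_labeling, simulate_flow_timecourse, simulate_pulse_chase

__all__ = ["load_config", "validate_config", "demo_config", "run_pipeline"]

_POP_KEYS = {"label", "tc", "ts", "gf", "quit_prob", "t_g2m", "proportion"}


def load_config(path) -> Dict:
    """Load and validate a YAML run config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: Dict) -> Dict:
    """Check the structural contract of a run config; raise ConfigError."""
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "seed" not in cfg or not isinstance(cfg["seed"], int):
        raise ConfigError("config requires an integer 'seed'")
    for section in ("cycle_study", "pulse_chase", "flow_study"):
        if section in cfg and not isinstance(cfg[section], dict):
            raise ConfigError(f"section {section!r} must be a mapping")
    cyc = cfg.get("cycle_study")
    if cyc:
        if "conditions" not in cyc or not cyc["conditions"]:
            raise ConfigError("cycle_study requires non-empty 'conditions'")
        for cond, spec in cyc["conditions"].items():
            pops = spec.get("populations")
            if not pops:
                raise ConfigError(f"cycle_study condition {cond!r} has no populations")
            for pop in pops:
                unknown = set(pop) - _POP_KEYS
                if unknown:
                    raise ConfigError(
                        f"unknown population keys {sorted(unknown)} in {cond!r}"
                    )
        labels = {
            pop["label"]
            for spec in cyc["conditions"].values()
            for pop in spec["populations"]
        }
        for entry in cyc.get("compare", []):
            if len(entry) != 3:
                raise ConfigError(
                    f"compare entries must be [cond_a, cond_b, label], got {entry}"
                )
            cond_a, cond_b, label = entry
            for cond in (cond_a, cond_b):
                if cond not in cyc["conditions"]:
                    raise ConfigError(f"compare references unknown condition {cond!r}")
            if label not in labels:
                raise ConfigError(f"compare references unknown population {label!r}")
    flow = cfg.get("flow_study")
    if flow:
        if not flow.get("conditions"):
            raise ConfigError("flow_study requires non-empty 'conditions'")
        for key in ("summary_reference", "summary_treated"):
            cond = flow.get(key)
            if cond is not None and cond not in flow["conditions"]:
                raise ConfigError(f"{key} references unknown condition {cond!r}")
    return cfg


def demo_config() -> Dict:
    """A self-contained demo study: reported MGE-progenitor kinetics under
    vehicle (DMSO) vs TGFbeta-receptor inhibition (LY), a pulse-chase exit
    contrast, and a two-condition flow timecourse."""
    return {
        "seed": 20210020,
        "output_dir": "cyclekin_demo_out",
        "cycle_study": {
            "times_h": [2, 4, 8, 16, 24],
            "n_cells_per_field": 200,
            "n_fields": 6,
            "n_replicates": 2,
            "fit_policy": "plateau_exclude",
            "conditions": {
                "dmso": {
                    "populations": [
                        {"label": "nkx2.1_pos", "tc": 39.98, "ts": 16.51,
                         "gf": 0.9, "proportion": 0.65},
                        {"label": "nkx2.1_neg", "tc": 38.80, "ts": 16.60,
                         "gf": 0.8, "proportion": 0.35},
                    ]
                },
                "ly": {
                    "populations": [
                        {"label": "nkx2.1_pos", "tc": 45.65, "ts": 21.76,
                         "gf": 0.9, "proportion": 0.65},
                        {"label": "nkx2.1_neg", "tc": 40.26, "ts": 16.11,
                         "gf": 0.8, "proportion": 0.35},
                    ]
                },
            },
            "compare": [["dmso", "ly", "nkx2.1_pos"], ["dmso", "ly", "nkx2.1_neg"]],
        },
        "pulse_chase": {
            "pulse_h": 2,
            "chase_h": 48,
            "n_cells_per_field": 300,
            "n_fields": 6,
            "n_replicates": 2,
            "marker_positive": "nkx2.1_pos",
            "conditions": {
                "control": {"label": "nkx2.1_pos", "tc": 39.98, "ts": 16.51,
                            "gf": 0.9, "quit_prob": 0.25},
                "tgfb3": {"label": "nkx2.1_pos", "tc": 39.98, "ts": 16.51,
                          "gf": 0.9, "quit_prob": 0.45},
            },
        },
        "flow_study": {
            "days": [25, 30, 35, 40, 45, 50, 55, 60],
            "n_events": 5000,
            "n_replicates": 3,
            "percentile": 99.9,
            "viability_multiple": 4.0,
            "simulate_controls": True,
            "conditions": {
                "control": {"hazard": 0.079, "onset_delay": 20.0,
                            "hazard_scale": 1.0},
                "ly": {"hazard": 0.079, "onset_delay": 20.0,
                       "hazard_scale": 0.45},
            },
            "summary_day": 45,
            "summary_reference": "control",
            "summary_treated": "ly",
        },
        "stats": {"alpha": 0.05},
    }


def _population(pop: Dict) -> CyclePopulationParams:
    kwargs = {k: v for k, v in pop.items() if k != "proportion"}
    return CyclePopulationParams(**kwargs)


def _mixture(spec: Dict, populations, seed: int) -> MixtureSpec:
    comps = tuple(
        (_population(pop), float(pop.get("proportion", 1.0 / len(populations))))
        for pop in populations
    )
    return MixtureSpec(
        components=comps,
        n_cells_per_field=int(spec.get("n_cells_per_field", 200)),
        n_fields=int(spec.get("n_fields", 6)),
        n_replicates=int(spec.get("n_replicates", 2)),
        seed=seed,
    )


def _stage_seeds(seed: int) -> Dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        stage: int(child.generate_state(1)[0] % (2**31 - 1))
        for stage, child in zip(("cycle", "pulse_chase", "flow"), children)
    }


def run_pipeline(config: Dict, output_dir: Optional[Path] = None) -> Dict:
    """Run every configured stage; return the report dict and write artifacts."""
    cfg = validate_config(config)
    out_dir = Path(output_dir or cfg.get("output_dir", "cyclekin_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    alpha = float(cfg.get("stats", {}).get("alpha", 0.05))
    seeds = _stage_seeds(cfg["seed"])

    report: Dict = {
        "software": {"name": "cyclekin", "version": __version__},
        "seed": cfg["seed"],
        "stage_seeds": seeds,
        "config": cfg,
    }

    if cfg.get("cycle_study"):
        report["cycle"] = _run_cycle_stage(
            cfg["cycle_study"], seeds["cycle"], alpha, out_dir
        )
    if cfg.get("pulse_chase"):
        report["exit_index"] = _run_exit_stage(
            cfg["pulse_chase"], seeds["pulse_chase"], alpha, out_dir
        )
    if cfg.get("flow_study"):
        report["flow"] = _run_flow_stage(cfg["flow_study"], seeds["flow"], out_dir)

    report_path = out_dir / "report.json"
    report_path.write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
    _write_log(out_dir / "run_log.txt", report)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_log(path: Path, report: Dict) -> None:
    lines = [
        f"cyclekin {report['software']['version']}",
        f"seed {report['seed']}",
        *(f"stage_seed {k} {v}" for k, v in sorted(report["stage_seeds"].items())),
        *(f"stage_ran {k}" for k in ("cycle", "exit_index", "flow") if k in report),
    ]
    path.write_text("\n".join(lines) + "\n")


def _run_cycle_stage(spec: Dict, seed: int, alpha: float, out_dir: Path) -> Dict:
    try:
        times = [float(t) for t in spec.get("times_h", [2, 4, 8, 16, 24])]
        plateau = spec.get("fit_policy", "all_points") == "plateau_exclude"
        rng = np.random.default_rng(seed)

        estimates: Dict[str, Dict[str, Dict]] = {}
        est_objects: Dict = {}
        curves = []
        for cond, cond_spec in spec["conditions"].items():
            pops = cond_spec["populations"]
            mix = _mixture(spec, pops, int(rng.integers(0, 2**31 - 1)))
            curve = simulate_cumulative_labeling(mix, times)
            curve.insert(0, "condition", cond)
            curves.append(curve)
            estimates[cond] = {}
            for pop in pops:
                params = _population(pop)
                est = estimate_cycle_from_curve(
                    curve,
                    gf=params.gf,
                    policy=FitPolicy(plateau_exclude=plateau, gf=params.gf),
                    label=params.label,
                )
                estimates[cond][params.label] = est.to_dict()
                est_objects[(cond, params.label)] = est

        all_curves = pd.concat(curves, ignore_index=True)
        write_labeling_curve(
            all_curves.drop(columns="condition").assign(
                label=all_curves["condition"] + ":" + all_curves["label"]
            ),
            out_dir / "labeling_curves.csv",
        )

        comparisons = []
        for cond_a, cond_b, label in spec.get("compare", []):
            cmp = compare_conditions(
                est_objects[(cond_a, label)],
                est_objects[(cond_b, label)],
                names=(cond_a, cond_b),
                alpha=alpha,
            )
            cmp["population"] = label
            comparisons.append(cmp)

        return {"estimates": estimates, "comparisons": comparisons}
    except CycleKinError as exc:
        raise StageError("cycle", str(exc)) from exc


def _run_exit_stage(spec: Dict, seed: int, alpha: float, out_dir: Path) -> Dict:
    try:
        pulse = float(spec.get("pulse_h", 2.0))
        chase = float(spec.get("chase_h", 48.0))
        marker = spec.get("marker_positive", "marker_pos")
        rng = np.random.default_rng(seed)

        results, per_field, tables = {}, {}, []
        for cond, pop in spec["conditions"].items():
            mix = _mixture(spec, [pop], int(rng.integers(0, 2**31 - 1)))
            table = simulate_pulse_chase(mix, pulse, chase)
            tables.append(table.assign(condition=cond))
            res = compute_exit_index(table, marker_positive=marker)
            results[cond] = res.to_dict()
            per_field[cond] = list(res.per_field)

        pd.concat(tables, ignore_index=True).to_csv(
            out_dir / "exit_counts.csv", index=False
        )

        out: Dict = {"pulse_h": pulse, "chase_h": chase, "indices": results}
        if len(per_field) >= 2 and all(len(v) >= 2 for v in per_field.values()):
            out["comparison"] = compare_groups(per_field, alpha=alpha).to_dict()
        return out
    except CycleKinError as exc:
        raise StageError("exit_index", str(exc)) from exc


def _run_flow_stage(spec: Dict, seed: int, out_dir: Path) -> Dict:
    try:
        trajectories = {
            cond: TrajectoryParams(**params)
            for cond, params in spec["conditions"].items()
        }
        events = simulate_flow_timecourse(
            trajectories,
            days=[float(d) for d in spec.get("days", [25, 35, 45])],
            n_events=int(spec.get("n_events", 5000)),
            n_replicates=int(spec.get("n_replicates", 3)),
            seed=seed,
        )
        if not spec.get("simulate_controls", True):
            events = events[events["role"] != "negative_control"]

        gated = gate_timecourse_events(
            events,
            percentile=float(spec.get("percentile", 99.9)),
            viability_multiple=float(spec.get("viability_multiple", 4.0)),
        )
        timecourse = build_timecourse(gated)
        gated.to_csv(out_dir / "flow_gated.csv", index=False)
        timecourse.to_csv(out_dir / "flow_timecourse.csv", index=False)

        out: Dict = {"timecourse": timecourse.to_dict(orient="records")}
        day = spec.get("summary_day")
        if day is not None:
            ref_cond = spec.get("summary_reference")
            trt_cond = spec.get("summary_treated")
            sel = timecourse.set_index(["condition", "day"])["mean_positive_fraction"]
            ref = float(sel[(ref_cond, float(day))])
            trt = float(sel[(trt_cond, float(day))])
            out["summary"] = {
                "day": float(day),
                "reference_condition": ref_cond,
                "treated_condition": trt_cond,
                "reference_pct": ref,
                "treated_pct": trt,
                "percent_reduction": percent_reduction(ref, trt),
                "fold_change": fold_change(ref, trt),
            }
        return out
    except CycleKinError as exc:
        raise StageError("flow", str(exc)) from exc
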
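"""End-to-end study orchestration: simulate → episodes → agreement → burden → power.

A study is described by a small config (YAML on disk or a plain dict)
with five sections; omitted sections take the defaults below, which
are the thresholds and conventions of the evaluation protocol
(MAP < 65 mmHg ≥ 1 min, HPI ≥ 85 for ≥ 2 records, 15-min prediction
window, CAD ±1 L·min⁻¹ / ±200 dynes·s·cm⁻⁵)::

    seed: 7
    synth: {}                # SynthConfig fields
    episodes:
      map_threshold: 65.0
      hpi_threshold: 85.0
      window_min: 15.0
    agreement:
      n_boot: 1000
      tolerance_pct: 20.0
      sd_method: anova
      gee_link: identity
      cad: {CO: 1.0, SVR: 200.0}
    burden:
      thresholds: [65.0, 60.0, 55.0]
    power:
      scenarios:
        - {label: CO, n_pairs: 125, true_mean_diff: 0.0, true_sd: 0.4, cad: 1.0}
        - {label: SVR, n_pairs: 122, true_mean_diff: 0.0, true_sd: 81.0, cad: 200.0}
      n_sims: 10000

The report is deterministic given the seed; every number in the
rendered text is a field of a component report.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import yaml

from hemoval import __version__
from hemoval.agreement import agreement_report
from hemoval.burden import cohort_burden
from hemoval.episodes import evaluate_prediction
from hemoval.io import DEFAULT_CAD, write_pairs, write_series
from hemoval.power import PowerSpec, agreement_power
from hemoval.synth import SynthConfig, simulate_cohort

logger = logging.getLogger(__name__)

DEFAULT_STUDY_CONFIG: dict = {
    "seed": 7,
    "synth": {},
    "episodes": {"map_threshold": 65.0, "hpi_threshold": 85.0, "window_min": 15.0},
    "agreement": {
        "n_boot": 1000,
        "tolerance_pct": 20.0,
        "sd_method": "anova",
        "gee_link": "identity",
        "cad": dict(DEFAULT_CAD),
    },
    "burden": {"thresholds": [65.0, 60.0, 55.0]},
    "power": {
        "scenarios": [
            {"label": "CO", "n_pairs": 125, "true_mean_diff": 0.0, "true_sd": 0.4, "cad": 1.0},
            {"label": "SVR", "n_pairs": 122, "true_mean_diff": 0.0, "true_sd": 81.0, "cad": 200.0},
        ],
        "n_sims": 10_000,
    },
}


def default_study_config() -> dict:
    return copy.deepcopy(DEFAULT_STUDY_CONFIG)


def load_study_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_study_config(user)


def merge_study_config(user: dict) -> dict:
    cfg = default_study_config()
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown study-config sections: {sorted(unknown)}")
    for key, val in user.items():
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            bad = set(val) - set(cfg[key]) if key != "synth" else set()
            if bad:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(bad)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_study(
    config: Optional[dict] = None,
    out_dir=None,
    seed: Optional[int] = None,
) -> dict:
    """Run the full synthetic study and return the consolidated report.

    ``seed`` overrides the config seed. When ``out_dir`` is given, the
    intermediate artifacts (series.csv, pairs.csv), the resolved
    config, report.json and report.txt are written there.
    """
    cfg = merge_study_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    base_seed = int(cfg["seed"])

    synth_cfg = SynthConfig.from_dict({**cfg["synth"], "seed": base_seed})
    logger.info(
        "conventions: MAP<%.0f mmHg >=1 min; HPI>=%.0f for >=2 records; "
        "%.0f-min window; CAD %s",
        cfg["episodes"]["map_threshold"],
        cfg["episodes"]["hpi_threshold"],
        cfg["episodes"]["window_min"],
        cfg["agreement"]["cad"],
    )
    cohort = simulate_cohort(synth_cfg)

    perf, _ = evaluate_prediction(
        cohort.series,
        map_threshold=cfg["episodes"]["map_threshold"],
        hpi_threshold=cfg["episodes"]["hpi_threshold"],
        window_s=cfg["episodes"]["window_min"] * 60.0,
    )

    agreement = {}
    for i, variable in enumerate(sorted(synth_cfg.variables)):
        try:
            rep = agreement_report(
                cohort.pairs,
                variable,
                cad=cfg["agreement"]["cad"].get(variable),
                n_boot=cfg["agreement"]["n_boot"],
                seed=base_seed + 1000 + i,
                tolerance_pct=cfg["agreement"]["tolerance_pct"],
                sd_method=cfg["agreement"]["sd_method"],
                gee_link=cfg["agreement"]["gee_link"],
            )
            agreement[variable] = rep.to_dict()
        except ValueError as exc:
            # e.g. a single-patient cohort: clustered statistics undefined
            warnings.warn(f"agreement for {variable} skipped: {exc}")
            agreement[variable] = {"variable": variable, "error": str(exc)}

    burden = cohort_burden(cohort.series, cfg["burden"]["thresholds"])

    power = []
    for j, sc in enumerate(cfg["power"]["scenarios"]):
        spec = PowerSpec(
            n_pairs=int(sc["n_pairs"]),
            true_mean_diff=float(sc.get("true_mean_diff", 0.0)),
            true_sd=float(sc["true_sd"]),
            cad=float(sc["cad"]),
            n_sims=int(cfg["power"]["n_sims"]),
            seed=base_seed + 2000 + j,
        )
        res = agreement_power(spec)
        power.append({"label": sc.get("label", f"scenario{j}"), **res.to_dict()})

    report = {
        "version": __version__,
        "seed": base_seed,
        "config": cfg,
        "prediction": perf.to_dict(),
        "agreement": agreement,
        "burden": burden,
        "power": power,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_series(cohort.series, out / "series.csv")
        write_pairs(cohort.pairs, out / "pairs.csv")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        (out / "report.txt").write_text(render_report(report))
    return report


def _fmt_ci(ci) -> str:
    return f"({ci[0]:.2f}, {ci[1]:.2f})" if ci else "n/a"


def render_report(report: dict) -> str:
    """Human-readable study summary; every number maps to a report field."""
    lines = [
        f"hemoval study report (version {report['version']}, seed {report['seed']})",
        "",
        "Prediction performance",
        "----------------------",
    ]
    p = report["prediction"]
    lines += [
        f"hypotension episodes: {p['n_hypotension']}  predicted: {p['n_predicted']}",
        f"alert segments: {p['n_alerts']}  true: {p['n_true_alerts']}  "
        f"false: {p['n_false_alerts']}  ignored: {p['n_ignored_alerts']}",
    ]
    if p["sensitivity"] is not None:
        lines.append(
            f"sensitivity: {p['sensitivity']:.2f} "
            f"{_fmt_ci(p['sensitivity_ci'])}"
        )
    if p["ppv"] is not None:
        lines.append(f"PPV: {p['ppv']:.2f} {_fmt_ci(p['ppv_ci'])}")
    if p["time_to_hypotension_median_s"] is not None:
        q = p["time_to_hypotension_quartiles_s"]
        lines.append(
            "time to hypotension (min): median "
            f"{p['time_to_hypotension_median_s'] / 60:.1f} "
            f"[{q[0] / 60:.1f}, {q[1] / 60:.1f}]"
        )
    lines += ["", "Agreement", "---------"]
    for var, a in report["agreement"].items():
        if "error" in a:
            lines.append(f"{var}: not computed ({a['error']})")
            continue
        dp = 2 if var == "CO" else 0
        lines += [
            f"{var} (n={a['n_pairs']} pairs, {a['n_patients']} patients, "
            f"CAD ±{a['cad']:g}):",
            f"  bias {a['bias']:.{dp}f} ± {a['sd']:.{dp}f}; "
            f"LOA [{a['loa_lower']:.{dp}f}, {a['loa_upper']:.{dp}f}]",
            f"  LOA CIs: lower ({a['loa_lower_ci'][0]:.{dp}f}, "
            f"{a['loa_lower_ci'][1]:.{dp}f}), upper ({a['loa_upper_ci'][0]:.{dp}f}, "
            f"{a['loa_upper_ci'][1]:.{dp}f})",
            f"  CCC {a['ccc']:.2f} {_fmt_ci(a['ccc_ci'])}; "
            f"proportion <20% diff {a['prop_within']:.2f} {_fmt_ci(a['prop_ci'])}",
            f"  agrees within CAD: point {a['agrees_point']}, CI {a['agrees_ci']}",
        ]
    lines += ["", "Hypotension burden (cohort median [Q1, Q3])", "-" * 43]
    for tau, stats in report["burden"]["cohort"].items():
        mb, auc, twa = stats["minutes_below"], stats["auc"], stats["twa"]
        lines.append(
            f"  MAP < {float(tau):g} mmHg: {mb['median']:.0f} "
            f"[{mb['q1']:.0f}, {mb['q3']:.0f}] min; "
            f"AUC {auc['median']:.0f} [{auc['q1']:.0f}, {auc['q3']:.0f}] mmHg·min; "
            f"TWA {twa['median']:.2f} [{twa['q1']:.2f}, {twa['q3']:.2f}] mmHg"
        )
    lines += ["", "Power to conclude agreement", "---------------------------"]
    for sc in report["power"]:
        lines.append(
            f"  {sc['label']}: power {sc['power']:.3f} "
            f"(MC SE {sc['mc_se']:.3f}, {sc['n_sims']} sims, "
            f"criterion {sc['criterion']}/{sc['ci_method']})"
        )
    return "\n".join(lines) + "\n"
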
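"""Simulate -> analyze -> report orchestration.

``run_study`` drives the full workflow on a synthetic study: generate
each modality, run the DWI regional statistics, the per-subject
permeability screen, the connectivity graph comparison and the behaviour
metrics, then write a summary mirroring the study's results structure
(regional DWI stats, permeability calls per group, network metrics per
group).  All thresholds (q = 0.1, raw p = 0.05, |Z| = 2.3, band
0.01-0.1 Hz) are config keys with the protocol defaults, and every output
is written at fixed precision so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from . import bbb as bbb_mod
from . import connectivity as conn_mod
from . import dwi as dwi_mod
from .core import extract_region_series, write_volume
from .simulate import (
    SimulationConfig,
    blood_label_of,
    make_phantom_atlas,
    simulate_behavior_tracks,
    simulate_bold_study,
    simulate_dwi_study,
    simulate_qutece_study,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "dwi", "bbb", "connectivity", "behavior", "report")

ANALYSIS_DEFAULTS = {
    "fdr_q": 0.1,
    "p_raw": 0.05,
    "z_threshold": 2.3,
    "band_hz": [0.01, 0.1],
    "knn_k": 3,
}

_FLOAT_FMT = "%.10g"


def load_config(path: str | Path) -> tuple[SimulationConfig, dict]:
    """Read a YAML config with ``simulation`` and ``analysis`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.get("simulation", {})
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(sim) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    for key in ("grid_shape", "post_contrast_scan_times_s", "affected_groups_bold"):
        if key in sim and isinstance(sim[key], list):
            sim[key] = tuple(sim[key])
    config = SimulationConfig(**sim)
    analysis = {**ANALYSIS_DEFAULTS, **raw.get("analysis", {})}
    return config, analysis


def config_hash(config: SimulationConfig, analysis: dict) -> str:
    payload = json.dumps(
        {"simulation": dataclasses.asdict(config), "analysis": analysis},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_study(
    config: SimulationConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    analysis: dict | None = None,
    write_volumes: bool = False,
) -> dict:
    """Run the requested stages on one synthetic study.

    Returns a result dictionary with the per-stage tables; files go under
    ``out_dir/<stage>/``.  ``report`` requires the analysis stages it
    summarises to have been run in the same call.
    """
    analysis = {**ANALYSIS_DEFAULTS, **(analysis or {})}
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config, "analysis": analysis}
    atlas = make_phantom_atlas(config)
    results["atlas"] = atlas
    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config, analysis),
        "subjects": config.subjects.to_dict(orient="records"),
        "stages": list(stages),
        "files": {},
    }

    if "simulate" in stages:
        sim_dir = out / "simulate"
        sim_dir.mkdir(parents=True, exist_ok=True)
        write_volume(atlas, sim_dir / "atlas.nii.gz")
        manifest["files"]["atlas"] = str(sim_dir / "atlas.nii.gz")

    analysis_needed = set(stages) & {"dwi", "bbb", "connectivity", "behavior", "report"}
    if analysis_needed and "simulate" not in stages:
        raise ValueError(
            "missing inputs for stages "
            f"{sorted(analysis_needed)}: run the 'simulate' stage in the same "
            "call (this pipeline analyses in-memory synthetic studies)"
        )

    if "dwi" in stages or "report" in stages:
        study = simulate_dwi_study(config, atlas)
        regionals = []
        for sid in study.subjects["subject_id"]:
            regional, _, _ = dwi_mod.dwi_study_scalars(
                study.volumes[sid], study.btable, atlas, subject_id=sid
            )
            regionals.append(regional)
        regional = pd.concat(regionals, ignore_index=True)
        regional = regional.merge(study.subjects, on="subject_id")
        regional = regional[regional["region_group"] != "blood"]
        stats_adc = dwi_mod.compare_regions_nonparametric(regional, value="mean_adc")
        stats_fa = dwi_mod.compare_regions_nonparametric(regional, value="mean_fa")
        stats_adc.insert(0, "metric", "adc")
        stats_fa.insert(0, "metric", "fa")
        dwi_stats = pd.concat([stats_adc, stats_fa], ignore_index=True)
        results["dwi_regional"] = regional
        results["dwi_stats"] = dwi_stats
        _write_csv(regional, out / "dwi" / "regional_scalars.csv")
        _write_csv(dwi_stats, out / "dwi" / "group_stats.csv")
        if write_volumes and "simulate" in stages:
            study.btable.save_fsl(out / "simulate" / "dwi")
            for sid in study.subjects["subject_id"]:
                write_volume(study.volumes[sid], out / "simulate" / f"dwi_{sid}.nii.gz")

    if "bbb" in stages or "report" in stages:
        study = simulate_qutece_study(config, atlas)
        blood = blood_label_of(atlas)
        tables = []
        for sid in study.subjects["subject_id"]:
            pre_series = extract_region_series(study.pre[sid], atlas, subject_id=sid)
            post_series = [
                extract_region_series(vol, atlas, subject_id=sid)
                for vol in study.post[sid]
            ]
            tables.append(
                bbb_mod.regional_qcbv_table(
                    pre_series, post_series, study.scan_times_s, blood, subject_id=sid
                )
            )
        qcbv = pd.concat(tables, ignore_index=True)
        qcbv = qcbv.merge(study.subjects, on="subject_id")
        calls, summary = bbb_mod.subject_permeability_screen(
            qcbv, q=analysis["fdr_q"], p_raw=analysis["p_raw"]
        )
        group_tests = bbb_mod.group_cbv_ttests(
            qcbv, q=analysis["fdr_q"], p_raw=analysis["p_raw"]
        )
        results["qcbv"] = qcbv
        results["bbb_calls"] = calls
        results["bbb_summary"] = summary
        results["bbb_group_tests"] = group_tests
        _write_csv(qcbv, out / "bbb" / "qcbv_timecourses.csv")
        _write_csv(calls, out / "bbb" / "permeability_calls.csv")
        _write_csv(summary, out / "bbb" / "group_summary.csv")
        _write_csv(group_tests, out / "bbb" / "group_cbv_ttests.csv")

    if "connectivity" in stages or "report" in stages:
        study = simulate_bold_study(config, atlas)
        lo, hi = analysis["band_hz"]
        z_by_group: dict[str, list] = {"sham": [], "impacted": []}
        for _, subj in study.subjects.iterrows():
            sid, group = subj["subject_id"], subj["group"]
            sig = study.signals[sid]
            resid = conn_mod.preprocess_timeseries(
                sig.to_numpy(),
                tr_s=config.tr_s,
                nuisance=study.nuisance[sid].to_numpy(),
                band_hz=(lo, hi),
            )
            _, z = conn_mod.pearson_fisher_matrix(
                resid, labels=np.asarray(sig.columns)
            )
            z_by_group[group].append(z)
        metrics_rows = []
        degrees = {}
        group_z_mats = {}
        for group, mats in z_by_group.items():
            gz, _ = conn_mod.group_edge_z(mats)
            group_z_mats[group] = gz
            binary = conn_mod.threshold_binarize(gz, zthr=analysis["z_threshold"])
            metrics = conn_mod.network_metrics(binary)
            degrees[group] = conn_mod.degree_table(binary, weights=gz)
            metrics_rows.append(
                {
                    "group": group,
                    "n_nodes": metrics.n_nodes,
                    "n_edges": metrics.n_edges,
                    "average_degree": metrics.average_degree,
                    "density": metrics.density,
                    "average_path_length": metrics.average_path_length,
                }
            )
            _write_csv(
                gz.to_edge_list(), out / "connectivity" / f"group_z_{group}.csv"
            )
        regions = atlas.regions[atlas.regions["region_group"] != "blood"]
        regional_tests, global_test = conn_mod.compare_degree_by_region(
            degrees["sham"], degrees["impacted"], regions, labels=("sham", "impacted")
        )
        metrics_df = pd.DataFrame(metrics_rows)
        results["network_metrics"] = metrics_df
        results["degree_tables"] = degrees
        results["group_z"] = group_z_mats
        results["degree_regional_tests"] = regional_tests
        results["degree_global_test"] = global_test
        _write_csv(metrics_df, out / "connectivity" / "network_metrics.csv")
        _write_csv(regional_tests, out / "connectivity" / "degree_region_tests.csv")
        for group, table in degrees.items():
            _write_csv(table, out / "connectivity" / f"degree_{group}.csv")

    if "behavior" in stages or "report" in stages:
        study = simulate_behavior_tracks(config)
        arena = behavior_mod.ArenaConfig(
            width_cm=config.arena_width_cm, height_cm=config.arena_height_cm
        )
        rows = []
        for _, subj in study.subjects.iterrows():
            sid = subj["subject_id"]
            metrics = behavior_mod.open_field_metrics(study.tracks[sid], arena)
            rows.append({"subject_id": sid, "group": subj["group"], **metrics})
        open_field = pd.DataFrame(rows)
        ir_table, nor_stats = behavior_mod.nor_investigation(study.contacts)
        results["open_field"] = open_field
        results["nor_ir"] = ir_table
        results["nor_stats"] = nor_stats
        _write_csv(open_field, out / "behavior" / "open_field.csv")
        _write_csv(ir_table, out / "behavior" / "nor_ir.csv")
        _write_csv(nor_stats, out / "behavior" / "nor_stats.csv")

    if "report" in stages:
        report_rows = []
        for _, row in results["bbb_summary"].iterrows():
            report_rows.append(
                {
                    "section": "bbb",
                    "item": f"subjects_with_permeability_call_{row['group']}",
                    "value": row["subjects_with_call"],
                }
            )
        for _, row in results["network_metrics"].iterrows():
            for key in ("average_degree", "density", "average_path_length"):
                report_rows.append(
                    {
                        "section": "connectivity",
                        "item": f"{key}_{row['group']}",
                        "value": row[key],
                    }
                )
        for _, row in results["dwi_stats"].iterrows():
            report_rows.append(
                {
                    "section": "dwi",
                    "item": f"{row['metric']}_{row['region_group']}_kw_p",
                    "value": row["kw_p"],
                }
            )
        report = pd.DataFrame(report_rows)
        results["report"] = report
        _write_csv(report, out / "report" / "summary.csv")
        from . import __version__

        run_log = {
            "tool_version": __version__,
            "seed": config.seed,
            "config_hash": manifest["config_hash"],
        }
        (out / "report").mkdir(parents=True, exist_ok=True)
        (out / "report" / "run_log.json").write_text(
            json.dumps(run_log, indent=2, sort_keys=True)
        )

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return results
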
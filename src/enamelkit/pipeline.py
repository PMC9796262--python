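"""Stage orchestration: bind the analysis stages into one reproducible run.

A RunConfig names the stages to execute, per-stage parameters, a seed and
an output directory.  Stages run in dependency order and contribute blocks
to a single JSON report (chronology, element summaries, event table, EDX
table); rasters and tables are written next to it.  A fixed config + seed
yields a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import casestudy
from .chronology import (RetziusRecord, CrownChronology, cuspal_time,
                         dsr_profile, lateral_time, periodicity,
                         spacing_table_to_measurements, total_crown_time)
from .edx import layer_summary, ratios_from_means
from .events import detect_events, time_events
from .io import extract_transect, read_transect_csv, write_element_map
from .raman import metric_maps
from .sxrf import MatrixModel, calibrate_sensitivity, denoise_map, \
    phase_summary, quantify_map
from .synthetic import SectionConfig, forward_xrf_counts, \
    generate_foil_standards, generate_section

__version__ = "0.1.0"
log = logging.getLogger("enamelkit")

STAGES = ("simulate", "chronology", "events", "sxrf", "raman", "edx",
          "worked-example")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    stages: tuple[str, ...]
    output_dir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        self.stages = tuple(self.stages)
        if not self.stages:
            raise ValueError("at least one stage must be requested")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; known: {STAGES}")
        for stage, p in self.params.items():
            for key, val in p.items():
                if key.endswith(("_csv", "_path", "_tif")) and \
                        not Path(val).exists():
                    raise ValueError(f"{stage}.{key}: file {val} not found")

    def hash(self) -> str:
        blob = json.dumps(
            {"stages": list(self.stages), "seed": self.seed,
             "params": self.params}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_simulate(cfg: RunConfig, ctx: dict, report: dict) -> None:
    p = dict(cfg.params.get("simulate", {}))
    p.setdefault("seed", cfg.seed)
    section = generate_section(SectionConfig(**p))
    ctx["section"] = section
    out = cfg.output_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    for name, tbl in section.tables.items():
        tbl.to_csv(out / f"{name}.csv", index=False)
    for el, emap in section.element_maps.items():
        write_element_map(emap, out / f"{el}.tif")
    report["simulate"] = {
        "n_events": len(section.ground_truth.event_days),
        "total_cuspal_days_analytic":
            round(section.ground_truth.total_cuspal_days_analytic, 2),
        "chronology_truth": section.ground_truth.chronology.to_dict(),
    }


def _stage_chronology(cfg: RunConfig, ctx: dict, report: dict) -> None:
    p = cfg.params.get("chronology", {})
    if "spacing_csv" in p:
        spacing = pd.read_csv(p["spacing_csv"])
        deciles = pd.read_csv(p["deciles_csv"])
        period_counts = tuple(p["periodicity_counts"])
        cuspal_thickness = p["cuspal_thickness_um"]
        d12_len = p["deciles12_length_um"]
        d12_dsr = p["deciles12_local_dsr"]
    elif "section" in ctx:
        section = ctx["section"]
        spacing = section.tables["spacing"]
        deciles = section.tables["deciles"]
        period_counts = tuple(
            section.tables["periodicity"]["crossings_between_striae"])
        scfg = section.config
        cuspal_thickness = scfg.cuspal_thickness_um
        d12_len = scfg.deciles12_length_um
        d12_dsr = scfg.dsr_inner
    else:
        raise PipelineError("chronology: no spacing_csv and no simulate stage")
    zone_width = p.get("zone_width_um", 100.0)
    profile = dsr_profile(spacing_table_to_measurements(spacing), zone_width)
    cuspal = cuspal_time(cuspal_thickness, profile)
    per = periodicity(list(period_counts))
    record = RetziusRecord(
        periodicity_days=per.days, periodicity_counts=per.counts,
        decile_stria_counts=tuple(deciles["stria_count"]),
        deciles12_prism_length_um=d12_len, deciles12_local_dsr=d12_dsr)
    d12, per_decile, _lateral = lateral_time(record)
    chron = total_crown_time(cuspal.days, d12, per_decile)
    ctx["dsr_profile"] = profile
    ctx["chronology"] = chron
    report["chronology"] = {
        **chron.to_dict(),
        "mean_cuspal_dsr_um_day": round(cuspal.mean_dsr, 3),
        "periodicity_days": per.days,
        "periodicity_unanimous": per.unanimous,
        "zone_dsr_um_day": [round(r, 4) for r in profile.rates],
    }


def _stage_events(cfg: RunConfig, ctx: dict, report: dict) -> None:
    p = cfg.params.get("events", {})
    if "transect_csv" in p:
        profile = read_transect_csv(p["transect_csv"])
    elif "section" in ctx:
        profile = ctx["section"].midline_transect("Sr")
    else:
        raise PipelineError("events: no transect_csv and no simulate stage")
    if "dsr_profile" not in ctx:
        raise PipelineError("events stage requires the chronology stage")
    evs = detect_events(
        profile,
        baseline_window_um=p.get("baseline_window_um", 400.0),
        k_threshold=p.get("k_threshold", 3.0))
    timeline = time_events(evs, ctx["dsr_profile"],
                           cv_threshold=p.get("cv_threshold", 0.25),
                           seed=cfg.seed)
    rows = [{
        "label": e.label, "kind": e.kind,
        "start_um": round(e.start_um, 2), "end_um": round(e.end_um, 2),
        "onset_day": round(e.onset_day, 1), "end_day": round(e.end_day, 1),
        "duration_days": round(e.duration_days, 1),
        "peak_ppm": round(e.peak_ppm, 1),
    } for e in timeline.events]
    out = cfg.output_dir / "events.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    report["events"] = {
        "table": rows,
        "inter_onset_days": [round(v, 1) for v in timeline.inter_onset_days],
        "cv": None if timeline.cv is None else round(timeline.cv, 3),
        "verdict": timeline.verdict,
    }


def _stage_sxrf(cfg: RunConfig, ctx: dict, report: dict) -> None:
    p = cfg.params.get("sxrf", {})
    sens_truth = p.get("sensitivity_truth", {"Ti": 2.0, "Fe": 2.0, "Cu": 2.0,
                                             "Ca": 2.0, "Zn": 2.0, "Sr": 2.0})
    foils = generate_foil_standards(sensitivity_truth=sens_truth,
                                    seed=cfg.seed)
    curve = calibrate_sensitivity(foils)
    matrix = MatrixModel(
        thickness_um=p.get("thickness_um",
                           casestudy.SECTION_THICKNESS_UM["HELIX"]))
    if "section" not in ctx:
        raise PipelineError("sxrf stage currently runs on simulated sections")
    section = ctx["section"]
    out = cfg.output_dir / "sxrf"
    out.mkdir(parents=True, exist_ok=True)
    block = {}
    for el, ppm_truth in section.element_maps.items():
        counts = forward_xrf_counts(ppm_truth, sens_truth[el], matrix)
        smoothed = denoise_map(counts, kernel_sigma=p.get("kernel_sigma", 0.8))
        ppm_map, areal_map, info = quantify_map(smoothed, curve, matrix)
        write_element_map(ppm_map, out / f"{el}_ppm.tif",
                          extra_meta={"seed": cfg.seed})
        block[el] = {
            "phase_summary_ppm": phase_summary(ppm_map),
            "sensitivity": round(info["sensitivity"], 6),
            "sensitivity_extrapolated": info["sensitivity_extrapolated"],
        }
    report["sxrf"] = block


def _stage_raman(cfg: RunConfig, ctx: dict, report: dict) -> None:
    if "section" not in ctx:
        raise PipelineError("raman stage currently runs on simulated sections")
    rmap = ctx["section"].raman_map
    metrics = metric_maps(rmap)
    out = cfg.output_dir / "raman"
    out.mkdir(parents=True, exist_ok=True)
    import tifffile

    from .raman import render_metric_map
    for name in ("FWHM960", "I1070_over_I960"):
        tifffile.imwrite(out / f"{name}.tif",
                         metrics[name].astype(np.float32))
        pd.DataFrame(metrics[name]).to_csv(out / f"{name}.csv", index=False)
        render_metric_map(metrics[name], str(out / f"{name}.png"),
                          metric=name, step_um=rmap.step_um)
    block = {"settings": {"profile": "pseudo-Voigt, center imposed",
                          "baseline": "linear through flanking anchors",
                          "phosphate_window_cm1": [930.0, 990.0],
                          "carbonate_window_cm1": [1050.0, 1090.0]}}
    for phase_code, phase in ((1, "enamel"), (2, "dentin")):
        sel = rmap.phase_mask == phase_code
        block[phase] = {
            "FWHM960_mean": round(float(np.nanmean(metrics["FWHM960"][sel])), 3),
            "I1070_over_I960_mean":
                round(float(np.nanmean(metrics["I1070_over_I960"][sel])), 4),
        }
    report["raman"] = block


def _stage_edx(cfg: RunConfig, ctx: dict, report: dict) -> None:
    p = cfg.params.get("edx", {})
    if "measurements_csv" not in p:
        raise PipelineError("edx stage requires measurements_csv")
    table = layer_summary(pd.read_csv(p["measurements_csv"]))
    table.to_csv(cfg.output_dir / "edx_summary.csv", index=False)
    report["edx"] = table.to_dict(orient="records")


def _stage_worked_example(cfg: RunConfig, ctx: dict, report: dict) -> None:
    """Replicate the published case-study numbers from the printed inputs."""
    per = periodicity(list(casestudy.PERIODICITY_COUNTS))
    record = RetziusRecord(
        periodicity_days=per.days, periodicity_counts=per.counts,
        decile_stria_counts=casestudy.DECILE_STRIA_COUNTS,
        deciles12_prism_length_um=casestudy.DECILES12_PRISM_LENGTH_UM,
        deciles12_local_dsr=casestudy.DECILES12_LOCAL_DSR)
    d12, per_decile, lateral = lateral_time(record)
    chron = CrownChronology(cuspal_days=casestudy.CUSPAL_DAYS,
                            deciles12_days=d12,
                            per_decile_days=per_decile)
    edx_rows = []
    for r in casestudy.EDX_LAYER_MEANS.itertuples():
        ratios = ratios_from_means(r.P, r.Ca, r.Mg)
        edx_rows.append({"specimen": r.specimen, "layer": r.layer,
                         "Ca_P": round(ratios["Ca_P"], 2),
                         "CaMg_P": round(ratios["CaMg_P"], 2)})
    report["worked_example"] = {
        "chronology": {
            **chron.to_dict(),
            "periodicity_days": per.days,
            "lateral_decile_days_3_10": lateral - d12,
        },
        "edx_ratios": edx_rows,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "chronology": _stage_chronology,
    "events": _stage_events,
    "sxrf": _stage_sxrf,
    "raman": _stage_raman,
    "edx": _stage_edx,
    "worked-example": _stage_worked_example,
}

# dependency order regardless of requested order
_ORDER = {s: i for i, s in enumerate(STAGES)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write ``report.json``.

    On stage failure a manifest of completed stages is retained and
    PipelineError is raised.
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
            "stages": list(config.stages),
        }
    }
    ctx: dict = {}
    completed = []
    for stage in sorted(config.stages, key=_ORDER.__getitem__):
        t0 = time.perf_counter()
        log.info("stage %s: start (params=%s)", stage,
                 config.params.get(stage, {}))
        try:
            _STAGE_FUNCS[stage](config, ctx, report)
        except Exception as exc:
            manifest = {"completed": completed, "failed": stage,
                        "error": str(exc)}
            (config.output_dir / "manifest.json").write_text(
                json.dumps(manifest, indent=2))
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
        completed.append(stage)
    text = json.dumps(report, indent=2, sort_keys=True)
    (config.output_dir / "report.json").write_text(text)
    (config.output_dir / "manifest.json").write_text(
        json.dumps({"completed": completed, "failed": None}, indent=2))
    return report
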
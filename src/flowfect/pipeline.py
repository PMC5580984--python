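"""End-to-end orchestration from a declarative run configuration.

A run config (YAML or JSON) lists sample files with assay ids and
timepoints, the three control files, the channel role map, gate and
threshold parameters, an optional plasmid description and an optional MESF
bead kit.  ``run_pipeline`` validates everything up front (listing all
problems before aborting), computes per-sample transfection and toxicity
readouts — quarantining samples that fail individually — and, when the
manifest declares assays or timepoints, adds the study-level block:
time-course peaks, inter-assay CV tables and readout correlations.

Reports are plain JSON with every tunable default echoed back; re-running
an identical config on identical inputs reproduces the report bit-for-bit
except for the timestamp.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, FlowfectError
from .event_io import EventTable, read_events
from .mesf import (BeadCalibration, BeadSet, PlasmidSpec, calibrate_beads,
                   labels_per_plasmid, plasmids_per_cell)
from .readouts import (ControlSet, PipelineParams, ToxicityReadout,
                       TransfectionReadout, toxicity_readout,
                       transfection_readouts)
from .study_stats import (AssayMatrix, TimeCourse, correlate_readouts,
                          interassay_cv, timecourse_peaks)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1
CV_READOUTS = ("mesf_dna", "pct_dna_pos", "pct_protein_pos", "dmfi_protein")


@dataclass
class SampleEntry:
    sample_id: str
    path: str
    timepoint_h: float | None = None
    assay: str | None = None
    group: str | None = None
    condition: str | None = None


@dataclass
class RunConfig:
    """Validated run configuration."""

    samples: list[SampleEntry]
    controls: dict[str, str]
    role_map: dict[str, str]
    params: PipelineParams = field(default_factory=PipelineParams)
    plasmid: PlasmidSpec | None = None
    bead_kit: str | None = None
    beads_file: str | None = None
    seed: int = 0
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        problems: list[str] = []
        base_dir = base_dir or Path()
        samples = []
        for i, s in enumerate(raw.get("samples", [])):
            if "path" not in s:
                problems.append(f"samples[{i}]: missing 'path'")
                continue
            samples.append(SampleEntry(
                sample_id=str(s.get("id", Path(s["path"]).stem)),
                path=s["path"],
                timepoint_h=(float(s["timepoint_h"])
                             if s.get("timepoint_h") is not None else None),
                assay=s.get("assay"), group=s.get("group"),
                condition=s.get("condition")))
        if not samples:
            problems.append("no samples declared")
        controls = dict(raw.get("controls", {}))
        for name in ("untransfected", "unlabeled_plasmid", "zero_timepoint"):
            if name not in controls:
                problems.append(f"missing control entry: {name}")
        role_map = dict(raw.get("role_map", {}))
        if not role_map:
            problems.append("missing role_map")
        dna_ch = next((k for k, v in role_map.items() if v == "dna_label"), None)
        prot_ch = next((k for k, v in role_map.items() if v == "protein"), None)
        if dna_ch and prot_ch and (
                dna_ch == prot_ch or "fitc" in prot_ch.lower()):
            problems.append(
                "role map assigns FITC-adjacent detectors to both readouts; "
                "spectral overlap between the DNA and protein channels is not "
                "supported (no compensation is applied)")
        params = PipelineParams(**raw.get("gating", {}))
        plasmid = None
        if raw.get("plasmid"):
            p = raw["plasmid"]
            plasmid = PlasmidSpec(name=p.get("name", "plasmid"),
                                  length_bp=int(p["length_bp"]),
                                  bp_per_label=float(p.get("bp_per_label", 40.0)))
        for name, rel in controls.items():
            if not (base_dir / rel).exists():
                problems.append(f"control {name!r}: file not found: {rel}")
        for s in samples:
            if not (base_dir / s.path).exists():
                problems.append(f"sample {s.sample_id!r}: file not found: {s.path}")
        if problems:
            raise ConfigurationError(
                "invalid run configuration:\n  - " + "\n  - ".join(problems))
        return cls(samples=samples, controls=controls, role_map=role_map,
                   params=params, plasmid=plasmid,
                   bead_kit=raw.get("bead_kit"), beads_file=raw.get("beads_file"),
                   seed=int(raw.get("seed", 0)), base_dir=base_dir)


def load_bead_kit(path) -> dict:
    with open(path) as fh:
        kit = json.load(fh)
    if "known_mesf" not in kit:
        raise ConfigurationError(f"bead kit {path} lacks 'known_mesf'")
    return kit


def calibrate_from_files(beads_path, kit_path, role_map=None) -> BeadCalibration:
    """Read a bead acquisition and kit description; fit the standard curve."""
    kit = load_bead_kit(kit_path)
    table = read_events(beads_path, role_map=role_map, require_scatter=False)
    if not table.has_role("dna_label"):
        # Single-channel bead files: treat the sole channel as the calibrated one.
        if len(table.channels) == 1:
            table.channels[0] = type(table.channels[0])(
                name=table.channels[0].name, role="dna_label")
        else:
            raise ConfigurationError(
                "bead file has several channels; map one to dna_label")
    beads = BeadSet(events=table, known_mesf=kit["known_mesf"],
                    has_blank=bool(kit.get("has_blank", False)))
    return calibrate_beads(beads)


def _readout_value(readout: TransfectionReadout, name: str) -> float:
    v = getattr(readout, name)
    return float("nan") if v is None else float(v)


def _study_block(entries, readouts) -> dict:
    """Time-course, CV and correlation analyses over per-sample readouts."""
    study: dict = {}
    rows = [(e, r) for e, r in zip(entries, readouts) if r is not None]

    # Time courses: per condition (or single implicit condition) when >= 2
    # distinct timepoints exist.
    by_condition: dict[str, list] = {}
    for e, r in rows:
        if e.timepoint_h is not None:
            by_condition.setdefault(e.condition or "all", []).append((e, r))
    peaks = {}
    for cond, pts in by_condition.items():
        pts = sorted(pts, key=lambda er: er[0].timepoint_h)
        times = [e.timepoint_h for e, _ in pts]
        if len(set(times)) >= 2 and len(times) == len(set(times)):
            tc = TimeCourse(points=[(e.timepoint_h, r) for e, r in pts])
            t_dna, t_prot = timecourse_peaks(tc)
            peaks[cond] = {"t_peak_dna_h": t_dna, "t_peak_protein_h": t_prot}
    if peaks:
        study["timecourse_peaks"] = peaks

    # Inter-assay CV: assays x samples matrices per readout.
    with_assay = [(e, r) for e, r in rows if e.assay is not None]
    assays = sorted({e.assay for e, _ in with_assay})
    sample_ids = sorted({e.sample_id for e, _ in with_assay})
    if len(assays) >= 2 and sample_ids:
        cv_block = {}
        for name in CV_READOUTS:
            matrix = np.full((len(assays), len(sample_ids)), np.nan)
            for e, r in with_assay:
                matrix[assays.index(e.assay), sample_ids.index(e.sample_id)] = \
                    _readout_value(r, name)
            if np.isnan(matrix).any():
                continue
            cvs, mean_cv, rng = interassay_cv(AssayMatrix(matrix, name))
            cv_block[name] = {
                "per_sample_cv": {s: None if np.isnan(c) else float(c)
                                  for s, c in zip(sample_ids, cvs)},
                "mean_cv": None if np.isnan(mean_cv) else mean_cv,
                "range": [None if np.isnan(v) else v for v in rng],
            }
        if cv_block:
            study["interassay_cv"] = {"assays": assays,
                                      "samples": sample_ids, "readouts": cv_block}

    # Correlations between % positive and ΔMFI readouts across samples.
    if len(rows) >= 4:
        corr = {}
        pairs = [("pct_dna_pos", "dmfi_dna"), ("pct_protein_pos", "dmfi_protein"),
                 ("dmfi_dna", "dmfi_protein"), ("pct_dna_pos", "pct_protein_pos")]
        for a, b in pairs:
            xs = [_readout_value(r, a) for _, r in rows]
            ys = [_readout_value(r, b) for _, r in rows]
            if np.isfinite(xs).all() and np.isfinite(ys).all() \
                    and np.ptp(xs) > 0 and np.ptp(ys) > 0:
                rho, p = correlate_readouts(xs, ys)
                corr[f"{a}~{b}"] = {"rho": rho, "p": p}
        if corr:
            study["readout_correlations"] = corr
    return study


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a configured run and return the report dictionary."""
    t0 = time.monotonic()
    load = lambda rel: read_events(cfg.base_dir / rel, role_map=cfg.role_map)
    controls = ControlSet(
        untransfected=load(cfg.controls["untransfected"]),
        unlabeled_plasmid=load(cfg.controls["unlabeled_plasmid"]),
        zero_timepoint=load(cfg.controls["zero_timepoint"]))

    calibration = None
    if cfg.beads_file and cfg.bead_kit:
        calibration = calibrate_from_files(cfg.base_dir / cfg.beads_file,
                                           cfg.base_dir / cfg.bead_kit)

    sample_reports: list[dict] = []
    readouts: list[TransfectionReadout | None] = []
    quarantined: list[dict] = []
    for entry in cfg.samples:
        try:
            table = load(entry.path)
            if entry.timepoint_h is not None:
                table.timepoint_h = entry.timepoint_h
            table.sample_id = entry.sample_id
            ro = transfection_readouts(table, controls, cfg.params,
                                       calibration=calibration)
            tox = toxicity_readout(table, controls.untransfected, cfg.params,
                                   dye_reference=controls.zero_timepoint)
            rec = {"sample_id": entry.sample_id, "assay": entry.assay,
                   "group": entry.group, "condition": entry.condition,
                   "dropped_rows": table.n_dropped,
                   "viability_denominator": tox.method,
                   **ro.to_dict(), "toxicity": tox.to_dict()}
            if cfg.plasmid is not None and ro.mesf_dna is not None:
                copies, moles = plasmids_per_cell(ro.mesf_dna, cfg.plasmid)
                rec["plasmid_copies_per_cell"] = copies
                rec["plasmid_moles_per_cell"] = moles
            sample_reports.append(rec)
            readouts.append(ro)
        except FlowfectError as exc:
            logger.error("sample %s quarantined: %s", entry.sample_id, exc)
            quarantined.append({"sample_id": entry.sample_id, "error": str(exc)})
            readouts.append(None)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "flowfect_version": __version__,
        "seed": cfg.seed,
        "parameters": cfg.params.to_dict(),
        "role_map": cfg.role_map,
        "plasmid": (None if cfg.plasmid is None else {
            "name": cfg.plasmid.name, "length_bp": cfg.plasmid.length_bp,
            "bp_per_label": cfg.plasmid.bp_per_label,
            "labels_per_plasmid": labels_per_plasmid(cfg.plasmid)}),
        "calibration": None if calibration is None else calibration.to_dict(),
        "samples": sample_reports,
        "quarantined": quarantined,
    }
    study = _study_block(cfg.samples, readouts)
    if study:
        report["study"] = study
    logger.info("pipeline finished in %.2f s", time.monotonic() - t0)
    return report


def write_report(report: dict, out_dir) -> Path:
    """Serialize report.json plus flat readouts.csv; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamped = dict(report)
    stamped["created_at"] = time.strftime("%Y-%m-%dT%H:%M:%S%z")
    path = out_dir / "report.json"
    with open(path, "w") as fh:
        json.dump(stamped, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    rows = []
    for s in report.get("samples", []):
        flat = {k: v for k, v in s.items() if not isinstance(v, (dict, list))}
        for k, v in s.get("toxicity", {}).items():
            flat[f"tox_{k}"] = v
        rows.append(flat)
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "readouts.csv", index=False)
    if "study" in report:
        with open(out_dir / "study.json", "w") as fh:
            json.dump(report["study"], fh, indent=2, sort_keys=True)
            fh.write("\n")
    return path
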
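"""End-to-end orchestration: simulate -> qc -> linkage -> stratify ->
permute -> power -> variants, with a JSON manifest of every artifact."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import qc as qcmod
from .linkage.scan import EngineConfig, genome_scan
from .pedigree import (Cohort, PedigreeError, estimate_allele_freqs,
                       read_mapfile, read_pedfile)
from .powersim import PowerConfig, estimate_power
from .simulate import CohortSpec, TruthLedger, emit_files, \
    generate_heterogeneity_cohort
from .stratperm import run_stratified_permutation, stratified_scan

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "pedlink_run"
    seed: int = 0
    ped_path: str | None = None        # None -> simulate
    map_path: str | None = None
    flags_path: str | None = None
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    qc_thresholds: qcmod.QCThresholds = field(default_factory=qcmod.QCThresholds)
    engine: EngineConfig = field(default_factory=EngineConfig)
    permutation_reps: int = 100
    power: PowerConfig = field(default_factory=PowerConfig)

    def validate(self) -> None:
        for p in (self.ped_path, self.map_path, self.flags_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if (self.ped_path is None) != (self.map_path is None):
            raise ValueError("ped_path and map_path must be given together")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; halts on the first failing stage with its
    name and cause.  Returns the manifest (also written to manifest.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def stage(name, fn):
        t0 = time.time()
        log.info("[%s] start", name)
        try:
            artifacts = fn() or {}
        except Exception as e:
            manifest["stages"].append({"name": name, "status": "failed",
                                       "error": str(e)})
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
        manifest["stages"].append({"name": name, "status": "ok",
                                   "wall_s": round(time.time() - t0, 3),
                                   "artifacts": artifacts})
        log.info("[%s] done (%.1fs)", name, time.time() - t0)
        return artifacts

    state: dict = {}

    def s_input():
        if config.ped_path is not None:
            mm = read_mapfile(config.map_path)
            cohort = read_pedfile(config.ped_path, mm)
            flags = (pd.read_csv(config.flags_path, sep="\t", index_col=0)
                     if config.flags_path else None)
            truth = None
            paths = {"ped": config.ped_path, "map": config.map_path}
        else:
            spec = config.cohort_spec
            cohort, flags, truth = generate_heterogeneity_cohort(
                spec, seed=config.seed)
            paths = emit_files(cohort, truth, out / "simulated", flags)
        state.update(cohort=cohort, flags=flags, truth=truth)
        return paths

    def s_qc():
        filtered, report = qcmod.snp_filter_cascade(state["cohort"],
                                                    config.qc_thresholds)
        state["cohort"] = filtered
        p = out / "qc_report.tsv"
        report.to_frame().to_csv(p, sep="\t", index=False)
        return {"qc_report": str(p), "surviving_markers": report.n_surviving}

    def s_linkage():
        estimate_allele_freqs(state["cohort"], who="founders")
        tp, mp, tables = genome_scan(state["cohort"], config.engine)
        state["tables"] = tables
        p1, p2 = out / "twopoint.tsv", out / "multipoint.tsv"
        tp.to_csv(p1, sep="\t", index=False)
        mp.to_csv(p2, sep="\t", index=False)
        return {"twopoint": str(p1), "multipoint": str(p2)}

    def s_stratify():
        if state.get("flags") is None:
            return {"skipped": "no clinical flags"}
        res = stratified_scan(state["cohort"], state["flags"], config.engine)
        arts = {}
        for label, (tp, mp, _) in res.items():
            p1 = out / f"stratum_{label}_twopoint.tsv"
            p2 = out / f"stratum_{label}_multipoint.tsv"
            tp.to_csv(p1, sep="\t", index=False)
            mp.to_csv(p2, sep="\t", index=False)
            arts[label] = [str(p1), str(p2)]
        return arts

    def s_permute():
        if state.get("flags") is None:
            return {"skipped": "no clinical flags"}
        dist, _ = run_stratified_permutation(
            state["cohort"], state["flags"], config.engine,
            reps=config.permutation_reps, seed=config.seed)
        p = out / "permutation.tsv"
        dist.to_frame().to_csv(p, sep="\t", index=False)
        return {"permutation": str(p)}

    def s_power():
        pw = dataclasses.replace(config.power, seed=config.seed)
        res = estimate_power(state["cohort"], pw)
        p = out / "power.tsv"
        pd.DataFrame({"max_lod": res.max_lods,
                      "lod_theta001": res.lods_theta001}).to_csv(
            p, sep="\t", index=False)
        return {"power": res.power, "ci95": list(res.ci95), "table": str(p)}

    def s_report():
        p = out / "run_summary.json"
        with open(p, "w") as fh:
            json.dump({"families": len(state["cohort"]),
                       "markers": len(state["cohort"].map)}, fh)
        return {"summary": str(p)}

    stage("input", s_input)
    stage("qc", s_qc)
    stage("linkage", s_linkage)
    stage("stratify", s_stratify)
    stage("permute", s_permute)
    stage("power", s_power)
    stage("report", s_report)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
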
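"""End-to-end pipeline orchestration with caching and provenance.

A single YAML (or dict) config drives: simulate -> preprocess -> dmp ->
dmr -> annotate -> enrich -> score.  Every stage records the digests of
its inputs and its config section in ``run_manifest.json``; a rerun skips
stages whose digest and outputs are unchanged, and recomputes anything
downstream of a change.  The global seed fans out to per-stage seeds by
stable hashing, so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import dmp as dmp_mod
from . import dmr as dmr_mod
from . import io as io_mod
from . import preprocess as pp_mod
from . import score as score_mod
from . import simulate as sim_mod
from .core import AnalysisConfig, MethylationMatrix, ValidationError

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

STAGES = ["simulate", "preprocess", "dmp", "dmr", "annotate", "enrich", "score"]


class ConfigError(ValueError):
    """Raised when the pipeline config fails schema validation."""


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = {
        "seed": int(raw.get("seed", 0)),
        "outdir": str(raw.get("outdir", "methcd8_out")),
        "design": dict(raw.get("design", {})),
        "analysis": dict(raw.get("analysis", {})),
        "contrast": list(raw.get("contrast", ["HC", "Pso"])),
        "paired": bool(raw.get("paired", False)),
        "pathways": dict(raw.get("pathways", {"n_terms": 20})),
        "score": dict(raw.get("score", {})),
    }
    if len(cfg["contrast"]) != 2:
        raise ConfigError("contrast must name exactly two groups")
    try:
        cfg["design"].setdefault("seed", stage_seed(cfg["seed"], "simulate"))
        sim_mod.CohortDesign.from_dict(cfg["design"])
        AnalysisConfig(**cfg["analysis"])
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return cfg


def _digest_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, digest: str, inputs: dict[str, str],
               outputs: list[str], counts: dict, elapsed: float) -> None:
        self.stages[stage] = {
            "digest": digest, "inputs": inputs, "outputs": outputs,
            "counts": counts, "elapsed_s": round(elapsed, 3),
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "config": self.config,
                       "stages": self.stages}, fh, indent=1, default=str)

    @classmethod
    def load(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        m = cls(config=d.get("config", {}), version=d.get("version", "?"))
        m.stages = d.get("stages", {})
        return m


class PipelineRunner:
    """Executes the stage graph with digest-based caching."""

    def __init__(self, config: dict, force: bool = False):
        self.cfg = config
        self.outdir = config["outdir"]
        os.makedirs(self.outdir, exist_ok=True)
        self.manifest_path = os.path.join(self.outdir, "run_manifest.json")
        self.previous = (RunManifest.load(self.manifest_path)
                         if os.path.exists(self.manifest_path) and not force else None)
        self.manifest = RunManifest(config=config)
        self.log_path = os.path.join(self.outdir, "run_log.jsonl")

    # -- helpers ------------------------------------------------------------
    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def _log(self, **event) -> None:
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps({"ts": round(time.time(), 3), **event}) + "\n")

    def _cached(self, stage: str, digest: str, outputs: list[str]) -> bool:
        if self.previous is None:
            return False
        rec = self.previous.stages.get(stage)
        ok = (rec is not None and rec["digest"] == digest
              and all(os.path.exists(self.path(o)) for o in outputs))
        return ok

    def _run_stage(self, stage: str, cfg_part, input_files: list[str],
                   outputs: list[str], fn: Callable[[], dict]) -> None:
        inputs = {}
        for f in input_files:
            p = self.path(f)
            if not os.path.exists(p):
                raise ValidationError(f"stage {stage!r}: missing input file {p}")
            inputs[f] = io_mod.file_digest(p)
        digest = _digest_obj({"cfg": cfg_part, "inputs": inputs,
                              "seed": self.cfg["seed"]})
        if self._cached(stage, digest, outputs):
            rec = dict(self.previous.stages[stage])
            self.manifest.stages[stage] = rec
            self._log(stage=stage, status="cached")
            return
        t0 = time.time()
        counts = fn() or {}
        self.manifest.record(stage, digest, inputs, outputs, counts, time.time() - t0)
        self._log(stage=stage, status="computed", counts=counts,
                  elapsed_s=round(time.time() - t0, 3))

    # -- stages -------------------------------------------------------------
    def run(self) -> RunManifest:
        cfg = self.cfg
        analysis = AnalysisConfig(**cfg["analysis"])
        a_name, b_name = cfg["contrast"]

        def do_simulate() -> dict:
            design = sim_mod.CohortDesign.from_dict(cfg["design"])
            man = sim_mod.generate_manifest(design)
            matrix, sheet, truth = sim_mod.generate_cohort(design, man)
            io_mod.write_manifest(man, self.path("manifest.csv"))
            io_mod.write_beta_matrix(matrix, self.path("beta.csv"))
            io_mod.write_detection_p(matrix, self.path("detection_p.csv"))
            io_mod.write_sample_sheet(sheet, self.path("samples.csv"))
            truth.to_json(self.path("truth.json"))
            io_mod.write_exclusion_list(truth.snp_probe_ids, self.path("snp.txt"))
            io_mod.write_exclusion_list(truth.crossreactive_probe_ids,
                                        self.path("crossreactive.txt"))
            sets = sim_mod.generate_pathway_sets(
                man, int(cfg["pathways"].get("n_terms", 20)),
                include_activity_set=True, activity_genes=truth.activity_genes,
                seed=stage_seed(cfg["seed"], "pathways"))
            io_mod.write_gmt(sets, self.path("pathways.gmt"))
            return {"n_probes": len(man), "n_samples": len(sheet.sample_ids)}

        self._run_stage(
            "simulate", cfg["design"], [],
            ["manifest.csv", "beta.csv", "detection_p.csv", "samples.csv",
             "truth.json", "snp.txt", "crossreactive.txt", "pathways.gmt"],
            do_simulate)

        def do_preprocess() -> dict:
            matrix = io_mod.read_beta_matrix(self.path("beta.csv"),
                                             self.path("detection_p.csv"))
            man = io_mod.read_manifest(self.path("manifest.csv"))
            sheet = io_mod.read_sample_sheet(self.path("samples.csv"))
            snp = io_mod.read_exclusion_list(self.path("snp.txt"))
            xreact = io_mod.read_exclusion_list(self.path("crossreactive.txt"))
            filtered, report = pp_mod.filter_probes(matrix, man, analysis, snp, xreact)
            normalized = pp_mod.normalize_probe_types(filtered, man)
            m = pp_mod.matrix_to_m(normalized)
            batch = sheet.batches().loc[normalized.sample_ids]
            groups = sheet.frame.set_index("sample_id")["group"].loc[normalized.sample_ids]
            if batch.nunique() > 1:
                m = pp_mod.combat_correct(m, batch, groups)
            corrected = MethylationMatrix(
                pd.DataFrame(np.clip(pp_mod.m_to_beta(m.to_numpy()), 0, 1),
                             index=m.index, columns=m.columns))
            io_mod.write_beta_matrix(corrected, self.path("corrected_beta.csv"))
            with open(self.path("filter_report.json"), "w") as fh:
                json.dump(report.to_dict(), fh, indent=1)
            return {"n_retained": report.n_retained}

        self._run_stage(
            "preprocess", cfg["analysis"],
            ["beta.csv", "detection_p.csv", "manifest.csv", "samples.csv",
             "snp.txt", "crossreactive.txt"],
            ["corrected_beta.csv", "filter_report.json"], do_preprocess)

        def _contrast_samples(sheet):
            if cfg["paired"]:
                subjects = sheet.paired_subjects()
                f = sheet.frame.set_index(["subject_id", "timepoint"])
                a = [f.loc[(s, "before"), "sample_id"] for s in subjects]
                b = [f.loc[(s, "after"), "sample_id"] for s in subjects]
                return a, b
            return sheet.samples_in_group(a_name), sheet.samples_in_group(b_name)

        def do_dmp() -> dict:
            matrix = io_mod.read_beta_matrix(self.path("corrected_beta.csv"))
            sheet = io_mod.read_sample_sheet(self.path("samples.csv"))
            sa, sb = _contrast_samples(sheet)
            dmps, table = dmp_mod.dmp_contrast(matrix, sa, sb,
                                               paired=cfg["paired"], config=analysis)
            io_mod.write_dmp_table(dmps, self.path("dmps.tsv"))
            table.to_csv(self.path("dmp_full_stats.tsv"), sep="\t",
                         float_format="%.17g")
            return {"n_dmps": len(dmps)}

        self._run_stage("dmp", {"contrast": cfg["contrast"], "paired": cfg["paired"],
                                "analysis": cfg["analysis"]},
                        ["corrected_beta.csv", "samples.csv"],
                        ["dmps.tsv", "dmp_full_stats.tsv"], do_dmp)

        def do_dmr() -> dict:
            table = pd.read_csv(self.path("dmp_full_stats.tsv"), sep="\t",
                                index_col="probe_id")
            man = io_mod.read_manifest(self.path("manifest.csv"))
            man = man.subset(list(table.index))
            params = dmr_mod.DMRParams(
                lambda_bp=analysis.dmr_lambda, scaling_C=analysis.dmr_scaling_C,
                fdr_threshold=analysis.fdr_threshold,
                min_mean_abs_delta_beta=analysis.min_delta_beta)
            by_k = dmr_mod.call_dmrs_multi(table, man, analysis.dmr_min_cpgs, params)
            counts = {}
            for k, dmrs in by_k.items():
                io_mod.write_dmr_table(dmrs, self.path(f"dmrs_min{k}.tsv"))
                counts[f"n_dmrs_min{k}"] = len(dmrs)
            smallest = min(by_k)
            io_mod.export_dmrs_bed(by_k[smallest], self.path("dmrs.bed"))
            return counts

        self._run_stage("dmr", cfg["analysis"],
                        ["dmp_full_stats.tsv", "manifest.csv"],
                        [f"dmrs_min{k}.tsv" for k in analysis.dmr_min_cpgs]
                        + ["dmrs.bed"], do_dmr)

        def do_annotate() -> dict:
            dmps = io_mod.read_dmp_table(self.path("dmps.tsv"))
            man = io_mod.read_manifest(self.path("manifest.csv"))
            if not dmps:
                pd.DataFrame().to_csv(self.path("distribution.tsv"), sep="\t")
                return {"n_dmps": 0}
            table = annotate_mod.distribution_table(dmps, man)
            table.to_csv(self.path("distribution.tsv"), sep="\t")
            return {"n_dmps": len(dmps)}

        self._run_stage("annotate", {}, ["dmps.tsv", "manifest.csv"],
                        ["distribution.tsv"], do_annotate)

        def do_enrich() -> dict:
            dmps = io_mod.read_dmp_table(self.path("dmps.tsv"))
            man = io_mod.read_manifest(self.path("manifest.csv"))
            gmt_path = cfg["pathways"].get("gmt") or self.path("pathways.gmt")
            sets = io_mod.read_gmt(gmt_path)
            universe = man.genes()
            query = annotate_mod.genes_with_promoter_dmp(dmps, man) & universe
            if query:
                records = annotate_mod.hypergeometric_enrichment(
                    query, universe, sets, analysis.enrichment_alpha)
                frame = annotate_mod.enrichment_frame(records)
            else:
                frame = pd.DataFrame(columns=["term_id", "k", "K", "n", "N", "p",
                                              "p_bonferroni", "significant"])
            frame.to_csv(self.path("enrichment.tsv"), sep="\t", index=False)
            return {"n_terms": len(frame),
                    "n_significant": int(frame["significant"].sum()) if len(frame) else 0}

        self._run_stage("enrich", {"pathways": cfg["pathways"]},
                        ["dmps.tsv", "manifest.csv"], ["enrichment.tsv"], do_enrich)

        def do_score() -> dict:
            dmps = io_mod.read_dmp_table(self.path("dmps.tsv"))
            man = io_mod.read_manifest(self.path("manifest.csv"))
            matrix = io_mod.read_beta_matrix(self.path("corrected_beta.csv"))
            sheet = io_mod.read_sample_sheet(self.path("samples.csv"))
            gmt_path = cfg["pathways"].get("gmt") or self.path("pathways.gmt")
            sets = io_mod.read_gmt(gmt_path)
            pathway_key = cfg["score"].get("pathway", "ACTIVITY_PATHWAY")
            if pathway_key not in sets:
                raise ValidationError(f"pathway {pathway_key!r} not in gene sets")
            try:
                result = score_mod.run_activity_score(
                    dmps, sets[pathway_key], matrix, man, sheet,
                    r_threshold=analysis.score_r_threshold,
                    selection_timepoint=cfg["score"].get("selection_timepoint"))
            except ValidationError as exc:
                with open(self.path("score_summary.json"), "w") as fh:
                    json.dump({"error": str(exc)}, fh)
                pd.Series(dtype=float, name="score").to_csv(
                    self.path("scores.tsv"), sep="\t")
                return {"n_selected_probes": 0}
            result.scores.rename("score").to_csv(self.path("scores.tsv"), sep="\t",
                                                 float_format="%.17g")
            model = result.model
            with open(self.path("score_model.json"), "w") as fh:
                json.dump({
                    "probe_ids": model.probe_ids,
                    "mean_hc": model.mean_hc.tolist(),
                    "sd_hc": model.sd_hc.tolist(),
                    "r_sel": model.r_sel.tolist(),
                    "r_threshold": model.r_threshold,
                }, fh, indent=1)
            with open(self.path("score_summary.json"), "w") as fh:
                json.dump(result.summary(), fh, indent=1)
            return {"n_selected_probes": len(model.probe_ids),
                    "r": result.r, "p": result.p}

        self._run_stage("score", {"score": cfg["score"], "analysis": cfg["analysis"]},
                        ["dmps.tsv", "manifest.csv", "corrected_beta.csv",
                         "samples.csv"],
                        ["scores.tsv", "score_summary.json"], do_score)

        self.manifest.save(self.manifest_path)
        return self.manifest


def run_pipeline(config, force: bool = False) -> RunManifest:
    """Run the full pipeline from a YAML path or config dict."""
    cfg = load_config(config)
    return PipelineRunner(cfg, force=force).run()
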
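"""End-to-end pipeline: simulate/load -> QC -> normalize -> detect ->
concordance -> GSEA -> clustering -> qPCR, with deterministic seeding."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import array_io, concordance, gsea, qc, qpcr
from .array_io import ExperimentSet, write_experiment, write_json, write_truth
from .preprocess import PreprocessConfig, run_preprocess
from .synthetic_data import SimConfig, simulate_experiment, simulate_qpcr

log = logging.getLogger("scarray")

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

DEFAULT_QPCR_GENES = {
    "RPL13A": 40.0, "ACTB": 60.0, "GAPDH": 30.0, "YWHAZ": 25.0,
    "AR": 20.0, "EPCAM": 12.0, "KLK3": 15.0,
    "TMPRSS2": 2.0, "FKBP5": 1.0, "ACPP": 0.5,
}


@dataclass
class RunConfig:
    """Pipeline parameters; defaults mirror the published analysis constants
    (detection threshold 300, normexp offset 50, 10,000 random pairs, top
    1,000 variable genes, 46 qPCR cycles)."""

    seed: int = 0
    signal_path: Optional[str] = None
    meta_path: Optional[str] = None
    gmt_path: Optional[str] = None
    qpcr_path: Optional[str] = None
    sim: Optional[SimConfig] = field(default_factory=SimConfig)
    qc_alpha: float = 0.05
    offset: float = 50.0
    span: float = 0.30
    detection_threshold: float = 300.0
    n_pairs: int = 10_000
    n_top_genes: int = 1000
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    qpcr_max_cycles: int = 46

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = asdict(self.sim)
            d["sim"]["groups"] = [list(g) for g in self.sim.groups]
            d["sim"]["days"] = list(self.sim.days)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            sim = dict(d["sim"])
            sim["groups"] = tuple(tuple(g) for g in sim.get("groups", ()))
            sim["days"] = tuple(sim.get("days", ("d1", "d2")))
            d["sim"] = SimConfig(**sim)
        return cls(**d)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed; stable across runs."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big")


class StageError(RuntimeError):
    pass


def _write_frame(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage the config has inputs for; return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "stages": []}
    write_json(config.to_dict(), out / "config.json")

    def run_stage(name, fn):
        log.info("stage %s", name)
        try:
            fn()
        except Exception as exc:  # surface which stage died
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)

    state: dict = {}

    def stage_input():
        if config.signal_path and config.meta_path:
            es = array_io.read_experiment(config.signal_path, config.meta_path)
        elif config.sim is not None:
            es = simulate_experiment(
                config.sim.with_(seed=stage_seed(config.seed, "simulate")))
            write_experiment(es, out / "signals.tsv", out / "samples.tsv")
            if es.truth is not None:
                write_truth(es.truth, out / "truth.tsv")
        else:
            raise ValueError("config provides neither input paths nor a SimConfig")
        state["es"] = es

    run_stage("input", stage_input)

    def stage_qc():
        es = state["es"]
        metrics = {"array_distribution": qc.array_distribution_metrics(es.af3)}
        groups = dict(zip(es.samples["sample_id"], es.samples["group"].astype(str)))
        report = qc.flag_outlier_samples(metrics, alpha=config.qc_alpha,
                                         groups=groups,
                                         seed=stage_seed(config.seed, "qc"))
        report.to_tsv(out / "qc_report.tsv")
        if report.exclusions:
            es = es.exclude_samples(report.exclusions)
        state["es"] = es.drop_excluded()
        state["qc"] = report

    run_stage("qc", stage_qc)

    def stage_normalize():
        ns = run_preprocess(state["es"],
                            PreprocessConfig(offset=config.offset,
                                             span=config.span))
        _write_frame(ns.af3, out / "normalized_af3.tsv", index_label="probe_id")
        _write_frame(ns.m, out / "m_ratio.tsv", index_label="probe_id")
        write_json({"provenance": ns.provenance,
                    "config_hash": config.config_hash()},
                   out / "provenance.json")
        state["ns"] = ns

    run_stage("normalize", stage_normalize)

    def stage_detect():
        ns = state["ns"]
        profiles = {}
        for g in ns.groups():
            prof = concordance.call_detection(ns, g,
                                              threshold=config.detection_threshold)
            profiles[g] = prof
            _write_frame(prof.to_frame(), out / f"detection_{g}.tsv",
                         index_label="probe_id")
        state["profiles"] = profiles

    run_stage("detect", stage_detect)

    def stage_concord():
        ns = state["ns"]
        profiles = state["profiles"]
        groups = list(profiles)
        reports = []
        for i, test_g in enumerate(groups):
            for gold_g in groups[i + 1:]:
                rep = concordance.sensitivity_specificity(
                    profiles[test_g], profiles[gold_g])
                mprof = concordance.build_m_ratio_profiles(
                    ns, [test_g, gold_g], threshold=config.detection_threshold)
                a, b = mprof[str(test_g)], mprof[str(gold_g)]
                rep.pearson_m = concordance.m_ratio_correlations(a, b, "pearson")
                rep.spearman_m = concordance.m_ratio_correlations(a, b, "spearman")
                n_shared = len(a.mean_m)
                n_pairs = min(config.n_pairs, n_shared * (n_shared - 1) // 2)
                seed = stage_seed(config.seed, f"pairs:{test_g}:{gold_g}")
                r, _ = concordance.random_pair_difference_correlation(
                    a, b, n_pairs=n_pairs, seed=seed)
                rep.pair_diff_pearson = r
                rep.n_pairs = n_pairs
                rep.pair_seed = seed
                reports.append(rep.to_dict())
        write_json(reports, out / "concordance.json")
        if len(ns.sample_ids) >= 2:
            tree = concordance.cluster_top_variable(ns, n_genes=config.n_top_genes)
            (out / "cluster.nwk").write_text(tree.to_newick() + "\n")
        state["concordance"] = reports

    run_stage("concord", stage_concord)

    if config.gmt_path:
        def stage_gsea():
            ns = state["ns"]
            sets = array_io.read_gmt(config.gmt_path)
            per_group = {}
            for g in ns.groups():
                ranked = gsea.build_ranked_list(ns, g)
                res = gsea.nes_and_fdr(ranked, sets,
                                       n_perm=config.gsea_n_perm,
                                       seed=stage_seed(config.seed, f"gsea:{g}"),
                                       p=config.gsea_weight)
                _write_frame(gsea.results_to_frame(res), out / f"gsea_{g}.tsv")
                per_group[g] = res
            groups = list(per_group)
            corr = {}
            for i, a in enumerate(groups):
                for b in groups[i + 1:]:
                    corr[f"{a}_vs_{b}"] = gsea.correlate_nes(per_group[a],
                                                             per_group[b])
            write_json(corr, out / "gsea_nes_correlation.json")

        run_stage("gsea", stage_gsea)

    def stage_qpcr():
        if config.qpcr_path:
            from .synthetic_data import QPCRPlate
            plate = QPCRPlate.from_tsv(config.qpcr_path,
                                       max_cycles=config.qpcr_max_cycles)
        elif config.sim is not None:
            plate = simulate_qpcr(config.sim, DEFAULT_QPCR_GENES,
                                  seed=stage_seed(config.seed, "qpcr"),
                                  max_cycles=config.qpcr_max_cycles)
            plate.to_tsv(out / "qpcr_plate.tsv")
        else:
            return
        calls = qpcr.summarize_plate(plate)
        _write_frame(qpcr.calls_to_frame(calls), out / "qpcr_calls.tsv",
                     index=False)
        failed = qpcr.flag_failed_samples(calls, alpha=config.qc_alpha,
                                          seed=stage_seed(config.seed, "qpcr_qc"))
        failed.to_tsv(out / "qpcr_failures.tsv")
        genes = sorted({c.gene for c in calls})
        groups = list(dict.fromkeys(c.group for c in calls))
        counts = qpcr.detection_count_table(calls, genes, groups)
        _write_frame(counts, out / "qpcr_detection_counts.tsv",
                     index_label="gene")

    run_stage("qpcr", stage_qpcr)

    if state["es"].truth is not None:
        def stage_truth():
            es = state["es"]
            profiles = state["profiles"]
            summary = {}
            for g, prof in profiles.items():
                expressed = es.truth.expressed[str(g)].reindex(
                    prof.mean_signal.index)
                det = prof.detected
                tp = int((det & expressed).sum())
                fn = int((~det & expressed).sum())
                tn = int((~det & ~expressed).sum())
                fp = int((det & ~expressed).sum())
                summary[str(g)] = {
                    "sensitivity_vs_truth": tp / (tp + fn) if tp + fn else None,
                    "specificity_vs_truth": tn / (tn + fp) if tn + fp else None,
                }
            manifest["truth_recovery"] = summary

        run_stage("truth", stage_truth)

    write_json(manifest, out / "manifest.json")
    return manifest
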
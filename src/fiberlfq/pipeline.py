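"""End-to-end orchestration: read/simulate -> filter -> impute -> statistics.

A run is driven by a YAML config with an ``input`` section (paths to a
protein-group TSV, design CSV and annotation TSV) or a ``simulate``
section (SimConfig fields), plus an ``analysis`` section (AnalysisConfig
fields).  One master seed determines every random draw, so a rerun with
the same config is byte-identical.  Every stage writes a plain TSV so it
can be rerun or inspected standalone, and the report's headline counts
are recomputable from those tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import abundance, differential, downstream, preprocess, simulate
from .io import (
    AnalysisConfig,
    AnnotationMap,
    ProteinGroupTable,
    SampleDesign,
    read_annotations,
    read_peptides,
    read_protein_groups,
    read_sample_design,
    write_results,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineReport:
    """Per-stage provenance and headline counts of one run."""

    config: dict
    seed: int
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config,
            "seed": self.seed,
            "counts": self.counts,
            "outputs": {k: str(v) for k, v in self.outputs.items()},
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "input" not in cfg and "simulate" not in cfg:
        raise PipelineError("config needs an 'input' or a 'simulate' section")
    return cfg


def _load_inputs(cfg: Mapping, out_dir: Path):
    if "simulate" in cfg:
        sim_cfg = simulate.SimConfig(**(cfg["simulate"] or {}))
        proteins, peptides, design, annotation, truth = simulate.generate_experiment(sim_cfg)
        sim_dir = out_dir / "simulated_input"
        simulate.write_experiment(sim_dir, proteins, peptides, design, annotation, truth)
        return proteins, peptides, design, annotation, truth
    paths = cfg["input"]
    design = read_sample_design(paths["design"])
    proteins = read_protein_groups(paths["protein_groups"], design)
    annotation = (
        read_annotations(paths["annotations"])
        if "annotations" in paths
        else AnnotationMap(pd.DataFrame(columns=["accession", "namespace", "term"]))
    )
    peptides = read_peptides(paths["peptides"]) if "peptides" in paths else None
    return proteins, peptides, design, annotation, None


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> PipelineReport:
    """Execute the full analysis and write tables + a JSON report."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig.from_dict(config.get("analysis", {}) or {})
    report = PipelineReport(config=dict(config), seed=analysis.seed)
    t0 = time.perf_counter()

    def stage(name):
        def wrap(fn, *a, **kw):
            t = time.perf_counter()
            try:
                result = fn(*a, **kw)
            except Exception as exc:  # halt with stage name and cause
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            report.timings[name] = time.perf_counter() - t
            return result
        return wrap

    proteins, peptides, design, annotation, truth = stage("load")(
        _load_inputs, config, out_dir
    )
    report.counts["n_proteins"] = len(proteins.protein_group_ids)
    report.counts["n_samples"] = len(design.sample_ids)
    report.counts["n_subjects"] = design.n

    log_m = stage("log2")(preprocess.log2_transform, proteins)
    status = stage("classify_exclusive")(
        preprocess.classify_exclusive, log_m, analysis.min_valid
    )
    report.counts["exclusive_slow"] = len(status.proteins_with("exclusive_slow"))
    report.counts["exclusive_fast"] = len(status.proteins_with("exclusive_fast"))
    report.counts["quantified_both"] = len(status.proteins_with("both"))

    imputed, impute_params = stage("impute")(
        preprocess.impute_gaussian_downshift, log_m, analysis
    )
    audit = preprocess.imputation_audit(log_m, imputed)

    results = {}
    for contrast in differential.CONTRASTS:
        res = stage(f"contrast:{contrast}")(
            differential.run_contrast, imputed, contrast, analysis, status
        )
        results[contrast] = res
        report.counts[f"tested_{contrast}"] = len(res)
        report.counts[f"regulated_{contrast}"] = int(res["regulated"].sum())

    overlap = stage("overlap")(
        differential.regulated_overlap,
        results["training_slow"], results["training_fast"],
        annotation, "GOCC", "mitochondrion",
    )
    report.counts["training_overlap_both"] = overlap["both"]
    report.counts["training_overlap_slow_only"] = overlap["a_only"]
    report.counts["training_overlap_fast_only"] = overlap["b_only"]

    categories = annotation.terms()
    cat_table = stage("category_abundance")(
        abundance.category_percent_abundance, proteins, annotation, categories
    )

    sig_fiber = differential.regulated_set(results["fiber_PRE"])
    cluster_tables = {}
    if len(sig_fiber) >= analysis.n_clusters:
        z = stage("zscores")(downstream.group_median_zscores, imputed, sig_fiber)
        clusters = stage("cluster")(
            downstream.hierarchical_cluster, z, analysis.n_clusters
        )
        cluster_tables["clusters"] = clusters.labels.reset_index().rename(
            columns={"index": "protein_group_id"}
        )
        background = set(results["fiber_PRE"]["protein_group_id"])
        enrich_frames = []
        for cid in range(1, analysis.n_clusters + 1):
            e = stage(f"enrich:cluster{cid}")(
                downstream.fisher_enrichment,
                clusters.members(cid), background, annotation,
                None, analysis.cluster_fisher_fdr,
            )
            e.insert(0, "cluster", cid)
            enrich_frames.append(e)
        cluster_tables["cluster_enrichment"] = pd.concat(enrich_frames, ignore_index=True)
        report.counts["enriched_terms_clusters"] = int(
            cluster_tables["cluster_enrichment"]["significant"].sum()
        )

    enrichment = {}
    for contrast in ("training_slow", "training_fast"):
        query = differential.regulated_set(results[contrast])
        background = set(results[contrast]["protein_group_id"])
        e = stage(f"enrich:{contrast}")(
            downstream.fisher_enrichment,
            query, background, annotation, ["GOBP"], analysis.enrich_fdr,
        )
        enrichment[f"enrichment_{contrast}"] = e
        report.counts[f"enriched_terms_{contrast}"] = int(e["significant"].sum())

    pca_res = stage("pca")(downstream.pca, imputed)
    report.counts["pca_pc1_variance_pct"] = round(
        100.0 * float(pca_res.variance_explained[0]), 3
    )
    qc = stage("reproducibility")(downstream.reproducibility_correlation, log_m)
    report.counts["median_within_group_pearson_r"] = round(qc.median_overall, 4)

    tables = {
        "differential": pd.concat(results.values(), ignore_index=True),
        "quant_status": status.status.reset_index().rename(
            columns={"index": "protein_group_id"}
        ),
        "imputation_audit": audit,
        "category_abundance": cat_table.reset_index(names="category"),
        "pca_scores": pca_res.scores.reset_index(names="sample_id"),
        "pca_variance": pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(pca_res.variance_explained))],
                "variance_fraction": pca_res.variance_explained,
            }
        ),
        "sample_correlations": qc.r_matrix.reset_index(names="sample_id"),
        **cluster_tables,
        **enrichment,
    }
    if peptides is not None:
        myh = [a for a in ("MYH7", "MYH2", "MYH1")]
        try:
            iso = abundance.isoform_percent_from_unique_peptides(peptides, myh)
            tables["isoform_percent"] = iso.reset_index(names="isoform")
        except ValueError:
            pass
    report.outputs = write_results(tables, out_dir)
    report.timings["total"] = time.perf_counter() - t0
    report.to_json(out_dir / "report.json")
    report.outputs["report"] = out_dir / "report.json"
    return report


def verify_report(report: PipelineReport) -> list[str]:
    """Recount headline numbers from the written tables; return mismatches."""
    problems = []
    diff_path = report.outputs.get("differential")
    if diff_path is not None:
        diff = pd.read_csv(diff_path, sep="\t")
        for contrast in differential.CONTRASTS:
            sub = diff[diff["contrast"] == contrast]
            for key, val in (
                (f"tested_{contrast}", len(sub)),
                (f"regulated_{contrast}", int(sub["regulated"].sum())),
            ):
                if report.counts.get(key) != val:
                    problems.append(f"{key}: report {report.counts.get(key)} != table {val}")
    status_path = report.outputs.get("quant_status")
    if status_path is not None:
        status = pd.read_csv(status_path, sep="\t")
        vc = status["status"].value_counts()
        for key, name in (
            ("exclusive_slow", "exclusive_slow"),
            ("exclusive_fast", "exclusive_fast"),
            ("quantified_both", "both"),
        ):
            val = int(vc.get(name, 0))
            if report.counts.get(key) != val:
                problems.append(f"{key}: report {report.counts.get(key)} != table {val}")
    return problems
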
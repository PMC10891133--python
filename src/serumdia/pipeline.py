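"""End-to-end orchestration: simulate (or ingest) -> normalize -> qc ->
differential -> models -> cluster -> ptm -> enrich, with a manifest
recording seeds, parameters and per-stage row counts.

A reproduction mode accepts already-rolled-up protein level tables (and PTM
intensity tables), skipping the fragment-level stages, so externally
processed datasets can be pushed through the statistical stages directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as clustermod
from . import cohort, differential, enrich, models, ptm, qc
from . import normalize as norm

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

STAGES = ("simulate", "normalize", "qc", "differential", "models",
          "cluster", "ptm", "enrich")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the emulated study's stated
    values (kernel sd 5 runs, CoV threshold 50%, tiers 0.05/0.20, 20
    clusters, 1000 permutations, set sizes 3-300, Jaccard 0.80)."""

    outdir: Path = Path("serumdia_out")
    design: cohort.CohortDesign = field(default_factory=cohort.CohortDesign)
    # reproduction-mode inputs (skip simulate+normalize when given)
    protein_levels: Path | None = None   # protein x sample log10 TSV
    metadata_table: Path | None = None
    ptm_table: Path | None = None
    fragment_table: Path | None = None   # measured fragments instead of simulate
    gene_sets: Path | None = None        # GMT; synthetic sets if absent
    kernel_sd: float = 5.0
    max_missing_frac: float = 0.5
    min_fragments: int = 2
    max_fragments: int = 5
    cov_threshold_pct: float = 50.0
    alpha: float = 0.05
    alpha_extended: float = 0.20
    min_pairs: int = 3
    k_clusters: int = 20
    ptm_max_missing_frac: float = 0.20
    n_perm: int = 1000
    min_set_size: int = 3
    max_set_size: int = 300
    fdr_cutoff: float = 0.01
    jaccard_min: float = 0.80
    seed: int = 0


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    matrix: norm.ProteinMatrix
    qc_report: qc.QCReport | None
    differential: pd.DataFrame
    model_fits: pd.DataFrame
    clusters: clustermod.ClusterAssignment
    cluster_summary: pd.DataFrame
    ptm_results: pd.DataFrame | None
    enrichment: enrich.EnrichmentResult
    graph: "object"
    truth: cohort.TruthTable | None = None
    ptm_truth: cohort.TruthTable | None = None


def load_config(path) -> PipelineConfig:
    """YAML pipeline configuration; a ``simulate:`` block maps onto the
    cohort design, every other key onto a config field."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    design = cohort.CohortDesign(**raw.pop("simulate", {}))
    paths = {k: Path(raw.pop(k)) for k in ("outdir", "protein_levels",
                                           "metadata_table", "ptm_table",
                                           "fragment_table", "gene_sets")
             if raw.get(k) is not None}
    return PipelineConfig(design=design, **paths, **raw)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {},
                      "parameters": {k: str(v) for k, v in vars(config).items()
                                     if k != "design"},
                      "design": {k: str(v) for k, v in
                                 vars(config.design).items()}}
    stage = "simulate"
    try:
        truth = ptm_truth = None
        records = None
        qc_report = None
        reproduction = config.protein_levels is not None

        # ---- simulate / ingest + normalize -------------------------------
        if reproduction:
            stage = "ingest"
            levels = pd.read_csv(config.protein_levels, sep="\t", index_col=0)
            meta = pd.read_csv(config.metadata_table, sep="\t", index_col=0)
            matrix = norm.ProteinMatrix(
                levels=levels[[c for c in levels.columns
                               if meta.loc[c, "cohort"] != "qc"]],
                qc_levels=levels[[c for c in levels.columns
                                  if meta.loc[c, "cohort"] == "qc"]])
            frags = None
            manifest["stages"]["ingest"] = {"n_proteins": len(levels)}
        else:
            if config.fragment_table is not None:
                stage = "ingest"
                meta = pd.read_csv(config.metadata_table, sep="\t", index_col=0)
                frags = cohort.FragmentTable.from_tsv(config.fragment_table,
                                                      runs=list(meta.index))
            else:
                design = config.design
                records = cohort.generate_metadata(design)
                meta = cohort.metadata_to_frame(records)
                frags, truth = cohort.generate_fragments(design, records)
                meta.to_csv(out / "metadata.tsv", sep="\t")
                truth.to_tsv(out / "truth_proteins.tsv")
                manifest["stages"]["simulate"] = {
                    "n_runs": len(meta), "n_fragments": len(frags.fragments)}
            stage = "normalize"
            matrix, provenance = norm.preprocess(
                frags, meta, kernel_sd=config.kernel_sd,
                max_fragments=config.max_fragments,
                min_fragments=config.min_fragments,
                max_missing_frac=config.max_missing_frac)
            (out / "provenance.json").write_text(json.dumps(provenance,
                                                            indent=2))
            manifest["stages"]["normalize"] = provenance[-1]
            _write(matrix.levels, out / "protein_levels.tsv")
            _write(matrix.qc_levels, out / "protein_levels_qc.tsv")

        # ---- qc ----------------------------------------------------------
        stage = "qc"
        if matrix.qc_levels.shape[1] >= 2:
            qc_report = qc.compute_cov(matrix, meta,
                                       threshold_pct=config.cov_threshold_pct)
            matrix.reliability = qc_report.reliable
            _write(pd.DataFrame({
                "average_cov_pct": qc_report.average_cov,
                "reliable": qc_report.reliable}), out / "qc_report.tsv")
            manifest["stages"]["qc"] = {
                "n_unreliable": len(qc_report.unreliable_proteins),
                "median_cov_per_batch_pct":
                    qc_report.median_cov_per_batch.round(2).to_dict()}

        # ---- differential ------------------------------------------------
        stage = "differential"
        diff = differential.differential_analysis(
            matrix.levels, meta, min_pairs=config.min_pairs,
            alpha=config.alpha, alpha_extended=config.alpha_extended)
        reliability = qc_report.reliable if qc_report is not None else None
        volcano = differential.volcano_table(diff, reliability)
        _write(diff, out / "differential.tsv")
        _write(volcano, out / "volcano.tsv")
        manifest["stages"]["differential"] = {
            "n_tested": int(diff["p"].notna().sum()),
            "n_primary": int((diff["tier"] == "primary").sum()),
            "n_extended": int((diff["tier"] == "extended").sum())}

        # ---- covariate models --------------------------------------------
        stage = "models"
        datasets = models.build_datasets(matrix, meta)
        fits = models.fit_models(datasets)
        grid = models.significance_grid(fits, diff, alpha=config.alpha,
                                        alpha_extended=config.alpha_extended)
        _write(fits, out / "model_fits.tsv", index=False)
        _write(grid, out / "significance_grid.tsv")
        manifest["stages"]["models"] = {"n_rows": len(fits)}

        # ---- clustering --------------------------------------------------
        stage = "cluster"
        centered = clustermod.median_center(matrix.levels)
        assignment = clustermod.cluster(centered, k=config.k_clusters)
        summary = clustermod.summarize_clusters(assignment, diff)
        _write(assignment.assignment.to_frame(), out / "clusters.tsv")
        _write(summary, out / "cluster_summary.tsv", index=False)
        manifest["stages"]["cluster"] = {
            "k": assignment.k,
            "n_clusters_with_significant":
                int(summary["contains_significant"].sum())}

        # ---- ptm ---------------------------------------------------------
        stage = "ptm"
        ptm_results = None
        ptm_table = None
        if config.ptm_table is not None:
            ptm_table = cohort.ModifiedPeptideTable.from_tsv(config.ptm_table)
        elif records is not None:
            ptm_table, ptm_truth = cohort.generate_ptm_table(config.design,
                                                             records)
        if ptm_table is not None:
            levels_ptm = ptm.modification_level_table(ptm_table)
            subj_runs = [r for r in levels_ptm.columns
                         if meta.loc[r, "cohort"] != "qc"]
            filtered, _ = ptm.filter_peptides(
                levels_ptm[subj_runs],
                max_missing_frac=config.ptm_max_missing_frac)
            ptm_results = ptm.test_occupancy(
                filtered, meta, min_pairs=config.min_pairs,
                alpha=config.alpha, alpha_extended=config.alpha_extended)
            _write(ptm_results, out / "ptm_results.tsv")
            manifest["stages"]["ptm"] = {
                "n_peptides_tested": len(ptm_results),
                "n_primary": int((ptm_results["tier"] == "primary").sum())}

        # ---- enrichment --------------------------------------------------
        stage = "enrich"
        ranked = enrich.rank_list(diff)
        if config.gene_sets is not None:
            sets = enrich.read_gmt(config.gene_sets)
        else:
            if truth is None:
                raise RuntimeError("gene_sets path required when not simulating")
            sets = cohort.make_gene_sets(list(matrix.proteins), truth,
                                         seed=config.seed)
        filtered_sets = enrich.filter_sets(sets, list(ranked["protein"]),
                                           min_size=config.min_set_size,
                                           max_size=config.max_set_size)
        result = enrich.preranked_enrichment(ranked, filtered_sets,
                                             n_perm=config.n_perm,
                                             seed=config.seed)
        graph = enrich.build_graph(result, fdr_cutoff=config.fdr_cutoff,
                                   jaccard_min=config.jaccard_min)
        _write(result.table, out / "enrichment.tsv", index=False)
        nodes = pd.DataFrame([{"set": n, **graph.nodes[n]}
                              for n in graph.nodes])
        edges = pd.DataFrame([{"set_a": a, "set_b": b,
                               "jaccard": graph.edges[a, b]["weight"]}
                              for a, b in graph.edges])
        _write(nodes, out / "enrichment_nodes.tsv", index=False)
        _write(edges, out / "enrichment_edges.tsv", index=False)
        manifest["stages"]["enrich"] = {"n_sets": len(result.table),
                                        "n_nodes": graph.number_of_nodes(),
                                        "n_edges": graph.number_of_edges()}

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc!r}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return PipelineResult(outdir=out, manifest=manifest, matrix=matrix,
                          qc_report=qc_report, differential=diff,
                          model_fits=fits, clusters=assignment,
                          cluster_summary=summary, ptm_results=ptm_results,
                          enrichment=result, graph=graph, truth=truth,
                          ptm_truth=ptm_truth)
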
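"""End-to-end orchestration of the meta-analysis over condition groups.

``analyze_group`` runs one condition group through preprocessing, the
gene-level meta-analysis, consensus network construction, and the module
eigengene meta-analysis.  ``compare_groups`` aligns two groups' networks
(matchLabels-style), runs RRHO gene classification, selects consensus hubs
and overlays them with the RRHO classes.  ``run_all`` simulates a full
two-group study, runs everything, and writes every output table plus a
JSON run report to an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import ModuleMatch, RRHOResult, classify_genes, match_labels, \
    rrho
from .config import PipelineConfig
from .enrichment import ora
from .gene_meta import gene_meta_table
from .hubs import hub_overlap_test, hub_table, module_scenario, \
    overlay_hubs_rrho
from .io import ExpressionDataset, GeneSetCollection, write_expression, \
    write_gmt, write_table
from .module_meta import module_meta_table
from .network import ConsensusNetwork, ModulePartition, \
    build_consensus_network
from .preprocess import preprocess_group
from .simulate import ComparisonSpec, ComparisonTruth, simulate_comparison

__all__ = ["GroupResult", "CompareResult", "analyze_group",
           "compare_groups", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class GroupResult:
    """Everything computed for one condition group."""

    datasets: list[ExpressionDataset]
    gene_meta: pd.DataFrame
    network: ConsensusNetwork
    module_stats: pd.DataFrame
    module_meta: pd.DataFrame
    preprocess_report: dict


@dataclass
class CompareResult:
    """Cross-group comparison artifacts."""

    module_match: ModuleMatch
    rrho_result: RRHOResult
    gene_classes: pd.Series
    hubs_a: pd.DataFrame
    hubs_b: pd.DataFrame
    hub_overlap: pd.DataFrame
    overlay_a: pd.DataFrame
    overlay_b: pd.DataFrame


def analyze_group(datasets: list[ExpressionDataset],
                  config: PipelineConfig,
                  quantile: bool = True) -> GroupResult:
    """Preprocess one group and run gene- and module-level meta-analysis."""
    processed, report = preprocess_group(datasets, quantile=quantile)
    meta = gene_meta_table(processed, config)
    network = build_consensus_network(processed, config)
    module_stats, module_meta = module_meta_table(
        network.eigengenes, processed, config)
    return GroupResult(datasets=processed, gene_meta=meta, network=network,
                       module_stats=module_stats, module_meta=module_meta,
                       preprocess_report=report)


def _relabelled_partition(partition: ModulePartition,
                          match: ModuleMatch) -> ModulePartition:
    mapping = dict(match.relabel_map)
    mapping["M0"] = "M0"
    return ModulePartition(partition.labels.map(lambda m: mapping.get(m, m)),
                           list(partition.merge_history))


def compare_groups(result_a: GroupResult, result_b: GroupResult,
                   config: PipelineConfig) -> CompareResult:
    """Compare two analyzed groups: labels, RRHO, hubs, overlay.

    Group A's network is the reference; group B's modules are relabelled
    onto it before hub overlap and scenario overlay.
    """
    shared = [g for g in result_a.gene_meta.index
              if g in set(result_b.gene_meta.index)]
    meta_a = result_a.gene_meta.loc[shared]
    meta_b = result_b.gene_meta.loc[shared]

    match = match_labels(result_a.network.partition,
                         result_b.network.partition,
                         alpha=config.ora_alpha) \
        if result_a.network.partition.modules and \
        result_b.network.partition.modules else ModuleMatch(
            overlap=pd.DataFrame(), p_values=pd.DataFrame(),
            q_values=pd.DataFrame(), relabel_map={}, unmatched_source=[])

    rrho_result = rrho(meta_a, meta_b, config)
    gene_classes = classify_genes(meta_a, meta_b, rrho_result)

    hubs_a = hub_table(result_a.datasets, result_a.network.eigengenes,
                       result_a.network.partition, config) \
        if result_a.network.partition.modules else pd.DataFrame(
            columns=["gene_id", "module", "Z_MM", "hub", "threshold"])
    hubs_b = hub_table(result_b.datasets, result_b.network.eigengenes,
                       result_b.network.partition, config) \
        if result_b.network.partition.modules else pd.DataFrame(
            columns=["gene_id", "module", "Z_MM", "hub", "threshold"])
    hubs_b_matched = hubs_b.copy()
    if len(hubs_b_matched):
        hubs_b_matched["module"] = hubs_b_matched["module"].map(
            lambda m: match.relabel_map.get(m, m))

    module_dir_a = result_a.module_meta["direction"].to_dict() \
        if len(result_a.module_meta) else {}
    module_dir_b_raw = result_b.module_meta["direction"].to_dict() \
        if len(result_b.module_meta) else {}
    module_dir_b = {match.relabel_map.get(m, m): d
                    for m, d in module_dir_b_raw.items()}

    universe = set(shared)
    overlap_rows = []
    shared_labels = sorted(
        set(hubs_a["module"]) & set(hubs_b_matched["module"])
        if len(hubs_a) and len(hubs_b_matched) else set())
    for module in shared_labels:
        set_a = set(hubs_a.loc[(hubs_a["module"] == module) &
                               hubs_a["hub"], "gene_id"])
        set_b = set(hubs_b_matched.loc[(hubs_b_matched["module"] == module) &
                                       hubs_b_matched["hub"], "gene_id"])
        if not set_a or not set_b:
            continue
        k, p = hub_overlap_test(set_a, set_b, universe)
        overlap_rows.append({"module": module, "hubs_A": len(set_a),
                             "hubs_B": len(set_b), "shared": k, "p": p})
    hub_overlap = pd.DataFrame(overlap_rows)

    scenarios = {}
    for module in set(module_dir_a) | set(module_dir_b):
        scenarios[module] = module_scenario(
            module_dir_a.get(module, "none"),
            module_dir_b.get(module, "none"))
    overlay_a = overlay_hubs_rrho(hubs_a, gene_classes, scenarios) \
        if len(hubs_a) else hubs_a
    overlay_b = overlay_hubs_rrho(hubs_b_matched, gene_classes, scenarios) \
        if len(hubs_b_matched) else hubs_b_matched

    return CompareResult(module_match=match, rrho_result=rrho_result,
                         gene_classes=gene_classes, hubs_a=hubs_a,
                         hubs_b=hubs_b_matched, hub_overlap=hub_overlap,
                         overlay_a=overlay_a, overlay_b=overlay_b)


def _truth_gmt(truth: ComparisonTruth, rng: np.random.Generator,
               n_random: int = 10) -> GeneSetCollection:
    """Synthetic gene-set collection for exercising the ORA stage: the
    planted modules plus random background terms."""
    sets: dict[str, tuple[str, list[str]]] = {}
    assignment = truth.truth_a.module_assignment
    for module in sorted(set(assignment) - {"M0"}):
        genes = list(assignment.index[assignment == module])
        sets[f"PLANTED_{module}"] = (f"planted module {module}", genes)
    genes_all = list(assignment.index)
    for i in range(n_random):
        size = int(rng.integers(30, 120))
        members = list(rng.choice(genes_all, size=size, replace=False))
        sets[f"RANDOM_{i + 1}"] = ("random background term", members)
    return GeneSetCollection(sets)


def _write_rrho(result: RRHOResult, outdir: Path) -> None:
    rows = []
    for quadrant, grid in result.grids.items():
        if grid.empty:
            continue
        long = grid.stack()
        for (i, j), v in long.items():
            rows.append((quadrant, int(i), int(j), float(v)))
    pd.DataFrame(rows, columns=["quadrant", "i", "j", "neglog10p"]).to_csv(
        outdir / "rrho_grid.tsv", sep="\t", index=False)
    opt_rows = []
    for quadrant, (i, j, peak) in result.optima.items():
        for gene in sorted(result.optimal_sets.get(quadrant, ())):
            opt_rows.append((quadrant, i, j, peak, gene))
    pd.DataFrame(opt_rows, columns=["quadrant", "i", "j", "neglog10p",
                                    "gene_id"]).to_csv(
        outdir / "optimal_sets.tsv", sep="\t", index=False)


def _write_group(result: GroupResult, tag: str, outdir: Path) -> None:
    write_table(result.gene_meta, outdir / f"gene_meta_{tag}.tsv")
    part = result.network.partition.labels.rename("module_label")
    part.rename_axis("gene_id").to_frame().to_csv(
        outdir / f"module_assignment_{tag}.tsv", sep="\t")
    for dataset_id, frame in result.network.eigengenes.scores.items():
        write_table(frame, outdir / f"eigengenes_{tag}_{dataset_id}.tsv")
    pd.DataFrame([
        {"dataset_id": d, "beta": b,
         "warning": bool(result.network.beta_scans[d].attrs.get("warning"))}
        for d, b in result.network.betas.items()
    ]).to_csv(outdir / f"beta_report_{tag}.tsv", sep="\t", index=False)
    if len(result.module_meta):
        write_table(result.module_meta, outdir / f"module_meta_{tag}.tsv")
        write_table(result.module_stats,
                    outdir / f"module_stats_{tag}.tsv", index=False)


def run_all(config: PipelineConfig, outdir: str | Path,
            spec: ComparisonSpec | None = None,
            write_datasets: bool = False) -> dict:
    """Simulate a two-group study, run the full pipeline, write outputs.

    Returns a summary dict (also written as ``run_report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = ComparisonSpec(
            module_shifts_a=(0.8, -0.8, 0.0, 0.0, 0.0),
            module_shifts_b=(0.8, 0.0, -0.8, 0.0, 0.0))
    ds_a, ds_b, truth = simulate_comparison(config, spec)
    if write_datasets:
        for ds in (*ds_a, *ds_b):
            write_expression(ds, outdir / f"expr_{ds.dataset_id}.tsv",
                             outdir / f"samples_{ds.dataset_id}.tsv")
    write_table(truth.truth_a.to_frame(), outdir / "truth_group_A.tsv")
    write_table(truth.truth_b.to_frame(), outdir / "truth_group_B.tsv")
    truth.effect_class.rename_axis("gene_id").to_frame().to_csv(
        outdir / "truth_effect_classes.tsv", sep="\t")

    result_a = analyze_group(ds_a, config)
    result_b = analyze_group(ds_b, config)
    comparison = compare_groups(result_a, result_b, config)

    _write_group(result_a, "A", outdir)
    _write_group(result_b, "B", outdir)
    _write_rrho(comparison.rrho_result, outdir)
    comparison.gene_classes.rename_axis("gene_id").to_frame().to_csv(
        outdir / "gene_classes.tsv", sep="\t")
    if len(comparison.module_match.overlap):
        write_table(comparison.module_match.overlap,
                    outdir / "module_match.tsv")
    write_table(comparison.overlay_a, outdir / "hub_table_A.tsv",
                index=False)
    write_table(comparison.overlay_b, outdir / "hub_table_B.tsv",
                index=False)
    if len(comparison.hub_overlap):
        write_table(comparison.hub_overlap, outdir / "hub_overlap.tsv",
                    index=False)

    rng = np.random.default_rng(config.seed + 1)
    collection = _truth_gmt(truth, rng)
    write_gmt(collection, outdir / "synthetic_sets.gmt")
    universe = set(result_a.gene_meta.index)
    de_up = set(result_a.gene_meta.index[
        (result_a.gene_meta["direction"] == "up")]) & universe
    if de_up:
        enr = ora(de_up, universe, collection, config)
        write_table(enr, outdir / "enrichment_A_up.tsv", index=False)
    else:
        enr = pd.DataFrame()

    summary = config.run_report(
        package_version=__version__,
        n_genes=len(result_a.gene_meta),
        betas_A=result_a.network.betas,
        betas_B=result_b.network.betas,
        calibration_reference="median per-dataset quantile",
        n_modules_A=len(result_a.network.partition.modules),
        n_modules_B=len(result_b.network.partition.modules),
        de_up_A=int((result_a.gene_meta["direction"] == "up").sum()),
        de_down_A=int((result_a.gene_meta["direction"] == "down").sum()),
        de_up_B=int((result_b.gene_meta["direction"] == "up").sum()),
        de_down_B=int((result_b.gene_meta["direction"] == "down").sum()),
        diff_modules_A=int(result_a.module_meta["diff_flag"].sum())
        if len(result_a.module_meta) else 0,
        diff_modules_B=int(result_b.module_meta["diff_flag"].sum())
        if len(result_b.module_meta) else 0,
        n_hubs_A=int(comparison.overlay_a["hub"].sum())
        if len(comparison.overlay_a) else 0,
        n_hubs_B=int(comparison.overlay_b["hub"].sum())
        if len(comparison.overlay_b) else 0,
        n_candidates_A=int(comparison.overlay_a["candidate"].sum())
        if "candidate" in comparison.overlay_a else 0,
        n_enriched_terms=int(enr["enriched"].sum()) if len(enr) else 0,
        preprocess_A=result_a.preprocess_report,
        preprocess_B=result_b.preprocess_report,
    )
    (outdir / "run_report.json").write_text(
        json.dumps(summary, indent=2, default=str) + "\n")
    return summary
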
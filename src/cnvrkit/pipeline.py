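"""End-to-end orchestration of the CNV downstream-analysis stages.

``run_pipeline`` reads a scenario directory (the layout written by
:func:`cnvrkit.simulate.write_scenario`, or equivalent user-supplied files),
runs the enabled stages in order — CNVR construction, gene annotation, GO
enrichment, selective constraint, expression breadth, network centrality —
and writes one report file per stage plus the resolved configuration.

Stage outputs are pure functions of the inputs and the configuration: a
re-run with the same inputs produces byte-identical files (reports carry no
timestamps; progress goes to the stderr log).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io_formats
from .cnvr import classify_all, filter_by_frequency, merge_cnvs, summarize_cnvrs
from .enrichment import binomial_enrichment
from .expression import (
    ExpressionMatrix,
    call_expressed,
    combine_experiments,
    compare_breadth,
    tissue_specific_genes,
)
from .gene_annotation import label_cnvrs, neutral_genes, overlap_genes, partition_gene_classes
from .network import build_network, compare_centrality, compute_degrees
from .ranksum import RankSumOutcome
from .selection import compare_constraint, dnds_pair, filter_saturated

logger = logging.getLogger(__name__)

ALL_STAGES = ("cnvr", "genes", "enrichment", "dnds", "breadth", "network")

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]


@dataclass
class PipelineConfig:
    """Resolved options of one pipeline run; defaults mirror the analysis protocol."""

    scenario_dir: Path
    out_dir: Path
    stages: tuple[str, ...] = ALL_STAGES
    overlap_threshold: float = 0.5
    min_samples: int = 3
    upc_threshold: float = 0.5
    fpkm_threshold: float = 1.0
    gap_open: float = 10.0
    gap_extend: float = 1.0
    calls_dialect: str = "bed_like"

    def __post_init__(self) -> None:
        self.scenario_dir = Path(self.scenario_dir)
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")


_STAGE_INPUTS = {
    "cnvr": ("genome.tsv", "cnv_calls.tsv"),
    "genes": ("genes.gff3",),
    "enrichment": ("go_annotations.tsv",),
    "dnds": ("orthologs_query.fasta", "orthologs_ortholog.fasta"),
    "breadth": ("expression/manifest.yaml",),
    "network": ("ppi_edges.tsv",),
}


def _outcome_row(name: str, outcome: RankSumOutcome) -> dict:
    return dict(
        contrast=name,
        n1=outcome.n1,
        n2=outcome.n2,
        median_class=outcome.median_x,
        median_neutral=outcome.median_y,
        u=outcome.u,
        method=outcome.method,
        alternative=outcome.alternative,
        p_one_tailed=outcome.p_one_tailed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and write their reports under ``config.out_dir``.

    Stages downstream of gene annotation (enrichment, dnds, breadth,
    network) require the ``cnvr`` and ``genes`` stages, which are enabled
    implicitly when any of them is requested.  Missing inputs for any
    enabled stage raise before any computation starts.

    Returns a dictionary of in-memory results keyed by stage.
    """
    stages = set(config.stages)
    if stages & {"enrichment", "dnds", "breadth", "network"}:
        stages |= {"cnvr", "genes"}
    if "genes" in stages:
        stages.add("cnvr")

    missing = [
        str(config.scenario_dir / f)
        for stage in stages
        for f in _STAGE_INPUTS[stage]
        if not (config.scenario_dir / f).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing inputs for enabled stages: {missing}")
    config.out_dir.mkdir(parents=True, exist_ok=True)

    results: dict = {}

    # ---- CNVR construction -------------------------------------------------
    genome = io_formats.read_genome(config.scenario_dir / "genome.tsv")
    calls = io_formats.read_cnv_calls(
        config.scenario_dir / "cnv_calls.tsv", dialect=config.calls_dialect
    )
    logger.info("cnvr: %d calls from %d samples", len(calls), len({c.sample_id for c in calls}))
    merged = merge_cnvs(calls, threshold=config.overlap_threshold)
    kept, removed = filter_by_frequency(merged, min_samples=config.min_samples)
    cnvrs = classify_all(kept, genome)
    summary = summarize_cnvrs(cnvrs, genome) if cnvrs else None
    io_formats.write_cnvr_report(
        cnvrs, config.out_dir / "cnvr_report.tsv", bed_path=config.out_dir / "cnvr_report.bed"
    )
    summary_payload = {
        "n_merged": len(merged),
        "n_removed_by_frequency": len(removed),
        "n_cnvrs": len(cnvrs),
        "state_counts": dict(summary.state_counts) if summary else {},
        "size_bases": {
            "min": summary.min_size,
            "max": summary.max_size,
            "mean": summary.mean_size,
            "median": summary.median_size,
        }
        if summary
        else {},
        "total_unique_bases": summary.total_unique if summary else 0,
        "genome_fraction": summary.genome_fraction if summary else 0.0,
    }
    with open(config.out_dir / "cnvr_summary.json", "w") as fh:
        json.dump(summary_payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["cnvr"] = dict(cnvrs=cnvrs, removed=removed, summary=summary)
    logger.info("cnvr: %d CNVRs kept (%d removed by frequency filter)", len(cnvrs), len(removed))

    if "genes" not in stages:
        _write_config(config)
        return results

    # ---- Gene annotation ---------------------------------------------------
    genes = io_formats.read_gene_models(config.scenario_dir / "genes.gff3")
    labelled = label_cnvrs(cnvrs)
    records = overlap_genes(labelled, genes)
    states = {cid: r.state for cid, r in labelled.items()}
    classes = partition_gene_classes(records, states)
    neutral = neutral_genes(genes, records)
    biotype = {g.gene_id: g.biotype for g in genes}
    class_of = {g: c for c, members in classes.items() for g in members}
    pd.DataFrame(
        [
            dict(
                gene_id=r.gene_id,
                biotype=r.biotype,
                overlap_kind=r.overlap_kind,
                gene_class=class_of[r.gene_id],
                cnvr_ids=",".join(r.cnvr_ids),
            )
            for r in sorted(records, key=lambda r: r.gene_id)
        ]
    ).to_csv(config.out_dir / "cnv_genes.tsv", sep="\t", index=False)
    results["genes"] = dict(records=records, classes=classes, neutral=neutral)
    logger.info(
        "genes: %d CNV genes (%d duplication / %d deletion / %d mixed), %d neutral",
        len(records),
        len(classes["duplication"]),
        len(classes["deletion"]),
        len(classes["mixed"]),
        len(neutral),
    )

    cnv_gene_ids = {r.gene_id for r in records}
    group_sets: dict[str, set[str]] = {
        "all_cnv": cnv_gene_ids,
        "duplication": classes["duplication"],
        "deletion": classes["deletion"],
        "mixed": classes["mixed"],
    }

    # ---- GO enrichment -----------------------------------------------------
    if "enrichment" in stages:
        annotation = io_formats.read_annotation_table(
            config.scenario_dir / "go_annotations.tsv",
            config.scenario_dir / "go_terms.tsv"
            if (config.scenario_dir / "go_terms.tsv").exists()
            else None,
        )
        protein_coding_cnv = {g for g in cnv_gene_ids if biotype.get(g) == "protein_coding"}
        rows = binomial_enrichment(protein_coding_cnv, annotation)
        pd.DataFrame(
            [
                dict(
                    term_id=r.term_id,
                    term_name=r.term_name,
                    aspect=r.aspect,
                    annotated_genes=r.K,
                    cnv_genes=r.k,
                    cnv_genes_expected=round(r.expected, 2),
                    direction=r.direction,
                    p_raw=r.p_raw,
                    p_bonferroni=r.p_bonferroni,
                )
                for r in rows
            ]
        ).to_csv(config.out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        results["enrichment"] = rows
        n_sig = sum(1 for r in rows if r.p_bonferroni < 0.05)
        logger.info("enrichment: %d/%d terms significant after Bonferroni", n_sig, len(rows))

    # ---- Selective constraint ----------------------------------------------
    if "dnds" in stages:
        pairs = io_formats.read_fasta_pairs(
            config.scenario_dir / "orthologs_query.fasta",
            config.scenario_dir / "orthologs_ortholog.fasta",
        )
        dnds_results = [
            dnds_pair(p, gap_open=config.gap_open, gap_extend=config.gap_extend) for p in pairs
        ]
        usable = filter_saturated(dnds_results)
        pd.DataFrame(
            [
                dict(
                    gene_id=r.gene_id,
                    S=r.S,
                    N=r.N,
                    Sd=r.Sd,
                    Nd=r.Nd,
                    dS=r.dS,
                    dN=r.dN,
                    omega=r.omega,
                    saturated=r.saturated,
                )
                for r in dnds_results
            ]
        ).to_csv(config.out_dir / "dnds.tsv", sep="\t", index=False, float_format="%.6g")
        by_gene = {r.gene_id: r for r in usable}
        neutral_res = [by_gene[g] for g in sorted(neutral) if g in by_gene]
        contrast_rows = []
        median_rows = []
        for name, group in group_sets.items():
            group_res = [by_gene[g] for g in sorted(group) if g in by_gene]
            if not group_res or not neutral_res:
                continue
            medians = {}
            for stat in ("dN", "dS", "omega"):
                outcome = compare_constraint(group_res, neutral_res, statistic=stat)
                contrast_rows.append(_outcome_row(f"{name}.{stat}", outcome))
                medians[stat] = outcome.median_x
                medians["neutral_" + stat] = outcome.median_y
            median_rows.append(dict(gene_set=name, **{k: v for k, v in medians.items()}))
        if neutral_res:
            vals = {
                stat: [getattr(r, stat) for r in neutral_res if not math.isinf(getattr(r, stat))]
                for stat in ("dN", "dS", "omega")
            }
            median_rows.append(
                dict(
                    gene_set="neutral",
                    **{
                        stat: float(pd.Series([v for v in vv if not math.isnan(v)]).median())
                        for stat, vv in vals.items()
                    },
                )
            )
        pd.DataFrame(contrast_rows).to_csv(
            config.out_dir / "dnds_contrasts.tsv", sep="\t", index=False, float_format="%.6g"
        )
        pd.DataFrame(median_rows).to_csv(
            config.out_dir / "dnds_medians.tsv", sep="\t", index=False, float_format="%.6g"
        )
        results["dnds"] = dict(results=dnds_results, usable=usable, contrasts=contrast_rows)
        logger.info(
            "dnds: %d pairs, %d usable after saturation filter", len(dnds_results), len(usable)
        )

    # ---- Expression breadth ------------------------------------------------
    if "breadth" in stages:
        manifest = io_formats.read_manifest(config.scenario_dir / "expression" / "manifest.yaml")
        callsets = []
        panel: set[str] = set()
        for exp_id in sorted(manifest):
            entry = manifest[exp_id]
            values = pd.read_csv(
                config.scenario_dir / "expression" / entry["file"], sep="\t", index_col=0
            )
            matrix = ExpressionMatrix(
                experiment_id=exp_id,
                platform=entry["platform"],
                values=values,
                sample_tissue=entry["samples"],
            )
            panel |= matrix.tissues
            callsets.append(
                call_expressed(
                    matrix,
                    upc_threshold=config.upc_threshold,
                    fpkm_threshold=config.fpkm_threshold,
                )
            )
        callset = combine_experiments(callsets, panel=panel)
        breadths = callset.breadths()
        pd.DataFrame(
            [
                dict(
                    gene_id=g,
                    breadth=b,
                    gene_class=class_of.get(g, "neutral"),
                    tissues=";".join(sorted(callset.tissues_by_gene[g])),
                )
                for g, b in sorted(breadths.items())
            ]
        ).to_csv(config.out_dir / "breadth.tsv", sep="\t", index=False)
        specific = tissue_specific_genes(callset)
        pd.DataFrame(
            [
                dict(
                    tissue=t,
                    n_tissue_specific=len(gs),
                    n_tissue_specific_cnv=sum(1 for g in gs if g in cnv_gene_ids),
                )
                for t, gs in specific.items()
            ]
        ).to_csv(config.out_dir / "tissue_specific_counts.tsv", sep="\t", index=False)
        outcome = compare_breadth(callset, cnv_gene_ids, neutral)
        pd.DataFrame([_outcome_row("breadth.cnv_vs_neutral", outcome)]).to_csv(
            config.out_dir / "breadth_contrast.tsv", sep="\t", index=False, float_format="%.6g"
        )
        results["breadth"] = dict(callset=callset, specific=specific, contrast=outcome)
        logger.info(
            "breadth: median %d (CNV) vs %d (neutral), p=%.3g",
            int(outcome.median_x),
            int(outcome.median_y),
            outcome.p_one_tailed,
        )

    # ---- Network centrality ------------------------------------------------
    if "network" in stages:
        edges = io_formats.read_edge_list(config.scenario_dir / "ppi_edges.tsv")
        net = build_network(edges)
        degrees = compute_degrees(net, genes=(g.gene_id for g in genes))
        pd.DataFrame(
            [
                dict(gene_id=g, degree=d, gene_class=class_of.get(g, "neutral"))
                for g, d in sorted(degrees.items())
            ]
        ).to_csv(config.out_dir / "degree.tsv", sep="\t", index=False)
        contrast_rows = []
        for name, group in group_sets.items():
            try:
                outcome = compare_centrality(group, neutral, degrees, alternative="less")
            except ValueError:
                continue
            contrast_rows.append(_outcome_row(f"{name}.degree", outcome))
        pd.DataFrame(contrast_rows).to_csv(
            config.out_dir / "centrality_contrasts.tsv", sep="\t", index=False, float_format="%.6g"
        )
        results["network"] = dict(degrees=degrees, contrasts=contrast_rows)
        logger.info("network: %d nodes, %d edges", net.n_nodes, net.n_edges)

    _write_config(config)
    return results


def _write_config(config: PipelineConfig) -> None:
    payload = asdict(config)
    payload["scenario_dir"] = str(config.scenario_dir)
    payload["out_dir"] = str(config.out_dir)
    payload["stages"] = list(config.stages)
    with open(config.out_dir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
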
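"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the shape of the real inputs — multi-sample CNV
calls jittered around planted CNVRs, ortholog codon pairs evolved at known
dN/dS, expression matrices with planted broad and tissue-specific genes,
GO-style annotation tables with planted enriched terms, and interaction
networks with class-specific degree distributions — and emits a
machine-readable truth table for each, so every stage can be tested for
exact or statistical recovery without any external download.

Defaults mirror the study conditions the pipeline targets: 175 samples, a
male-X ploidy baseline (all animals are bulls: autosomes 2, X 1), a 22-tissue
expression panel split across microarray and RNA-seq experiments with six
tissues assayed twice, CNVR state proportions of roughly 53% loss / 28% gain
/ 19% mixed, and per-class dN/dS around 0.18 (neutral) to 0.32
(duplication).  The synthetic genome is a scaled-down stand-in: 29 autosomes
plus X of 3 Mb each, so that whole-pipeline runs stay fast while preserving
all the coordinate arithmetic of a real assembly.

Determinism: a fixed seed yields byte-identical output files.  Each
sub-generator draws from its own stream spawned from the master seed, so
adding or removing one stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .cnvr import CnvCall
from .enrichment import AnnotationTable
from .expression import ExpressionMatrix
from .gene_annotation import GeneModel
from .io_formats import (
    GenomeDescription,
    write_cnv_calls,
    write_edge_list,
    write_gene_models_gff3,
    write_genome,
)
from .selection import CodonSequencePair, _CODE

__all__ = [
    "SimulationConfig",
    "ScenarioData",
    "default_genome",
    "simulate_cnv_calls",
    "simulate_gene_models",
    "simulate_ortholog_pairs",
    "simulate_expression",
    "simulate_ppi",
    "simulate_go_annotations",
    "simulate_all",
    "write_scenario",
]

TISSUES_22 = (
    "mesenteric_fat",
    "spleen",
    "duodenum",
    "jejunum",
    "ileum",
    "brain",
    "colon",
    "heart",
    "kidney",
    "liver",
    "lung",
    "skeletal_muscle",
    "testes",
    "hypothalamus",
    "pituitary_gland",
    "uterus",
    "endometrium",
    "ovary",
    "subcutaneous_fat",
    "longissimus_dorsi_muscle",
    "rumen",
    "adipose",
)

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def default_genome(
    n_autosomes: int = 29, chrom_length: int = 3_000_000
) -> dict[str, GenomeDescription]:
    """A scaled-down cattle-like genome: 29 autosomes (ploidy 2) plus X (ploidy 1)."""
    genome = {
        str(i): GenomeDescription(str(i), chrom_length, 2) for i in range(1, n_autosomes + 1)
    }
    genome["X"] = GenomeDescription("X", chrom_length, 1)
    return genome


@dataclass
class SimulationConfig:
    """Knobs of the synthetic scenario; defaults are the study conditions."""

    seed: int = 0
    genome: dict[str, GenomeDescription] = field(default_factory=default_genome)
    n_samples: int = 175
    n_true_cnvrs: int = 100
    boundary_jitter_sd: float = 300.0  # bases
    boundary_jitter_frac: float | None = None  # overrides: sd = frac * region length
    min_region_size: int = 2_000
    max_region_size: int = 200_000
    state_probs: tuple[float, float, float] = (0.53, 0.28, 0.19)  # loss, gain, mixed
    max_carrier_fraction: float = 0.36
    n_genes: int = 2_000
    genes_per_cnvr: int = 1
    biotype_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.873,
            "snRNA": 0.064,
            "pseudogene": 0.054,
            "rRNA": 0.009,
        }
    )
    class_omega: Mapping[str, float] = field(
        default_factory=lambda: {
            "duplication": 0.3151,
            "deletion": 0.2308,
            "mixed": 0.2702,
            "neutral": 0.1843,
        }
    )
    target_ds: float = 0.43
    n_codons: int = 300
    tissues: tuple[str, ...] = TISSUES_22
    cnv_breadth_median: int = 2
    neutral_breadth_median: int = 10
    samples_per_tissue: int = 2
    degree_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "duplication": 5.0,
            "deletion": 10.0,
            "mixed": 10.0,
            "neutral": 10.0,
        }
    )
    n_background_terms: int = 40
    n_enriched_terms: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.state_probs) - 1.0) > 1e-9:
            raise ValueError("state_probs must sum to 1")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")


# one spawned stream per sub-generator, in fixed order
_STREAMS = ("cnvs", "genes", "orthologs", "expression", "ppi", "annotations")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[idx])


# ---------------------------------------------------------------------------
# CNV calls


def simulate_cnv_calls(config: SimulationConfig) -> tuple[list[CnvCall], pd.DataFrame]:
    """Plant non-overlapping CNVRs and emit jittered per-carrier calls.

    Each planted region receives a carrier count drawn from a 1/f frequency
    spectrum (rare regions common, one region may reach ``max_carrier_fraction``
    of the population).  Carrier calls jitter both endpoints by a truncated
    normal; the jitter is clamped to a sixth of the region length per
    endpoint, which guarantees that every call keeps >= 50% reciprocal
    overlap with its planted region and with every sibling call.

    Returns the calls plus a truth table (one row per planted region).
    """
    rng = _rng(config, "cnvs")
    genome = config.genome
    chroms = sorted(genome)
    weights = np.array([genome[c].length for c in chroms], dtype=float)
    weights /= weights.sum()

    def jitter_sd(length: int) -> float:
        if config.boundary_jitter_frac is not None:
            return config.boundary_jitter_frac * length
        return config.boundary_jitter_sd

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    regions: list[dict] = []
    samples = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    fmax = max(3, int(round(config.max_carrier_fraction * config.n_samples)))
    freq_support = np.arange(1, fmax + 1)
    freq_weights = 1.0 / freq_support
    freq_weights /= freq_weights.sum()
    states = np.array(["loss", "gain", "mixed"])

    for idx in range(config.n_true_cnvrs):
        size = int(
            np.exp(
                rng.uniform(np.log(config.min_region_size), np.log(config.max_region_size))
            )
        )
        ok = False
        for _ in range(2000):
            chrom = str(rng.choice(chroms, p=weights))
            limit = genome[chrom].length - size
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + size
            margin = size / 6.0 + 2.0 * jitter_sd(size) + 1.0
            conflict = any(
                start - (margin + (e - s) / 6.0) < e and end + (margin + (e - s) / 6.0) > s
                for s, e in placed[chrom]
            )
            if not conflict:
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place planted region {idx + 1} without conflict: "
                "genome too small for the requested region count/sizes"
            )
        placed[chrom].append((start, end))
        freq = int(rng.choice(freq_support, p=freq_weights))
        state = str(rng.choice(states, p=config.state_probs))
        if state == "mixed" and freq < 2:
            # a single carrier cannot show both directions
            p_loss_gain = config.state_probs[0] + config.state_probs[1]
            if p_loss_gain > 0:
                state = "loss" if rng.random() < config.state_probs[0] / p_loss_gain else "gain"
            else:
                freq = 2  # all-mixed scenario: force a second carrier

        carriers = sorted(rng.choice(samples, size=freq, replace=False).tolist())
        regions.append(
            dict(
                cnvr_id=f"TRUE_{idx + 1}",
                chrom=chrom,
                start=start,
                end=end,
                state=state,
                carriers=carriers,
            )
        )

    calls: list[CnvCall] = []
    for region in regions:
        baseline = genome[region["chrom"]].expected_copy_number
        length = region["end"] - region["start"]
        max_shift = length // 6
        n_car = len(region["carriers"])
        if region["state"] == "mixed":
            n_loss = int(rng.integers(1, n_car))  # both directions present
            direction = ["loss"] * n_loss + ["gain"] * (n_car - n_loss)
        else:
            direction = [region["state"]] * n_car
        sd = jitter_sd(length)
        for sample, dirn in zip(region["carriers"], direction):
            ds = int(np.clip(round(rng.normal(0.0, sd)), -max_shift, max_shift))
            de = int(np.clip(round(rng.normal(0.0, sd)), -max_shift, max_shift))
            if dirn == "loss":
                cn = int(rng.integers(0, baseline))
            else:
                cn = baseline + int(rng.integers(1, 3))
            calls.append(
                CnvCall(sample, region["chrom"], region["start"] + ds, region["end"] + de, cn)
            )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    truth = pd.DataFrame(
        [
            dict(
                cnvr_id=r["cnvr_id"],
                chrom=r["chrom"],
                start=r["start"],
                end=r["end"],
                length=r["end"] - r["start"],
                state=r["state"],
                n_carriers=len(r["carriers"]),
            )
            for r in regions
        ]
    )
    return calls, truth


# ---------------------------------------------------------------------------
# Gene models


_STATE_TO_CLASS = {"gain": "duplication", "loss": "deletion", "mixed": "mixed"}


def simulate_gene_models(
    config: SimulationConfig, cnvr_truth: pd.DataFrame
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place genes on the synthetic genome, some inside planted CNVRs.

    Each planted region hosts ``genes_per_cnvr`` genes fully inside it, so
    the planted gene class follows directly from the region state; all other
    genes are placed clear of every planted region (with the jitter margin)
    and are neutral by construction.
    """
    rng = _rng(config, "genes")
    genome = config.genome
    chroms = sorted(genome)
    weights = np.array([genome[c].length for c in chroms], dtype=float)
    weights /= weights.sum()
    biotypes = list(config.biotype_probs)
    bio_p = np.array([config.biotype_probs[b] for b in biotypes], dtype=float)
    bio_p /= bio_p.sum()

    regions_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for row in cnvr_truth.itertuples():
        regions_by_chrom[row.chrom].append((row.start, row.end))

    genes: list[GeneModel] = []
    truth_rows: list[dict] = []
    gid = 0

    def next_id() -> str:
        nonlocal gid
        gid += 1
        return f"G{gid:05d}"

    # genes planted inside CNVRs
    for row in cnvr_truth.itertuples():
        for _ in range(config.genes_per_cnvr):
            glen = min(row.length - 2, int(rng.integers(1_000, 5_000)))
            glen = max(glen, 200)
            gstart = row.start + int(rng.integers(0, max(1, row.length - glen)))
            gene_id = next_id()
            biotype = str(rng.choice(biotypes, p=bio_p))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gene_id, row.chrom, gstart, gstart + glen, strand, biotype))
            truth_rows.append(
                dict(
                    gene_id=gene_id,
                    gene_class=_STATE_TO_CLASS[row.state],
                    biotype=biotype,
                    cnvr_id=row.cnvr_id,
                )
            )

    # neutral genes, clear of every planted region plus jitter margin
    n_neutral = config.n_genes - len(genes)
    for _ in range(max(0, n_neutral)):
        glen = int(rng.integers(2_000, 10_000))
        for _ in range(2000):
            chrom = str(rng.choice(chroms, p=weights))
            limit = genome[chrom].length - glen
            if limit <= 0:
                continue
            gstart = int(rng.integers(0, limit))
            gend = gstart + glen
            conflict = any(
                gstart < e + (e - s) / 6.0 + 2 * config.boundary_jitter_sd
                and gend > s - (e - s) / 6.0 - 2 * config.boundary_jitter_sd
                for s, e in regions_by_chrom[chrom]
            )
            if not conflict:
                break
        else:
            raise RuntimeError("could not place a neutral gene clear of planted regions")
        gene_id = next_id()
        biotype = str(rng.choice(biotypes, p=bio_p))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id, chrom, gstart, gend, strand, biotype))
        truth_rows.append(
            dict(gene_id=gene_id, gene_class="neutral", biotype=biotype, cnvr_id="")
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes, pd.DataFrame(truth_rows).sort_values("gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Ortholog codon pairs


def _evolve_sequence(
    codons: list[str], omega: float, mu: float, rng: np.random.Generator
) -> list[str]:
    """Propose/accept per-site substitutions along one branch.

    Every nucleotide site receives Poisson(mu) proposal events; a proposed
    change to one of the three alternative bases is accepted with
    probability 1 when synonymous and ``omega`` when nonsynonymous, and
    always rejected when it would create a stop codon.  At low divergence
    the accepted synonymous rate per site approaches ``mu``, so ``mu``
    doubles as the target dS.
    """
    derived = list(codons)
    n_sites = 3 * len(derived)
    n_events = rng.poisson(mu, size=n_sites)
    for site in np.nonzero(n_events)[0]:
        ci, pos = divmod(int(site), 3)
        for _ in range(int(n_events[site])):
            codon = derived[ci]
            current = codon[pos]
            alt = "ACGT".replace(current, "")[int(rng.integers(0, 3))]
            candidate = codon[:pos] + alt + codon[pos + 1 :]
            if candidate in ("TAA", "TAG", "TGA"):
                continue
            if _CODE[codon] == _CODE[candidate] or rng.random() < omega:
                derived[ci] = candidate
    return derived


def simulate_ortholog_pairs(
    config: SimulationConfig, gene_classes: Mapping[str, str]
) -> tuple[list[CodonSequencePair], pd.DataFrame]:
    """Evolve a codon pair per gene at the dN/dS of its class.

    The ancestor is drawn uniformly from sense codons; one lineage is
    evolved at target synonymous divergence ``target_ds`` (kept < 0.5 so the
    Jukes-Cantor correction never saturates in expectation).  Returns the
    pairs and a truth table with the true omega per gene.
    """
    if config.target_ds >= 0.5:
        raise ValueError("target_ds must stay below 0.5 to avoid saturation")
    rng = _rng(config, "orthologs")
    pairs: list[CodonSequencePair] = []
    rows: list[dict] = []
    for gene_id in sorted(gene_classes):
        cls = gene_classes[gene_id]
        omega = config.class_omega[cls]
        ancestor = [
            _SENSE_CODONS[i]
            for i in rng.integers(0, len(_SENSE_CODONS), size=config.n_codons)
        ]
        derived = _evolve_sequence(ancestor, omega, config.target_ds, rng)
        pairs.append(CodonSequencePair(gene_id, "".join(derived), "".join(ancestor)))
        rows.append(dict(gene_id=gene_id, gene_class=cls, omega_true=omega))
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression


def default_expression_design(tissues: Sequence[str]) -> dict[str, dict]:
    """Three experiments over the panel with several tissues assayed twice.

    One microarray experiment plus two RNA-seq experiments; the shared
    tissues exercise the cross-experiment union rule.
    """
    t = list(tissues)
    third = max(1, len(t) // 3)
    microarray = t[:third]
    rnaseq_a = t[third : 2 * third + 2]
    rnaseq_b = t[2 * third + 2 :]
    # assay some tissues twice (union rule): first two of each RNA-seq block
    shared_a = microarray[:1] + rnaseq_b[:2]
    shared_b = rnaseq_a[:3]
    return {
        "microarray_a": {"platform": "microarray_upc", "tissues": microarray},
        "rnaseq_a": {"platform": "rnaseq_fpkm", "tissues": rnaseq_a + shared_a},
        "rnaseq_b": {"platform": "rnaseq_fpkm", "tissues": rnaseq_b + shared_b},
    }


def simulate_expression(
    config: SimulationConfig, gene_classes: Mapping[str, str]
) -> tuple[list[ExpressionMatrix], pd.DataFrame]:
    """Planted expression breadth per gene, realized across experiments.

    CNV genes draw a narrow breadth (median ``cnv_breadth_median``), neutral
    genes a broad one (median ``neutral_breadth_median``); the expressed
    tissues are then chosen uniformly.  In every experiment covering an
    expressed tissue (or, for twice-assayed tissues, in at least one of
    them) one sample is given a clearly supra-threshold value; all other
    values sit below threshold, so the calling stage recovers the planted
    sets exactly.
    """
    rng = _rng(config, "expression")
    panel = list(config.tissues)
    n_t = len(panel)
    design = default_expression_design(panel)
    genes = sorted(gene_classes)

    p_cnv = (config.cnv_breadth_median - 1) / (n_t - 1)
    p_neutral = (config.neutral_breadth_median - 1) / (n_t - 1)
    truth_rows: list[dict] = []
    expressed_in: dict[str, set[str]] = {}
    for gene_id in genes:
        p = p_neutral if gene_classes[gene_id] == "neutral" else p_cnv
        breadth = 1 + int(rng.binomial(n_t - 1, p))
        tissues = set(rng.choice(panel, size=breadth, replace=False).tolist())
        expressed_in[gene_id] = tissues
        truth_rows.append(
            dict(
                gene_id=gene_id,
                gene_class=gene_classes[gene_id],
                breadth=breadth,
                tissues=";".join(sorted(tissues)),
            )
        )

    # which experiment(s) reveal each expressed (gene, tissue)
    tissue_experiments: dict[str, list[str]] = {}
    for exp_id, spec in design.items():
        for tissue in spec["tissues"]:
            tissue_experiments.setdefault(tissue, []).append(exp_id)

    reveal: dict[tuple[str, str], set[str]] = {}
    for gene_id in genes:
        for tissue in expressed_in[gene_id]:
            exps = tissue_experiments[tissue]
            chosen = {e for e in exps if rng.random() < 0.7}
            if not chosen:
                chosen = {exps[int(rng.integers(0, len(exps)))]}
            reveal[(gene_id, tissue)] = chosen

    matrices: list[ExpressionMatrix] = []
    for exp_id, spec in design.items():
        platform = spec["platform"]
        samples: list[str] = []
        sample_tissue: dict[str, str] = {}
        for tissue in spec["tissues"]:
            for i in range(1, config.samples_per_tissue + 1):
                name = f"{exp_id}.{tissue}.{i}"
                samples.append(name)
                sample_tissue[name] = tissue
        if platform == "microarray_upc":
            low = rng.uniform(0.0, 0.4, size=(len(genes), len(samples)))
        else:
            low = rng.uniform(0.0, 0.8, size=(len(genes), len(samples)))
        values = pd.DataFrame(low, index=genes, columns=samples)
        col_of = {s: i for i, s in enumerate(samples)}
        gene_row = {g: i for i, g in enumerate(genes)}
        arr = values.to_numpy()
        for (gene_id, tissue), chosen in reveal.items():
            if exp_id not in chosen or tissue not in spec["tissues"]:
                continue
            sample = f"{exp_id}.{tissue}.{1 + int(rng.integers(0, config.samples_per_tissue))}"
            if platform == "microarray_upc":
                arr[gene_row[gene_id], col_of[sample]] = rng.uniform(0.6, 0.98)
            else:
                arr[gene_row[gene_id], col_of[sample]] = rng.uniform(2.0, 150.0)
        values.iloc[:, :] = arr
        matrices.append(
            ExpressionMatrix(
                experiment_id=exp_id,
                platform=platform,
                values=values,
                sample_tissue=sample_tissue,
            )
        )
    return matrices, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# PPI network


def simulate_ppi(
    config: SimulationConfig, gene_classes: Mapping[str, str]
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Configuration-model network with class-specific mean degrees.

    Target degrees are Poisson with the class mean; the resulting multigraph
    is simplified (self-loops and parallel edges removed), so realized
    degrees sit slightly below target — the truth table records the target.
    """
    import networkx as nx

    rng = _rng(config, "ppi")
    genes = sorted(gene_classes)
    target = [int(rng.poisson(config.degree_mean[gene_classes[g]])) for g in genes]
    if sum(target) % 2:
        target[0] += 1
    mg = nx.configuration_model(target, seed=int(rng.integers(0, 2**31 - 1)))
    g = nx.Graph(mg)
    g.remove_edges_from(nx.selfloop_edges(g))
    edges = sorted(
        (genes[a], genes[b]) if genes[a] <= genes[b] else (genes[b], genes[a])
        for a, b in g.edges()
    )
    truth = pd.DataFrame(
        dict(
            gene_id=genes,
            gene_class=[gene_classes[g_] for g_ in genes],
            target_degree=target,
        )
    )
    return edges, truth


# ---------------------------------------------------------------------------
# GO-style annotations


def simulate_go_annotations(
    config: SimulationConfig, gene_classes: Mapping[str, str]
) -> tuple[AnnotationTable, pd.DataFrame]:
    """Annotation terms with a handful planted as CNV-enriched.

    Background terms annotate genes independently of class; enriched terms
    annotate CNV genes at a much higher rate, so the over-representation
    test should flag exactly those.
    """
    rng = _rng(config, "annotations")
    genes = sorted(gene_classes)
    cnv = [g for g in genes if gene_classes[g] != "neutral"]
    term_to_genes: dict[str, frozenset[str]] = {}
    term_names: dict[str, str] = {}
    term_aspects: dict[str, str] = {}
    rows: list[dict] = []
    aspects = ("biological_process", "molecular_function", "cellular_component")
    for i in range(1, config.n_background_terms + 1):
        term = f"TERM_BG_{i:03d}"
        frac = float(rng.uniform(0.01, 0.15))
        mask = rng.random(len(genes)) < frac
        members = frozenset(g for g, m in zip(genes, mask) if m)
        if not members:
            members = frozenset({genes[int(rng.integers(0, len(genes)))]})
        term_to_genes[term] = members
        term_names[term] = f"background process {i}"
        term_aspects[term] = aspects[i % 3]
        rows.append(dict(term_id=term, enriched=False, n_genes=len(members)))
    for i in range(1, config.n_enriched_terms + 1):
        term = f"TERM_ENR_{i:03d}"
        members = set(g for g in cnv if rng.random() < 0.3)
        members |= {g for g in genes if gene_classes[g] == "neutral" and rng.random() < 0.01}
        if not members & set(cnv):
            members.add(cnv[int(rng.integers(0, len(cnv)))])
        term_to_genes[term] = frozenset(members)
        term_names[term] = f"planted enriched process {i}"
        term_aspects[term] = aspects[i % 3]
        rows.append(dict(term_id=term, enriched=True, n_genes=len(members)))
    table = AnnotationTable(
        term_to_genes=term_to_genes, term_names=term_names, term_aspects=term_aspects
    )
    return table, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-scenario assembly


@dataclass
class ScenarioData:
    """Everything one synthetic scenario produced, inputs and truth together."""

    config: SimulationConfig
    calls: list[CnvCall]
    cnvr_truth: pd.DataFrame
    genes: list[GeneModel]
    gene_truth: pd.DataFrame
    pairs: list[CodonSequencePair]
    omega_truth: pd.DataFrame
    matrices: list[ExpressionMatrix]
    breadth_truth: pd.DataFrame
    edges: list[tuple[str, str]]
    degree_truth: pd.DataFrame
    annotation: AnnotationTable
    term_truth: pd.DataFrame

    @property
    def gene_classes(self) -> dict[str, str]:
        return dict(zip(self.gene_truth["gene_id"], self.gene_truth["gene_class"]))


def simulate_all(config: SimulationConfig) -> ScenarioData:
    """Run every sub-generator and return the full in-memory scenario."""
    calls, cnvr_truth = simulate_cnv_calls(config)
    genes, gene_truth = simulate_gene_models(config, cnvr_truth)
    classes = dict(zip(gene_truth["gene_id"], gene_truth["gene_class"]))
    pairs, omega_truth = simulate_ortholog_pairs(config, classes)
    matrices, breadth_truth = simulate_expression(config, classes)
    edges, degree_truth = simulate_ppi(config, classes)
    annotation, term_truth = simulate_go_annotations(config, classes)
    return ScenarioData(
        config=config,
        calls=calls,
        cnvr_truth=cnvr_truth,
        genes=genes,
        gene_truth=gene_truth,
        pairs=pairs,
        omega_truth=omega_truth,
        matrices=matrices,
        breadth_truth=breadth_truth,
        edges=edges,
        degree_truth=degree_truth,
        annotation=annotation,
        term_truth=term_truth,
    )


def write_scenario(data: ScenarioData, outdir: str | Path) -> dict[str, Path]:
    """Write a scenario to disk in the exact formats the pipeline reads.

    Layout::

        genome.tsv  cnv_calls.tsv  genes.gff3
        go_annotations.tsv  go_terms.tsv
        orthologs_query.fasta  orthologs_ortholog.fasta
        expression/manifest.yaml  expression/<experiment>.tsv
        ppi_edges.tsv
        truth/{cnvrs,gene_classes,omega,breadth,degrees,terms}.tsv

    Output is byte-identical for a fixed configuration and seed.
    """
    outdir = Path(outdir)
    (outdir / "expression").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.tsv"
    write_genome(data.config.genome, paths["genome"])
    paths["calls"] = outdir / "cnv_calls.tsv"
    write_cnv_calls(data.calls, paths["calls"], dialect="bed_like")
    paths["genes"] = outdir / "genes.gff3"
    write_gene_models_gff3(data.genes, paths["genes"])

    paths["annotations"] = outdir / "go_annotations.tsv"
    with open(paths["annotations"], "w") as fh:
        fh.write("term_id\tgene_id\n")
        for term in sorted(data.annotation.term_to_genes):
            for gene in sorted(data.annotation.term_to_genes[term]):
                fh.write(f"{term}\t{gene}\n")
    paths["terms"] = outdir / "go_terms.tsv"
    with open(paths["terms"], "w") as fh:
        fh.write("term_id\tterm_name\taspect\n")
        for term in sorted(data.annotation.term_to_genes):
            fh.write(
                f"{term}\t{data.annotation.term_names.get(term, term)}\t"
                f"{data.annotation.term_aspects.get(term, 'biological_process')}\n"
            )

    paths["fasta_query"] = outdir / "orthologs_query.fasta"
    paths["fasta_ortholog"] = outdir / "orthologs_ortholog.fasta"
    SeqIO.write(
        [SeqRecord(Seq(p.seq_query), id=p.gene_id, description="") for p in data.pairs],
        str(paths["fasta_query"]),
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(p.seq_ortholog), id=p.gene_id, description="") for p in data.pairs],
        str(paths["fasta_ortholog"]),
        "fasta",
    )

    manifest: dict[str, dict] = {}
    for m in data.matrices:
        fname = f"{m.experiment_id}.tsv"
        m.values.to_csv(outdir / "expression" / fname, sep="\t", float_format="%.6g")
        manifest[m.experiment_id] = {
            "platform": m.platform,
            "file": fname,
            "samples": dict(sorted(m.sample_tissue.items())),
        }
    paths["manifest"] = outdir / "expression" / "manifest.yaml"
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    paths["edges"] = outdir / "ppi_edges.tsv"
    write_edge_list(data.edges, paths["edges"])

    truth_tables = {
        "cnvrs": data.cnvr_truth,
        "gene_classes": data.gene_truth,
        "omega": data.omega_truth,
        "breadth": data.breadth_truth,
        "degrees": data.degree_truth,
        "terms": data.term_truth,
    }
    for name, frame in truth_tables.items():
        p = outdir / "truth" / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[f"truth_{name}"] = p
    return paths
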
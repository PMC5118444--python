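"""Expression calling across platforms, expression breadth, and tissue specificity.

Each experiment contributes a gene x sample value matrix on one of two
platforms: microarray UPC scores in [0, 1] (probability the gene is active)
or RNA-seq FPKM/RPKM values.  A gene is called *expressed* in a tissue when
at least one sample of that tissue strictly exceeds the platform threshold
(UPC > 0.5; FPKM/RPKM > 1.0).  Calls are unioned across experiments — a
tissue assayed by two experiments counts as expressed if either says so.

*Expression breadth* is the number of tissues a gene is expressed in; a
breadth of exactly 1 defines a *tissue-specific* gene.  The breadth contrast
asks, one-tailed, whether expressed CNV genes are expressed in fewer tissues
than expressed neutral genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ranksum import RankSumOutcome, wilcoxon_rank_sum

__all__ = [
    "ExpressionMatrix",
    "ExpressionCallSet",
    "call_expressed",
    "combine_experiments",
    "tissue_specific_genes",
    "compare_breadth",
]

PLATFORMS = ("microarray_upc", "rnaseq_fpkm")


@dataclass
class ExpressionMatrix:
    """One experiment: a gene x sample matrix plus a sample -> tissue map."""

    experiment_id: str
    platform: str
    values: pd.DataFrame  # genes as index, samples as columns
    sample_tissue: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        missing = [s for s in self.values.columns if s not in self.sample_tissue]
        if missing:
            raise ValueError(f"{self.experiment_id}: samples without tissue assignment: {missing}")
        if self.platform == "microarray_upc":
            vals = self.values.to_numpy()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{self.experiment_id}: UPC values must lie in [0, 1]")
        else:
            if (self.values.to_numpy() < 0).any():
                raise ValueError(f"{self.experiment_id}: FPKM/RPKM values must be non-negative")

    @property
    def tissues(self) -> set[str]:
        return set(self.sample_tissue.values())


@dataclass(frozen=True)
class ExpressionCallSet:
    """Per-gene sets of tissues called expressed, over a fixed tissue panel."""

    tissues_by_gene: Mapping[str, frozenset[str]]
    panel: frozenset[str] = field(default_factory=frozenset)

    def breadth(self, gene: str) -> int:
        return len(self.tissues_by_gene.get(gene, frozenset()))

    def breadths(self) -> dict[str, int]:
        return {g: len(t) for g, t in self.tissues_by_gene.items()}


def call_expressed(
    matrix: ExpressionMatrix,
    upc_threshold: float = 0.5,
    fpkm_threshold: float = 1.0,
) -> dict[str, set[str]]:
    """Per-gene expressed-tissue calls for one experiment.

    The inequality is strict and a single qualifying sample suffices; a gene
    exactly at the threshold in every sample is not expressed.
    """
    if upc_threshold <= 0 or fpkm_threshold <= 0:
        raise ValueError("thresholds must be positive")
    threshold = upc_threshold if matrix.platform == "microarray_upc" else fpkm_threshold
    calls: dict[str, set[str]] = {g: set() for g in matrix.values.index}
    by_tissue: dict[str, list[str]] = {}
    for sample, tissue in matrix.sample_tissue.items():
        if sample in matrix.values.columns:
            by_tissue.setdefault(tissue, []).append(sample)
    for tissue, samples in by_tissue.items():
        expressed = (matrix.values[samples] > threshold).any(axis=1)
        for gene in matrix.values.index[expressed]:
            calls[gene].add(tissue)
    return calls


def combine_experiments(
    callsets: Iterable[dict[str, set[str]]],
    synonyms: Mapping[str, str] | None = None,
    panel: Iterable[str] | None = None,
) -> ExpressionCallSet:
    """Union per-(gene, tissue) calls across experiments.

    ``synonyms`` maps raw tissue labels to canonical panel names; when
    supplied, every tissue must be a key of the table or already canonical
    (a value), otherwise the offenders are listed in the error.  Breadth is
    recomputed on the unioned calls.
    """
    canonical: set[str] = set(synonyms.values()) if synonyms else set()
    merged: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for calls in callsets:
        for gene, tissues in calls.items():
            bucket = merged.setdefault(gene, set())
            for tissue in tissues:
                if synonyms is not None:
                    if tissue in synonyms:
                        tissue = synonyms[tissue]
                    elif tissue not in canonical:
                        unmapped.add(tissue)
                        continue
                bucket.add(tissue)
    if unmapped:
        raise ValueError(f"unmapped tissue names: {sorted(unmapped)}")
    all_tissues = set().union(*merged.values()) if merged else set()
    return ExpressionCallSet(
        tissues_by_gene={g: frozenset(t) for g, t in merged.items()},
        panel=frozenset(panel) if panel is not None else frozenset(all_tissues),
    )


def tissue_specific_genes(callset: ExpressionCallSet) -> dict[str, list[str]]:
    """Genes expressed in exactly one tissue, listed under that tissue.

    Every panel tissue appears in the result, possibly with an empty list.
    """
    out: dict[str, list[str]] = {t: [] for t in sorted(callset.panel)}
    for gene, tissues in callset.tissues_by_gene.items():
        if len(tissues) == 1:
            (tissue,) = tissues
            out.setdefault(tissue, []).append(gene)
    for genes in out.values():
        genes.sort()
    return out


def compare_breadth(
    callset: ExpressionCallSet,
    cnv_genes: set[str],
    neutral_genes: set[str],
) -> RankSumOutcome:
    """One-tailed contrast: are expressed CNV genes expressed in fewer tissues?

    Only genes expressed in at least one tissue enter either group
    ("expressed CNV genes" vs "expressed neutral genes").
    """
    breadths = callset.breadths()
    x = [b for g, b in breadths.items() if g in cnv_genes and b >= 1]
    y = [b for g, b in breadths.items() if g in neutral_genes and b >= 1]
    if not x or not y:
        raise ValueError("both groups must contain expressed genes")
    return wilcoxon_rank_sum(x, y, alternative="less")
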
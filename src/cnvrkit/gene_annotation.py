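"""Intersect CNVRs with gene models and partition genes into CNV classes.

A gene is a *CNV gene* when it shares at least one base with at least one
CNVR (strand is ignored).  The overlap is *complete* when the gene interval
is fully covered by the union of the CNVRs that overlap it, otherwise
*partial*.  CNV genes are partitioned by the states of their overlapping
CNVRs: only-gain regions make a *duplication* gene, only-loss a *deletion*
gene, and anything else (a mixed region, or gain and loss regions together)
a *mixed* gene.  Genes not touched by any CNVR form the complementary
*neutral* set used by the downstream contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cnvr import CnvrRegion

__all__ = [
    "GeneModel",
    "CnvGeneRecord",
    "label_cnvrs",
    "overlap_genes",
    "partition_gene_classes",
    "neutral_genes",
]

GENE_CLASSES = ("duplication", "deletion", "mixed")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with identifier, strand and biotype (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvGeneRecord:
    gene_id: str
    biotype: str
    overlap_kind: str  # "complete" | "partial"
    cnvr_ids: tuple[str, ...]
    gene_class: str | None = None


def label_cnvrs(cnvrs: Sequence[CnvrRegion]) -> dict[str, CnvrRegion]:
    """Assign stable identifiers CNVR_1.. to a CNVR list (in given order)."""
    return {f"CNVR_{i}": r for i, r in enumerate(cnvrs, 1)}


def _covered(gene: GeneModel, intervals: list[tuple[int, int]]) -> bool:
    """True when the union of intervals covers [gene.start, gene.end)."""
    pos = gene.start
    for s, e in sorted(intervals):
        if s > pos:
            return False
        pos = max(pos, e)
        if pos >= gene.end:
            return True
    return pos >= gene.end


def overlap_genes(
    cnvrs: Sequence[CnvrRegion] | Mapping[str, CnvrRegion],
    genes: Sequence[GeneModel],
) -> list[CnvGeneRecord]:
    """Report every gene sharing at least one base with at least one CNVR.

    ``cnvrs`` may be a list (labelled CNVR_1.. in order) or a mapping of
    identifier to region.  Duplicate gene ids are an error.  Records carry
    ``gene_class`` already assigned when the CNVRs are state-classified.
    """
    labelled = cnvrs if isinstance(cnvrs, Mapping) else label_cnvrs(cnvrs)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    by_chrom: dict[str, list[tuple[str, CnvrRegion]]] = {}
    for cid, r in labelled.items():
        by_chrom.setdefault(r.chrom, []).append((cid, r))
    records: list[CnvGeneRecord] = []
    states = {cid: r.state for cid, r in labelled.items()}
    for g in genes:
        hits = [
            (cid, r)
            for cid, r in by_chrom.get(g.chrom, [])
            if min(g.end, r.end) - max(g.start, r.start) > 0
        ]
        if not hits:
            continue
        kind = "complete" if _covered(g, [(r.start, r.end) for _, r in hits]) else "partial"
        cnvr_ids = tuple(sorted(cid for cid, _ in hits))
        gene_class = None
        if all(states[cid] is not None for cid in cnvr_ids):
            gene_class = _class_from_states([states[cid] for cid in cnvr_ids])
        records.append(CnvGeneRecord(g.gene_id, g.biotype, kind, cnvr_ids, gene_class))
    return records


def _class_from_states(states: Iterable[str]) -> str:
    states = set(states)
    if states == {"gain"}:
        return "duplication"
    if states == {"loss"}:
        return "deletion"
    return "mixed"


def partition_gene_classes(
    records: Sequence[CnvGeneRecord], cnvr_states: Mapping[str, str]
) -> dict[str, set[str]]:
    """Partition CNV genes into duplication/deletion/mixed sets.

    A gene overlapped only by gain CNVRs is a duplication gene; only by loss,
    a deletion gene; otherwise mixed.  The three sets are disjoint and
    exhaust the CNV gene set.
    """
    out: dict[str, set[str]] = {c: set() for c in GENE_CLASSES}
    for rec in records:
        states = []
        for cid in rec.cnvr_ids:
            if cid not in cnvr_states:
                raise KeyError(f"no state for CNVR {cid!r}")
            states.append(cnvr_states[cid])
        out[_class_from_states(states)].add(rec.gene_id)
    return out


def neutral_genes(genes: Sequence[GeneModel], records: Sequence[CnvGeneRecord]) -> set[str]:
    """Genes not overlapped by any CNVR: the complement of the CNV gene set."""
    cnv = {r.gene_id for r in records}
    return {g.gene_id for g in genes} - cnv
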
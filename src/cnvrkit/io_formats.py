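"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
All *internal* coordinates are 0-based half-open ``[start, end)``, so that
``length == end - start``.  GFF3/GTF input (1-based inclusive) is shifted on
read.  BED input is taken as-is.  Report TSVs display 1-based inclusive
coordinates to match Ensembl-style tables, and every writer states its
convention in a leading ``#`` comment.

Chromosome names are matched as exact text; no "chr" prefix normalization is
applied (silent renaming hides data errors).  Strand is carried on gene
models but ignored by all overlap computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

from .cnvr import CnvCall, CnvrRegion
from .gene_annotation import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeDescription",
    "make_genome",
    "read_genome",
    "write_genome",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_gene_models",
    "write_gene_models_gff3",
    "write_cnvr_report",
    "read_cnvr_report",
    "read_annotation_table",
    "read_edge_list",
    "write_edge_list",
    "read_fasta_pairs",
    "read_manifest",
]


@dataclass(frozen=True)
class GenomeDescription:
    """One chromosome: name, length in bases, and ploidy baseline.

    ``expected_copy_number`` is the copy number of a neutral locus on this
    chromosome (2 for autosomes; 1 for the X chromosome of male samples).
    """

    name: str
    length: int
    expected_copy_number: int = 2

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be positive")
        if self.expected_copy_number < 1:
            raise ValueError(f"chromosome {self.name}: expected copy number must be >= 1")


def make_genome(
    lengths: Mapping[str, int],
    baselines: Mapping[str, int] | None = None,
    default_baseline: int = 2,
) -> dict[str, GenomeDescription]:
    """Build a genome description from chromosome lengths and optional baselines."""
    baselines = baselines or {}
    return {
        name: GenomeDescription(name, length, baselines.get(name, default_baseline))
        for name, length in lengths.items()
    }


def read_genome(path: str | Path) -> dict[str, GenomeDescription]:
    """Read a genome TSV with columns chrom, length, expected_copy_number."""
    genome: dict[str, GenomeDescription] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "chrom":
                continue
            try:
                name, length, ecn = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: malformed genome row: {exc}") from None
            if name in genome:
                raise ValueError(f"{path}, line {lineno}: duplicate chromosome {name!r}")
            genome[name] = GenomeDescription(name, length, ecn)
    return genome


def write_genome(genome: Mapping[str, GenomeDescription], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\texpected_copy_number\n")
        for g in genome.values():
            fh.write(f"{g.name}\t{g.length}\t{g.expected_copy_number}\n")


# ---------------------------------------------------------------------------
# CNV calls

_CALL_COLUMNS = ("sample", "chrom", "start", "end", "copy_number")


def read_cnv_calls(path: str | Path, dialect: str = "bed_like") -> list[CnvCall]:
    """Read per-sample CNV calls from a BED-like or headered TSV table.

    Dialects
    --------
    ``bed_like``
        Five whitespace-separated columns ``sample chrom start end
        copy_number`` with 0-based half-open coordinates and no header.
    ``tsv_with_header``
        Tab-separated with a header naming the same columns in any order;
        coordinates are 1-based inclusive (Ensembl-style) and shifted on
        read.

    Records are returned sorted by (chrom, start, end, sample).  Malformed
    rows raise a :class:`ValueError` naming the offending line.
    """
    if dialect not in ("bed_like", "tsv_with_header"):
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: list[CnvCall] = []
    with open(path) as fh:
        header: dict[str, int] | None = None
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t") if "\t" in line else line.split()
            if dialect == "tsv_with_header" and header is None:
                header = {name: i for i, name in enumerate(fields)}
                missing = [c for c in _CALL_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"{path}: header missing columns {missing}")
                continue
            try:
                if dialect == "bed_like":
                    sample, chrom = fields[0], fields[1]
                    start, end = int(fields[2]), int(fields[3])
                    cn = int(fields[4])
                else:
                    sample = fields[header["sample"]]
                    chrom = fields[header["chrom"]]
                    start = int(fields[header["start"]]) - 1  # 1-based inclusive
                    end = int(fields[header["end"]])
                    cn = int(fields[header["copy_number"]])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: malformed CNV call row: {exc}") from None
            try:
                calls.append(CnvCall(sample, chrom, start, end, cn))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path, dialect: str = "bed_like") -> None:
    """Write CNV calls in a dialect readable by :func:`read_cnv_calls`."""
    with open(path, "w") as fh:
        if dialect == "bed_like":
            fh.write("# columns: sample chrom start end copy_number (0-based half-open)\n")
            for c in calls:
                fh.write(f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.copy_number}\n")
        elif dialect == "tsv_with_header":
            fh.write("# coordinates: 1-based inclusive\n")
            fh.write("\t".join(_CALL_COLUMNS) + "\n")
            for c in calls:
                fh.write(f"{c.sample_id}\t{c.chrom}\t{c.start + 1}\t{c.end}\t{c.copy_number}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Gene models


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3, GTF, or BED.

    Only features of type ``gene`` are kept from GFF3/GTF (the number of
    skipped features is logged).  GFF3/GTF coordinates (1-based inclusive)
    are shifted to the internal 0-based half-open convention; BED is taken
    as-is.  BED columns: chrom, start, end, gene_id, [score], [strand],
    [biotype].
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".gff": "gff3", ".gff3": "gff3", ".gtf": "gtf", ".bed": "bed"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer gene-model format from {path.name!r}; pass fmt=")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    skipped = 0
    if fmt == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    gene_id = fields[3]
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}, line {lineno}: malformed BED row: {exc}") from None
                strand = fields[5] if len(fields) > 5 else "."
                biotype = fields[6] if len(fields) > 6 else "protein_coding"
                if gene_id in seen:
                    raise ValueError(f"{path}, line {lineno}: duplicate gene_id {gene_id!r}")
                seen.add(gene_id)
                genes.append(GeneModel(gene_id, chrom, start, end, strand, biotype))
    else:
        from gffutils.iterators import DataIterator

        for feature in DataIterator(str(path)):
            if feature.featuretype != "gene":
                skipped += 1
                continue
            attrs = feature.attributes
            gene_id = (attrs.get("gene_id") or attrs.get("ID") or [None])[0]
            if gene_id is None:
                raise ValueError(
                    f"{path}: gene feature at {feature.seqid}:{feature.start}-{feature.end} "
                    "lacks a gene_id/ID attribute"
                )
            gene_id = gene_id.removeprefix("gene:")
            biotype = (attrs.get("biotype") or attrs.get("gene_biotype") or ["protein_coding"])[0]
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id,
                    feature.seqid,
                    feature.start - 1,  # GFF/GTF are 1-based inclusive
                    feature.end,
                    feature.strand,
                    biotype,
                )
            )
    if skipped:
        logger.info("read_gene_models(%s): skipped %d non-gene features", path, skipped)
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def write_gene_models_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID=gene:{g.gene_id};gene_id={g.gene_id};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tcnvrkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# CNVR reports


def write_cnvr_report(
    cnvrs: Sequence[CnvrRegion], path: str | Path, bed_path: str | Path | None = None
) -> None:
    """Write a CNVR report TSV (1-based inclusive) and optionally a BED track.

    Member calls are serialized as ``sample:start-end:cn`` (1-based inclusive
    display) separated by commas, which :func:`read_cnvr_report` parses back.
    """
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive; member calls sample:start-end:cn\n")
        fh.write("cnvr_id\tchrom\tstart\tend\tlength\tstate\tn_samples\tmembers\n")
        for i, r in enumerate(cnvrs, 1):
            members = ",".join(
                f"{m.sample_id}:{m.start + 1}-{m.end}:{m.copy_number}" for m in r.members
            )
            fh.write(
                f"CNVR_{i}\t{r.chrom}\t{r.start + 1}\t{r.end}\t{r.length}\t"
                f"{r.state or 'NA'}\t{r.n_samples}\t{members}\n"
            )
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            fh.write('track name="CNVRs" description="copy-number variable regions (0-based half-open)"\n')
            for i, r in enumerate(cnvrs, 1):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tCNVR_{i}_{r.state or 'NA'}\n")


def read_cnvr_report(path: str | Path) -> list[CnvrRegion]:
    """Parse a report written by :func:`write_cnvr_report` back into regions."""
    cnvrs: list[CnvrRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#") or line.startswith("cnvr_id\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                chrom = fields[1]
                state = None if fields[5] == "NA" else fields[5]
                members = []
                for token in fields[7].split(","):
                    sample, span, cn = token.rsplit(":", 2)
                    s, e = span.split("-")
                    members.append(CnvCall(sample, chrom, int(s) - 1, int(e), int(cn)))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: malformed CNVR row: {exc}") from None
            cnvrs.append(
                CnvrRegion(
                    chrom=chrom,
                    start=int(fields[2]) - 1,
                    end=int(fields[3]),
                    members=tuple(sorted(members)),
                    state=state,
                )
            )
    return cnvrs


# ---------------------------------------------------------------------------
# Annotation tables, edge lists, sequences, manifests


def read_annotation_table(
    term_gene_path: str | Path, term_meta_path: str | Path | None = None
):
    """Read a term->gene annotation table (two-column TSV) and optional metadata.

    The metadata TSV has columns term_id, term_name, aspect.  Returns an
    :class:`~cnvrkit.enrichment.AnnotationTable`.
    """
    from .enrichment import AnnotationTable

    term_to_genes: dict[str, set[str]] = {}
    with open(term_gene_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#") or line.startswith("term_id\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{term_gene_path}, line {lineno}: expected 2 columns")
            term_to_genes.setdefault(fields[0], set()).add(fields[1])
    term_names: dict[str, str] = {}
    term_aspects: dict[str, str] = {}
    if term_meta_path is not None:
        with open(term_meta_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#") or line.startswith("term_id\t"):
                    continue
                fields = line.rstrip("\n").split("\t")
                term_names[fields[0]] = fields[1] if len(fields) > 1 else fields[0]
                if len(fields) > 2:
                    term_aspects[fields[0]] = fields[2]
    return AnnotationTable(
        term_to_genes={t: frozenset(g) for t, g in term_to_genes.items()},
        term_names=term_names,
        term_aspects=term_aspects,
    )


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read an undirected interaction edge list (two-column TSV, optional score).

    Duplicate and reversed edges are *not* deduplicated here; network
    construction handles symmetrization.  Malformed rows raise with line
    numbers.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#") or line.startswith("gene_a\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}, line {lineno}: malformed edge row {line.rstrip()!r}")
            edges.append((fields[0], fields[1]))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_fasta_pairs(path1: str | Path, path2: str | Path) -> list:
    """Read paired coding sequences from two FASTA files with matched record order.

    Returns a list of :class:`~cnvrkit.selection.CodonSequencePair`, one per
    record pair; the gene id is taken from the first file's record ids.
    """
    from .selection import CodonSequencePair

    recs1 = list(SeqIO.parse(str(path1), "fasta"))
    recs2 = list(SeqIO.parse(str(path2), "fasta"))
    if len(recs1) != len(recs2):
        raise ValueError(
            f"paired FASTA files differ in record count: {len(recs1)} vs {len(recs2)}"
        )
    return [
        CodonSequencePair(r1.id, str(r1.seq).upper(), str(r2.seq).upper())
        for r1, r2 in zip(recs1, recs2)
    ]


def read_manifest(path: str | Path) -> dict:
    """Read a YAML manifest (expression experiments, scenario layout, ...)."""
    with open(path) as fh:
        return yaml.safe_load(fh)
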
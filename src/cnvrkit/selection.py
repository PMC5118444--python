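"""Selective constraint on gene pairs: Nei-Gojobori dN/dS with Jukes-Cantor correction.

The estimation protocol mirrors the classic pairwise workflow for ortholog
coding sequences:

1. translate both nucleotide sequences with the standard genetic code;
2. globally align the proteins under the BLOSUM50 matrix with affine gap
   penalties (defaults: open 10, extend 1);
3. copy the amino-acid gaps back onto the nucleotide sequences, producing a
   codon alignment;
4. count synonymous (S) and nonsynonymous (N) sites and observed
   differences (Sd, Nd) with the Nei-Gojobori (1986) proportion method,
   averaging multi-substitution codons over all minimal mutational pathways
   that avoid stop codons;
5. correct the proportions pS = Sd/S and pN = Nd/N for multiple hits with
   the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).

Pairs with pS or pN >= 3/4 are *saturated* (the logarithm is undefined) and
are excluded from downstream contrasts.  The ratio omega = dN/dS measures
selective pressure: omega << 1 purifying selection, omega ~ 1 neutrality,
omega > 1 positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .ranksum import RankSumOutcome, wilcoxon_rank_sum

__all__ = [
    "CodonSequencePair",
    "DndsResult",
    "translate",
    "align_proteins",
    "project_gaps",
    "nei_gojobori_dnds",
    "dnds_pair",
    "filter_saturated",
    "compare_constraint",
]

_TABLE = unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_CODE = dict(_TABLE.forward_table)
_NUCS = "ACGT"
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class CodonSequencePair:
    """Paired coding sequences for one gene and its ortholog."""

    gene_id: str
    seq_query: str
    seq_ortholog: str

    def __post_init__(self) -> None:
        for name, seq in (("query", self.seq_query), ("ortholog", self.seq_ortholog)):
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"{self.gene_id} {name} sequence contains invalid characters {sorted(bad)}"
                )


@dataclass(frozen=True)
class DndsResult:
    """Per-pair substitution-rate estimates.

    S and N are the (fractional) synonymous and nonsynonymous site counts
    averaged between the two sequences; Sd and Nd the pathway-averaged
    observed differences.  ``omega`` is NaN when both rates are zero and
    infinite when dS = 0 but dN > 0.
    """

    gene_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    saturated: bool


def translate(nt: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Codons containing N become X; a terminal stop codon is trimmed; an
    internal stop raises naming the codon position (1-based).
    """
    nt = nt.upper()
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} is not divisible by 3")
    bad = set(nt) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide characters {sorted(bad)}")
    n_codons = len(nt) // 3
    aa: list[str] = []
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        if "N" in codon:
            aa.append("X")
        elif codon in _STOPS:
            if i == n_codons - 1:
                break  # trim terminal stop
            raise ValueError(f"internal stop codon {codon} at codon position {i + 1}")
        else:
            aa.append(_CODE[codon])
    return "".join(aa)


def align_proteins(
    aa1: str, aa2: str, gap_open: float = 10.0, gap_extend: float = 1.0
) -> tuple[str, str]:
    """Global protein alignment under BLOSUM50 with affine gap penalties.

    Returns the two gapped sequences.  Tie-breaking among co-optimal
    alignments follows the aligner's canonical traceback order, which is
    deterministic for fixed inputs.
    """
    if not aa1 or not aa2:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM50")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(aa1, aa2)[0]
    return str(aln[0]), str(aln[1])


def project_gaps(pair: CodonSequencePair, aa_alignment: tuple[str, str]) -> tuple[str, str]:
    """Copy amino-acid alignment gaps onto the nucleotide sequences.

    Every aligned amino-acid column maps to one codon column; each gap
    becomes a three-base gap ``---``.  The ungapped columns reproduce the
    original codons in order.  Terminal stop codons (trimmed during
    translation) are dropped from the projection.
    """
    out: list[str] = []
    for gapped_aa, nt in zip(aa_alignment, (pair.seq_query, pair.seq_ortholog)):
        n_aa = len(gapped_aa.replace("-", ""))
        if len(nt) < 3 * n_aa:
            raise ValueError(
                f"{pair.gene_id}: nucleotide sequence ({len(nt)} nt) shorter than "
                f"3 x {n_aa} aligned residues"
            )
        codons = iter(nt[3 * i : 3 * i + 3] for i in range(n_aa))
        out.append("".join("---" if ch == "-" else next(codons) for ch in gapped_aa))
    if len(out[0]) != len(out[1]):
        raise ValueError(f"{pair.gene_id}: projected codon alignments differ in length")
    return out[0], out[1]


@lru_cache(maxsize=None)
def _site_counts(codon: str) -> tuple[float, float]:
    """Nei-Gojobori synonymous/nonsynonymous site counts for one sense codon.

    At each of the three positions, the synonymous fraction is the share of
    the three alternative nucleotides whose substitution preserves the amino
    acid; changes producing a stop codon count as nonsynonymous.
    """
    s = 0.0
    aa = _CODE[codon]
    for pos in range(3):
        syn = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if alt not in _STOPS and _CODE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between two codons.

    For codons differing at d positions, every order of applying the d
    single-nucleotide changes is a minimal pathway.  Pathways passing
    through a stop codon are discarded; each remaining pathway contributes
    its per-step synonymous/nonsynonymous tally and the average is returned.
    If every pathway is blocked by stops (rare), all pathways are used with
    steps into stop codons counted as nonsynonymous.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and not allow_stops:
                return None
            # a step is synonymous iff both codons are sense and code the same aa
            if cur not in _STOPS and nxt not in _STOPS and _CODE[cur] == _CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    tallies = [t for t in (walk(o, False) for o in permutations(diffs)) if t is not None]
    if not tallies:
        tallies = [walk(o, True) for o in permutations(diffs)]
    sd = sum(t[0] for t in tallies) / len(tallies)
    nd = sum(t[1] for t in tallies) / len(tallies)
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.nan, True
    d = -0.75 * math.log(arg)
    return (d if d != 0 else 0.0), False


def nei_gojobori_dnds(codon_alignment: tuple[str, str], gene_id: str = "") -> DndsResult:
    """Estimate dN and dS from a codon alignment by the proportion method.

    Columns containing a gap character or a stop codon in either sequence
    are skipped.  Site counts are averaged between the two sequences;
    multi-substitution codons are averaged over minimal mutational pathways
    (see :func:`_diff_counts`).  Proportions are Jukes-Cantor corrected;
    pairs whose correction is undefined are flagged saturated.
    """
    a, b = codon_alignment
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("codon alignment strings must have equal length divisible by 3")
    S = N = Sd = Nd = 0.0
    n_columns = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        n_columns += 1
        sa, na = _site_counts(ca)
        sb, nb = _site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_columns == 0:
        raise ValueError(f"{gene_id or 'pair'}: no ungapped, stop-free codon columns")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, sat_s = _jukes_cantor(pS)
    dN, sat_n = _jukes_cantor(pN)
    saturated = sat_s or sat_n
    if saturated:
        omega = math.nan
    elif dS > 0:
        omega = dN / dS
    elif dN > 0:
        omega = math.inf
    else:
        omega = math.nan  # no substitutions at all: ratio undefined
    return DndsResult(
        gene_id=gene_id,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        saturated=saturated,
    )


def dnds_pair(
    pair: CodonSequencePair, gap_open: float = 10.0, gap_extend: float = 1.0
) -> DndsResult:
    """Full protocol for one ortholog pair: translate, align, project, estimate."""
    aa1 = translate(pair.seq_query)
    aa2 = translate(pair.seq_ortholog)
    aln = align_proteins(aa1, aa2, gap_open=gap_open, gap_extend=gap_extend)
    codon_aln = project_gaps(pair, aln)
    return nei_gojobori_dnds(codon_aln, gene_id=pair.gene_id)


def filter_saturated(results: Iterable[DndsResult]) -> list[DndsResult]:
    """Drop saturated pairs and pairs without defined dN and dS."""
    return [
        r
        for r in results
        if not r.saturated and not math.isnan(r.dN) and not math.isnan(r.dS)
    ]


def compare_constraint(
    class_results: Sequence[DndsResult],
    neutral_results: Sequence[DndsResult],
    statistic: str = "omega",
) -> RankSumOutcome:
    """One-tailed rank-sum contrast of a CNV gene class against neutral genes.

    Tests whether the chosen statistic (``dN``, ``dS`` or ``omega``) of the
    class is shifted toward *higher* values than in neutral genes, i.e.
    relaxed selective constraint.  Saturated pairs must have been removed;
    for ``omega``, pairs with dS = 0 (infinite or undefined ratio) are
    excluded.
    """
    if statistic not in ("dN", "dS", "omega"):
        raise ValueError(f"unknown statistic {statistic!r}")

    def values(results: Sequence[DndsResult]) -> list[float]:
        vals = []
        for r in results:
            v = getattr(r, statistic)
            if math.isnan(v) or math.isinf(v):
                continue
            vals.append(v)
        return vals

    vx, vy = values(class_results), values(neutral_results)
    if not vx or not vy:
        raise ValueError("both groups must be non-empty after filtering")
    return wilcoxon_rank_sum(vx, vy, alternative="greater")
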
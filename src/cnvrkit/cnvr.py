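"""Copy-number variable region (CNVR) construction and summaries.

Per-sample CNV calls (the output shape of a multi-sample read-depth caller)
are merged across samples into CNVRs under a pairwise reciprocal-overlap
rule: two regions qualify when ``min(o/|A|, o/|B|) >= threshold`` where ``o``
is the shared length.  Merging is an iterative fixed point: starting from the
calls sorted by (chrom, start, end, sample), the first qualifying pair in
sorted order is merged into a region spanning min start to max end, and the
scan restarts until no pair qualifies.  The result is a deterministic
partition of the input calls, independent of the order in which they were
supplied.

All coordinates are 0-based half-open; interval length is ``end - start``.
Overlap fractions are compared against the threshold with exact rational
arithmetic on integer lengths so that boundary cases (e.g. exactly 50%) are
never subject to floating-point noise.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CnvCall",
    "CnvrRegion",
    "CnvrSummary",
    "reciprocal_overlap",
    "merge_cnvs",
    "filter_by_frequency",
    "classify_state",
    "classify_all",
    "summarize_cnvrs",
    "compare_cnvr_sets",
]


@dataclass(frozen=True, order=True)
class CnvCall:
    """One sample-level CNV interval with an integer copy number.

    ``start``/``end`` are 0-based half-open base coordinates.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CNV call for {self.sample_id} on {self.chrom}: "
                f"end ({self.end}) must exceed start ({self.start})"
            )
        if self.copy_number < 0:
            raise ValueError(f"negative copy number {self.copy_number}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvrRegion:
    """A cross-sample region formed by merging reciprocally overlapping calls.

    The extent runs from the minimum member start to the maximum member end.
    ``state`` is ``None`` until :func:`classify_state` assigns loss/gain/mixed.
    """

    chrom: str
    start: int
    end: int
    members: tuple[CnvCall, ...]
    state: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("CNVR must have at least one member call")
        if any(m.chrom != self.chrom for m in self.members):
            raise ValueError("all member calls must share the CNVR chromosome")
        if self.start != min(m.start for m in self.members):
            raise ValueError("CNVR start must equal minimum member start")
        if self.end != max(m.end for m in self.members):
            raise ValueError("CNVR end must equal maximum member end")

    @property
    def n_samples(self) -> int:
        """Number of distinct samples contributing a member call."""
        return len({m.sample_id for m in self.members})

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvrSummary:
    count: int
    min_size: int
    max_size: int
    mean_size: float
    median_size: float
    total_unique: int
    genome_fraction: float
    state_counts: Mapping[str, int]


def _interval(x) -> tuple[str, int, int]:
    if isinstance(x, tuple):
        chrom, start, end = x
    else:
        chrom, start, end = x.chrom, x.start, x.end
    if end <= start:
        raise ValueError(f"zero- or negative-length interval [{start}, {end}) on {chrom}")
    return chrom, start, end


def reciprocal_overlap(a, b) -> float:
    """Reciprocal overlap fraction ``min(o/|a|, o/|b|)`` of two intervals.

    Returns 0.0 for intervals on different chromosomes or disjoint
    (half-open: intervals abutting at a single coordinate do not overlap).
    Symmetric in its arguments.
    """
    ca, sa, ea = _interval(a)
    cb, sb, eb = _interval(b)
    if ca != cb:
        return 0.0
    o = min(ea, eb) - max(sa, sb)
    if o <= 0:
        return 0.0
    return min(o / (ea - sa), o / (eb - sb))


def _qualifies(sa: int, ea: int, sb: int, eb: int, thr: Fraction) -> bool:
    # exact rational comparison: min(o/la, o/lb) >= thr  <=>  o >= thr*max(la, lb)
    o = min(ea, eb) - max(sa, sb)
    if o <= 0:
        return False
    longer = max(ea - sa, eb - sb)
    return Fraction(o, longer) >= thr


def merge_cnvs(calls: Iterable[CnvCall], threshold: float = 0.5) -> list[CnvrRegion]:
    """Merge CNV calls into CNVRs by iterated pairwise reciprocal overlap.

    Parameters
    ----------
    calls
        Sample-level CNV calls; may span multiple chromosomes.
    threshold
        Minimum reciprocal overlap for two current regions to merge,
        in (0, 1].  Default 0.5 (50% reciprocal overlap).

    Returns
    -------
    list of CnvrRegion
        One region per merged group, sorted by (chrom, start, end).
        Every input call belongs to exactly one region.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    thr = Fraction(threshold)
    ordered = sorted(calls)
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in sorted(ordered, key=lambda c: (c.chrom, c.start, c.end, c.sample_id)):
        by_chrom.setdefault(c.chrom, []).append(c)

    out: list[CnvrRegion] = []
    for chrom in sorted(by_chrom):
        # region: [start, end, members]; tiebreak key = smallest member tuple
        regs: list[list] = [[c.start, c.end, [c]] for c in by_chrom[chrom]]
        while True:
            regs.sort(key=lambda r: (r[0], r[1], min((m.start, m.end, m.sample_id) for m in r[2])))
            merged = False
            for i in range(len(regs)):
                si, ei = regs[i][0], regs[i][1]
                for j in range(i + 1, len(regs)):
                    sj, ej = regs[j][0], regs[j][1]
                    if sj >= ei:
                        break  # sorted by start: no later region can overlap i
                    if _qualifies(si, ei, sj, ej, thr):
                        regs[i] = [min(si, sj), max(ei, ej), regs[i][2] + regs[j][2]]
                        del regs[j]
                        merged = True
                        break
                if merged:
                    break
            if not merged:
                break
        for s, e, members in regs:
            out.append(
                CnvrRegion(
                    chrom=chrom,
                    start=s,
                    end=e,
                    members=tuple(sorted(members)),
                )
            )
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out


def filter_by_frequency(
    cnvrs: Sequence[CnvrRegion], min_samples: int = 3
) -> tuple[list[CnvrRegion], list[CnvrRegion]]:
    """Split CNVRs into (kept, removed) by distinct-sample count.

    A CNVR is kept when it is present in at least ``min_samples`` distinct
    samples; rarer regions — likely false positives or private variants —
    are returned in the removed list for reporting.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    kept = [r for r in cnvrs if r.n_samples >= min_samples]
    removed = [r for r in cnvrs if r.n_samples < min_samples]
    return kept, removed


def classify_state(cnvr: CnvrRegion, genome: Mapping[str, "GenomeDescription"]) -> str:
    """Classify a CNVR as ``loss``, ``gain`` or ``mixed`` against ploidy baseline.

    Every member call is compared with the expected copy number of its
    chromosome (e.g. 2 for autosomes, 1 for the X of male samples).  A member
    exactly at baseline is an error: a no-change call has no place in a CNV
    list.
    """
    try:
        baseline = genome[cnvr.chrom].expected_copy_number
    except KeyError:
        raise KeyError(f"no baseline copy number for chromosome {cnvr.chrom!r}") from None
    below = above = False
    for m in cnvr.members:
        if m.copy_number < baseline:
            below = True
        elif m.copy_number > baseline:
            above = True
        else:
            raise ValueError(
                f"member call {m.sample_id} {m.chrom}:{m.start}-{m.end} has copy "
                f"number {m.copy_number} equal to the baseline {baseline}"
            )
    if below and above:
        return "mixed"
    return "loss" if below else "gain"


def classify_all(
    cnvrs: Iterable[CnvrRegion], genome: Mapping[str, "GenomeDescription"]
) -> list[CnvrRegion]:
    """Return copies of the CNVRs with their state field assigned."""
    return [replace(r, state=classify_state(r, genome)) for r in cnvrs]


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def summarize_cnvrs(
    cnvrs: Sequence[CnvrRegion], genome: Mapping[str, "GenomeDescription"]
) -> CnvrSummary:
    """Size statistics, unique coverage and per-state counts for a CNVR set."""
    if not cnvrs:
        raise ValueError("cannot summarize an empty CNVR set")
    genome_size = sum(g.length for g in genome.values())
    for r in cnvrs:
        if r.chrom not in genome:
            raise KeyError(f"CNVR chromosome {r.chrom!r} not in genome description")
        if r.end > genome[r.chrom].length:
            raise ValueError(
                f"CNVR {r.chrom}:{r.start}-{r.end} extends beyond chromosome "
                f"length {genome[r.chrom].length}"
            )
        if r.state is None:
            raise ValueError("all CNVRs must be state-classified before summarizing")
    sizes = [r.length for r in cnvrs]
    total_unique = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for ivs in by_chrom.values():
        total_unique += _union_length(ivs)
    state_counts = {"loss": 0, "gain": 0, "mixed": 0}
    for r in cnvrs:
        state_counts[r.state] += 1
    return CnvrSummary(
        count=len(cnvrs),
        min_size=min(sizes),
        max_size=max(sizes),
        mean_size=sum(sizes) / len(sizes),
        median_size=statistics.median(sizes),
        total_unique=total_unique,
        genome_fraction=total_unique / genome_size,
        state_counts=state_counts,
    )


def compare_cnvr_sets(query: Sequence, reference: Sequence) -> float:
    """Fraction of query regions sharing at least one base with any reference interval.

    This is the permissive criterion used when comparing CNVR maps between
    studies: any shared base counts, regardless of reciprocal fraction.
    """
    if not query:
        raise ValueError("query CNVR set is empty")
    ref = [_interval(r) for r in reference]
    hits = 0
    for q in query:
        cq, sq, eq = _interval(q)
        for cr, sr, er in ref:
            if cq == cr and min(eq, er) - max(sq, sr) > 0:
                hits += 1
                break
    return hits / len(query)
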
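"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force (full pair
scans, per-base bitmaps, explicit enumeration) so that the efficient
implementations are checked against an independent route.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from cnvrkit.cnvr import CnvCall
from cnvrkit.io_formats import GenomeDescription, make_genome


@pytest.fixture
def genome():
    """Two autosomes (ploidy 2) and an X (ploidy 1)."""
    return make_genome({"1": 1_000_000, "2": 500_000, "X": 400_000}, baselines={"X": 1})


@pytest.fixture
def rng():
    return np.random.default_rng(20_160_207)


# ---------------------------------------------------------------------------
# brute-force oracles


def merge_oracle(calls: list[CnvCall], threshold: float) -> set[tuple]:
    """Fixed-point agglomeration recomputed from scratch at every step.

    Regions are re-sorted and *all* pairs re-examined after each merge; the
    first qualifying pair in sorted order is merged.  Returns the final
    partition as a set of (chrom, start, end, frozenset-of-members) tuples.
    """
    thr = Fraction(threshold)
    by_chrom: dict[str, list] = {}
    for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample_id)):
        by_chrom.setdefault(c.chrom, []).append([c.start, c.end, frozenset([c])])
    result = set()
    for chrom, regs in by_chrom.items():
        while True:
            regs.sort(
                key=lambda r: (r[0], r[1], min((m.start, m.end, m.sample_id) for m in r[2]))
            )
            pair = None
            for i, j in combinations(range(len(regs)), 2):
                (si, ei, _), (sj, ej, _) = regs[i], regs[j]
                o = min(ei, ej) - max(si, sj)
                if o <= 0:
                    continue
                if Fraction(o, max(ei - si, ej - sj)) >= thr:
                    pair = (i, j)
                    break
            if pair is None:
                break
            i, j = pair
            merged = [
                min(regs[i][0], regs[j][0]),
                max(regs[i][1], regs[j][1]),
                regs[i][2] | regs[j][2],
            ]
            regs = [r for k, r in enumerate(regs) if k not in (i, j)] + [merged]
        for s, e, members in regs:
            result.add((chrom, s, e, members))
    return result


def ranksum_enumeration_oracle(x, y, alternative: str) -> float:
    """Exact rank-sum p by enumerating every split of the pooled values."""
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)

    def u_of(idx: tuple[int, ...]) -> float:
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(idx) for idx in combinations(range(n), n1)]
    if alternative == "greater":
        hits = sum(1 for u in us if u >= u_obs - 1e-9)
    else:
        hits = sum(1 for u in us if u <= u_obs + 1e-9)
    return hits / len(us)


def binomial_upper_tail_oracle(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct term summation."""
    from math import comb

    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))
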
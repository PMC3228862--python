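"""Genomic interval arithmetic on (chrom, start, end) triples.

All coordinates are 0-based half-open.  Inputs may be any iterable of
(chrom, start, end) tuples or objects with .chrom/.start/.end attributes;
outputs are sorted lists of plain tuples.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, List, Tuple

Interval = Tuple[str, int, int]


def as_triples(items: Iterable) -> List[Interval]:
    """Normalize intervals to (chrom, start, end) tuples."""
    out = []
    for it in items:
        if isinstance(it, tuple):
            chrom, start, end = it[0], it[1], it[2]
        else:
            chrom, start, end = it.chrom, it.start, it.end
        out.append((str(chrom), int(start), int(end)))
    return out


def merge(items: Iterable) -> List[Interval]:
    """Merge overlapping or abutting intervals into a disjoint sorted set."""
    triples = sorted(as_triples(items))
    merged: List[Interval] = []
    for chrom, start, end in triples:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def total_bp(items: Iterable) -> int:
    """Total unique bp covered (intervals are merged first)."""
    return sum(e - s for _, s, e in merge(items))


def intersect(a: Iterable, b: Iterable) -> List[Interval]:
    """Intersection of two interval sets as a disjoint sorted list."""
    a_by = defaultdict(list)
    for chrom, s, e in merge(a):
        a_by[chrom].append((s, e))
    out: List[Interval] = []
    for chrom, s, e in merge(b):
        for s2, e2 in a_by.get(chrom, ()):
            lo, hi = max(s, s2), min(e, e2)
            if lo < hi:
                out.append((chrom, lo, hi))
    return sorted(out)


def subtract(a: Iterable, b: Iterable) -> List[Interval]:
    """Parts of interval set ``a`` not covered by ``b``."""
    b_by = defaultdict(list)
    for chrom, s, e in merge(b):
        b_by[chrom].append((s, e))
    out: List[Interval] = []
    for chrom, s, e in merge(a):
        cursor = s
        for s2, e2 in b_by.get(chrom, ()):
            if e2 <= cursor or s2 >= e:
                continue
            if s2 > cursor:
                out.append((chrom, cursor, s2))
            cursor = max(cursor, e2)
            if cursor >= e:
                break
        if cursor < e:
            out.append((chrom, cursor, e))
    return out
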
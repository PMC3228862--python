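"""Convergent primer-site pairing: candidate amplicons and capturable footprint.

An amplicon is the segment bounded by (and including) a rightward-extending
site and a downstream leftward-extending site — the two primers face each
other, so PCR can amplify the intervening sequence.  All convergent pairs
inside the size window are enumerated, nested and overlapping pairs
included: these are amplicons capturable "in principle"; competition between
products in a real reaction is not modelled.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from interalu import intervals
from interalu.site_search import PrimerSite


@dataclass(frozen=True)
class Amplicon:
    """Outer span of a convergent site pair, both primer footprints included."""

    chrom: str
    start: int
    end: int
    left_site: PrimerSite
    right_site: PrimerSite
    pair_class: Optional[str]  # "HH" | "HT" | "TT" | None if a ptype is unknown

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Footprint:
    """Merged union of amplicon spans: the capturable subset of the genome."""

    intervals: List[Tuple[str, int, int]]
    total_bp: int


def _pair_class(a: PrimerSite, b: PrimerSite) -> Optional[str]:
    if a.ptype is None or b.ptype is None:
        return None
    return "".join(sorted((a.ptype, b.ptype)))  # order-insensitive: HT == TH


def enumerate_amplicons(
    sites: Sequence[PrimerSite], min_len: int = 200, max_len: int = 6000
) -> List[Amplicon]:
    """All convergent site pairs whose outer span falls in [min_len, max_len].

    For every rightward-extending site L and leftward-extending site R on the
    same chromosome with L.start < R.end, the span is [L.start, R.end); the
    pair is reported when min_len <= span length <= max_len.  Output sorted
    by (chrom, start, end).
    """
    if not min_len < max_len:
        raise ValueError("need min_len < max_len")
    by_chrom_left: dict = defaultdict(list)
    by_chrom_right: dict = defaultdict(list)
    for s in sites:
        (by_chrom_right if s.extension_direction == "right" else by_chrom_left)[
            s.chrom
        ].append(s)
    amplicons: List[Amplicon] = []
    for chrom, rights in by_chrom_right.items():
        lefts = sorted(by_chrom_left.get(chrom, ()), key=lambda s: s.end)
        if not lefts:
            continue
        ends = [s.end for s in lefts]
        for L in rights:
            lo = bisect_left(ends, L.start + min_len)
            hi = bisect_right(ends, L.start + max_len)
            for R in lefts[lo:hi]:
                amplicons.append(
                    Amplicon(
                        chrom=chrom,
                        start=L.start,
                        end=R.end,
                        left_site=L,
                        right_site=R,
                        pair_class=_pair_class(L, R),
                    )
                )
    return sorted(amplicons, key=lambda a: (a.chrom, a.start, a.end))


def merged_footprint(amplicons: Sequence[Amplicon]) -> Footprint:
    """Union of amplicon spans; total_bp counts each base once."""
    merged = intervals.merge((a.chrom, a.start, a.end) for a in amplicons)
    return Footprint(intervals=merged, total_bp=sum(e - s for _, s, e in merged))


def amplicon_length_histogram(
    amplicons: Sequence[Amplicon],
    bin_width: int = 500,
    min_len: int = 200,
    max_len: int = 6000,
) -> pd.DataFrame:
    """Length distribution: per-bin amplicon count and summed bp.

    Returns a DataFrame with columns bin_start, bin_end, count, bp covering
    [min_len, max_len]; the last bin is right-inclusive.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(min_len, max_len + bin_width, bin_width, dtype=np.int64)
    if edges[-1] < max_len:
        edges = np.append(edges, max_len)
    lengths = np.array([a.length for a in amplicons], dtype=np.int64)
    counts, _ = np.histogram(lengths, bins=edges)
    bp, _ = np.histogram(lengths, bins=edges, weights=lengths)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
            "bp": bp.astype(np.int64),
        }
    )
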
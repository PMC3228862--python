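"""Mismatch-tolerant primer binding-site search.

Two modes: a sequence scan that slides the primer (and its reverse
complement) along the genome counting Hamming mismatches, and a fast
annotation-only mode that places sites arithmetically inside annotated Alu
copies using the primer's consensus offset.

A site's ``extension_direction`` is the direction of 3' polymerase
extension in genome coordinates: a primer matching the top strand extends
rightward; its reverse-complement match on the top strand corresponds to a
bottom-strand annealing that extends leftward.  An amplicon needs one
rightward and one downstream leftward site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np

from interalu.annotations_io import AluElement
from interalu.primer_model import Primer, revcomp


@dataclass(frozen=True)
class PrimerSite:
    chrom: str
    start: int
    end: int
    extension_direction: str  # "left" | "right"
    primer_name: str
    mismatches: int
    ptype: Optional[str] = None

    def __post_init__(self):
        if self.extension_direction not in ("left", "right"):
            raise ValueError("extension_direction must be 'left' or 'right'")


def _hamming_scan(seq: np.ndarray, pattern: str, max_mismatches: int) -> np.ndarray:
    """Offsets where pattern matches seq within the mismatch budget.

    Genome N bases (and any N in the pattern) always count as mismatches,
    so assembly gaps cannot produce phantom sites.
    """
    m = len(pattern)
    if m == 0 or m > seq.size:
        return np.empty(0, dtype=np.int64)
    parr = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq, m)
    mism = (windows != parr) | (windows == ord("N")) | (parr == ord("N"))
    counts = mism.sum(axis=1)
    return np.nonzero(counts <= max_mismatches)[0]


def find_sites(
    genome: Mapping[str, str],
    primer: Primer,
    max_mismatches: int = 0,
    anchor_3prime: int = 0,
) -> List[PrimerSite]:
    """Scan genome sequences for primer binding sites on both strands.

    Every offset where the primer equals the top-strand substring within
    Hamming distance ``max_mismatches`` yields a rightward-extending site;
    every match of its reverse complement yields a leftward-extending site.
    ``anchor_3prime`` > 0 additionally requires the 3'-most that many primer
    bases to match exactly (PCR extension realism; off by default).
    Overlapping sites are all reported.  Output sorted by (chrom, start).
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    fwd = primer.sequence.upper()
    rev = revcomp(fwd)
    m = len(fwd)
    sites: List[PrimerSite] = []
    for chrom in sorted(genome):
        seq = np.frombuffer(genome[chrom].upper().encode("ascii"), dtype=np.uint8)
        for pattern, direction in ((fwd, "right"), (rev, "left")):
            offsets = _hamming_scan(seq, pattern, max_mismatches)
            if anchor_3prime > 0 and offsets.size:
                # 3' end of the annealed primer: rightmost bases for a
                # rightward site, leftmost bases of the revcomp pattern
                # for a leftward site.
                if direction == "right":
                    anchor = pattern[m - anchor_3prime :]
                    keep = [
                        off
                        for off in offsets
                        if genome[chrom][off + m - anchor_3prime : off + m].upper()
                        == anchor
                    ]
                else:
                    anchor = pattern[:anchor_3prime]
                    keep = [
                        off
                        for off in offsets
                        if genome[chrom][off : off + anchor_3prime].upper() == anchor
                    ]
                offsets = np.array(keep, dtype=np.int64)
            parr = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
            for off in offsets:
                window = seq[off : off + m]
                n_mism = int(
                    ((window != parr) | (window == ord("N")) | (parr == ord("N"))).sum()
                )
                sites.append(
                    PrimerSite(
                        chrom=chrom,
                        start=int(off),
                        end=int(off) + m,
                        extension_direction=direction,
                        primer_name=primer.name,
                        mismatches=n_mism,
                        ptype=primer.ptype,
                    )
                )
    return sorted(sites, key=lambda s: (s.chrom, s.start, s.extension_direction))


def predict_sites_from_annotation(
    elements: Sequence[AluElement], primer: Primer
) -> List[PrimerSite]:
    """Place sites arithmetically inside annotated elements (no sequence).

    Requires a convention primer with a consensus offset.  On a + strand
    element the footprint starts at ``element.start + consensus_start - 1``;
    T-type extends rightward, H-type leftward.  On a - strand element the
    footprint mirrors from ``element.end`` and directions flip.  Sites whose
    footprint would fall outside the (possibly truncated) element are dropped.
    """
    if primer.consensus_start is None:
        raise ValueError(
            f"primer {primer.name!r} has no consensus offset; "
            "use find_sites for explicit-sequence primers"
        )
    cs, m = primer.consensus_start, primer.length
    sites: List[PrimerSite] = []
    for elem in elements:
        if elem.strand == "+":
            start = elem.start + cs - 1
            end = start + m
            direction = "right" if primer.ptype == "T" else "left"
        else:
            end = elem.end - (cs - 1)
            start = end - m
            direction = "left" if primer.ptype == "T" else "right"
        if start < elem.start or end > elem.end:
            continue
        sites.append(
            PrimerSite(
                chrom=elem.chrom,
                start=start,
                end=end,
                extension_direction=direction,
                primer_name=primer.name,
                mismatches=0,
                ptype=primer.ptype,
            )
        )
    return sorted(sites, key=lambda s: (s.chrom, s.start, s.extension_direction))


def find_sites_multi(
    genome: Mapping[str, str],
    primers: Iterable[Primer],
    max_mismatches: int = 0,
    anchor_3prime: int = 0,
) -> List[PrimerSite]:
    """Union of find_sites over a primer set, sorted by (chrom, start)."""
    sites: List[PrimerSite] = []
    for primer in primers:
        sites.extend(find_sites(genome, primer, max_mismatches, anchor_3prime))
    return sorted(sites, key=lambda s: (s.chrom, s.start, s.extension_direction))
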
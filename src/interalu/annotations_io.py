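"""Repeat and gene annotation I/O plus inter-Alu gap structures.

Internal coordinates are 0-based half-open throughout; RepeatMasker input
(1-based inclusive, ``C`` for minus strand) is converted on read.  The gap
between two adjacent Alu elements is the open space between their boundaries
(``right.start - left.end``), the sequence an inter-Alu amplicon would span.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import groupby
from typing import List, Optional, Sequence

import numpy as np

from interalu import intervals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AluElement:
    """One annotated repeat copy. divergence is substitutions per 1000 bp."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    divergence: Optional[float] = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty element {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.subfamily:
            raise ValueError("subfamily must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GapRecord:
    """The interval between two adjacent same-chromosome elements."""

    chrom: str
    start: int
    end: int
    left_alu: AluElement
    right_alu: AluElement

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GapHistogram:
    bin_width: int
    min_len: int
    max_len: int
    edges: np.ndarray
    counts: np.ndarray
    total_bp_in_range: int


_RM_HEADER = re.compile(r"^\s*(SW|score|$)")


def read_repeatmasker_out(
    path,
    subfamily_pattern: str = r"^Alu",
    class_pattern: str = r"SINE/Alu",
) -> List[AluElement]:
    """Parse a RepeatMasker .out file, keeping Alu-family records.

    The format has three header lines followed by whitespace-delimited
    columns: score, %div, %del, %ins, query, begin (1-based inclusive),
    end, (left), strand (+ or C), repeat name, repeat class/family, ...
    Records are kept when the class/family matches ``class_pattern`` and
    the repeat name matches ``subfamily_pattern``.  Returned elements use
    0-based half-open coordinates, sorted by (chrom, start).
    """
    sub_re = re.compile(subfamily_pattern)
    cls_re = re.compile(class_pattern)
    elements: List[AluElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _RM_HEADER.match(line):
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: malformed RepeatMasker record at line {lineno}: "
                    f"expected >= 11 fields, got {len(fields)}"
                )
            try:
                div = float(fields[1])
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed RepeatMasker record at line {lineno}: {exc}"
                ) from None
            strand_field, name, cls = fields[8], fields[9], fields[10]
            if not (cls_re.search(cls) and sub_re.search(name)):
                continue
            strand = "-" if strand_field == "C" else "+"
            elements.append(
                AluElement(
                    chrom=chrom,
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    subfamily=name,
                    divergence=div * 10.0,  # percent -> per-1000
                )
            )
    if not elements:
        logger.warning("no Alu records found in %s", path)
    return sorted(elements, key=lambda e: (e.chrom, e.start))


def read_bed6(path) -> List[AluElement]:
    """Read elements from BED6 (chrom, start, end, name, score, strand)."""
    elements = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: BED6 needs 6 columns at line {lineno}")
            elements.append(
                AluElement(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                    subfamily=fields[3],
                )
            )
    return sorted(elements, key=lambda e: (e.chrom, e.start))


def write_bed6(elements: Sequence[AluElement], path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.subfamily}\t0\t{e.strand}\n")


def merge_overlapping(elements: Sequence[AluElement]) -> List[AluElement]:
    """Merge overlapping/abutting same-chromosome elements.

    The merged interval keeps the subfamily and strand of its longest
    constituent.  Output is non-overlapping and sorted.
    """
    merged: List[AluElement] = []
    for elem in sorted(elements, key=lambda e: (e.chrom, e.start)):
        if merged and merged[-1].chrom == elem.chrom and elem.start <= merged[-1].end:
            prev = merged[-1]
            longest = prev if prev.length >= elem.length else elem
            merged[-1] = AluElement(
                chrom=prev.chrom,
                start=prev.start,
                end=max(prev.end, elem.end),
                strand=longest.strand,
                subfamily=longest.subfamily,
                divergence=longest.divergence,
            )
        else:
            merged.append(elem)
    return merged


def inter_alu_gaps(elements: Sequence[AluElement]) -> List[GapRecord]:
    """One gap per adjacent same-chromosome element pair.

    Elements must be merged and sorted; an overlapping pair (negative gap)
    raises.  n elements on a chromosome yield n-1 gaps; no gap spans a
    chromosome boundary.
    """
    gaps: List[GapRecord] = []
    for _, group in groupby(elements, key=lambda e: e.chrom):
        group = list(group)
        for left, right in zip(group, group[1:]):
            if right.start < left.end:
                raise ValueError(
                    f"overlapping elements at {left.chrom}:{left.start}-{left.end} "
                    f"and {right.start}-{right.end}; merge before computing gaps"
                )
            gaps.append(
                GapRecord(
                    chrom=left.chrom,
                    start=left.end,
                    end=right.start,
                    left_alu=left,
                    right_alu=right,
                )
            )
    return gaps


def gap_histogram(
    gaps: Sequence[GapRecord],
    bin_width: int = 200,
    min_len: int = 200,
    max_len: int = 6000,
) -> GapHistogram:
    """Histogram of gap lengths restricted to [min_len, max_len] (inclusive).

    Gaps below min_len model short inter-Alu fragments removed during library
    construction; gaps above max_len exceed the practical amplicon range.
    total_bp_in_range sums the lengths of the included gaps.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if min_len < 0 or max_len <= min_len:
        raise ValueError("need 0 <= min_len < max_len")
    lengths = np.array([g.length for g in gaps], dtype=np.int64)
    in_range = lengths[(lengths >= min_len) & (lengths <= max_len)]
    edges = np.arange(min_len, max_len + bin_width, bin_width, dtype=np.int64)
    if edges[-1] < max_len:
        edges = np.append(edges, max_len)
    counts, _ = np.histogram(in_range, bins=edges)
    return GapHistogram(
        bin_width=bin_width,
        min_len=min_len,
        max_len=max_len,
        edges=edges,
        counts=counts,
        total_bp_in_range=int(in_range.sum()),
    )


def mean_gap_length(gaps: Sequence[GapRecord]) -> float:
    """Arithmetic mean of inter-Alu gap lengths."""
    if not gaps:
        raise ValueError("cannot average an empty gap list")
    return float(np.mean([g.length for g in gaps]))


def write_histogram_tsv(hist: GapHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for i, count in enumerate(hist.counts):
            fh.write(f"{hist.edges[i]}\t{hist.edges[i + 1]}\t{count}\n")
        fh.write(f"# total_bp_in_range\t{hist.total_bp_in_range}\n")
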
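"""Rule-based post-processing of paired control/tumor per-site variant calls.

The genotype statistic is the non-reference read frequency f = nonref/total:
f < 0.10 is homozygous reference, 0.10 <= f < 0.85 heterozygous, f >= 0.85
homozygous non-reference; sites under the minimum depth are left
unclassified.  A somatic SNV is a tumor heterozygote at a control
homozygote (reference or non-reference, read literally); an LOH event is
the reverse — a control heterozygote that is homozygous in the tumor.  The
two sets are disjoint by construction.  Novel somatic SNVs are those left
after removing LOH sites and positions on a known-SNP list.

Hotspots are fixed-width windows (default 5 Mb, anchored at position 0)
whose somatic SNV count strictly exceeds mean + 2*SD of the per-window
counts (sample SD, n-1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from interalu import intervals

logger = logging.getLogger(__name__)

HET_MIN_FRACTION = 0.10
HOMALT_MIN_FRACTION = 0.85


class GenotypeClass(str, Enum):
    HOMREF = "HOMREF"
    HET = "HET"
    HOMALT = "HOMALT"
    UNCLASSIFIED = "UNCLASSIFIED"


class PairedClass(str, Enum):
    SOMATIC_SNV = "SOMATIC_SNV"
    LOH = "LOH"
    NONE = "NONE"


@dataclass(frozen=True)
class SiteCall:
    """One sample's call at one position (pos is 1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    nonref_depth: int

    def __post_init__(self):
        if not 0 <= self.nonref_depth <= self.total_depth:
            raise ValueError(
                f"need 0 <= nonref_depth <= total_depth at {self.chrom}:{self.pos}"
            )

    @property
    def genotype_class(self) -> GenotypeClass:
        return classify_genotype(self.nonref_depth, self.total_depth)


@dataclass(frozen=True)
class PairedSite:
    control: SiteCall
    tumor: SiteCall

    def __post_init__(self):
        c, t = self.control, self.tumor
        if (c.chrom, c.pos, c.ref) != (t.chrom, t.pos, t.ref):
            raise ValueError(
                f"control/tumor disagree on locus: {c.chrom}:{c.pos}:{c.ref} vs "
                f"{t.chrom}:{t.pos}:{t.ref}"
            )

    @property
    def key(self) -> Tuple[str, int]:
        return (self.control.chrom, self.control.pos)


def classify_genotype(
    nonref_depth: int, total_depth: int, min_depth: int = 10
) -> GenotypeClass:
    """Classify by non-reference read frequency with the printed boundaries.

    f < 0.10 -> HOMREF; 0.10 <= f < 0.85 -> HET; f >= 0.85 -> HOMALT.
    Depth below min_depth (including zero) -> UNCLASSIFIED.
    """
    if nonref_depth < 0 or total_depth < 0:
        raise ValueError("depths must be nonnegative")
    if total_depth < min_depth:
        return GenotypeClass.UNCLASSIFIED
    f = nonref_depth / total_depth
    if f < HET_MIN_FRACTION:
        return GenotypeClass.HOMREF
    if f < HOMALT_MIN_FRACTION:
        return GenotypeClass.HET
    return GenotypeClass.HOMALT


_HOM = {GenotypeClass.HOMREF, GenotypeClass.HOMALT}


def classify_paired(paired: PairedSite, min_depth: int = 10) -> PairedClass:
    """Somatic/LOH call for one paired site; raises on unclassified members."""
    c = classify_genotype(paired.control.nonref_depth, paired.control.total_depth, min_depth)
    t = classify_genotype(paired.tumor.nonref_depth, paired.tumor.total_depth, min_depth)
    if GenotypeClass.UNCLASSIFIED in (c, t):
        raise ValueError(
            f"unclassified member at {paired.control.chrom}:{paired.control.pos}"
        )
    if c in _HOM and t is GenotypeClass.HET:
        return PairedClass.SOMATIC_SNV
    if c is GenotypeClass.HET and t in _HOM:
        return PairedClass.LOH
    return PairedClass.NONE


def classify_pairs(
    pairs: Iterable[PairedSite], min_depth: int = 10
) -> Dict[PairedClass, List[PairedSite]]:
    """Classify a batch, skipping (and logging) under-depth sites."""
    out: Dict[PairedClass, List[PairedSite]] = {
        PairedClass.SOMATIC_SNV: [],
        PairedClass.LOH: [],
        PairedClass.NONE: [],
    }
    skipped = 0
    for p in pairs:
        try:
            out[classify_paired(p, min_depth)].append(p)
        except ValueError:
            skipped += 1
            logger.debug(
                "skipping %s:%d: member below depth %d",
                p.control.chrom, p.control.pos, min_depth,
            )
    if skipped:
        logger.info("skipped %d paired sites with an unclassified member", skipped)
    return out


def filter_novel(
    somatic_snvs: Sequence[PairedSite],
    loh_sites: Sequence[PairedSite],
    known_positions: Set[Tuple[str, int]],
) -> List[PairedSite]:
    """Novel somatic SNVs: somatic minus LOH positions minus known positions."""
    loh_keys = {p.key for p in loh_sites}
    seen: Set[Tuple[str, int]] = set()
    novel = []
    for p in somatic_snvs:
        k = p.key
        if k in loh_keys or k in known_positions or k in seen:
            continue
        seen.add(k)
        novel.append(p)
    return sorted(novel, key=lambda p: p.key)


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def ts_tv(ref: str, alt: str) -> str:
    """'transition' for A<->G / C<->T, 'transversion' otherwise."""
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not single-base SNV alleles: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    same_class = (ref in _PURINES) == (alt in _PURINES)
    return "transition" if same_class else "transversion"


def tally_changes(calls: Iterable[Tuple[str, str]]) -> Dict[str, int]:
    """Counts per unordered change class plus transition/transversion totals.

    The six unordered classes are A:G, C:T (transitions) and A:C, A:T,
    C:G, G:T (transversions); (ref, alt) and (alt, ref) are pooled.
    """
    counts: Dict[str, int] = {
        "A:G": 0, "C:T": 0, "A:C": 0, "A:T": 0, "C:G": 0, "G:T": 0,
        "transition": 0, "transversion": 0,
    }
    for ref, alt in calls:
        kind = ts_tv(ref, alt)
        key = ":".join(sorted((ref, alt)))
        counts[key] += 1
        counts[kind] += 1
    return counts


@dataclass(frozen=True)
class Indel:
    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def size(self) -> int:
        return abs(len(self.ref) - len(self.alt))


def partition_indels(
    indels: Sequence[Indel], small_max: int = 30
) -> Tuple[List[Indel], List[Indel]]:
    """Split indels into small (size <= small_max) and large; size 0 raises."""
    small, large = [], []
    for ind in indels:
        if ind.size == 0:
            raise ValueError(f"not an indel at {ind.chrom}:{ind.pos}: equal lengths")
        (small if ind.size <= small_max else large).append(ind)
    return small, large


@dataclass(frozen=True)
class HotspotWindow:
    chrom: str
    start: int
    end: int
    snv_count: int
    is_hotspot: bool


@dataclass
class HotspotResult:
    windows: List[HotspotWindow]
    mean: float
    sd: float
    threshold: float

    @property
    def hotspots(self) -> List[HotspotWindow]:
        return [w for w in self.windows if w.is_hotspot]


def hotspot_threshold(mean: float, sd: float) -> float:
    """The flagging threshold: mean + 2*SD of per-window counts."""
    return mean + 2.0 * sd


def detect_hotspots(
    snv_positions: Iterable[Tuple[str, int]],
    chrom_lengths: Mapping[str, int],
    window: int = 5_000_000,
    covered_regions: Optional[Iterable] = None,
    absolute_threshold: Optional[float] = None,
) -> HotspotResult:
    """Flag fixed windows whose SNV count strictly exceeds mean + 2*SD.

    Windows are anchored at 0 on every chromosome in ``chrom_lengths`` (last
    window truncated).  The mean and sample SD are computed over all windows,
    or — when ``covered_regions`` is given — only over windows overlapping at
    least one region, since windows the assay cannot reach would deflate the
    mean.  ``absolute_threshold`` replaces the statistical rule with a plain
    count cutoff (still strict).  Positions are 1-based.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    wins: List[Tuple[str, int, int]] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start in range(0, length, window):
            wins.append((chrom, start, min(start + window, length)))
    if covered_regions is not None:
        covered = intervals.merge(covered_regions)
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for c, s, e in covered:
            by_chrom.setdefault(c, []).append((s, e))
        wins = [
            (c, s, e)
            for c, s, e in wins
            if any(rs < e and s < re_ for rs, re_ in by_chrom.get(c, ()))
        ]
    if len(wins) < 2:
        raise ValueError("need at least 2 windows to estimate the SD")
    index = {(c, s): i for i, (c, s, _) in enumerate(wins)}
    counts = np.zeros(len(wins), dtype=np.int64)
    for chrom, pos in snv_positions:
        w = ((pos - 1) // window) * window
        i = index.get((chrom, w))
        if i is not None:
            counts[i] += 1
    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1))
    cutoff = absolute_threshold if absolute_threshold is not None else hotspot_threshold(mean, sd)
    windows = [
        HotspotWindow(c, s, e, int(n), bool(n > cutoff))
        for (c, s, e), n in zip(wins, counts)
    ]
    return HotspotResult(
        windows=windows, mean=round(mean, 1), sd=round(sd, 1), threshold=float(cutoff)
    )


# ---------------------------------------------------------------------------
# I/O: the 7-column TSV dialect and VCF with per-sample AD

TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "total_depth", "nonref_depth"]


def read_calls_tsv(path) -> Dict[str, List[SiteCall]]:
    """Read per-site calls grouped by sample from the 7-column TSV dialect."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "sample": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: Dict[str, List[SiteCall]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample, []).append(
            SiteCall(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                total_depth=int(row.total_depth),
                nonref_depth=int(row.nonref_depth),
            )
        )
    return out


def write_calls_tsv(calls_by_sample: Mapping[str, Sequence[SiteCall]], path) -> None:
    rows = []
    for sample in sorted(calls_by_sample):
        for c in calls_by_sample[sample]:
            rows.append(
                (c.chrom, c.pos, c.ref, c.alt, sample, c.total_depth, c.nonref_depth)
            )
    rows.sort(key=lambda r: (r[0], r[1], r[4]))
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_vcf_calls(path, sample: Optional[str] = None) -> List[SiteCall]:
    """Read per-site calls from a VCF using the per-sample AD field.

    nonref_depth sums the non-reference allele depths; total_depth is the
    AD sum (or DP when AD is absent).
    """
    import pysam

    calls: List[SiteCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        if sample is None:
            samples = list(vcf.header.samples)
            if len(samples) != 1:
                raise ValueError("sample must be named for a multi-sample VCF")
            sample = samples[0]
        for rec in vcf:
            sdata = rec.samples[sample]
            ad = sdata.get("AD")
            if ad is not None and ad[0] is not None:
                total = int(sum(ad))
                nonref = int(sum(ad[1:]))
            else:
                total = int(sdata.get("DP") or 0)
                nonref = 0
            alt = rec.alts[0] if rec.alts else "."
            calls.append(
                SiteCall(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    total_depth=total, nonref_depth=nonref,
                )
            )
    return calls


def pair_calls(
    control: Sequence[SiteCall], tumor: Sequence[SiteCall]
) -> List[PairedSite]:
    """Match control and tumor calls on (chrom, pos); unmatched sites dropped."""
    tumor_by_key = {(c.chrom, c.pos): c for c in tumor}
    pairs = []
    for c in control:
        t = tumor_by_key.get((c.chrom, c.pos))
        if t is not None:
            pairs.append(PairedSite(control=c, tumor=t))
    return sorted(pairs, key=lambda p: p.key)


def read_known_positions(path) -> Set[Tuple[str, int]]:
    """Known-SNP list: tab-separated chrom, pos (1-based), header optional."""
    known: Set[Tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("chrom", "chromosome"):
                continue
            known.add((fields[0], int(fields[1])))
    return known
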
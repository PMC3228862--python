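"""Capture enrichment summaries for depth-filtered mapped regions.

Covers the standard on-target accounting for an Alu-anchored capture:
high-coverage region extraction from a per-base depth track, genic and
candidate-gene enrichment over genome-wide baselines, the inter-Alu
fraction, per-chromosome correlation between captured bp and Alu counts,
fixed-window density tracks, and control/tumor region reproducibility.

Baselines default to the usual human-genome figures: ~40% of the genome is
genic (gene bodies, exons plus introns) and ~26% of genes appear on the
cancer-candidate list used for comparison; both are configurable since they
depend on annotation versions.  Percentages are reported to 1 decimal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from interalu import intervals
from interalu.annotations_io import AluElement


@dataclass(frozen=True)
class CoverageRegion:
    """A maximal run of bases at or above the depth threshold."""

    chrom: str
    start: int
    end: int
    mean_depth: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("empty region")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")


@dataclass
class CaptureSummary:
    total_region_bp: int
    average_depth: float
    inter_alu_bp: int
    inter_alu_pct: float
    genic_bp: int
    genic_pct: float
    genic_excess_pct: float
    genes_hit: int
    candidate_genes_hit: int
    candidate_pct: float
    candidate_excess_pct: float


def read_depth_tsv(path) -> pd.DataFrame:
    """Per-base depth track: tab-separated chrom, pos0, depth (no header)."""
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "pos", "depth"], comment="#", dtype={"chrom": str}
    )
    return df


def filter_regions_by_depth(
    depth_track, min_depth: int = 10
) -> List[CoverageRegion]:
    """Maximal runs of consecutive bases with depth >= min_depth.

    ``depth_track`` is a DataFrame with columns chrom/pos/depth or an
    iterable of (chrom, pos0, depth).  Positions absent from the track are
    treated as zero depth, so a gap in positions breaks a run.  Bases below
    the threshold are excluded entirely; each region carries the mean depth
    of its own bases.
    """
    if isinstance(depth_track, pd.DataFrame):
        rows = depth_track[["chrom", "pos", "depth"]].itertuples(index=False)
    else:
        rows = depth_track
    by_chrom: Dict[str, List[Tuple[int, float]]] = defaultdict(list)
    for chrom, pos, depth in rows:
        if depth < 0:
            raise ValueError(f"negative depth at {chrom}:{pos}")
        by_chrom[str(chrom)].append((int(pos), float(depth)))
    regions: List[CoverageRegion] = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        run_start = None
        run_depths: List[float] = []
        prev_pos = None
        for pos, depth in entries:
            ok = depth >= min_depth
            contiguous = prev_pos is not None and pos == prev_pos + 1
            if ok and run_start is not None and contiguous:
                run_depths.append(depth)
            elif ok:
                if run_start is not None:
                    regions.append(
                        CoverageRegion(chrom, run_start, prev_pos + 1,
                                       float(np.mean(run_depths)))
                    )
                run_start, run_depths = pos, [depth]
            else:
                if run_start is not None:
                    regions.append(
                        CoverageRegion(chrom, run_start, prev_pos + 1,
                                       float(np.mean(run_depths)))
                    )
                    run_start, run_depths = None, []
            prev_pos = pos if ok else None
            if not ok:
                prev_pos = None
        if run_start is not None:
            regions.append(
                CoverageRegion(chrom, run_start, prev_pos + 1, float(np.mean(run_depths)))
            )
    return regions


def enrichment_from_counts(
    part_bp: int, total_bp: int, baseline_pct: float
) -> Tuple[float, float]:
    """(percentage, excess over baseline), both rounded to 1 decimal."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    pct = round(100.0 * part_bp / total_bp, 1)
    return pct, round(pct - baseline_pct, 1)


def genic_overlap(
    regions: Iterable,
    gene_intervals: Iterable,
    genome_gene_fraction: float = 40.0,
) -> Tuple[int, float, float]:
    """Overlap of regions with gene bodies: (genic_bp, genic_pct, excess_pct).

    excess_pct is the enrichment over the genome-wide genic fraction.
    """
    region_triples = intervals.merge(regions)
    total = sum(e - s for _, s, e in region_triples)
    genic = intervals.total_bp(intervals.intersect(region_triples, gene_intervals))
    pct, excess = enrichment_from_counts(genic, total, genome_gene_fraction)
    return genic, pct, excess


def genes_hit(regions: Iterable, genes: Sequence[Tuple[str, int, int, str]]) -> Set[str]:
    """Gene names with >= 1 bp of region overlap (case-normalized upper)."""
    region_by_chrom: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for chrom, s, e in intervals.merge(regions):
        region_by_chrom[chrom].append((s, e))
    hit: Set[str] = set()
    for chrom, s, e, name in genes:
        for rs, re_ in region_by_chrom.get(str(chrom), ()):
            if rs < e and s < re_:
                hit.add(name.upper())
                break
    return hit


def candidate_gene_stats(
    genes_hit_set: Set[str],
    candidate_list: Iterable[str],
    genome_candidate_fraction: float = 26.0,
) -> Tuple[int, float, float]:
    """(count, pct of hit genes on the candidate list, excess over baseline)."""
    if not genes_hit_set:
        raise ValueError("no genes hit")
    hits = {g.upper() for g in genes_hit_set}
    candidates = {g.upper() for g in candidate_list}
    n = len(hits & candidates)
    pct, excess = enrichment_from_counts(n, len(hits), genome_candidate_fraction)
    return n, pct, excess


def inter_alu_fraction(
    regions: Iterable, alu_elements: Sequence[AluElement]
) -> Tuple[int, float]:
    """Region bp outside any Alu element and its percentage of total region bp."""
    region_triples = intervals.merge(regions)
    total = sum(e - s for _, s, e in region_triples)
    if total == 0:
        return 0, 0.0
    alu_bp = intervals.total_bp(intervals.intersect(region_triples, alu_elements))
    inter = total - alu_bp
    return inter, round(100.0 * inter / total, 1)


def chromosome_correlation(
    per_chrom_bp: Mapping[str, float], per_chrom_alu_counts: Mapping[str, float]
) -> float:
    """Pearson r between captured bp and Alu counts across chromosomes."""
    if set(per_chrom_bp) != set(per_chrom_alu_counts):
        raise ValueError("chromosome sets differ between the two vectors")
    chroms = sorted(per_chrom_bp)
    if len(chroms) < 3:
        raise ValueError("need at least 3 chromosomes")
    x = np.array([per_chrom_bp[c] for c in chroms], dtype=float)
    y = np.array([per_chrom_alu_counts[c] for c in chroms], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def window_density(regions: Iterable, window: int = 10_000) -> pd.DataFrame:
    """bp of region coverage per non-overlapping window anchored at 0.

    Returns a BedGraph-shaped DataFrame (chrom, start, end, bp) containing
    only windows with nonzero coverage; the per-window bp totals sum to the
    total region bp.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    acc: Dict[Tuple[str, int], int] = defaultdict(int)
    for chrom, s, e in intervals.merge(regions):
        w = s // window
        while w * window < e:
            lo = max(s, w * window)
            hi = min(e, (w + 1) * window)
            acc[(chrom, w)] += hi - lo
            w += 1
    rows = [
        {"chrom": c, "start": w * window, "end": (w + 1) * window, "bp": bp}
        for (c, w), bp in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "bp"])


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


def paired_region_overlap(
    regions_a: Iterable, regions_b: Iterable, window: int = 10_000
) -> Tuple[int, float, float]:
    """Reproducibility of two capture runs over the same genome.

    Returns (intersection bp, percentage of set A covered, Pearson r between
    the two window-density tracks over the union of occupied windows).
    """
    a = intervals.merge(regions_a)
    b = intervals.merge(regions_b)
    total_a = sum(e - s for _, s, e in a)
    if total_a == 0:
        raise ValueError("region set A is empty")
    overlap = intervals.total_bp(intervals.intersect(a, b))
    pct = round(100.0 * overlap / total_a, 1)
    ta = window_density(a, window)
    tb = window_density(b, window)
    da = {(r.chrom, r.start): r.bp for r in ta.itertuples()}
    db = {(r.chrom, r.start): r.bp for r in tb.itertuples()}
    keys = sorted(set(da) | set(db))
    if len(keys) < 3:
        return overlap, pct, float("nan")
    x = np.array([da.get(k, 0) for k in keys], dtype=float)
    y = np.array([db.get(k, 0) for k in keys], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return overlap, pct, float("nan")
    r, _ = stats.pearsonr(x, y)
    return overlap, pct, float(r)


def summarize_capture(
    regions: Sequence[CoverageRegion],
    alu_elements: Sequence[AluElement],
    genes: Sequence[Tuple[str, int, int, str]],
    candidate_genes: Iterable[str],
    genome_gene_fraction: float = 40.0,
    genome_candidate_fraction: float = 26.0,
) -> CaptureSummary:
    """One-stop capture summary over depth-filtered regions."""
    merged = intervals.merge(regions)
    total = sum(e - s for _, s, e in merged)
    if total == 0:
        raise ValueError("no regions to summarize")
    depth_num = sum(r.mean_depth * (r.end - r.start) for r in regions)
    avg_depth = round(depth_num / sum(r.end - r.start for r in regions), 1)
    gene_triples = [(c, s, e) for c, s, e, _ in genes]
    genic_bp, genic_pct, genic_excess = genic_overlap(
        merged, gene_triples, genome_gene_fraction
    )
    hit = genes_hit(merged, genes)
    if hit:
        n_cand, cand_pct, cand_excess = candidate_gene_stats(
            hit, candidate_genes, genome_candidate_fraction
        )
    else:
        n_cand, cand_pct, cand_excess = 0, 0.0, round(-genome_candidate_fraction, 1)
    inter_bp, inter_pct = inter_alu_fraction(merged, alu_elements)
    return CaptureSummary(
        total_region_bp=total,
        average_depth=avg_depth,
        inter_alu_bp=inter_bp,
        inter_alu_pct=inter_pct,
        genic_bp=genic_bp,
        genic_pct=genic_pct,
        genic_excess_pct=genic_excess,
        genes_hit=len(hit),
        candidate_genes_hit=n_cand,
        candidate_pct=cand_pct,
        candidate_excess_pct=cand_excess,
    )
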
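"""Fully in-silico fixtures with known truth.

Two generators: a genome simulator that plants diverged Alu copies and gene
intervals on a uniform-random background, writing the same file formats the
readers consume (FASTA, RepeatMasker-style .out, BED); and a paired-call
simulator that draws control/tumor allele depths binomially around true
allele fractions in {0, 0.5, 1} for planted germline, somatic and LOH sites.

Defaults mirror the study conditions this package models: Alu density of
roughly one copy per 3 kb, 15% sequence divergence from consensus, ~40% of
the genome genic with 26% of genes on the candidate list; paired calls at
Poisson read depth with mean 67.4, 274 somatic SNVs, 357 LOH events,
~18,500 germline SNVs of which ~40% sit on the known-SNP list (~30% of
somatic SNVs known).  All randomness flows from one seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from interalu.annotations_io import AluElement
from interalu.primer_model import ConsensusRegistry, revcomp
from interalu.variant_post import PairedSite, SiteCall

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulatedGenome:
    sequences: Dict[str, str]
    alus: List[AluElement]
    genes: List[Tuple[str, int, int, str]]
    candidate_genes: Set[str]
    params: dict

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_repeatmasker_out(self, path) -> None:
        """Truth annotation in RepeatMasker .out layout (3 header lines)."""
        with open(path, "w") as fh:
            fh.write(
                "   SW  perc perc perc  query     position in query     matching"
                "  repeat          position in repeat\n"
                "score  div. del. ins.  sequence  begin end     (left)  repeat"
                "  class/family    begin end (left) ID\n\n"
            )
            for i, e in enumerate(self.alus, start=1):
                strand = "+" if e.strand == "+" else "C"
                div = (e.divergence or 0.0) / 10.0
                fh.write(
                    f"  500 {div:5.1f}  0.0  0.0  {e.chrom} {e.start + 1} {e.end}"
                    f" (0) {strand} {e.subfamily} SINE/Alu 1 {e.length} (0) {i}\n"
                )

    def write_alu_bed(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.alus:
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.subfamily}\t0\t{e.strand}\n")

    def write_genes_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e, name in self.genes:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t+\n")

    def write_candidate_list(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.candidate_genes):
                fh.write(name + "\n")


def _place_nonoverlapping(
    rng: np.random.Generator, n: int, item_lengths: Sequence[int], genome_length: int
) -> List[int]:
    """Uniform non-overlapping placement via the spacing construction.

    Draw n sorted start offsets in the free space left after removing the
    items' total length, then shift each by the cumulative length of the
    items before it — guaranteed non-overlap, uniform over arrangements.
    """
    total = int(sum(item_lengths))
    free = genome_length - total
    if free < 0:
        raise ValueError(
            f"genome of {genome_length} bp cannot hold {n} items totalling {total} bp"
        )
    offsets = np.sort(rng.integers(0, free + 1, size=n))
    starts = []
    cum = 0
    for off, length in zip(offsets, item_lengths):
        starts.append(int(off) + cum)
        cum += int(length)
    return starts


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently at the given rate (no indels)."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_genome(
    length: int = 1_000_000,
    n_alus: int = 300,
    chrom: str = "chr1",
    subfamilies: Sequence[str] = ("AluY",),
    divergence: float = 0.15,
    registry: Optional[ConsensusRegistry] = None,
    truncation_fraction: float = 0.0,
    n_genes: int = 30,
    gene_fraction: float = 0.40,
    candidate_fraction: float = 0.26,
    seed: int = 0,
) -> SimulatedGenome:
    """One-chromosome genome with planted Alu copies and gene intervals.

    Background sequence is i.i.d. uniform A/C/G/T.  Each Alu copy is a
    (possibly head-truncated) consensus copy on a uniformly chosen strand,
    substituted base-by-base at the divergence rate; copies never overlap.
    Gene intervals cover about ``gene_fraction`` of the chromosome and a
    ``candidate_fraction`` subset of gene names forms the candidate list.
    Deterministic for a fixed seed.
    """
    if not 0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    if n_alus < 0:
        raise ValueError("n_alus must be >= 0")
    if registry is None:
        registry = ConsensusRegistry.bundled()
    rng = np.random.default_rng(seed)

    background = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    seq = list(background)

    fams = [subfamilies[int(i)] for i in rng.integers(0, len(subfamilies), size=n_alus)]
    copies: List[Tuple[str, str, str]] = []  # (subfamily, strand, inserted sequence)
    for fam in fams:
        consensus = registry[fam]
        cut = 0
        if truncation_fraction > 0 and rng.random() < truncation_fraction:
            cut = int(rng.integers(1, max(2, int(len(consensus) * 0.6))))
        body = _diverge(rng, consensus[cut:], divergence)
        strand = "+" if rng.random() < 0.5 else "-"
        copies.append((fam, strand, body if strand == "+" else revcomp(body)))

    starts = _place_nonoverlapping(rng, n_alus, [len(c[2]) for c in copies], length)
    alus: List[AluElement] = []
    for (fam, strand, inserted), start in zip(copies, starts):
        end = start + len(inserted)
        seq[start:end] = inserted
        alus.append(
            AluElement(
                chrom=chrom, start=start, end=end, strand=strand, subfamily=fam,
                divergence=divergence * 1000.0,
            )
        )
    alus.sort(key=lambda e: e.start)

    genes: List[Tuple[str, int, int, str]] = []
    if n_genes > 0:
        gene_bp = int(gene_fraction * length)
        sizes = np.full(n_genes, gene_bp // n_genes, dtype=np.int64)
        gstarts = _place_nonoverlapping(rng, n_genes, sizes.tolist(), length)
        genes = [
            (chrom, int(s), int(s + sz), f"GENE{i + 1:04d}")
            for i, (s, sz) in enumerate(zip(gstarts, sizes))
        ]
    n_cand = int(round(candidate_fraction * len(genes)))
    cand_idx = rng.choice(len(genes), size=n_cand, replace=False) if n_cand else []
    candidates = {genes[int(i)][3] for i in cand_idx}

    return SimulatedGenome(
        sequences={chrom: "".join(seq)},
        alus=alus,
        genes=genes,
        candidate_genes=candidates,
        params=dict(
            length=length, n_alus=n_alus, subfamilies=tuple(subfamilies),
            divergence=divergence, truncation_fraction=truncation_fraction,
            n_genes=n_genes, gene_fraction=gene_fraction,
            candidate_fraction=candidate_fraction, seed=seed,
        ),
    )


@dataclass
class SimulatedPairedCalls:
    pairs: List[PairedSite]
    truth: Dict[Tuple[str, int], str]  # label per (chrom, pos)
    known: Set[Tuple[str, int]]
    params: dict

    def write_tsv(self, path) -> None:
        from interalu.variant_post import write_calls_tsv

        write_calls_tsv(
            {
                "control": [p.control for p in self.pairs],
                "tumor": [p.tumor for p in self.pairs],
            },
            path,
        )

    def write_known_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\n")
            for chrom, pos in sorted(self.known):
                fh.write(f"{chrom}\t{pos}\n")


_LABEL_FRACTIONS = {
    # (control fraction, tumor fraction)
    "ref": (0.0, 0.0),
    "germline_het": (0.5, 0.5),
    "germline_hom": (1.0, 1.0),
    "somatic_from_homref": (0.0, 0.5),
    "somatic_from_homalt": (1.0, 0.5),
    "loh_to_homref": (0.5, 0.0),
    "loh_to_homalt": (0.5, 1.0),
}


def simulate_paired_calls(
    n_germline_het: int = 12_000,
    n_germline_hom: int = 6_500,
    n_somatic: int = 274,
    n_loh: int = 357,
    n_ref: int = 1_000,
    depth_mean: float = 67.4,
    depth_fixed: Optional[int] = None,
    known_germline_fraction: float = 0.404,
    known_somatic_fraction: float = 0.296,
    noise: bool = True,
    chrom: str = "chr1",
    chrom_length: int = 240_000_000,
    seed: int = 0,
) -> SimulatedPairedCalls:
    """Paired control/tumor call table with planted truth labels.

    Each site gets a true allele fraction pair per its label (hom-ref 0,
    het 0.5, hom-alt 1).  Depths are Poisson(depth_mean) — or a fixed depth
    when ``depth_fixed`` is given — and the observed non-reference depth is
    Binomial(depth, fraction) when ``noise`` is on, else the rounded
    expectation.  Somatic sites arise mostly from hom-ref control (10% from
    hom-alt); LOH resolves to hom-ref or hom-alt tumor with equal odds.
    The known-SNP list samples germline and somatic positions at the stated
    fractions.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_total = n_germline_het + n_germline_hom + n_somatic + n_loh + n_ref
    if n_total == 0:
        raise ValueError("no sites requested")
    positions = np.sort(rng.choice(chrom_length, size=n_total, replace=False)) + 1

    labels: List[str] = []
    n_som_alt = int(round(0.10 * n_somatic))
    labels += ["germline_het"] * n_germline_het
    labels += ["germline_hom"] * n_germline_hom
    labels += ["somatic_from_homref"] * (n_somatic - n_som_alt)
    labels += ["somatic_from_homalt"] * n_som_alt
    n_loh_alt = n_loh // 2
    labels += ["loh_to_homref"] * (n_loh - n_loh_alt)
    labels += ["loh_to_homalt"] * n_loh_alt
    labels += ["ref"] * n_ref
    order = rng.permutation(n_total)
    labels = [labels[int(i)] for i in order]

    bases = "ACGT"
    pairs: List[PairedSite] = []
    truth: Dict[Tuple[str, int], str] = {}
    known: Set[Tuple[str, int]] = set()
    for pos, label in zip(positions, labels):
        f_control, f_tumor = _LABEL_FRACTIONS[label]
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[int(rng.integers(0, 4))]
        while alt == ref:
            alt = bases[int(rng.integers(0, 4))]
        calls = {}
        for sample, f in (("control", f_control), ("tumor", f_tumor)):
            depth = depth_fixed if depth_fixed is not None else int(rng.poisson(depth_mean))
            depth = max(depth, 1)
            nonref = int(rng.binomial(depth, f)) if noise else int(round(f * depth))
            calls[sample] = SiteCall(
                chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                total_depth=depth, nonref_depth=nonref,
            )
        pairs.append(PairedSite(control=calls["control"], tumor=calls["tumor"]))
        simple = (
            "somatic" if label.startswith("somatic")
            else "loh" if label.startswith("loh")
            else label
        )
        truth[(chrom, int(pos))] = simple
        p_known = (
            known_germline_fraction if simple.startswith("germline")
            else known_somatic_fraction if simple == "somatic"
            else 0.0
        )
        if p_known and rng.random() < p_known:
            known.add((chrom, int(pos)))

    return SimulatedPairedCalls(
        pairs=pairs,
        truth=truth,
        known=known,
        params=dict(
            n_germline_het=n_germline_het, n_germline_hom=n_germline_hom,
            n_somatic=n_somatic, n_loh=n_loh, n_ref=n_ref,
            depth_mean=depth_mean, depth_fixed=depth_fixed,
            known_germline_fraction=known_germline_fraction,
            known_somatic_fraction=known_somatic_fraction,
            noise=noise, chrom=chrom, chrom_length=chrom_length, seed=seed,
        ),
    )
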
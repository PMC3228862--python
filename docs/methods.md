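# Methods

## Capture model

The assay amplifies sequence between nearby Alu copies using consensus
primers in two orientation classes. A **T-type** primer pairs with the
consensus in sense orientation starting at a stated 1-based consensus
position, so its 3' extension proceeds toward and beyond the element's
poly-A tail; an **H-type** primer is the reverse complement of its
consensus window, extending out of the head. Primer names follow
`<family><start><H|T><length>` (e.g. `AluY278T18`, an 18-mer paired with
AluY consensus positions 278–295). Legacy primers without a consensus
offset are supported only as explicit sequences with a declared type.

A binding site is any genomic offset where the primer (rightward
extension) or its reverse complement (leftward extension) matches the top
strand within a Hamming distance budget — substitutions only, no
indel/bulge model, matching the substitution-only divergence of the
simulator. Genome `N` bases always count as mismatches so assembly gaps
cannot create phantom sites. An optional 3'-anchor flag requires the
3'-most *m* bases to match exactly (PCR extension realism); it is off by
default so the plain mismatch count defines the site set. All overlapping
sites are reported; this is enumeration, not alignment.

An **amplicon** is the outer span of a convergent pair: a
rightward-extending site L and a leftward-extending site R on one
chromosome with `min_len <= R.end - L.start <= max_len` (defaults
200–6000 bp: fragments under 200 bp are lost in library construction and
products much over 6 kb amplify poorly). Every such pair is counted,
nested and overlapping pairs included — the quantity modelled is what is
capturable *in principle*; template competition is out of scope. The
**capturable footprint** is the merged union of amplicon spans. The pair
class (HH/HT/TT) is the unordered pair of primer types.

The annotation-only mode places sites arithmetically inside annotated
elements (`element.start + consensus_start - 1` on the plus strand,
mirrored from `element.end` on the minus strand, directions flipped),
dropping sites that exceed the element bounds. It assumes full-length,
consensus-length elements; for 5'-truncated copies it only guarantees the
bounds check, so sequence mode is authoritative whenever sequence is
available. On zero-divergence simulated genomes the two modes agree
exactly, which the tests assert.

## Gap structure

Inter-Alu gaps are computed per chromosome between adjacent elements after
merging overlapping/abutting annotations (the merged interval keeps the
longest constituent's subfamily and strand; merging first guarantees
non-negative, unique gaps). Gap length is the open space
`right.start - left.end`, not a midpoint distance — it is the sequence an
amplicon would read. Histograms restrict to a length range (default
200–6000 bp, inclusive) and report both per-bin counts and the summed bp
in range. Coordinates are 0-based half-open internally; RepeatMasker
input (1-based inclusive, `C` = minus strand) is converted on read, BED
output stays 0-based, VCF-style positions are 1-based.

## Variant post-processing

Genotypes are classified from the non-reference read frequency
`f = nonref_depth / total_depth` with verbatim boundaries: `f < 0.10`
hom-ref, `0.10 <= f < 0.85` het, `f >= 0.85` hom-alt; sites with depth
below 10 (including zero) are unclassified and skipped in paired calling.
The boundaries partition [0, 1] with no gaps, which a property test
asserts. A somatic SNV is a tumor het at a control *homozygote* — read
literally, hom-ref **or** hom-alt, so a 1.0 → 0.5 allele-fraction shift
also counts; LOH is the reverse (control het, tumor homozygote). The two
sets are disjoint by construction. Novel somatic SNVs remove LOH positions
and positions on a known-SNP list (set difference on (chrom, pos), output
in coordinate order).

Transitions are A↔G and C↔T; tallies are kept per unordered change class.
Indels partition at size ≤ 30 bp (size = allele length difference; size 0
is rejected).

Hotspot windows are fixed-width (default 5 Mb), anchored at position 0,
last window truncated. A window is flagged when its somatic SNV count
**strictly** exceeds mean + 2·SD of the per-window counts. Design choices
where the rule leaves room:

- The SD is the sample (n−1) standard deviation — counts are small and
  few.
- The statistic can be restricted to windows overlapping at least one
  covered region (`covered_regions=`), since windows the assay cannot
  reach would deflate the mean; the default uses all genomic windows.
- The published description of this rule also quotes an absolute count
  cutoff ("> 4") alongside mean 1.5 + 2 × 1.9 = 5.3, which a window of 5
  would pass only under the absolute reading. The statistical rule is the
  implementation; `absolute_threshold=` exposes the absolute variant. The
  discrepancy is documented, not resolved.
- Flags depend only on the multiset of window counts plus each window's
  own count (permutation-invariance is tested).

## Synthetic data

`simulate_genome` plants non-overlapping Alu copies (uniform placement via
the spacing construction, uniform random strand) on an i.i.d. uniform
A/C/G/T background, substituting each copy base independently at the
divergence rate. Defaults: 1 Mb, 300 copies (≈ one per 3.3 kb, the human
Alu density scaled), 15% divergence (typical for genomic Alu copies
against consensus), full-length copies; an optional truncation fraction
produces 5'-truncated copies to exercise the annotation-mode bounds
check. Gene intervals cover 40% of the chromosome with 26% of genes on
the candidate list, matching the enrichment baselines. Everything derives
from one seed; same seed, byte-identical outputs.

`simulate_paired_calls` draws, per site, a true allele-fraction pair from
the label (hom-ref 0, het 0.5, hom-alt 1), depth from Poisson with mean
67.4 (the assay's typical high-quality coverage) or a fixed depth, and
the observed non-reference depth binomially. Default composition echoes a
paired control/tumor comparison at study scale: 12,000 germline hets +
6,500 germline hom-alts (≈ 18,500 germline SNVs at a 2:1 het:hom ratio,
the usual human proportion), 274 somatic SNVs (90% from hom-ref control,
10% from hom-alt, since the somatic rule covers both), 357 LOH events
(tumor resolves hom-ref or hom-alt with equal odds), 1,000 hom-ref
background sites. 40.4% of germline and 29.6% of somatic positions are
written to the known-SNP list.

What the simulator does **not** model: non-uniform background composition
and repeat context (so chance primer sites are rarer than in a real
genome), Alu insertion-length polymorphism and indel divergence, mapping
artifacts, strand bias, contamination, and copy-number-driven allele
fractions between 0 and 0.5. Passing tests therefore demonstrate
correctness of the rules and enumeration, not calibrated performance on
real sequencing data.

## Numerical and scale choices

Percentages are rounded to 1 decimal at the reporting boundary;
underlying bp counts are exact integers. Pearson correlations use
scipy and require ≥ 3 points and nonzero variance. The site scan is a
vectorized sliding-window Hamming count (O(genome × primer length)),
adequate for whole-genome runs given hours; tests and the acceptance
script use 0.2–0.5 Mb simulated genomes and 10⁴-site call tables, which
exercise every code path in seconds. The bundled consensus FASTA is a
synthetic Alu-family stand-in constructed so the two documented AluY
primer windows sit at their named offsets with correct orientation;
real-genome work should supply a published consensus via
`ConsensusRegistry.from_fasta`.

## Known limitations

- Amplicon enumeration ignores PCR competition, primer concentration and
  annealing thermodynamics; it upper-bounds the capturable set.
- Annotation-mode site placement is exact only for full-length elements.
- The somatic/LOH rules are depth-threshold heuristics; they do not model
  tumor purity or subclonality.
- Genome-scale totals (gigabase gap sums, megabase footprints) depend on
  the annotation version and consensus used and are not reproduced by the
  desk-scale test suite.
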
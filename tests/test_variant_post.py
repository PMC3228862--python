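"""Genotype classification, somatic/LOH rules, Ts/Tv, indels, hotspots."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from interalu.variant_post import (
    GenotypeClass,
    HotspotWindow,
    Indel,
    PairedClass,
    PairedSite,
    SiteCall,
    classify_genotype,
    classify_paired,
    classify_pairs,
    detect_hotspots,
    filter_novel,
    hotspot_threshold,
    partition_indels,
    tally_changes,
    ts_tv,
)


class TestGenotypeClassification:
    @pytest.mark.parametrize(
        "nonref,total,expected",
        [
            (2, 40, GenotypeClass.HOMREF),    # f = 0.05 < 0.10
            (20, 40, GenotypeClass.HET),      # f = 0.50
            (36, 40, GenotypeClass.HOMALT),   # f = 0.90
            (4, 40, GenotypeClass.HET),       # boundary: f = 0.10 is HET
            (34, 40, GenotypeClass.HOMALT),   # boundary: f = 0.85 is HOMALT
            (5, 9, GenotypeClass.UNCLASSIFIED),  # depth < 10 not analyzed
            (0, 0, GenotypeClass.UNCLASSIFIED),
        ],
    )
    def test_printed_thresholds(self, nonref, total, expected):
        assert classify_genotype(nonref, total) == expected

    def test_negative_depth_raises(self):
        with pytest.raises(ValueError):
            classify_genotype(-1, 10)

    @given(nonref=st.integers(0, 200), total=st.integers(10, 200))
    def test_partition_of_unit_interval(self, nonref, total):
        """Every frequency maps to exactly one class; no gaps at 0.10 or 0.85."""
        if nonref > total:
            nonref = total
        cls = classify_genotype(nonref, total)
        f = nonref / total
        expected = (
            GenotypeClass.HOMREF if f < 0.10
            else GenotypeClass.HET if f < 0.85
            else GenotypeClass.HOMALT
        )
        assert cls == expected


def _pair(c_nonref, c_total, t_nonref, t_total, chrom="chr1", pos=100):
    return PairedSite(
        control=SiteCall(chrom, pos, "A", "G", c_total, c_nonref),
        tumor=SiteCall(chrom, pos, "A", "G", t_total, t_nonref),
    )


class TestPairedClassification:
    @pytest.mark.parametrize(
        "c,t,expected",
        [
            ((0, 40), (20, 40), PairedClass.SOMATIC_SNV),   # HOMREF -> HET
            ((40, 40), (20, 40), PairedClass.SOMATIC_SNV),  # HOMALT -> HET (literal rule)
            ((20, 40), (40, 40), PairedClass.LOH),          # HET -> HOMALT
            ((20, 40), (0, 40), PairedClass.LOH),           # HET -> HOMREF
            ((20, 40), (20, 40), PairedClass.NONE),         # HET -> HET
            ((0, 40), (0, 40), PairedClass.NONE),
            ((0, 40), (40, 40), PairedClass.NONE),          # hom -> hom is neither
        ],
    )
    def test_rule_table(self, c, t, expected):
        assert classify_paired(_pair(*c, *t)) == expected

    def test_unclassified_member_raises(self):
        with pytest.raises(ValueError):
            classify_paired(_pair(0, 5, 20, 40))

    def test_batch_skips_underdepth_sites(self):
        pairs = [_pair(0, 40, 20, 40, pos=1), _pair(0, 5, 20, 40, pos=2)]
        out = classify_pairs(pairs)
        assert len(out[PairedClass.SOMATIC_SNV]) == 1

    def test_somatic_and_loh_disjoint_for_any_input(self):
        rng = np.random.default_rng(2)
        pairs = [
            _pair(int(rng.integers(0, 41)), 40, int(rng.integers(0, 41)), 40, pos=i + 1)
            for i in range(500)
        ]
        out = classify_pairs(pairs)
        som = {p.key for p in out[PairedClass.SOMATIC_SNV]}
        loh = {p.key for p in out[PairedClass.LOH]}
        assert som.isdisjoint(loh)

    def test_mismatched_locus_rejected(self):
        with pytest.raises(ValueError):
            PairedSite(
                control=SiteCall("chr1", 1, "A", "G", 40, 0),
                tumor=SiteCall("chr1", 2, "A", "G", 40, 20),
            )


class TestNovelty:
    def test_known_sites_removed(self):
        som = [_pair(0, 40, 20, 40, pos=p) for p in (10, 20, 30)]
        novel = filter_novel(som, [], {("chr1", 20)})
        assert [p.key for p in novel] == [("chr1", 10), ("chr1", 30)]

    def test_empty_known_set_is_identity(self):
        som = [_pair(0, 40, 20, 40, pos=p) for p in (10, 20)]
        assert filter_novel(som, [], set()) == som

    def test_loh_positions_removed(self):
        som = [_pair(0, 40, 20, 40, pos=p) for p in (10, 20)]
        loh = [_pair(20, 40, 0, 40, pos=20)]
        assert [p.key for p in filter_novel(som, loh, set())] == [("chr1", 10)]

    def test_random_against_set_difference_oracle(self):
        rng = np.random.default_rng(6)
        som = [_pair(0, 40, 20, 40, pos=int(p))
               for p in rng.choice(10_000, 200, replace=False)]
        loh_pos = set(map(int, rng.choice(10_000, 50, replace=False)))
        loh = [_pair(20, 40, 0, 40, pos=p) for p in loh_pos]
        known = {("chr1", int(p)) for p in rng.choice(10_000, 100, replace=False)}
        novel = filter_novel(som, loh, known)
        expected = {p.key for p in som} - {("chr1", p) for p in loh_pos} - known
        assert {p.key for p in novel} == expected


class TestTsTv:
    def test_transitions_and_transversions(self):
        assert ts_tv("A", "G") == "transition"
        assert ts_tv("C", "T") == "transition"
        assert ts_tv("A", "C") == "transversion"

    def test_all_12_ordered_pairs(self):
        pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        tally = tally_changes(pairs)
        assert tally["transition"] == 4 and tally["transversion"] == 8
        assert tally["A:G"] == 2 and tally["C:T"] == 2
        assert sum(tally[k] for k in ("A:C", "A:T", "C:G", "G:T")) == 8

    @pytest.mark.parametrize("ref,alt", [("A", "A"), ("AT", "A"), ("A", "U")])
    def test_non_snv_alleles_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            ts_tv(ref, alt)


class TestIndelPartition:
    def _indel(self, size, pos=1):
        return Indel("chr1", pos, "A" * (size + 1), "A")

    def test_threshold_as_printed(self):
        indels = [self._indel(s, i) for i, s in enumerate([5, 30, 31, 767], 1)]
        small, large = partition_indels(indels)
        assert [i.size for i in small] == [5, 30]
        assert [i.size for i in large] == [31, 767]

    def test_empty_input(self):
        assert partition_indels([]) == ([], [])

    def test_size_zero_raises(self):
        with pytest.raises(ValueError):
            partition_indels([Indel("chr1", 1, "A", "G")])

    def test_random_against_brute_force(self):
        rng = np.random.default_rng(44)
        sizes = rng.integers(1, 100, size=100).tolist()
        small, large = partition_indels([self._indel(s, i) for i, s in enumerate(sizes, 1)])
        assert sorted(i.size for i in small) == sorted(s for s in sizes if s <= 30)
        assert sorted(i.size for i in large) == sorted(s for s in sizes if s > 30)


class TestHotspots:
    def test_threshold_formula(self):
        assert hotspot_threshold(1.5, 1.9) == pytest.approx(5.3)

    def test_equal_counts_flag_nothing(self):
        # 2 SNVs in each of 4 windows: sd = 0, threshold = count, strict >
        positions = [("chr1", w * 5_000_000 + off)
                     for w in range(4) for off in (1, 2)]
        res = detect_hotspots(positions, {"chr1": 20_000_000})
        assert res.sd == 0.0 and res.hotspots == []

    def test_absolute_override_flags_6_not_5(self):
        positions = [("chr1", 1)] * 6 + [("chr1", 5_000_001)] * 5
        res = detect_hotspots(
            positions, {"chr1": 15_000_000}, absolute_threshold=hotspot_threshold(1.5, 1.9)
        )
        flags = {w.start: w.is_hotspot for w in res.windows}
        assert flags[0] is True and flags[5_000_000] is False

    def test_seeded_counts_against_direct_formula(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(1.5, size=20)
        positions = [("chr1", w * 5_000_000 + j + 1)
                     for w, c in enumerate(counts) for j in range(c)]
        res = detect_hotspots(positions, {"chr1": 100_000_000})
        mean, sd = counts.mean(), counts.std(ddof=1)
        expected = {i * 5_000_000: c > mean + 2 * sd for i, c in enumerate(counts)}
        assert {w.start: w.is_hotspot for w in res.windows} == expected
        assert res.mean == pytest.approx(round(mean, 1))
        assert res.sd == pytest.approx(round(sd, 1))

    def test_flags_depend_only_on_count_multiset(self):
        """Relabeling which window holds which count leaves the flag counts fixed."""
        counts = [0, 1, 6, 2, 1, 0, 3, 1]
        for perm_seed in (0, 1):
            rng = np.random.default_rng(perm_seed)
            perm = rng.permutation(len(counts))
            positions = [("chr1", int(w) * 1_000_000 + j + 1)
                         for w, c in zip(perm, counts) for j in range(c)]
            res = detect_hotspots(positions, {"chr1": 8_000_000}, window=1_000_000)
            assert sum(w.is_hotspot for w in res.windows) == 1
            (hot,) = res.hotspots
            assert hot.snv_count == 6

    def test_covered_windows_restrict_the_statistic(self):
        positions = [("chr1", 1)] * 3
        # only the first two windows overlap covered regions
        covered = [("chr1", 0, 6_000_000)]
        res = detect_hotspots(positions, {"chr1": 50_000_000}, covered_regions=covered)
        assert len(res.windows) == 2

    def test_fewer_than_two_windows_raises(self):
        with pytest.raises(ValueError):
            detect_hotspots([], {"chr1": 1_000_000})

    def test_last_window_truncated(self):
        res = detect_hotspots([("chr1", 1)], {"chr1": 7_000_000})
        assert [(w.start, w.end) for w in res.windows] == [
            (0, 5_000_000), (5_000_000, 7_000_000)
        ]
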
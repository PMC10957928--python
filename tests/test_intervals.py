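"""Interval arithmetic: parsing, overlap algebra, shuffling, TSS annotation."""

import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import base_mask, mask_to_regions, random_region_set
from ecre.intervals import (
    AnnotationResult,
    GenomeTable,
    GeneModel,
    PlacementError,
    Region,
    RegionSet,
    RegionParseError,
    annotate_nearest_tss,
    consensus_peaks,
    filter_excluded,
    intersect,
    overlaps,
    parse_region_id,
    shuffle_match,
)
from ecre.discovery import load_table2_candidates, load_table3_scores


class TestRegionParsing:
    def test_display_ids_are_one_based_inclusive(self):
        r = parse_region_id("chr11-55022942-55023482")
        assert (r.chrom, r.start, r.end) == ("chr11", 55022941, 55023482)
        assert r.id == "chr11-55022942-55023482"

    @pytest.mark.parametrize("bad", ["chr1-5-5", "chr1-9-3", "chr1:1-10", "chr1-a-b", ""])
    def test_malformed_ids_raise(self, bad):
        with pytest.raises(RegionParseError):
            parse_region_id(bad)

    def test_roundtrip_on_published_candidate_ids(self):
        ids = [c.region.id for c in load_table2_candidates()]
        ids += list(load_table3_scores().region_id)
        assert len(ids) == 107
        for text in ids:
            assert parse_region_id(text).id == text

    @given(
        st.integers(min_value=0, max_value=10**8),
        st.integers(min_value=2, max_value=10**6),
    )
    def test_roundtrip_random_coordinates(self, start, length):
        # length >= 2: a single-base region displays with equal bounds,
        # which the id dialect treats as degenerate
        r = Region("chrX", start, start + length)
        back = parse_region_id(r.id)
        assert (back.start, back.end) == (r.start, r.end)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            Region("chr1", 10, 10)


class TestOverlaps:
    def test_bookended_half_open_do_not_overlap(self):
        assert not overlaps(Region("chr1", 0, 10), Region("chr1", 10, 20))

    def test_identical_regions_overlap(self):
        r = Region("chr1", 5, 9)
        assert overlaps(r, r)

    def test_different_chromosomes_never_overlap(self):
        assert not overlaps(Region("chr1", 0, 100), Region("chr2", 0, 100))

    def test_agrees_with_base_set_oracle(self, rng):
        for _ in range(10_000):
            s1, s2 = rng.integers(0, 500, size=2)
            l1, l2 = rng.integers(1, 60, size=2)
            a, b = Region("chr1", int(s1), int(s1 + l1)), Region("chr1", int(s2), int(s2 + l2))
            expected = bool(set(range(a.start, a.end)) & set(range(b.start, b.end)))
            assert overlaps(a, b) == expected


class TestIntersect:
    def test_disjoint_sets_give_empty(self):
        a = RegionSet([Region("chr1", 0, 10)])
        b = RegionSet([Region("chr1", 20, 30)])
        assert len(intersect(a, b)) == 0

    def test_self_intersection_is_merge(self, rng):
        a = random_region_set(rng, 50)
        assert intersect(a, a) == a.merged()

    def test_matches_base_mask_oracle(self, rng):
        for _ in range(200):
            a = random_region_set(rng, int(rng.integers(1, 40)))
            b = random_region_set(rng, int(rng.integers(1, 40)))
            got = intersect(a, b)
            want = mask_to_regions(base_mask(a) & base_mask(b))
            assert got == want

    def test_commutative_on_base_sets(self, rng):
        a = random_region_set(rng, 30)
        b = random_region_set(rng, 30)
        assert intersect(a, b) == intersect(b, a)

    def test_agrees_with_bedtools(self, rng, tmp_path):
        """Independent cross-check against bedtools merge + intersect."""
        a = random_region_set(rng, 60)
        b = random_region_set(rng, 60)
        for name, rs in (("a", a), ("b", b)):
            with open(tmp_path / f"{name}.bed", "w") as fh:
                for r in rs:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            merged = subprocess.run(
                f"sort -k1,1 -k2,2n {tmp_path}/{name}.bed | bedtools merge -i -",
                shell=True, capture_output=True, text=True, check=True,
            ).stdout
            (tmp_path / f"{name}.merged.bed").write_text(merged)
        out = subprocess.run(
            ["bedtools", "intersect", "-a", str(tmp_path / "a.merged.bed"),
             "-b", str(tmp_path / "b.merged.bed")],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = [
            Region(c, int(s), int(e))
            for c, s, e in (ln.split("\t") for ln in out.strip().splitlines())
        ]
        assert intersect(a, b).regions == sorted(expected, key=lambda r: (r.chrom, r.start, r.end))


class TestFilterExcluded:
    def test_empty_exclusion_is_identity(self, rng):
        a = random_region_set(rng, 20)
        assert filter_excluded(a, RegionSet()).regions == a.regions

    def test_full_genome_exclusion_empties(self, rng):
        a = random_region_set(rng, 20)
        excl = RegionSet([Region("chr1", 0, 10_000)])
        assert len(filter_excluded(a, excl)) == 0

    def test_matches_pairwise_scan_oracle(self, rng):
        for _ in range(200):
            a = random_region_set(rng, int(rng.integers(1, 30)))
            excl = random_region_set(rng, int(rng.integers(1, 30)))
            got = filter_excluded(a, excl)
            want = [r for r in a if not any(overlaps(r, x) for x in excl)]
            assert got.regions == want


class TestConsensusPeaks:
    def test_empty_replicate_gives_empty(self, rng):
        rep1 = random_region_set(rng, 10)
        assert len(consensus_peaks(rep1, RegionSet())) == 0

    def test_subset_replicate_recovered(self):
        rep1 = RegionSet([Region("chr1", 100, 200), Region("chr1", 500, 600)])
        rep2 = RegionSet([Region("chr1", 50, 300), Region("chr1", 400, 700)])
        assert consensus_peaks(rep1, rep2) == rep1.merged()

    def test_planted_common_peaks_recovered(self, rng):
        common = [Region("chr1", int(s), int(s) + 100) for s in range(0, 5000, 500)]
        only1 = [Region("chr1", 6000, 6100)]
        only2 = [Region("chr1", 8000, 8100)]
        rep1 = RegionSet(common + only1)
        rep2 = RegionSet(common + only2)
        assert consensus_peaks(rep1, rep2) == RegionSet(common)

    def test_every_consensus_region_in_both_replicates(self, rng):
        rep1 = random_region_set(rng, 40)
        rep2 = random_region_set(rng, 40)
        for r in consensus_peaks(rep1, rep2):
            assert rep1.any_overlap(r) and rep2.any_overlap(r)

    def test_rep1_mode_keeps_full_peaks(self):
        rep1 = RegionSet([Region("chr1", 100, 200), Region("chr1", 500, 600)])
        rep2 = RegionSet([Region("chr1", 150, 160)])
        got = consensus_peaks(rep1, rep2, mode="rep1")
        assert got.regions == [Region("chr1", 100, 200)]


class TestShuffleMatch:
    def test_empty_templates(self, toy_genome, rng):
        assert len(shuffle_match(RegionSet(), toy_genome, RegionSet(), rng)) == 0

    def test_length_multiset_conserved_at_published_scale(self, rng):
        genome = GenomeTable(("chr1", "chr2"), (5_000_000, 5_000_000))
        lengths = rng.integers(200, 2000, size=695)
        templates = RegionSet(
            [Region("chr1", int(1000 + 3000 * i), int(1000 + 3000 * i + l))
             for i, l in enumerate(lengths)]
        )
        excl = templates
        out = shuffle_match(templates, genome, excl, rng)
        assert len(out) == 695
        assert sorted(out.lengths()) == sorted(templates.lengths())
        assert all(not excl.any_overlap(r) for r in out)

    def test_no_exclusion_overlap_across_seeds(self, toy_genome):
        templates = RegionSet([Region("chr1", 0, 200), Region("chr1", 300, 450)])
        excl = RegionSet([Region("chr1", 2000, 6000)])
        for seed in range(100):
            out = shuffle_match(templates, toy_genome, excl, np.random.default_rng(seed))
            assert sorted(out.lengths()) == [150, 200]
            assert all(not excl.any_overlap(r) for r in out)
            assert all(r.end <= 10_000 for r in out)

    def test_reproducible_from_seed(self, toy_genome):
        t = RegionSet([Region("chr1", 0, 100)] * 1)
        a = shuffle_match(t, toy_genome, RegionSet(), np.random.default_rng(5))
        b = shuffle_match(t, toy_genome, RegionSet(), np.random.default_rng(5))
        assert a.regions == b.regions

    def test_start_positions_uniform_over_admissible_space(self, toy_genome):
        """Chi-square on placement starts vs the enumerated admissible set."""
        from scipy.stats import chisquare

        length = 100
        excl = RegionSet([Region("chr1", 4000, 5000)])
        admissible = [
            s for s in range(0, 10_000 - length + 1)
            if not (max(s, 4000) < min(s + length, 5000))
        ]
        rng = np.random.default_rng(11)
        template = RegionSet([Region("chr1", 0, length)])
        draws = [
            shuffle_match(template, toy_genome, excl, rng)[0].start
            for _ in range(1000)
        ]
        assert set(draws) <= set(admissible)
        # bin admissible space into 10 equal-count bins
        edges = np.quantile(admissible, np.linspace(0, 1, 11))
        counts, _ = np.histogram(draws, bins=edges)
        assert chisquare(counts).pvalue > 0.01

    def test_placement_failure_names_length(self, toy_genome):
        templates = RegionSet([Region("chr1", 0, 9000)])
        excl = RegionSet([Region("chr1", 4000, 5000)])
        with pytest.raises(PlacementError, match="9000"):
            shuffle_match(templates, toy_genome, excl, np.random.default_rng(0), max_attempts=50)


def brute_nearest(region, genes):
    """Exhaustive signed-distance scan — the annotation oracle."""
    best = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        if region.start <= g.tss < region.end:
            d = 0
        elif region.start > g.tss:
            d = region.start - g.tss
        else:
            d = (region.end - 1) - g.tss
        signed = d if g.strand == "+" else -d
        key = (abs(signed), g.symbol)
        if best is None or key < best[0]:
            best = (key, g, signed)
    return best[1], best[2]


class TestAnnotateNearestTss:
    def test_promoter_overlap(self):
        gene = GeneModel("Kdr", "chr5", "+", 10_000)
        res = annotate_nearest_tss(Region("chr5", 9500, 10_100), [gene])
        assert res == AnnotationResult("Kdr", 0, "Promoter")

    def test_promoter_window_without_tss_overlap(self):
        gene = GeneModel("Hapln1", "chr13", "+", 10_000)
        res = annotate_nearest_tss(Region("chr13", 10_400, 10_700), [gene])
        assert res.location == "Promoter"
        assert res.distance_to_tss == 400

    def test_upstream_region_has_negative_distance(self):
        plus = GeneModel("Sox18", "chr2", "+", 50_000)
        res = annotate_nearest_tss(Region("chr2", 40_000, 42_000), [plus])
        assert res.distance_to_tss == -8001
        minus = GeneModel("Sox18", "chr2", "-", 50_000)
        res = annotate_nearest_tss(Region("chr2", 55_000, 56_000), [minus])
        assert res.distance_to_tss == -5000

    def test_intron_and_exon_numbering_is_strand_aware(self):
        exons = tuple(Region("chr1", s, s + 100) for s in (10_000, 20_000, 30_000))
        plus = GeneModel("A", "chr1", "+", 10_000, exons)
        minus = GeneModel("B", "chr1", "-", 30_099, exons)
        mid_intron1 = Region("chr1", 15_000, 15_100)  # between exons 1 and 2 genomically
        assert annotate_nearest_tss(mid_intron1, [plus]).location == "intron 1 of 2"
        far = Region("chr1", 25_000, 25_100)
        assert annotate_nearest_tss(far, [minus]).location == "intron 1 of 2"
        in_exon = Region("chr1", 20_010, 20_050)
        assert annotate_nearest_tss(in_exon, [plus]).location == "exon 2 of 3"
        assert annotate_nearest_tss(in_exon, [minus]).location == "exon 2 of 3"

    def test_distal_intergenic_without_exon_structure(self):
        gene = GeneModel("C", "chr1", "+", 100_000)
        res = annotate_nearest_tss(Region("chr1", 0, 50), [gene])
        assert res.location == "Distal Intergenic"

    def test_empty_gene_list_raises(self):
        with pytest.raises(ValueError):
            annotate_nearest_tss(Region("chr1", 0, 10), [])

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(1000):
            n_genes = int(rng.integers(1, 8))
            genes = [
                GeneModel(
                    f"G{k}",
                    "chr1",
                    "+" if rng.random() < 0.5 else "-",
                    int(rng.integers(0, 100_000)),
                )
                for k in range(n_genes)
            ]
            start = int(rng.integers(0, 99_000))
            region = Region("chr1", start, start + int(rng.integers(1, 1000)))
            want_gene, want_dist = brute_nearest(region, genes)
            got = annotate_nearest_tss(region, genes)
            assert got.gene == want_gene.symbol
            assert got.distance_to_tss == want_dist

    def test_ties_break_lexicographically(self):
        a = GeneModel("Zzz", "chr1", "+", 1000)
        b = GeneModel("Aaa", "chr1", "+", 3000)
        res = annotate_nearest_tss(Region("chr1", 1950, 2051), [a, b])
        assert res.gene == "Aaa"
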
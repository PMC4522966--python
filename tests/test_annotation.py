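"""Interval expansion, intersection vs quadratic oracle, TATA/CpG windows,
histone-mark region classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cageprom import (
    AnalysisConfig,
    GenomicInterval,
    PromoterRecord,
    classify_cpg,
    classify_regulatory_regions,
    classify_tata,
    expand_interval,
    intersect,
    promoter_context,
)
from cageprom.annotation import (
    ACTIVE_ENHANCER,
    ACTIVE_PROMOTER,
    CPG,
    CPG_LESS,
    DUAL,
    TATA_CONTAINING,
    TATA_LESS,
)
from cageprom.io import BedFeature, strands_compatible


def feat(start, end, strand=".", chrom="chr1", name=None):
    return BedFeature(GenomicInterval(chrom, start, end, strand), name or f"{start}-{end}")


def promoter(center, strand="+", chrom="chr1"):
    return PromoterRecord(
        "p", "G", GenomicInterval(chrom, center - 20, center + 20, strand), center
    )


class TestExpandInterval:
    @pytest.mark.parametrize(
        "start,end,pad,expected",
        [(1000, 1010, 500, (500, 1510)), (100, 110, 500, (0, 610)), (100, 110, 0, (100, 110))],
    )
    def test_padding_and_clipping(self, start, end, pad, expected):
        out = expand_interval(GenomicInterval("chr1", start, end, "+"), pad)
        assert (out.start, out.end) == expected and out.strand == "+"


def oracle_pairs(a, b):
    """Quadratic all-pairs oracle, written from the overlap definition."""
    out = set()
    for i, fa in enumerate(a):
        for j, fb in enumerate(b):
            ia, ib = fa.interval, fb.interval
            if ia.chrom != ib.chrom or not strands_compatible(ia.strand, ib.strand):
                continue
            ovl = min(ia.end, ib.end) - max(ia.start, ib.start)
            if ovl > 0:
                out.add((i, j, ovl))
    return out


class TestIntersect:
    def test_basic_overlap_length(self):
        pairs = intersect([feat(10, 20)], [feat(15, 25)])
        assert len(pairs) == 1 and pairs[0][2] == 5

    def test_half_open_abutment_no_pair(self):
        assert intersect([feat(10, 20)], [feat(20, 30)]) == []

    def test_strand_semantics(self):
        plus, minus, nostrand = feat(0, 10, "+"), feat(0, 10, "-"), feat(0, 10, ".")
        assert intersect([plus], [minus]) == []
        assert len(intersect([plus], [nostrand])) == 1

    @given(
        a=st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60), st.sampled_from("+-."),
                      st.sampled_from(["chr1", "chr2"])),
            max_size=60,
        ),
        b=st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60), st.sampled_from("+-."),
                      st.sampled_from(["chr1", "chr2"])),
            max_size=60,
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_quadratic_oracle(self, a, b):
        fa = [feat(s, s + w, strand, chrom, name=f"a{i}")
              for i, (s, w, strand, chrom) in enumerate(a)]
        fb = [feat(s, s + w, strand, chrom, name=f"b{i}")
              for i, (s, w, strand, chrom) in enumerate(b)]
        ia = {f.name: i for i, f in enumerate(fa)}
        ib = {f.name: i for i, f in enumerate(fb)}
        got = {(ia[x.name], ib[y.name], ovl) for x, y, ovl in intersect(fa, fb)}
        assert got == oracle_pairs(fa, fb)


class TestClassifyTata:
    def test_box_30bp_upstream_plus_strand(self, config):
        box = feat(10_000 - 34, 10_000 - 26)
        assert classify_tata(promoter(10_000), [box], config) == TATA_CONTAINING

    def test_box_600bp_upstream_is_tata_less(self, config):
        box = feat(10_000 - 605, 10_000 - 596)
        assert classify_tata(promoter(10_000), [box], config) == TATA_LESS

    def test_downstream_box_does_not_count(self, config):
        box = feat(10_000 + 26, 10_000 + 34)
        assert classify_tata(promoter(10_000), [box], config) == TATA_LESS

    def test_minus_strand_mirror_symmetry(self, config):
        # flip the whole fixture around the center: calls must agree
        c = 10_000
        for offset in (-450, -30, 30, 450, 600):
            box_plus = feat(c + offset - 4, c + offset + 4)
            mirrored = feat(c - offset - 4, c - offset + 4)
            assert classify_tata(promoter(c, "+"), [box_plus], config) == classify_tata(
                promoter(c, "-"), [mirrored], config
            )

    def test_unstranded_promoter_rejected(self, config):
        with pytest.raises(ValueError):
            classify_tata(promoter(10_000, "."), [], config)


class TestClassifyCpg:
    def test_island_spanning_center(self, config):
        assert classify_cpg(promoter(10_000), [feat(9_900, 10_100)], config) == CPG

    def test_edge_exactly_500_away_closed_boundary(self, config):
        # island ending at base 9500: distance to center 10_000 is 500
        island = feat(9_400, 9_501)
        assert classify_cpg(promoter(10_000), [island], config) == CPG

    def test_edge_501_away_is_cpg_less(self, config):
        island = feat(9_400, 9_500)  # nearest covered base is 9_499
        assert classify_cpg(promoter(10_000), [island], config) == CPG_LESS


class TestRegulatoryRegions:
    def test_lone_h3k27ac_is_enhancer(self):
        (region,) = classify_regulatory_regions([], [feat(0, 100)])
        assert region.label == ACTIVE_ENHANCER

    def test_partial_overlap_is_active_promoter(self):
        regions = classify_regulatory_regions([feat(100, 200)], [feat(150, 400)])
        labels = {r.label for r in regions}
        assert labels == {ACTIVE_PROMOTER}

    def test_complete_containment_is_dual(self):
        (region,) = classify_regulatory_regions([feat(100, 200)], [feat(50, 400)])
        assert region.label == DUAL

    def test_union_coverage_across_several_peaks(self):
        # two H3K27ac peaks jointly covering the H3K4me3 peak: dual
        k4 = [feat(100, 200)]
        k27 = [feat(50, 150), feat(150, 250)]
        (region,) = classify_regulatory_regions(k4, k27)
        assert region.label == DUAL
        # leave a 1-bp hole: active promoter
        (region,) = classify_regulatory_regions(k4, [feat(50, 150), feat(151, 250)])
        assert region.label == ACTIVE_PROMOTER

    @given(
        k4=st.lists(st.tuples(st.integers(0, 400), st.integers(1, 80)), max_size=25),
        k27=st.lists(st.tuples(st.integers(0, 400), st.integers(1, 80)), max_size=25),
    )
    @settings(max_examples=150, deadline=None)
    def test_partition_exhaustive(self, k4, k27):
        fk4 = [feat(s, s + w, name=f"k4_{i}") for i, (s, w) in enumerate(k4)]
        fk27 = [feat(s, s + w, name=f"k27_{i}") for i, (s, w) in enumerate(k27)]
        regions = classify_regulatory_regions(fk4, fk27)
        # every H3K4me3 peak gets exactly one label
        k4_regions = [r for r in regions if "H3K4me3" in r.source_marks]
        assert len(k4_regions) == len(fk4)
        for r in k4_regions:
            assert r.label in (ACTIVE_PROMOTER, DUAL)
        # H3K27ac-only regions are enhancers; none overlaps any H3K4me3 peak
        for r in regions:
            if r.label == ACTIVE_ENHANCER:
                assert all(r.interval.overlap(f.interval) == 0 for f in fk4)


class TestPromoterContext:
    def regions(self):
        return classify_regulatory_regions(
            [feat(11_050, 11_850)], [feat(8_600, 9_400)]
        )

    def test_signed_distances(self, config):
        ctx = promoter_context(promoter(10_000), self.regions(), 500_000)
        enh, enh_dist = ctx[ACTIVE_ENHANCER]
        prom, prom_dist = ctx[ACTIVE_PROMOTER]
        assert enh_dist == -601  # upstream edge-to-center, negative on +
        assert prom_dist == 1050

    def test_minus_strand_flips_signs(self, config):
        ctx = promoter_context(promoter(10_000, "-"), self.regions(), 500_000)
        assert ctx[ACTIVE_ENHANCER][1] == 601
        assert ctx[ACTIVE_PROMOTER][1] == -1050

    def test_out_of_range_absent(self, config):
        ctx = promoter_context(promoter(10_000), self.regions(), 100)
        assert ctx[ACTIVE_ENHANCER] is None and ctx[ACTIVE_PROMOTER] is None

    def test_equidistant_tie_smaller_start(self, config):
        regions = classify_regulatory_regions([], [feat(9_000, 9_500), feat(10_501, 11_001)])
        region, dist = promoter_context(promoter(10_000), regions, 10_000)[ACTIVE_ENHANCER]
        assert region.interval.start == 9_000 and dist == -501
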
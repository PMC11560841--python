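import numpy as np
import pandas as pd
import pytest
from math import comb

from sc3dmulti import regulatory_overlap as ro


def _dmrs(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestLoopConnectedDmrs:
    def _loops(self):
        return pd.DataFrame({"chrom": ["chr1"], "bin1": [10], "bin2": [50]})

    def test_dmr_inside_anchor_kept(self):
        dmrs = _dmrs([("chr1", 101_000, 101_500)])  # inside [100000,110000)
        out = ro.loop_connected_dmrs(dmrs, self._loops())
        assert len(out) == 1

    def test_dmr_one_bp_outside_dropped(self):
        dmrs = _dmrs([("chr1", 110_000, 110_500)])  # starts at anchor end
        out = ro.loop_connected_dmrs(dmrs, self._loops())
        assert len(out) == 0

    def test_one_bp_overlap_kept(self):
        dmrs = _dmrs([("chr1", 109_999, 110_500)])
        assert len(ro.loop_connected_dmrs(dmrs, self._loops())) == 1

    def test_matches_brute_force_intersection(self, rng):
        loops = pd.DataFrame({"chrom": ["chr1"] * 5,
                              "bin1": rng.integers(0, 50, 5),
                              "bin2": rng.integers(60, 100, 5)})
        dmrs = _dmrs([("chr1", int(s), int(s) + 400)
                      for s in rng.integers(0, 1_000_000, 200)])
        out = ro.loop_connected_dmrs(dmrs, loops)
        anchors = []
        for _, l in loops.iterrows():
            anchors.append((l.bin1 * 10_000, (l.bin1 + 1) * 10_000))
            anchors.append((l.bin2 * 10_000, (l.bin2 + 1) * 10_000))
        expected = sum(
            any(d.start < ae and d.end > as_ for as_, ae in anchors)
            for _, d in dmrs.iterrows())
        assert len(out) == expected


def hypergeom_sf_oracle(x, N, K, n):
    """P(X >= x) by explicit pmf summation."""
    total = 0.0
    for k in range(x, min(K, n) + 1):
        total += comb(K, k) * comb(N - K, n - k) / comb(N, n)
    return total


class TestMotifEnrichment:
    def test_everything_overlaps(self):
        hits = _dmrs([("chr1", 0, 1_000_000)])
        fg = _dmrs([("chr1", 1000 * i, 1000 * i + 100) for i in range(10)])
        bg = _dmrs([("chr1", 1000 * i, 1000 * i + 100) for i in range(100)])
        out = ro.motif_enrichment(fg, bg, hits)
        assert out.pvalue == pytest.approx(1.0)
        assert out.fold == pytest.approx(1.0)

    def test_matches_pmf_summation(self):
        # construct N=100 bg, K=10 overlapping, n=10 fg, x=5 overlapping;
        # keep everything > 600 bp apart so the +-250 bp extensions stay disjoint
        step = 2000
        bg = _dmrs([("chr1", step * i, step * i + 100) for i in range(100)])
        hits = _dmrs([("chr1", step * i, step * i + 100) for i in range(10)])
        fg = _dmrs([("chr1", step * i, step * i + 100)
                    for i in list(range(5)) + list(range(50, 55))])
        out = ro.motif_enrichment(fg, bg, hits)
        assert (out.x, out.n, out.K, out.N) == (5, 10, 10, 100)
        assert out.pvalue == pytest.approx(
            hypergeom_sf_oracle(5, 100, 10, 10), rel=1e-12)
        assert out.fold == pytest.approx((5 / 10) / (10 / 100))

    def test_zero_hits_p_one(self):
        bg = _dmrs([("chr1", 10_000 * i, 10_000 * i + 100) for i in range(20)])
        fg = bg.iloc[:5]
        hits = _dmrs([("chr2", 0, 100)])
        out = ro.motif_enrichment(fg, bg, hits)
        assert out.pvalue == 1.0
        assert np.isinf(out.fold)  # K = 0 sentinel

    def test_extension_conventions(self):
        # fg extends from edges, bg from centre
        fg = ro.extend_from_edges(_dmrs([("chr1", 1000, 2000)]))
        assert fg.iloc[0]["start"] == 750 and fg.iloc[0]["end"] == 2250
        bg = ro.extend_from_centre(_dmrs([("chr1", 1000, 2000)]))
        assert bg.iloc[0]["start"] == 1250 and bg.iloc[0]["end"] == 1750


class TestFinemapOverlap:
    def test_or_arithmetic(self):
        # a=8, b=2, c=100, d=900 -> OR = 36
        snps = pd.DataFrame({"chrom": "chr1",
                             "pos": np.arange(1, 11) * 100,
                             "locus": [f"l{i}" for i in range(10)],
                             "pip": 0.5})
        annot = _dmrs([("chr1", 0, 850)])  # first 8 SNPs inside
        bg = pd.DataFrame({"chrom": "chr1",
                           "pos": np.r_[np.arange(1, 101) * 5,
                                        900_000 + np.arange(900)],
                           "locus": "bg", "pip": 0.01})
        out = ro.finemap_overlap(snps, annot, bg)
        assert out.table.tolist() == [[8, 2], [100, 900]]
        assert out.odds_ratio == pytest.approx(36.0)

    def test_total_annotation_sentinel(self):
        snps = pd.DataFrame({"chrom": "chr1", "pos": [100, 200],
                             "locus": ["a", "b"], "pip": [0.5, 0.5]})
        bg = pd.DataFrame({"chrom": "chr1", "pos": [300, 400],
                           "locus": "bg", "pip": 0.01})
        annot = _dmrs([("chr1", 0, 1000)])
        out = ro.finemap_overlap(snps, annot, bg)
        assert np.isinf(out.odds_ratio)

    def test_locus_counted_once(self):
        snps = pd.DataFrame({"chrom": "chr1", "pos": [100, 200, 5000],
                             "locus": ["L", "L", "L"], "pip": [0.5] * 3})
        annot = _dmrs([("chr1", 0, 300)])
        bg = pd.DataFrame({"chrom": "chr1", "pos": [90_000],
                           "locus": "bg", "pip": 0.01})
        out = ro.finemap_overlap(snps, annot, bg)
        assert len(out.locus_hits) == 1
        assert bool(out.locus_hits["any_overlap"].iloc[0])

    def test_pip_filter(self):
        snps = pd.DataFrame({"chrom": "chr1", "pos": [100, 200],
                             "locus": ["a", "b"], "pip": [0.05, 0.5]})
        assert len(ro.filter_pip(snps)) == 1

    def test_p_matches_scipy_cross_check(self):
        from scipy.stats import fisher_exact
        snps = pd.DataFrame({"chrom": "chr1", "pos": [50, 150, 9000],
                             "locus": list("abc"), "pip": [0.9] * 3})
        annot = _dmrs([("chr1", 0, 200)])
        bg = pd.DataFrame({"chrom": "chr1",
                           "pos": np.r_[np.arange(10) + 1, 8000 + np.arange(90)],
                           "locus": "bg", "pip": 0.01})
        out = ro.finemap_overlap(snps, annot, bg)
        assert out.pvalue == pytest.approx(
            fisher_exact(out.table)[1], rel=1e-12)


class TestLinkSnpToGenes:
    def _setup(self):
        loops = pd.DataFrame({"chrom": ["chr1"], "bin1": [10], "bin2": [50]})
        dmrs = _dmrs([("chr1", 101_000, 101_500)])   # inside anchor 1
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [502_000],
                            "name": ["geneA"]})      # inside anchor 2
        return loops, dmrs, tss

    def test_cross_anchor_pair_found(self):
        loops, dmrs, tss = self._setup()
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [101_200],
                             "locus": ["l"], "pip": [0.5]})
        out = ro.link_snp_to_genes(snps, dmrs, loops, tss)
        assert len(out) == 1
        assert out.iloc[0]["gene"] == "geneA"

    def test_same_anchor_no_pair(self):
        loops, dmrs, _ = self._setup()
        tss_same = pd.DataFrame({"chrom": ["chr1"], "tss": [103_000],
                                 "name": ["geneB"]})  # same anchor as SNP
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [101_200],
                             "locus": ["l"], "pip": [0.5]})
        out = ro.link_snp_to_genes(snps, dmrs, loops, tss_same)
        assert len(out) == 0

    def test_matches_brute_force_join(self, rng):
        loops = pd.DataFrame({"chrom": ["chr1"] * 4,
                              "bin1": [10, 20, 30, 40],
                              "bin2": [60, 70, 80, 90]})
        dmrs = _dmrs([("chr1", int(s), int(s) + 300)
                      for s in rng.integers(50_000, 950_000, 30)])
        snps = pd.DataFrame({"chrom": "chr1",
                             "pos": rng.integers(50_000, 950_000, 40),
                             "locus": "l", "pip": 0.5})
        tss = pd.DataFrame({"chrom": "chr1",
                            "tss": rng.integers(50_000, 950_000, 15),
                            "name": [f"g{i}" for i in range(15)]})
        got = ro.link_snp_to_genes(snps, dmrs, loops, tss)
        got_set = set(map(tuple, got.to_numpy()))
        expected = set()
        for _, l in loops.iterrows():
            anchors = [(l.bin1 * 10_000, (l.bin1 + 1) * 10_000),
                       (l.bin2 * 10_000, (l.bin2 + 1) * 10_000)]
            for k in (0, 1):
                a_s, a_e = anchors[k]
                o_s, o_e = anchors[1 - k]
                for _, s in snps.iterrows():
                    p0 = s.pos - 1
                    in_dmr_on_anchor = any(
                        d.start <= p0 < d.end and d.start < a_e and d.end > a_s
                        for _, d in dmrs.iterrows())
                    if not in_dmr_on_anchor:
                        continue
                    for _, t in tss.iterrows():
                        gap = max(o_s - t.tss, 0) + max(t.tss - (o_e - 1), 0)
                        if gap <= 5000:
                            expected.add(("chr1", int(s.pos), t["name"]))
        assert got_set == expected


class TestEnrichmentDifference:
    def test_equal_enrichments(self):
        t, p = ro.enrichment_difference_test(5.0, 1.0, 5.0, 2.0)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_arithmetic_example(self):
        t, p = ro.enrichment_difference_test(10, 2, 6, 1)
        assert t == pytest.approx(4 / np.sqrt(5), rel=1e-12)

    def test_symmetry_up_to_sign(self):
        t1, p1 = ro.enrichment_difference_test(10, 2, 6, 1)
        t2, p2 = ro.enrichment_difference_test(6, 1, 10, 2)
        assert t1 == -t2 and p1 == p2

    def test_uses_398_degrees_of_freedom(self):
        from scipy.stats import t as t_dist
        t, p = ro.enrichment_difference_test(10, 2, 6, 1)
        assert p == pytest.approx(2 * t_dist.sf(abs(t), 398), rel=1e-12)

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            ro.enrichment_difference_test(1, 0, 2, 1)
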
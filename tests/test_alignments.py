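"""Read-pair compatibility, implied fragment lengths, likelihood terms."""

import numpy as np
import pytest

from isousage.alignments import (
    FragmentLengthDistribution,
    ReadFilters,
    build_compatibility,
    effective_length,
    estimate_fragment_length_distribution,
    implied_fragment_length,
    likelihood_matrix,
    load_read_pairs,
    log_likelihood,
    per_read_term,
    unambiguous_fragment_lengths,
)
from isousage.annotation import ExonInterval, GeneModel, IsoformModel

from conftest import make_pair


def oracle_pair(exon_list, t_start, frag_len, read_len=50):
    """Independent fragment->pair constructor: walks explicit genomic
    position lists instead of interval arithmetic."""
    positions = []
    for s, e in exon_list:
        positions.extend(range(s, e))

    def blocks(lo, hi):  # transcript interval [lo, hi) -> genomic blocks
        sel = positions[lo:hi]
        out = [[sel[0], sel[0] + 1]]
        for p in sel[1:]:
            if p == out[-1][1]:
                out[-1][1] = p
            else:
                out.append([p, p + 1])
            out[-1][1] = p + 1
        return tuple((a, b) for a, b in out)

    m = min(read_len, frag_len)
    return blocks(t_start, t_start + m), blocks(t_start + frag_len - m, t_start + frag_len)


class TestImpliedFragmentLength:
    def test_single_exon_outer_span(self):
        iso = IsoformModel("i", "g", [ExonInterval("chr1", 0, 500)])
        pair = make_pair("r1", "chr1", [(100, 150)], [(350, 400)])
        assert implied_fragment_length(pair, iso) == 300

    def test_junction_absent_from_isoform(self, three_iso_gene):
        full, skipped, _ = three_iso_gene.isoforms
        # mate1 straddles the exon1-exon2 junction of the full isoform
        pair = make_pair("r2", "chr1", [(1270, 1300), (1500, 1520)], [(1600, 1650)])
        assert implied_fragment_length(pair, full) > 0
        assert implied_fragment_length(pair, skipped) == 0

    def test_mate_in_intron_incompatible(self, three_iso_gene):
        _, skipped, _ = three_iso_gene.isoforms
        pair = make_pair("r3", "chr1", [(1550, 1600)], [(1950, 2000)])
        assert implied_fragment_length(pair, skipped) == 0

    def test_oracle_brute_force(self, three_iso_gene):
        """Every fragment of a 3-exon isoform, rebuilt from explicit
        position lists, is recovered at its drawn length."""
        exons = [(1000, 1300), (1500, 1700), (1900, 2200)]
        iso = three_iso_gene.isoforms[0]
        rng = np.random.default_rng(11)
        for _ in range(200):
            frag = int(rng.integers(60, 700))
            start = int(rng.integers(0, iso.length - frag + 1))
            b1, b2 = oracle_pair(exons, start, frag)
            pair = make_pair("o", "chr1", b1, b2)
            assert implied_fragment_length(pair, iso) == frag

    def test_mates_in_exons_1_and_3(self, three_iso_gene):
        # exon lengths 300/200/300; mate1 in exon1, mate2 in exon3
        iso = three_iso_gene.isoforms[0]
        pair = make_pair("r4", "chr1", [(1200, 1250)], [(1950, 2000)])
        # transcript offsets: 1200 -> 200, 1999 (last base 1999) -> 599
        expected = (
            iso.genomic_to_transcript(1999) - iso.genomic_to_transcript(1200) + 1
        )
        assert implied_fragment_length(pair, iso) == expected == 400

    def test_mate_swap_invariance(self, three_iso_gene):
        iso = three_iso_gene.isoforms[0]
        a = make_pair("r", "chr1", [(1100, 1150)], [(1600, 1650)])
        b = make_pair("r", "chr1", [(1600, 1650)], [(1100, 1150)])
        assert implied_fragment_length(a, iso) == implied_fragment_length(b, iso) > 0


class TestCompatibilityMatrix:
    def test_identical_isoforms_equal_columns(self):
        exons = [ExonInterval("chr1", 0, 400)]
        gene = GeneModel(
            "dup",
            [IsoformModel("d.1", "dup", exons), IsoformModel("d.2", "dup", list(exons))],
        )
        rng = np.random.default_rng(0)
        pairs = [
            make_pair(f"r{i}", "chr1", [(s, s + 50)], [(s + 150, s + 200)])
            for i, s in enumerate(rng.integers(0, 200, size=10))
        ]
        compat = build_compatibility(pairs, gene)
        np.testing.assert_array_equal(compat.lkn[:, 0], compat.lkn[:, 1])
        assert np.all(compat.lkn > 0)

    def test_private_exon_read(self, three_iso_gene):
        # read pair within exon 2 (private to isoforms 1 and 3, absent from 2)
        pair = make_pair("r", "chr1", [(1500, 1550)], [(1620, 1670)])
        compat = build_compatibility([pair], three_iso_gene)
        row = compat.lkn[0]
        assert row[0] > 0 and row[2] > 0 and row[1] == 0

    def test_unassignable_dropped_and_counted(self, three_iso_gene):
        good = make_pair("g", "chr1", [(1010, 1060)], [(1150, 1200)])
        # mate2 spans a junction none of the isoforms has
        bad = make_pair("b", "chr1", [(1010, 1060)], [(1290, 1300), (1700, 1740)])
        compat = build_compatibility([good, bad], three_iso_gene)
        assert compat.n_reads == 1 and compat.n_unassignable == 1

    def test_hand_computed_table(self, three_iso_gene):
        """Hand-placed pairs on the 3-isoform gene; expected l_k^n worked out
        from exon lengths 300/200/300 (isoform lengths 800/600/800)."""
        pairs = [
            make_pair("p1", "chr1", [(1000, 1050)], [(1200, 1250)]),  # exon1 only
            make_pair("p2", "chr1", [(1500, 1550)], [(1600, 1650)]),  # exon2 only
            make_pair("p3", "chr1", [(1250, 1300), (1500, 1550)], [(1600, 1650)]),  # 1-2 junction
            make_pair("p4", "chr1", [(1250, 1300), (1900, 1950)], [(1950, 2000)]),  # 1-3 junction (skip)
            make_pair("p5", "chr1", [(1950, 2000)], [(2100, 2150)]),  # exon3 shared 1,2
        ]
        compat = build_compatibility(pairs, three_iso_gene)
        expected = np.array(
            [
                [250, 250, 250],
                [150, 0, 150],
                [200, 0, 200],
                [0, 150, 0],
                [200, 200, 0],
            ]
        )
        np.testing.assert_array_equal(compat.lkn, expected)


class TestFragmentLengthDistribution:
    def test_point_mass_and_empirical(self):
        f = FragmentLengthDistribution.from_lengths([300] * 10, quantiles=(0, 1))
        assert f.pmf(300) == 1.0 and f.mean == 300
        f = FragmentLengthDistribution.from_lengths([200] * 5 + [300] * 5, quantiles=(0, 1))
        assert f.pmf(200) == 0.5 and f.pmf(300) == 0.5
        assert f.pmf(250) == 0.0 and f.pmf(1000) == 0.0

    def test_normal_estimation_recovers_mean(self, three_iso_gene):
        from isousage.simulate import simulate_read_pairs

        truth_fld = FragmentLengthDistribution.from_normal(250.0, 25.0)
        # single-isoform gene: every pair unambiguous
        gene = GeneModel("solo", [IsoformModel("s.1", "solo", [ExonInterval("chr1", 0, 2000)])])
        pairs, _ = simulate_read_pairs(gene, [1.0], 2 * 50 * 10000 / 2000, truth_fld, 50, rng=5)
        lengths = unambiguous_fragment_lengths(build_compatibility(pairs, gene))
        assert lengths.size >= 9000
        est = FragmentLengthDistribution.from_lengths(lengths)
        assert abs(est.mean - 250.0) < 3.0

    def test_fallback_on_too_few_fragments(self, three_iso_gene, bam_from_sam):
        sam = (
            "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:5000\n"
            "r1\t99\tchr1\t1001\t60\t50M\t=\t1201\t250\t"
            + "A" * 50 + "\t*\n"
            "r1\t147\tchr1\t1201\t60\t50M\t=\t1001\t-250\t" + "A" * 50 + "\t*\n"
        )
        bam = bam_from_sam(sam, "few")
        with pytest.warns(UserWarning, match="falling back"):
            f = estimate_fragment_length_distribution(
                [bam], {"g3": three_iso_gene}, min_fragments=1000,
                fallback_mean=250, fallback_sd=25,
            )
        assert abs(f.mean - 250.0) < 1.0


class TestLikelihoodTerms:
    def test_effective_length(self):
        point = FragmentLengthDistribution(100, np.array([1.0]))
        assert effective_length(100, point) == 1.0
        assert effective_length(99, point) == 0.0
        mix = FragmentLengthDistribution(200, np.r_[0.5, np.zeros(99), 0.5])
        assert effective_length(250, mix) == pytest.approx(0.5 * 51)

    def test_per_read_term(self):
        mix = FragmentLengthDistribution(200, np.r_[0.5, np.zeros(99), 0.5])
        assert per_read_term(0, 400, mix) == 0.0
        point = FragmentLengthDistribution(300, np.array([1.0]))
        assert per_read_term(300, 300, point) == 1.0
        assert per_read_term(300, 400, mix) == pytest.approx(0.5 / 101)

    def test_log_likelihood_hand_computed(self, three_iso_gene, fld_point300):
        lk = [800, 600, 800]
        lkn = np.array([[300, 0, 300], [0, 300, 0], [300, 300, 300]])
        from isousage.alignments import CompatibilityMatrix

        compat = CompatibilityMatrix("g3", ["a", "b", "c"], ["1", "2", "3"], lkn)
        A = likelihood_matrix(compat, fld_point300, lk)
        a1 = 1.0 / (800 - 300 + 1)
        a2 = 1.0 / (600 - 300 + 1)
        np.testing.assert_allclose(
            A, [[a1, 0, a1], [0, a2, 0], [a1, a2, a1]], rtol=1e-14
        )
        p = np.array([0.5, 0.3, 0.2])
        expected = (
            np.log(0.5 * a1 + 0.2 * a1)
            + np.log(0.3 * a2)
            + np.log(0.5 * a1 + 0.3 * a2 + 0.2 * a1)
        )
        assert log_likelihood(p, A) == pytest.approx(expected, abs=1e-12)
        assert log_likelihood([0, 1, 0], A) == -np.inf

    def test_concavity_along_random_segments(self, fld_normal):
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1e-3, size=(30, 4))
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            ts = np.linspace(0, 1, 9)
            vals = [log_likelihood((1 - t) * p + t * q, A) for t in ts]
            mid = [(vals[i - 1] + vals[i + 1]) / 2 for i in range(1, 8)]
            assert all(v >= m - 1e-9 for v, m in zip(vals[1:-1], mid))


class TestLoadReadPairs:
    HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:5000\n@SQ\tSN:chr9\tLN:5000\n"

    @staticmethod
    def _rec(name, flag, chrom, pos1, cigar, mchrom, mpos1, tlen, seqlen=50):
        seq = "A" * seqlen
        return f"{name}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t{mchrom}\t{mpos1}\t{tlen}\t{seq}\t*\n"

    def test_empty_region(self, three_iso_gene, bam_from_sam):
        bam = bam_from_sam(self.HEADER + self._rec("far", 99, "chr1", 4001, "50M", "=", 4101, 150)
                           + self._rec("far", 147, "chr1", 4101, "50M", "=", 4001, -150), "empty")
        pairs, _ = load_read_pairs(bam, three_iso_gene)
        assert pairs == []

    def test_one_pair_inside_exon(self, three_iso_gene, bam_from_sam):
        sam = (
            self.HEADER
            + self._rec("ok", 99, "chr1", 1001, "50M", "=", 1201, 250)
            + self._rec("ok", 147, "chr1", 1201, "50M", "=", 1001, -250)
        )
        pairs, counters = load_read_pairs(bam_from_sam(sam, "one"), three_iso_gene)
        assert len(pairs) == 1
        assert pairs[0].blocks_mate1 == ((1000, 1050),)
        assert pairs[0].blocks_mate2 == ((1200, 1250),)

    def test_cross_chromosome_mate_excluded(self, three_iso_gene, bam_from_sam):
        sam = (
            self.HEADER
            + self._rec("ok", 99, "chr1", 1001, "50M", "=", 1201, 250)
            + self._rec("ok", 147, "chr1", 1201, "50M", "=", 1001, -250)
            + self._rec("xchr", 97, "chr1", 1001, "50M", "chr9", 1201, 0)
        )
        pairs, counters = load_read_pairs(bam_from_sam(sam, "xc"), three_iso_gene,
                                          ReadFilters(proper_pair_only=False))
        assert len(pairs) == 1
        assert counters["filtered"] == 1

    def test_unpaired_mate_counted(self, three_iso_gene, bam_from_sam):
        # mate2 aligned outside the gene span -> only one mate fetched
        sam = (
            self.HEADER
            + self._rec("half", 99, "chr1", 1001, "50M", "=", 4501, 3550)
        )
        pairs, counters = load_read_pairs(bam_from_sam(sam, "half"), three_iso_gene)
        assert pairs == [] and counters["unpaired_in_region"] == 1

    def test_spliced_cigar_blocks(self, three_iso_gene, bam_from_sam):
        sam = (
            self.HEADER
            + self._rec("spl", 99, "chr1", 1251, "50M200N50M", "=", 1601, 450, seqlen=100)
            + self._rec("spl", 147, "chr1", 1601, "50M", "=", 1251, -450)
        )
        pairs, _ = load_read_pairs(bam_from_sam(sam, "spl"), three_iso_gene)
        assert pairs[0].blocks_mate1 == ((1250, 1300), (1500, 1550))
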
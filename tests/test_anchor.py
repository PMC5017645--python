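"""Bins, sequence allocation, paired-end links, marker anchoring, evaluation."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_dna
from fgm import anchor, dna, simulate
from fgm.anchor import Bin, SeqContig
from fgm.features import FSet
from fgm.physmap import PhysContig
from fgm.simulate import Clone, Marker


def kset(seq: str, owner: str, k: int = 31) -> FSet:
    words = np.sort(np.unique(
        dna.canonical(dna.window_codes(dna.encode(seq), k), k)))
    return FSet("KMER", k, words, np.ones(len(words), dtype=np.int64),
                owner=owner, stage="final")


class TestSplitIntoBins:
    def test_single_clone_contig_single_bin(self):
        s = random_dna(2_000, 1)
        ks = {"a": kset(s, "a")}
        bins = anchor.split_into_bins(PhysContig("x", ["a"]), ks)
        assert len(bins) == 1
        assert np.array_equal(bins[0].words, ks["a"].words)

    def test_two_overlapping_clones_three_ordered_bins(self):
        g = random_dna(6_000, 2)
        a, b = g[:4_000], g[2_000:]
        ks = {"a": kset(a, "a"), "b": kset(b, "b")}
        bins = anchor.split_into_bins(PhysContig("x", ["a", "b"]), ks)
        assert [b_.clones for b_ in bins] == [["a"], ["a", "b"], ["b"]]
        shared = bins[1].words
        assert np.all(np.isin(shared, ks["a"].words))
        assert np.all(np.isin(shared, ks["b"].words))

    def test_bin_kmers_subset_of_true_interval_with_high_recall(self):
        """Error-free: each bin's k-mers lie within the true genomic segment
        spanned by its covering clones, recovering >=90% of the segment."""
        g = random_dna(10_000, 3)
        iv = {"a": (0, 4_500), "b": (3_000, 7_500), "c": (6_000, 10_000)}
        ks = {c: kset(g[s:e], c) for c, (s, e) in iv.items()}
        bins = anchor.split_into_bins(PhysContig("x", ["a", "b", "c"]), ks)
        k = 31
        for b_ in bins:
            lo = max(iv[c][0] for c in b_.clones)
            hi = min(iv[c][1] for c in b_.clones)
            exact = np.setdiff1d(
                kset(g[lo:hi], "seg").words,
                np.concatenate([ks[c].words for c in iv if c not in b_.clones]))
            assert np.all(np.isin(b_.words, kset(g[lo:hi], "seg").words))
            if len(exact) > 50:
                assert np.isin(exact, b_.words).mean() >= 0.90


class TestAllocate:
    def _bins(self):
        g = random_dna(9_000, 4)
        ks = {"a": kset(g[:6_000], "a"), "b": kset(g[3_000:], "b")}
        return g, anchor.split_into_bins(PhysContig("x", ["a", "b"]), ks)

    def test_verbatim_segment_goes_to_its_bin(self):
        g, bins = self._bins()
        seq = SeqContig("s", g[500:2_500])
        a = anchor.allocate(seq, bins)
        assert a is not None and (a.contig_id, a.bin_rank) == ("x", 0)
        assert a.score > 0.9

    def test_foreign_sequence_unallocated(self):
        _, bins = self._bins()
        assert anchor.allocate(SeqContig("s", random_dna(1_000, 99)), bins) is None

    def test_straddling_sequence_takes_higher_share_bin(self):
        g, bins = self._bins()
        seq = SeqContig("s", g[2_000:3_800])  # 1500 bp in bin0's segment, 800 in shared
        a = anchor.allocate(seq, bins, min_frac=0.5)
        assert a is not None and a.bin_rank == 0

    def test_exact_tie_left_unallocated(self):
        w1 = np.array([1, 2], dtype=np.uint64)
        w2 = np.array([3, 4], dtype=np.uint64)
        bins = [Bin("x", 0, ["a"], w1), Bin("x", 1, ["b"], w2)]
        seq = SeqContig("s", "ACGT", k=2)
        seq.words = np.array([1, 3], dtype=np.uint64)  # one k-mer in each bin
        assert anchor.allocate(seq, bins, min_frac=0.2) is None


def _junction_batch(contig_a: str, contig_b: str, R=100, n=12):
    """Pairs whose fragment spans the junction of two genome-adjacent contigs."""
    frag = contig_a[-260:] + contig_b[:260]
    m1 = np.stack([dna.encode(frag[:R])] * n)
    m2 = np.stack([dna.encode(dna.revcomp(frag[-R:]))] * n)
    z = np.zeros(n, dtype=np.int64)
    return simulate.ReadBatch("p", m1, m2, z, z, np.full(n, len(frag)), np.ones(n, bool))


class TestMapPairs:
    def test_junction_pair_links_contigs_with_correct_strands(self):
        a, b = random_dna(2_000, 5), random_dna(2_000, 6)
        batch = _junction_batch(a, b)
        links = anchor.map_pairs([batch], {"A": a, "B": b})
        assert len(links) == 1
        row = links.iloc[0]
        # mate1 reads A forward (+), mate2 reads B reverse-complemented (-):
        # opposite mate strands mean the contigs already face the same way
        assert (row.contig_a, row.contig_b) == ("A", "B")
        assert (row.strand_a, row.strand_b) == (1, -1)
        assert row.n == 12

    def test_both_mates_same_contig_no_link(self):
        a = random_dna(3_000, 7)
        batch = _junction_batch(a[:1_500], a[1_500:])  # same underlying contig
        links = anchor.map_pairs([batch], {"A": a})
        assert len(links) == 0

    def test_unmappable_mate_ignored(self):
        a = random_dna(2_000, 8)
        foreign = random_dna(2_000, 9)
        batch = _junction_batch(a, foreign)
        links = anchor.map_pairs([batch], {"A": a})  # mate2 hits nothing
        assert len(links) == 0

    def test_repeat_kmers_excluded_from_index(self):
        a = random_dna(1_000, 10)
        links = anchor.map_pairs([_junction_batch(a, a)], {"A": a, "B": a})
        assert len(links) == 0  # all k-mers ambiguous between A and B


def _alloc(seq_id, contig_id, rank):
    return anchor.Allocation(seq_id, contig_id, rank, 1.0)


def links_frame(rows):
    return pd.DataFrame(rows, columns=["contig_a", "contig_b", "strand_a",
                                       "strand_b", "n"])


class TestConnectAndOrient:
    def test_concordant_links_same_orientation(self):
        sa, sb = random_dna(500, 11), random_dna(500, 12)
        seqs = {"A": SeqContig("A", sa), "B": SeqContig("B", sb)}
        allocs = {"A": _alloc("A", "x", 0), "B": _alloc("B", "x", 1)}
        links = links_frame([("A", "B", 1, -1, 5)])
        sc = anchor.connect_and_orient(allocs, links, {}, seqs)["x"]
        assert sc.members == [("A", "+"), ("B", "+")]
        assert sc.sequence == sa + "N" * 100 + sb

    def test_same_strand_links_flip_second_contig(self):
        sa, sb = random_dna(500, 13), random_dna(500, 14)
        seqs = {"A": SeqContig("A", sa), "B": SeqContig("B", sb)}
        allocs = {"A": _alloc("A", "x", 0), "B": _alloc("B", "x", 1)}
        links = links_frame([("A", "B", 1, 1, 5)])
        sc = anchor.connect_and_orient(allocs, links, {}, seqs)["x"]
        assert sc.members == [("A", "+"), ("B", "-")]
        assert sc.sequence == sa + "N" * 100 + dna.revcomp(sb)

    def test_contradictory_equal_weight_links_dropped(self):
        sa, sb = random_dna(500, 15), random_dna(500, 16)
        seqs = {"A": SeqContig("A", sa), "B": SeqContig("B", sb)}
        allocs = {"A": _alloc("A", "x", 0), "B": _alloc("B", "x", 1)}
        links = links_frame([("A", "B", 1, 1, 3), ("A", "B", 1, -1, 3)])
        sc = anchor.connect_and_orient(allocs, links, {}, seqs)["x"]
        assert sc.members == [("A", "+"), ("B", "+")]  # unjoined default order

    def test_distant_bin_links_ignored(self):
        seqs = {k: SeqContig(k, random_dna(300, 20 + i)) for i, k in enumerate("AB")}
        allocs = {"A": _alloc("A", "x", 0), "B": _alloc("B", "x", 5)}
        links = links_frame([("A", "B", 1, 1, 9)])
        sc = anchor.connect_and_orient(allocs, links, {}, seqs)["x"]
        assert sc.members == [("A", "+"), ("B", "+")]  # link not honored


def _contig_with_clones():
    contig = PhysContig("x", ["c1", "c2", "c3"])
    scaffold = anchor.Scaffold("x", [("s", "+")], "ACGT" * 250)
    return contig, {"x": scaffold}


class TestAnchorContigs:
    def test_two_markers_in_reversed_order_give_minus_orientation(self):
        contig, scaffolds = _contig_with_clones()
        markers = [Marker("m1", "chr1", 100_000, {"c1"}),
                   Marker("m2", "chr1", 900_000, {"c3"})]
        markers[0].clone_hits, markers[1].clone_hits = {"c3"}, {"c1"}
        asm = anchor.anchor_contigs([contig], scaffolds, markers)
        pl = asm.placements["x"]
        assert (pl.chrom, pl.orientation) == ("chr1", "-")
        assert pl.position == pytest.approx(500_000)

    def test_single_marker_placed_with_unknown_orientation(self):
        contig, scaffolds = _contig_with_clones()
        markers = [Marker("m1", "chr2", 42_000, {"c2"})]
        asm = anchor.anchor_contigs([contig], scaffolds, markers)
        pl = asm.placements["x"]
        assert (pl.chrom, pl.orientation) == ("chr2", "?")
        assert not asm.unplaced

    def test_no_markers_unplaced(self):
        contig, scaffolds = _contig_with_clones()
        asm = anchor.anchor_contigs([contig], scaffolds, [Marker("m", "chr1", 5, set())])
        assert asm.unplaced == ["x"] and not asm.placements

    def test_gap_runs_are_exactly_gap_size(self):
        c1, s1 = _contig_with_clones()
        c2 = PhysContig("y", ["c9"])
        scaffolds = dict(s1)
        scaffolds["y"] = anchor.Scaffold("y", [("t", "+")], "TTTT" * 200)
        markers = [Marker("m1", "chr1", 10_000, {"c1"}),
                   Marker("m2", "chr1", 90_000, {"c9"})]
        asm = anchor.anchor_contigs([c1, c2], scaffolds, markers, gap=5_000)
        seq = asm.pseudomolecules["chr1"].sequence
        assert "N" * 5_000 in seq and "N" * 5_001 not in seq
        assert len(seq) == 1_000 + 5_000 + 800


class TestEvaluate:
    def test_n50_hand_example(self):
        assert anchor.n50([40, 30, 20, 10]) == 30
        assert anchor.n50([]) == 0
        assert anchor.n50([7]) == 7

    def test_misplaced_contig_counted(self):
        genome = simulate.Genome.from_strings({"chr1": "A" * 1_000, "chr2": "C" * 1_000})
        clones = [Clone("c1", "chr1", 0, 500), Clone("c2", "chr1", 250, 750)]
        contig = PhysContig("x", ["c1", "c2"])
        scaffolds = {"x": anchor.Scaffold("x", [("s", "+")], "G" * 400)}
        markers = [Marker("m", "chr2", 100, {"c1"})]  # wrong-chromosome marker
        asm = anchor.anchor_contigs([contig], scaffolds, markers)
        report = anchor.evaluate(asm, genome, clones, [contig])
        assert report.n_misplaced == 1 and report.n_inverted == 0

    def test_perfect_placement_scores_clean(self, toy_run):
        report = toy_run.report
        assert report.n_misplaced == 0 and report.n_inverted == 0

    def test_every_seq_contig_allocated_at_most_once(self, toy_run):
        placed = [m for s in toy_run.assembly.scaffolds.values() for m, _ in s.members]
        assert len(placed) == len(set(placed))

    def test_bin_rank_order_is_monotone_in_genomic_position(self, toy_run):
        """Allocated sequences' true positions increase with bin rank within
        each physical contig, up to whole-contig reversal."""
        from scipy import stats as sps
        seeds = __import__("fgm.pipeline", fromlist=["_stage_seeds"])._stage_seeds(
            toy_run.resolved.config.seed)
        _, truth = simulate.fragment_truth_contigs(
            toy_run.resolved.genome, toy_run.resolved.config.seq_mean_len,
            seeds["seqs"], min_len=toy_run.resolved.config.min_seq_len)
        checked = 0
        for scaffold in toy_run.assembly.scaffolds.values():
            pos = [truth[m][1] for m, _ in scaffold.members if m in truth]
            if len(pos) < 5:
                continue
            rho = sps.spearmanr(pos, range(len(pos))).statistic
            assert abs(rho) > 0.9
            checked += 1
        assert checked >= 1
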
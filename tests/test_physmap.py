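"""Sulston scoring, contiging, Q-clone analysis and .size file round-trips."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from fgm import features, physmap, simulate
from fgm.physmap import SulstonParams, sulston_score


def bands(*ids):
    return np.array(sorted(ids), dtype=np.int64)


class TestSulstonScore:
    def test_no_shared_bands_scores_one(self):
        assert sulston_score(bands(1, 2, 3), bands(4, 5, 6), gellen=10) == 1.0

    def test_identical_large_sets_far_below_cutoff(self):
        b = np.arange(1, 51, dtype=np.int64)
        assert sulston_score(b, b, gellen=100_000) < 1e-12

    def test_symmetry(self):
        b1, b2 = bands(1, 2, 3, 9), bands(2, 3, 7)
        g = 1000
        assert sulston_score(b1, b2, g) == sulston_score(b2, b1, g)

    def test_fresh_shared_band_never_increases_score(self):
        b1, b2 = bands(*range(1, 40)), bands(*range(30, 70))
        g = 100_000
        s0 = sulston_score(b1, b2, g)
        s1 = sulston_score(np.append(b1, 99_000), np.append(b2, 99_000), g)
        assert s1 <= s0

    def test_agrees_with_log_space_tail_sum(self):
        """Independent oracle: direct binomial tail in log space."""
        b1 = bands(*range(1, 31))
        b2 = bands(*range(21, 56))
        g = 5_000
        nH, nL = 35, 30
        q = 1 - (1 - 1 / g) ** nH
        m = 10
        terms = [gammaln(nL + 1) - gammaln(i + 1) - gammaln(nL - i + 1)
                 + i * np.log(q) + (nL - i) * np.log1p(-q) for i in range(m, nL + 1)]
        oracle = np.exp(terms).sum()
        assert sulston_score(b1, b2, g) == pytest.approx(oracle, rel=1e-9)

    def test_monte_carlo_chance_match_oracle(self):
        """Empirical P(shared >= m) for random band sets matches the score.

        Drawing two random |b|-subsets of [1, gellen] and intersecting is
        by definition hypergeometric, sampled directly at 10^6 draws.
        """
        rng = np.random.default_rng(0)
        nb, gellen, m = 100, 100_000, 2
        draws = rng.hypergeometric(nb, gellen - nb, nb, size=1_000_000)
        emp = (draws >= m).mean()
        q = 1 - (1 - 1 / gellen) ** nb
        score = float(stats.binom.sf(m - 1, nb, q))
        sigma = np.sqrt(emp * (1 - emp) / len(draws))
        assert abs(emp - score) < 3 * sigma + 1e-5

    def test_gellen_smaller_than_band_ids_rejected(self):
        with pytest.raises(ValueError):
            sulston_score(bands(1, 200), bands(1, 2), gellen=100)

    def test_empty_band_list_rejected(self):
        with pytest.raises(ValueError):
            sulston_score(np.array([], dtype=np.int64), bands(1), gellen=10)


def _chain_bands(n_shared=30, n_clones=3, gellen=100_000):
    """A, B, C on a line: A-B and B-C share bands, A-C share none."""
    rng = np.random.default_rng(1)
    vals = rng.choice(np.arange(1, gellen), size=5 * n_shared, replace=False)
    a = vals[: 2 * n_shared]
    b = np.concatenate([vals[n_shared : 3 * n_shared]])
    c = vals[2 * n_shared : 4 * n_shared]
    return {"A": np.sort(a), "B": np.sort(b), "C": np.sort(c)}


class TestBuildContigs:
    def test_transitive_chain_forms_one_contig_with_interior_clone(self):
        cb = _chain_bands()
        contigs, singles, _ = physmap.build_contigs(cb, SulstonParams(1e-12, 100_000))
        assert len(contigs) == 1 and not singles
        assert contigs[0].clones[1] == "B"  # B is interior

    def test_no_overlap_all_singletons(self):
        rng = np.random.default_rng(2)
        cb = {f"c{i}": np.sort(rng.choice(100_000, 40, replace=False) + 1)
              for i in range(5)}
        contigs, singles, _ = physmap.build_contigs(cb, SulstonParams(1e-12, 100_000))
        assert contigs == [] and len(singles) == 5

    def test_error_free_simulation_recovers_genomic_order(self, small_genome):
        """Clone order within each contig equals true order up to reversal."""
        model = simulate.LibraryModel().scaled(30_000, n_clones=100)
        clones = simulate.simulate_library(small_genome, model, seed=21)
        params = features.FeatureParams(("GGATCC", "GAATTC", "TCTAGA", "CTCGAG"), 31, 31)
        fsets = {c.id: features.fset_of_sequence(
            small_genome.sequences[c.chrom][c.start:c.end], params, "FS", owner=c.id)
            for c in clones}
        cb, index, _ = physmap.clone_bands(fsets, min_bands=10)
        contigs, _, _ = physmap.build_contigs(cb, SulstonParams(1e-12, len(index)))
        iv = {c.id: (c.start, c.end) for c in clones}
        n_checked = 0
        for contig in contigs:
            if len(contig.clones) < 3:
                continue
            # clones with disjoint intervals are orderable from band data;
            # nested/overlapping clones are not, so only disjoint pairs are
            # required to be concordant with one global direction
            votes = []
            for i, a in enumerate(contig.clones):
                for b in contig.clones[i + 1:]:
                    (s1, e1), (s2, e2) = iv[a], iv[b]
                    if e1 <= s2:
                        votes.append(1)
                    elif e2 <= s1:
                        votes.append(-1)
            if votes:
                assert abs(sum(votes)) == len(votes)  # unanimous direction
                n_checked += 1
        assert n_checked >= 1

    def test_no_false_joins_in_sub1x_library(self, small_genome, desk_library):
        """Non-overlapping clones (truth) are never joined at cutoff 1e-12."""
        params = features.FeatureParams()
        fsets = {c.id: features.fset_of_sequence(
            small_genome.sequences[c.chrom][c.start:c.end], params, "FS", owner=c.id)
            for c in desk_library}
        cb, index, _ = physmap.clone_bands(fsets, min_bands=10)
        contigs, _, _ = physmap.build_contigs(cb, SulstonParams(1e-12, len(index)))
        iv = {c.id: (c.start, c.end) for c in desk_library}
        false_joins = 0
        for contig in contigs:
            for a, b in zip(contig.clones, contig.clones[1:]):
                (s1, e1), (s2, e2) = iv[a], iv[b]
                if min(e1, e2) <= max(s1, s2):
                    false_joins += 1
        assert false_joins == 0


class TestQAnalysis:
    def test_clean_contig_unchanged(self):
        cb = _chain_bands()
        params = SulstonParams(1e-12, 100_000)
        contigs, _, table = physmap.build_contigs(cb, params)
        out, singles = physmap.q_analysis(contigs, cb, table, params)
        assert [c.clones for c in out] == [contigs[0].clones] and not singles

    def test_planted_chimeras_are_split_or_flagged(self):
        """Six chimeric clones (random band unions) planted into one linkage
        group: afterwards no contig carries more than 5 Q-clones."""
        rng = np.random.default_rng(3)
        gellen = 50_000
        # a clean tiling of 12 clones along a line
        line = rng.choice(np.arange(1, gellen), size=400, replace=False)
        cb = {}
        for i in range(12):
            cb[f"t{i:02d}"] = np.sort(line[i * 30 : i * 30 + 60])
        # chimeras: a weak 10-band link into one tile plus random junk, so
        # they join at 1e-12 but detach once the cutoff tightens
        for j in range(6):
            junk = rng.choice(np.arange(1, gellen), size=60, replace=False)
            cb[f"q{j}"] = np.unique(np.concatenate([line[j * 60 : j * 60 + 10], junk]))
        params = SulstonParams(1e-12, gellen)
        contigs, _, table = physmap.build_contigs(cb, params)
        assert sum(len(c.clones) for c in contigs) >= 12  # tiling stays contiged
        out, _ = physmap.q_analysis(contigs, cb, table, params, max_q=5)
        assert all(c.n_q <= 5 for c in out)

    def test_clone_usage_definition(self):
        contigs = [physmap.PhysContig("x", ["a", "b", "c"])]
        assert physmap.clone_usage(contigs, 4) == pytest.approx(0.75)


class TestSizeFile(object):
    def test_exact_format_lines(self, tmp_path):
        path = tmp_path / "c.size"
        physmap.write_size_file({"c1": np.array([3, 7])}, path)
        assert path.read_text() == "c1 2\n3\n7\n-1\n"

    def test_empty_collection_empty_file(self, tmp_path):
        path = tmp_path / "e.size"
        physmap.write_size_file({}, path)
        assert path.read_text() == ""

    def test_roundtrip(self, tmp_path):
        data = {"c1": np.array([3, 7, 9]), "long name": np.array([1]),
                "c3": np.array([2, 4, 6, 8])}
        path = tmp_path / "r.size"
        physmap.write_size_file(data, path)
        back = physmap.read_size_file(path)
        assert set(back) == set(data)
        for k in data:
            assert np.array_equal(back[k], data[k])

    def test_nonpositive_band_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            physmap.write_size_file({"c1": np.array([0, 2])}, tmp_path / "bad.size")


def test_band_index_is_lexicographic_and_dense(small_genome):
    params = features.FeatureParams()
    fs = features.fset_of_sequence(small_genome.sequences["chr1"][:200_000],
                                   params, "FS", owner="c")
    index = physmap.BandIndex.from_fsets({"c": fs})
    ids = index.band_ids(fs)
    assert ids[0] == 1 and ids[-1] == len(index)
    assert np.all(np.diff(ids) > 0)
    strings = [index.band_string(int(i)) for i in ids[:5]]
    assert strings == sorted(strings)
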
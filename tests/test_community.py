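"""Alpha/beta/phylogenetic diversity metrics and permutation tests."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beedelim.community import (
    anosim,
    beta_partition,
    bray_curtis,
    comdist,
    comdist_phenogram,
    dissimilarity_matrix,
    diversity_table,
    faith_pd,
    mantel,
    mntd,
    mpd,
    permanova,
    ses_index,
    simpson_diversity,
    upgma,
)
from beedelim.dataio import CommunityTable, read_newick
from beedelim.simulate import simulate_species_tree
from beedelim.trees import patristic_matrix


@pytest.fixture(scope="module")
def random_tree():
    return simulate_species_tree(20, 1.0, 17)


@pytest.fixture(scope="module")
def random_pdm(random_tree):
    return patristic_matrix(random_tree)


def _brute_patristic(tree, a, b):
    """Oracle: path length via explicit root paths."""

    def path_to_root(label):
        node = next(l for l in tree.leaf_node_iter() if l.taxon.label == label)
        path = []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        return path

    pa = path_to_root(a)
    pb = path_to_root(b)
    ancestors_a = {id(n.parent_node) for n in pa}
    shared = [n for n in pb if id(n.parent_node) in ancestors_a]
    # walk both paths, dropping the shared suffix above the MRCA
    ids_b = [id(n) for n in pb]
    total = 0.0
    mrca_found = False
    for paths in (pa, pb):
        pass
    # simpler: sum both root paths then subtract twice the shared prefix
    sum_a = sum(n.edge.length for n in pa)
    sum_b = sum(n.edge.length for n in pb)
    # shared part: edges above the MRCA appear in both paths
    set_b = {}
    node = next(l for l in tree.leaf_node_iter() if l.taxon.label == b)
    depth = 0.0
    chain_b = []
    while node.parent_node is not None:
        chain_b.append((id(node), node.edge.length))
        node = node.parent_node
    ids_in_b = dict(chain_b)
    shared_len = 0.0
    node = next(l for l in tree.leaf_node_iter() if l.taxon.label == a)
    chain_a = set()
    while node.parent_node is not None:
        chain_a.add(id(node))
        node = node.parent_node
    shared_len = sum(l for i, l in chain_b if i in chain_a)
    return sum_a + sum_b - 2 * shared_len


class TestSimpson:
    def test_monoculture_is_zero(self):
        assert simpson_diversity([7]) == 0.0

    def test_even_two_species(self):
        assert simpson_diversity([50, 50]) == pytest.approx(0.5)

    def test_matches_direct_formula(self):
        counts = [10, 5, 3, 1, 1]
        p = np.array(counts) / 20
        assert simpson_diversity(counts) == pytest.approx(1 - np.sum(p**2))

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            simpson_diversity([0, 0])
        with pytest.raises(ValueError):
            simpson_diversity([3, -1])


class TestPhyloAlpha:
    def test_pd_of_all_tips_is_total_length(self, random_tree):
        from beedelim.trees import total_branch_length

        tips = [l.taxon.label for l in random_tree.leaf_node_iter()]
        assert faith_pd(random_tree, tips) == pytest.approx(
            total_branch_length(random_tree)
        )

    def test_two_taxa_mpd_equals_mntd_equals_patristic(self, random_tree, random_pdm):
        a, b = random_pdm.index[0], random_pdm.index[5]
        expected = _brute_patristic(random_tree, a, b)
        assert mpd(random_pdm, [a, b]) == pytest.approx(expected)
        assert mntd(random_pdm, [a, b]) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_mpd_mntd_match_brute_force(self, seed, random_tree, random_pdm):
        rng = np.random.default_rng(seed)
        taxa = list(rng.choice(random_pdm.index, size=5, replace=False))
        pairs = [
            _brute_patristic(random_tree, a, b)
            for i, a in enumerate(taxa)
            for b in taxa[i + 1:]
        ]
        assert mpd(random_pdm, taxa) == pytest.approx(np.mean(pairs))
        mins = []
        for a in taxa:
            mins.append(
                min(_brute_patristic(random_tree, a, b) for b in taxa if b != a)
            )
        assert mntd(random_pdm, taxa) == pytest.approx(np.mean(mins))

    def test_abundance_weighting(self, random_pdm):
        taxa = list(random_pdm.index[:3])
        w = [5.0, 1.0, 1.0]
        sub = random_pdm.loc[taxa, taxa].to_numpy()
        pair_w = [5 * 1, 5 * 1, 1 * 1]
        pair_d = [sub[0, 1], sub[0, 2], sub[1, 2]]
        assert mpd(random_pdm, taxa, w) == pytest.approx(
            np.average(pair_d, weights=pair_w)
        )

    def test_singleton_community_rejected(self, random_pdm):
        with pytest.raises(ValueError):
            mpd(random_pdm, [random_pdm.index[0]])


class TestSES:
    def test_whole_pool_community_degenerate(self, random_tree):
        tips = [l.taxon.label for l in random_tree.leaf_node_iter()]
        with pytest.raises(ValueError, match="degenerate"):
            ses_index(random_tree, tips, "mpd", n_iter=99, seed=0)

    def test_one_clade_community_detected_as_clustered(self):
        # five well-separated clades; a community equal to one clade scores
        # both indices above the 1.96 clustering bar
        rng = np.random.default_rng(4)
        tree = dendropy.Tree()
        ns = tree.taxon_namespace
        for c in range(5):
            node = dendropy.Node(edge_length=1.0)
            for i in range(4):
                ch = dendropy.Node(edge_length=0.05 + float(rng.random()) * 0.01)
                ch.taxon = ns.new_taxon(f"C{c}_{i}")
                node.add_child(ch)
            tree.seed_node.add_child(node)
        community = [f"C0_{i}" for i in range(4)]
        res = ses_index(tree, community, "mpd", n_iter=999, seed=1)
        assert res.index > 1.96  # positive NRI = clustering, by convention
        res_t = ses_index(tree, community, "mntd", n_iter=999, seed=2)
        assert res_t.index > 1.96

    def test_requires_minimum_iterations(self, random_tree):
        with pytest.raises(ValueError):
            ses_index(random_tree, ["S001", "S002"], "mpd", n_iter=10)


class TestBrayCurtisAndUPGMA:
    def test_identity_and_disjoint_bounds(self):
        assert bray_curtis([3, 2, 1], [3, 2, 1]) == 0.0
        assert bray_curtis([3, 0, 0], [0, 2, 5]) == 1.0

    def test_half_overlap(self):
        assert bray_curtis([1, 1, 0], [0, 1, 1]) == pytest.approx(0.5)

    def test_rejects_double_empty(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_upgma_tree_tips_are_plots(self):
        counts = pd.DataFrame(
            [[5, 0, 1], [4, 1, 1], [0, 9, 2], [0, 8, 3]],
            index=["p1", "p2", "p3", "p4"],
            columns=["o1", "o2", "o3"],
        )
        table = CommunityTable(counts=counts)
        tree = upgma(dissimilarity_matrix(table))
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        assert labels == {"p1", "p2", "p3", "p4"}
        # similar plots cluster together
        pdm = patristic_matrix(tree)
        assert pdm.loc["p1", "p2"] < pdm.loc["p1", "p3"]


class TestBetaPartition:
    def _table(self, rows):
        counts = pd.DataFrame(
            rows, index=[f"p{i}" for i in range(len(rows))],
            columns=[f"o{j}" for j in range(len(rows[0]))],
        )
        return CommunityTable(counts=counts)

    def test_identical_plots_zero(self):
        res = beta_partition(self._table([[3, 1, 0], [3, 1, 0]]))
        assert res.btotal == 0.0

    def test_unit_shared_and_unique(self):
        # a = 1 shared, b = c = 1 unique per side
        res = beta_partition(self._table([[1, 1, 0], [1, 0, 1]]))
        assert res.btotal == pytest.approx(2 / 3)
        assert res.brepl == pytest.approx(2 / 3)
        assert res.brich == pytest.approx(0.0)

    def test_richness_difference_only(self):
        # nested composition: pure richness difference, no replacement
        res = beta_partition(self._table([[1, 1, 1, 1], [1, 1, 0, 0]]))
        assert res.brepl == 0.0
        assert res.brich == pytest.approx(2 / 4)

    def test_rarefaction_excludes_small_plots(self, caplog):
        table = self._table([[30, 20, 10], [25, 25, 10], [1, 0, 0]])
        with caplog.at_level("WARNING"):
            res = beta_partition(table, rarefy_to=20, n_resample=10, seed=0)
        assert "excluded 1 plot" in caplog.text
        assert 0 <= res.btotal <= 1

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=20), min_size=4, max_size=4),
            min_size=2,
            max_size=5,
        ),
        st.sampled_from(["incidence", "abundance"]),
    )
    def test_partition_identity(self, rows, mode):
        if not any(any(r) for r in rows):
            return
        res = beta_partition(self._table(rows), mode=mode)
        assert res.btotal == pytest.approx(res.brepl + res.brich, abs=1e-12)
        assert 0 <= res.btotal <= 1


@pytest.fixture(scope="module")
def dmat():
    rng = np.random.default_rng(0)
    pts = rng.random((10, 4))
    return np.linalg.norm(pts[:, None] - pts[None, :], axis=2)


class TestPermutationTests:

    def test_mantel_self_correlation(self, dmat):
        r, p = mantel(dmat, dmat, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_mantel_antisymmetric_under_negation(self, dmat):
        other = dmat[::-1, ::-1]
        r1, _ = mantel(dmat, other, n_perm=9, seed=0)
        r2, _ = mantel(dmat, -other, n_perm=9, seed=0)
        assert r1 == pytest.approx(-r2)

    def test_mantel_constant_matrix_rejected(self, dmat):
        with pytest.raises(ValueError):
            mantel(dmat, np.ones_like(dmat) - np.eye(10), n_perm=9)

    def test_anosim_perfect_separation(self):
        # within-group distances all smaller than between-group
        n = 8
        d = np.full((n, n), 10.0)
        d[:4, :4] = 1.0
        d[4:, 4:] = 1.0
        np.fill_diagonal(d, 0)
        r, p = anosim(d, ["a"] * 4 + ["b"] * 4, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_anosim_rejects_singleton_group(self, dmat):
        with pytest.raises(ValueError):
            anosim(dmat, ["a"] * 9 + ["b"], n_perm=9)

    def test_statistics_match_scikit_bio(self, dmat):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim
        from skbio.stats.distance import permanova as sk_permanova

        groups = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        r, _ = anosim(dmat, groups, n_perm=9, seed=0)
        f, r2, _ = permanova(dmat, groups, n_perm=9, seed=0)
        sk_r = sk_anosim(SkDM(dmat), groups, permutations=0)["test statistic"]
        sk_f = sk_permanova(SkDM(dmat), groups, permutations=0)["test statistic"]
        assert r == pytest.approx(sk_r, abs=1e-12)
        assert f == pytest.approx(sk_f, abs=1e-9)

    def test_permanova_continuous_covariate(self, dmat):
        rng = np.random.default_rng(3)
        covariate = rng.random(10)
        f, r2, p = permanova(dmat, covariate, n_perm=99, seed=0)
        assert f > 0 and 0 <= r2 <= 1
        assert 1 / 100 <= p <= 1

    def test_p_values_within_permutation_bounds(self, dmat):
        groups = ["a"] * 5 + ["b"] * 5
        for n_perm in (9, 99):
            _, p = anosim(dmat, groups, n_perm=n_perm, seed=1)
            assert 1 / (n_perm + 1) <= p <= 1


class TestComdist:
    def test_identical_single_species_plots(self, random_tree):
        sp = next(iter(l.taxon.label for l in random_tree.leaf_node_iter()))
        counts = pd.DataFrame([[3], [5]], index=["p1", "p2"], columns=[sp])
        out = comdist(random_tree, CommunityTable(counts=counts))
        assert out.loc["p1", "p2"] == 0.0

    def test_matches_double_sum_oracle(self, random_tree, random_pdm):
        rng = np.random.default_rng(5)
        otus = list(random_pdm.index[:6])
        counts = pd.DataFrame(
            rng.integers(0, 6, size=(3, 6)), index=["p1", "p2", "p3"], columns=otus
        )
        counts.iloc[0, 0] = 1  # ensure no empty plot
        table = CommunityTable(counts=counts)
        out = comdist(random_tree, table)
        f = counts.to_numpy(dtype=float)
        f = f / f.sum(axis=1, keepdims=True)
        d = random_pdm.loc[otus, otus].to_numpy()
        expected = 0.0
        for i in range(6):
            for j in range(6):
                expected += f[0, i] * f[1, j] * d[i, j]
        assert out.loc["p1", "p2"] == pytest.approx(expected)

    def test_disjoint_clades_exceed_within_plot_rao(self):
        tree = read_newick("((a1:0.1,a2:0.1):1,(b1:0.1,b2:0.1):1);")
        counts = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]],
            index=["pa", "pb"], columns=["a1", "a2", "b1", "b2"],
        )
        table = CommunityTable(counts=counts)
        out = comdist(tree, table)
        pdm = patristic_matrix(tree)
        rao_a = 0.25 * 2 * pdm.loc["a1", "a2"] / 2  # within-plot quadratic entropy
        assert out.loc["pa", "pb"] >= rao_a

    def test_phenogram_tips_are_plots(self, random_tree, random_pdm):
        rng = np.random.default_rng(6)
        otus = list(random_pdm.index[:5])
        counts = pd.DataFrame(
            rng.integers(1, 6, size=(4, 5)),
            index=["p1", "p2", "p3", "p4"], columns=otus,
        )
        out = comdist(random_tree, CommunityTable(counts=counts))
        phen = comdist_phenogram(out)
        assert {l.taxon.label for l in phen.leaf_node_iter()} == {
            "p1", "p2", "p3", "p4",
        }


class TestDiversityTable:
    def _setup(self, random_tree, random_pdm):
        rng = np.random.default_rng(8)
        otus = list(random_pdm.index)
        counts = pd.DataFrame(
            rng.integers(0, 8, size=(4, len(otus))),
            index=["p1", "p2", "p3", "p4"], columns=otus,
        )
        counts.iloc[:, 0] = np.maximum(counts.iloc[:, 0], 2)
        return CommunityTable(counts=counts)

    def test_reference_equal_to_community_tree_gives_identical_columns(
        self, random_tree, random_pdm
    ):
        table = self._setup(random_tree, random_pdm)
        df, corrs = diversity_table(
            table, random_tree, random_tree, n_iter=199, seed=5
        )
        for k in ("PD", "MPD", "MNTD"):
            assert np.allclose(df[k], df[f"{k}_ref"], equal_nan=True)
            assert corrs[k][0] == pytest.approx(1.0)
        assert df["nOTU"].tolist() == (table.counts > 0).sum(axis=1).tolist()

    def test_notu_and_simpson_columns(self, random_tree, random_pdm):
        table = self._setup(random_tree, random_pdm)
        df, _ = diversity_table(table, random_tree, n_iter=199, seed=5)
        row = table.counts.loc["p1"].to_numpy()
        assert df.loc["p1", "Div"] == pytest.approx(simpson_diversity(row))

    def test_seeded_determinism(self, random_tree, random_pdm):
        table = self._setup(random_tree, random_pdm)
        df1, _ = diversity_table(table, random_tree, n_iter=199, seed=9)
        df2, _ = diversity_table(table, random_tree, n_iter=199, seed=9)
        pd.testing.assert_frame_equal(df1, df2)
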
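import numpy as np
import pandas as pd
import pytest

from metabotrend.exceptions import DataError, ValidationError
from metabotrend.network import (
    TOMModuleClustering,
    cluster_tree,
    concatenate_trends,
    dynamic_cut,
    kme_prune_and_merge,
    linkage_to_newick,
    module_eigengene,
    signed_adjacency,
    tom_similarity,
)
from metabotrend.simulate import generate_trend_templates


def tom_bruteforce(a):
    """Triple-loop oracle for the topological overlap matrix."""
    n = len(a)
    k = a.sum(axis=1) - np.diag(a)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (s + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def template_profiles(n_per=30, sd=0.2, seed=42):
    rng = np.random.default_rng(seed)
    curves = generate_trend_templates(7, 8).reshape(7, -1)
    rows, labels = [], []
    for t in range(7):
        for _ in range(n_per):
            rows.append(curves[t] + rng.normal(0, sd, curves.shape[1]))
            labels.append(t)
    idx = [f"M{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), np.array(labels)


class TestConcatenateTrends:
    @pytest.fixture()
    def curves(self):
        rows = []
        for comp in ["a", "b", "c"]:
            for v in ["V1", "V2", "V3"]:
                for w in range(1, 9):
                    val = 0.0 if comp == "c" else np.sin(w / 3) * (1 if comp == "a" else 1.0)
                    rows.append((comp, v, w, val))
        return pd.DataFrame(rows, columns=["compound_id", "variety", "week", "logfc"])

    def test_three_varieties_eight_weeks_gives_24_columns(self, curves):
        wide = concatenate_trends(curves, ["a", "b"])
        assert wide.shape == (2, 24)

    def test_identical_curves_identical_rows(self, curves):
        wide = concatenate_trends(curves, ["a", "b"])
        assert np.allclose(wide.loc["a"], wide.loc["b"])

    def test_empty_selection_rejected(self, curves):
        with pytest.raises(DataError, match="empty|nothing"):
            concatenate_trends(curves, [])

    def test_missing_curve_named(self, curves):
        with pytest.raises(DataError, match="zzz"):
            concatenate_trends(curves, ["a", "zzz"])


class TestSignedAdjacency:
    def test_perfect_correlation_endpoints(self):
        x = np.linspace(0, 1, 10)
        trends = np.vstack([x, 2 * x + 1, -x])
        a = signed_adjacency(trends, beta=12)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_half_correlation_value(self):
        # cor = 0.5 -> ((1+0.5)/2)^12 = 0.75^12
        rng = np.random.default_rng(1)
        z1, z2 = rng.normal(size=20000), rng.normal(size=20000)
        x = z1
        y = 0.5 * z1 + np.sqrt(0.75) * z2
        a = signed_adjacency(np.vstack([x, y]), beta=12)
        assert a[0, 1] == pytest.approx(0.75**12, rel=0.15)
        # and the exact arithmetic on a constructed correlation
        assert ((1 + 0.5) / 2) ** 12 == pytest.approx(0.03168, abs=5e-5)

    def test_beta_monotonicity(self):
        rng = np.random.default_rng(2)
        trends = rng.normal(size=(10, 24))
        a6 = signed_adjacency(trends, beta=6)
        a12 = signed_adjacency(trends, beta=12)
        off = ~np.eye(10, dtype=bool)
        assert np.all(a12[off] <= a6[off] + 1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError, match="beta"):
            signed_adjacency(np.random.default_rng(0).normal(size=(3, 5)), beta=0)
        with pytest.raises(ValidationError, match="zero-variance"):
            signed_adjacency(np.vstack([np.ones(5), np.arange(5.0)]))


class TestTOM:
    def test_clique_and_empty_graph(self):
        ones = np.ones((3, 3))
        assert np.allclose(tom_similarity(ones), 1.0)
        empty = np.eye(4)
        t = tom_similarity(empty)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(t[off], 0.0)

    def test_matches_bruteforce_oracle_exhaustive_small(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            a = random_adjacency(rng, n)
            assert np.abs(tom_similarity(a) - tom_bruteforce(a)).max() <= 1e-12

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(5)
        a = random_adjacency(rng, 12)
        t = tom_similarity(a)
        assert t.min() >= 0 and t.max() <= 1
        assert np.allclose(t, t.T, atol=1e-12)
        assert np.all(np.diag(t) == 1.0)

    def test_invalid_adjacency_rejected(self):
        bad = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            tom_similarity(bad)
        with pytest.raises(ValidationError, match="\\[0, 1\\]"):
            tom_similarity(np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestClusterTree:
    def test_exact_duplicates_merge_first_at_zero(self):
        d = np.array(
            [
                [0.0, 0.0, 0.9, 0.8],
                [0.0, 0.0, 0.9, 0.8],
                [0.9, 0.9, 0.0, 0.7],
                [0.8, 0.8, 0.7, 0.0],
            ]
        )
        Z = cluster_tree(d)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_average_linkage_heights_monotone(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.normal(size=(20, 6))
            d = 1 - np.corrcoef(x)
            Z = cluster_tree(d)
            assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_two_block_fixture_splits_at_top(self):
        n = 10
        d = np.full((2 * n, 2 * n), 0.9)
        d[:n, :n] = 0.05
        d[n:, n:] = 0.05
        np.fill_diagonal(d, 0.0)
        Z = cluster_tree(d)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(labels[:n])) == 1 and len(set(labels[n:])) == 1
        assert labels[0] != labels[-1]

    def test_single_item_rejected(self):
        with pytest.raises(ValidationError):
            cluster_tree(np.zeros((1, 1)))


def block_dissimilarity(sizes, within, between):
    n = sum(sizes)
    d = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        d[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


class TestDynamicCut:
    def test_two_tight_blocks_of_15(self):
        d = block_dissimilarity([15, 15], within=0.02, between=0.95)
        labels = dynamic_cut(cluster_tree(d), d, min_module_size=10, deep_split=2)
        assert set(labels) == {1, 2}
        assert (labels[:15] == labels[0]).all() and (labels[15:] == labels[15]).all()

    def test_undersized_block_unassigned(self):
        d = block_dissimilarity([15, 8], within=0.02, between=0.95)
        labels = dynamic_cut(cluster_tree(d), d, min_module_size=10, deep_split=2)
        assert (labels[15:] == 0).all()
        assert (labels[:15] == 1).all()

    def test_module_count_nondecreasing_in_deep_split(self):
        # nested fixture: two super-blocks of two sub-blocks each; the
        # sub-block separation (0.5) sits just above the within-sub heights
        # (0.32), so only the more aggressive cuts resolve the sub-blocks
        d = block_dissimilarity([12, 12, 12, 12], within=0.32, between=0.95)
        d[:12, 12:24] = d[12:24, :12] = 0.5
        d[24:36, 36:] = d[36:, 24:36] = 0.5
        Z = cluster_tree(d)
        counts = [len(set(dynamic_cut(Z, d, 10, ds)) - {0}) for ds in range(5)]
        assert counts == sorted(counts)
        assert counts[0] == 2 and counts[-1] == 4

    def test_min_module_size_above_n_warns_all_unassigned(self):
        d = block_dissimilarity([6], within=0.1, between=0.5)
        with pytest.warns(UserWarning):
            labels = dynamic_cut(cluster_tree(d), d, min_module_size=10, deep_split=2)
        assert (labels == 0).all()


class TestModuleEigengene:
    def test_identical_profiles_explained_fully(self):
        prof = np.tile(np.sin(np.linspace(0, 3, 12)), (5, 1))
        eig, expl = module_eigengene(prof, range(5))
        assert expl == pytest.approx(1.0)
        z = (prof[0] - prof[0].mean()) / prof[0].std()
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)

    def test_sign_alignment_flips_with_members(self):
        rng = np.random.default_rng(3)
        prof = rng.normal(size=(6, 10)) + np.sin(np.linspace(0, 3, 10))
        eig, _ = module_eigengene(prof, range(6))
        eig_neg, _ = module_eigengene(-prof, range(6))
        assert np.allclose(eig_neg, -eig, atol=1e-10)

    def test_explained_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        prof = rng.normal(size=(8, 15))
        _, expl = module_eigengene(prof, range(8))
        Xs = (prof - prof.mean(1, keepdims=True)) / prof.std(1, keepdims=True)
        w = np.linalg.eigvalsh(Xs @ Xs.T)
        assert expl == pytest.approx(w[-1] / w.sum(), abs=1e-10)


class TestKmePruneAndMerge:
    def test_member_equal_to_eigengene_retained(self):
        prof, labels = template_profiles(n_per=12, sd=0.05)
        prov = np.repeat(np.arange(1, 8), 12)
        out = kme_prune_and_merge(prof, prov, min_module_size=10)
        assert (out.kme.dropna() >= 0.5).all()
        assert (out.labels != "unassigned").sum() >= 80

    def test_identical_eigengene_modules_merged(self):
        prof, _ = template_profiles(n_per=24, sd=0.05)
        # split each true template into two provisional halves: every pair
        # has near-identical eigengenes and must merge back
        prov = np.repeat(np.arange(1, 15), 12)
        out = kme_prune_and_merge(prof, prov, min_module_size=10)
        labels = out.labels.to_numpy()
        n_modules = len(set(labels) - {"unassigned"})
        assert n_modules == 7

    def test_template_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        prof, truth = template_profiles(n_per=30, sd=0.2)
        clu = TOMModuleClustering().fit(prof)
        ari = adjusted_rand_score(truth, clu.labels_)
        assert ari >= 0.8


class TestEndToEndProperties:
    def test_permutation_invariance(self):
        prof, truth = template_profiles(n_per=15, sd=0.1, seed=9)
        clu = TOMModuleClustering().fit(prof)
        rng = np.random.default_rng(10)
        perm = rng.permutation(len(prof))
        clu_p = TOMModuleClustering().fit(prof.iloc[perm])
        from sklearn.metrics import adjusted_rand_score

        labels_back = pd.Series(clu_p.labels_, index=prof.index[perm]).loc[prof.index]
        assert adjusted_rand_score(clu.labels_, labels_back) == pytest.approx(1.0)

    def test_newick_export_parses(self):
        prof, _ = template_profiles(n_per=5, sd=0.1)
        clu = TOMModuleClustering(min_module_size=3).fit(prof)
        nwk = linkage_to_newick(clu.linkage_, prof.index)
        assert nwk.endswith(";") and nwk.count("(") == len(prof) - 1
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert tree.count_terminals() == len(prof)
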
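"""Correlation graphs, threshold scanning, Markov clustering, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexatlas import (
    ExpressionMatrix,
    build_graph,
    correlate,
    mcl,
    profiles,
    threshold_scan,
)
from coexatlas.network import CorrelationGraph, PRESETS


def matrix_from_array(arr, gene_prefix="g"):
    values = pd.DataFrame(arr, index=[f"{gene_prefix}{i}" for i in range(arr.shape[0])],
                          columns=[f"s{j}" for j in range(arr.shape[1])])
    return ExpressionMatrix(values)


class TestCorrelate:
    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        m = matrix_from_array(rng.exponential(10, (20, 8)))
        corr = correlate(m, axis="gene")
        assert np.allclose(np.diag(corr.r), 1.0)
        assert np.allclose(corr.r, corr.r.T, atol=1e-12)

    def test_perfect_anticorrelation(self):
        m = matrix_from_array(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        corr = correlate(m, axis="gene")
        assert corr.r[0, 1] == pytest.approx(-1.0)

    def test_known_value(self):
        m = matrix_from_array(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]))
        corr = correlate(m, axis="gene")
        assert corr.r[0, 1] == pytest.approx(9 / (2 * np.sqrt(21)), abs=1e-10)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(1)
        data = rng.exponential(5, (60, 12))
        corr = correlate(matrix_from_array(data), axis="gene")
        for _ in range(300):
            i, j = rng.integers(60, size=2)
            expected = stats.pearsonr(data[i], data[j]).statistic
            assert corr.r[i, j] == pytest.approx(expected, abs=1e-10)

    def test_sample_axis_transposes(self):
        rng = np.random.default_rng(2)
        m = matrix_from_array(rng.exponential(10, (30, 5)))
        corr = correlate(m, axis="sample")
        assert corr.ids == m.sample_ids
        assert corr.r.shape == (5, 5)

    def test_zero_variance_entity_excluded(self):
        arr = np.vstack([np.full(6, 3.0), np.random.default_rng(3).random((4, 6))])
        corr = correlate(matrix_from_array(arr), axis="gene")
        assert "g0" not in corr.ids and len(corr.ids) == 4

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="3 observations"):
            correlate(matrix_from_array(np.ones((4, 2))), axis="gene")

    def test_log_transform_flag_changes_result(self):
        rng = np.random.default_rng(4)
        m = matrix_from_array(rng.exponential(100, (10, 8)))
        raw = correlate(m, axis="gene").r
        logged = correlate(m, axis="gene", log_transform=True).r
        assert not np.allclose(raw, logged)


class TestBuildGraph:
    def corr3(self):
        from coexatlas.network import CorrelationMatrix
        r = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.2], [0.5, 0.2, 1.0]])
        return CorrelationMatrix(ids=["a", "b", "c"], r=r, axis="gene")

    def test_threshold_inclusive(self):
        g = build_graph(self.corr3(), 0.38)
        assert (g.n_nodes, g.n_edges) == (3, 2)
        g = build_graph(self.corr3(), 0.5)
        assert (g.n_nodes, g.n_edges) == (3, 2)  # r=0.5 edge kept at t=0.5

    def test_isolated_nodes_dropped(self):
        g = build_graph(self.corr3(), 0.85)
        assert g.nodes == ["a", "b"] and g.n_edges == 1
        g = build_graph(self.corr3(), 0.95)
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        data = rng.exponential(10, (40, 10))
        corr = correlate(matrix_from_array(data), axis="gene")
        for t in (0.2, 0.5, 0.8):
            g = build_graph(corr, t)
            n = len(corr.ids)
            expected_edges = sum(
                1 for i in range(n) for j in range(i + 1, n)
                if corr.r[i, j] >= t)
            expected_nodes = len({x for i in range(n) for j in range(i + 1, n)
                                  if corr.r[i, j] >= t for x in (i, j)})
            assert (g.n_nodes, g.n_edges) == (expected_nodes, expected_edges)

    def test_invalid_threshold(self):
        for t in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                build_graph(self.corr3(), t)


def test_threshold_scan_monotone():
    rng = np.random.default_rng(6)
    corr = correlate(matrix_from_array(rng.exponential(10, (50, 12))), axis="gene")
    scan = threshold_scan(corr, [0.3, 0.5, 0.7, 0.9])
    assert (scan["edges"].diff().dropna() <= 0).all()
    assert (scan["nodes"].diff().dropna() <= 0).all()
    g = build_graph(corr, 0.5)
    row = scan.set_index("r").loc[0.5]
    assert (row["nodes"], row["edges"]) == (g.n_nodes, g.n_edges)


def clique_graph(k, size, weight=1.0):
    nodes, edges = [], []
    for c in range(k):
        members = [f"c{c}_n{i}" for i in range(size)]
        nodes += members
        edges += [(members[i], members[j], weight)
                  for i in range(size) for j in range(i + 1, size)]
    return CorrelationGraph(threshold=0.5, nodes=nodes, edges=edges)


class TestMcl:
    def test_two_disjoint_triangles(self):
        cs = mcl(clique_graph(2, 3), inflation=2.2)
        assert sorted(sorted(c) for c in cs.clusters) == [
            ["c0_n0", "c0_n1", "c0_n2"], ["c1_n0", "c1_n1", "c1_n2"]]

    @pytest.mark.parametrize("inflation", [1.2, 1.7, 2.2, 3.5, 5.0])
    def test_k_cliques_give_k_clusters(self, inflation):
        cs = mcl(clique_graph(4, 5), inflation=inflation)
        assert len(cs.clusters) == 4
        assert all(len(c) == 5 for c in cs.clusters)

    def test_empty_graph(self):
        g = CorrelationGraph(threshold=0.5, nodes=[], edges=[])
        assert mcl(g, 2.2).clusters == []

    def test_invalid_inflation(self):
        with pytest.raises(ValueError):
            mcl(clique_graph(1, 3), inflation=1.0)

    def test_column_stochasticity_enforced(self):
        """Columns sum to one after every inflation step (validated in-loop)."""
        rng = np.random.default_rng(7)
        nodes = [f"n{i}" for i in range(30)]
        edges = [(nodes[i], nodes[j], float(rng.uniform(0.4, 1.0)))
                 for i in range(30) for j in range(i + 1, 30)
                 if rng.random() < 0.2]
        touched = {x for e in edges for x in e[:2]}
        g = CorrelationGraph(0.4, [n for n in nodes if n in touched], edges)
        cs = mcl(g, 2.0, validate=True)
        assert cs.clusters  # ran to completion with the invariant holding

    def test_clusters_disjoint_and_size_ordered(self):
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(40)]
        edges = [(nodes[i], nodes[j], float(rng.uniform(0.5, 1.0)))
                 for i in range(40) for j in range(i + 1, 40)
                 if rng.random() < 0.15]
        touched = {x for e in edges for x in e[:2]}
        cs = mcl(CorrelationGraph(0.5, sorted(touched), edges), 2.2)
        sizes = [len(c) for c in cs.clusters]
        assert sizes == sorted(sizes, reverse=True)
        flat = [m for c in cs.clusters for m in c]
        assert len(flat) == len(set(flat))
        assert set(flat) <= touched

    def test_planted_module_recovery(self, recovery_truth):
        """Modules planted by the generator are recovered at r>=0.7, I=2.2."""
        from sklearn.metrics import adjusted_rand_score
        truth = recovery_truth
        corr = correlate(truth.true_tpm, axis="gene")
        cs = mcl(build_graph(corr, 0.7), inflation=2.2)
        labels = cs.labels()
        module = truth.module_membership
        common = [g for g in module if g in labels]
        assert len(common) == len(module)  # every module gene enters the graph
        ari = adjusted_rand_score([module[g] for g in common],
                                  [labels[g] for g in common])
        assert ari >= 0.9


class TestProfiles:
    def test_singleton_profile_is_gene_row(self):
        values = pd.DataFrame({"s1": [1.0, 5.0], "s2": [2.0, 6.0]},
                              index=["g0", "g1"])
        m = ExpressionMatrix(values)
        from coexatlas.network import ClusterSet
        cs = ClusterSet(clusters=[["g1"]], inflation=2.2)
        prof = profiles(cs, m, min_size=1)
        assert list(prof[0].mean_tpm_per_sample) == [5.0, 6.0]

    def test_small_clusters_omitted(self):
        values = pd.DataFrame(np.ones((20, 3)),
                              index=[f"g{i}" for i in range(20)],
                              columns=["s1", "s2", "s3"])
        from coexatlas.network import ClusterSet
        cs = ClusterSet(clusters=[[f"g{i}" for i in range(12)],
                                  [f"g{i}" for i in range(12, 20)]],
                        inflation=2.2)
        prof = profiles(cs, ExpressionMatrix(values), min_size=10)
        assert [p.cluster_number for p in prof] == [1]
        assert prof[0].size == 12

    def test_module_cluster_peaks_in_its_tissue(self, recovery_truth):
        """A planted module's top-ranked sample comes from its host tissue."""
        truth = recovery_truth
        corr = correlate(truth.true_tpm, axis="gene")
        cs = mcl(build_graph(corr, 0.7), inflation=2.2)
        prof = profiles(cs, truth.true_tpm, min_size=10)
        labels = cs.labels()
        module_of_cluster = {}
        for gene, mod in truth.module_membership.items():
            if gene in labels:
                module_of_cluster.setdefault(labels[gene], set()).add(mod)
        matrix = truth.true_tpm
        checked = 0
        for p in prof:
            mods = module_of_cluster.get(p.cluster_number, set())
            if len(mods) == 1:
                host = next(iter(mods))
                top_tissue = matrix.samples.loc[p.top_samples[0], "tissue"]
                assert top_tissue == host
                checked += 1
        assert checked == 5


def test_preset_pipeline_runs_each_configuration(recovery_truth):
    """Each named preset drives filter -> graph -> MCL without error."""
    from coexatlas import expression_filter
    m = recovery_truth.true_tpm
    for preset in PRESETS.values():
        filtered = expression_filter(m, min_tpm=preset.min_tpm)
        corr = correlate(filtered, axis="gene")
        cs = mcl(build_graph(corr, preset.r_threshold), preset.inflation)
        assert cs.clusters
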
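"""Co-expression clustering and core-network extension."""

import numpy as np
import pytest

from netard.gnce import (ClusterAssignment, CoreGN, coexpression_distance,
                         extend_core_gn, hierarchical_clusters,
                         select_core_clusters)


def block_data(rng, n_samples, block_sizes, rho=0.85, n_noise=0):
    """Genes in the same block share a latent factor (correlation ~ rho)."""
    cols, labels = [], []
    for b, size in enumerate(block_sizes, start=1):
        latent = rng.standard_normal(n_samples)
        noise_sd = np.sqrt(1 / rho ** 2 - 1)
        for _ in range(size):
            cols.append(latent + noise_sd * rng.standard_normal(n_samples))
            labels.append(b)
    for _ in range(n_noise):
        cols.append(rng.standard_normal(n_samples))
        labels.append(0)
    return np.column_stack(cols), np.array(labels)


class TestCoexpressionDistance:
    def test_perfectly_correlated_pair(self):
        t = np.linspace(0, 1, 20)
        x = np.column_stack([t, 2 * t + 1])
        d = coexpression_distance(x)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelation_also_gives_zero_distance(self):
        t = np.linspace(0, 1, 20)
        x = np.column_stack([t, -t])
        assert coexpression_distance(x)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_pair_distance_near_one(self, rng):
        x = rng.standard_normal((1000, 2))
        assert abs(coexpression_distance(x)[0, 1] - 1.0) < 0.08

    def test_constant_gene_named_in_error(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="flat"):
            coexpression_distance(x, gene_ids=["flat", "ok"])


class TestHierarchicalClusters:
    def test_two_separated_blocks_recovered(self, rng):
        x, truth = block_data(rng, 120, [20, 20])
        d = coexpression_distance(x)
        assign = hierarchical_clusters(d, "average", min_cluster_size=5)
        assert assign.n_clusters == 2
        assert np.all(assign.labels > 0)
        # same partition as the construction
        a = assign.labels[truth == 1]
        b = assign.labels[truth == 2]
        assert len(set(a)) == 1 and len(set(b)) == 1 and a[0] != b[0]

    def test_min_size_equal_to_p_gives_single_cluster(self, rng):
        x, _ = block_data(rng, 60, [10, 10])
        d = coexpression_distance(x)
        assign = hierarchical_clusters(d, "complete", min_cluster_size=20)
        assert assign.n_clusters <= 1

    def test_permutation_invariance(self, rng):
        x, _ = block_data(rng, 100, [12, 12], n_noise=3)
        d = coexpression_distance(x)
        assign = hierarchical_clusters(d, "average", min_cluster_size=5)
        perm = rng.permutation(x.shape[1])
        d2 = coexpression_distance(x[:, perm])
        assign2 = hierarchical_clusters(d2, "average", min_cluster_size=5)
        # the same partition up to label names
        for lab in range(1, assign.n_clusters + 1):
            members = set(np.where(assign.labels == lab)[0])
            image = {np.where(perm == m)[0][0] for m in members}
            labs = {assign2.labels[i] for i in image}
            assert len(labs) == 1
        assert assign2.n_clusters == assign.n_clusters

    def test_noise_genes_land_in_noise_cluster(self, rng):
        x, truth = block_data(rng, 150, [15, 15], n_noise=4)
        d = coexpression_distance(x)
        assign = hierarchical_clusters(d, "average", min_cluster_size=6)
        assert assign.n_clusters == 2
        assert np.all(assign.labels[truth == 0] == 0)

    def test_min_size_larger_than_p_rejected(self, rng):
        x, _ = block_data(rng, 30, [5])
        with pytest.raises(ValueError):
            hierarchical_clusters(coexpression_distance(x), "average",
                                  min_cluster_size=10)

    def test_fixed_height_mode(self, rng):
        x, _ = block_data(rng, 120, [20, 20])
        d = coexpression_distance(x)
        assign = hierarchical_clusters(d, "average", min_cluster_size=5,
                                       method="height")
        assert assign.n_clusters == 2


class TestSelectCoreClusters:
    def test_selection_matches_core_membership(self):
        labels = np.array([1, 1, 2, 2, 3, 3, 0])
        genes = [f"g{i}" for i in range(7)]
        core = CoreGN([("g0", "g4")])  # core genes in clusters 1 and 3
        sel = select_core_clusters(ClusterAssignment(labels), core, genes)
        assert [lab for lab, *_ in sel] == [1, 3]
        assert sel[0][2] == ["g0"]

    def test_core_gene_in_noise_not_selected(self):
        labels = np.array([0, 1, 1])
        core = CoreGN([("g0", "gX")])
        sel = select_core_clusters(ClusterAssignment(labels), core,
                                   ["g0", "g1", "g2"])
        assert sel == []


def planted_core_data(rng, n=120, members_per_core=8, n_cores=3, rho=0.8,
                      n_background=15):
    """Each core gene drives a cluster of correlated members; background
    genes are independent."""
    genes, cols, planted = [], [], []
    noise_sd = np.sqrt(1 / rho ** 2 - 1)
    for c in range(n_cores):
        core_expr = rng.standard_normal(n)
        core_name = f"core{c}"
        genes.append(core_name)
        cols.append(core_expr)
        for m in range(members_per_core):
            name = f"c{c}m{m}"
            genes.append(name)
            cols.append(core_expr + noise_sd * rng.standard_normal(n))
            planted.append((core_name, name))
    for b in range(n_background):
        genes.append(f"bg{b}")
        cols.append(rng.standard_normal(n))
    x = np.column_stack(cols)
    core_edges = [(f"core{c}", f"core{(c + 1) % n_cores}")
                  for c in range(n_cores)]
    return x, genes, CoreGN(core_edges), planted


class TestExtendCoreGN:
    def test_planted_members_attach_to_their_core_gene(self, rng):
        x, genes, core, planted = planted_core_data(rng)
        res = extend_core_gn(x, genes, core, linkage_method="average",
                             min_cluster_size=5, c_shrink=0.0)
        inferred = {(a, b) for a, b, o in res.extended_edges}
        hits = sum(1 for a, b in planted
                   if (a, b) in inferred or (b, a) in inferred)
        assert hits / len(planted) >= 0.8

    def test_core_edges_always_preserved(self, rng):
        x, genes, core, _ = planted_core_data(rng)
        res = extend_core_gn(x, genes, core, linkage_method="average",
                             min_cluster_size=5, c_shrink=0.0)
        out_core = {(a, b) for a, b, o in res.extended_edges if o == "core"}
        assert set(core.edges) <= out_core

    def test_zero_shrinkage_output_is_bipartite_restricted(self, rng):
        x, genes, core, _ = planted_core_data(rng)
        res = extend_core_gn(x, genes, core, linkage_method="average",
                             min_cluster_size=5, c_shrink=0.0)
        for a, b, origin in res.extended_edges:
            if origin == "inferred":
                assert a in core.genes or b in core.genes

    def test_empty_core_gives_empty_extension(self, rng):
        x, genes, _, _ = planted_core_data(rng)
        res = extend_core_gn(x, genes, CoreGN([]), linkage_method="average",
                             min_cluster_size=5)
        assert res.extended_edges == []
        assert res.selected_clusters == []
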
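"""Split networks: NeighborNet consistency, splits graph, degree comparison."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from introphy.network import (
    NetworkError,
    build_splits_graph,
    circular_ordering,
    degree_distribution,
    genetic_distances,
    group_degrees,
    neighbor_net,
    poisson_glm_compare,
    write_nexus_splits,
)
from introphy.trees import Node, Tree

from conftest import make_alignment, tree_metric

BOX = pd.DataFrame(
    [[0, 1, 1, 2], [1, 0, 2, 1], [1, 2, 0, 1], [2, 1, 1, 0]],
    index=list("ABCD"), columns=list("ABCD"), dtype=float,
)


def random_binary_tree(n: int, rng: np.random.Generator) -> Tree:
    nodes = [Node(name=f"t{i}") for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        for k in (i, j):
            nodes[k].length = float(rng.uniform(0.5, 2.0))
        p = Node()
        p.add_child(nodes[i])
        p.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [p]
    return Tree(nodes[0])


class TestNeighborNet:
    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_tree_metric_consistency(self, n, seed):
        # on additive (tree) distances the recovered splits are exactly the
        # tree's splits with the generating branch lengths
        tree = random_binary_tree(n, np.random.default_rng(seed))
        dist = tree_metric(tree)
        system = neighbor_net(dist)
        fitted = pd.DataFrame(0.0, index=dist.index, columns=dist.columns)
        for side, w in system.splits:
            for a in dist.index:
                for b in dist.columns:
                    if (a in side) != (b in side):
                        fitted.loc[a, b] += w
        assert np.abs(fitted.to_numpy() - dist.to_numpy()).max() < 1e-6
        # non-trivial splits = the tree's internal bipartitions
        all_taxa = frozenset(dist.index)
        ref = min(dist.index)
        canon = lambda s: frozenset(s) if ref not in s else all_taxa - s
        nontrivial = {
            canon(s) for s, w in system.splits if 1 < len(s) < n - 1
        }
        true = {canon(b) for b in tree.bipartitions()}
        assert nontrivial == true

    def test_box_metric_two_incompatible_splits(self):
        system = neighbor_net(BOX)
        sides = {frozenset(s) for s, w in system.splits}
        weights = [w for _, w in system.splits]
        assert len(system.splits) == 2
        assert all(w == pytest.approx(1.0, abs=1e-9) for w in weights)
        canon = {
            frozenset(s) if "A" in s else frozenset("ABCD") - s for s in sides
        }
        assert canon == {frozenset("AB"), frozenset("AC")}

    def test_three_taxa_three_point_weights(self):
        m = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        system = neighbor_net(m)
        assert system.weight_of({"A"}) == pytest.approx(1.0, abs=1e-9)
        assert system.weight_of({"B"}) == pytest.approx(2.0, abs=1e-9)
        assert system.weight_of({"C"}) == pytest.approx(3.0, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        m = BOX.copy()
        m.iloc[0, 1] = 5.0
        with pytest.raises(NetworkError, match="symmetric"):
            circular_ordering(m)


class TestSplitsGraph:
    def test_tree_compatible_system_is_a_tree(self):
        tree = random_binary_tree(4, np.random.default_rng(5))
        system = neighbor_net(tree_metric(tree))
        graph, taxon_node = build_splits_graph(system)
        assert nx.is_tree(graph)
        degs = sorted(d for _, d in graph.degree())
        assert degs == [1, 1, 1, 1, 3, 3]
        assert len(set(taxon_node.values())) == 4

    def test_box_system_is_four_cycle(self):
        system = neighbor_net(BOX)
        graph, taxon_node = build_splits_graph(system)
        assert graph.number_of_nodes() == 4
        assert sorted(d for _, d in graph.degree()) == [2, 2, 2, 2]
        assert nx.cycle_basis(graph)

    def test_empty_system_has_no_edges(self):
        from introphy.network import SplitSystem

        system = SplitSystem(ordering=list("ABC"), splits=[])
        graph, taxon_node = build_splits_graph(system)
        assert graph.number_of_edges() == 0

    def test_handshake_lemma(self):
        tree = random_binary_tree(7, np.random.default_rng(9))
        system = neighbor_net(tree_metric(tree))
        graph, _ = build_splits_graph(system)
        assert sum(d for _, d in graph.degree()) == 2 * graph.number_of_edges()

    def test_removing_split_class_disconnects_its_sides(self):
        system = neighbor_net(BOX)
        graph, taxon_node = build_splits_graph(system)
        for k, (side, w) in enumerate(system.splits):
            pruned = nx.Graph(
                (u, v) for u, v, d in graph.edges(data=True) if d["split"] != k
            )
            pruned.add_nodes_from(graph.nodes)
            comps = list(nx.connected_components(pruned))
            assert len(comps) == 2
            groups = {
                frozenset(t for t, nd in taxon_node.items() if nd in comp)
                for comp in comps
            }
            assert groups == {side, frozenset("ABCD") - side}

    def test_parallel_edge_classes_match_split_multiplicity(self):
        # every split appears once per crossing + 1
        system = neighbor_net(BOX)
        graph, _ = build_splits_graph(system)
        counts = {}
        for _, _, d in graph.edges(data=True):
            counts[d["split"]] = counts.get(d["split"], 0) + 1
        assert counts == {0: 2, 1: 2}  # two crossing splits: 2 copies each


class TestDegreeDistribution:
    def test_path_graph_degrees(self):
        g = nx.path_graph(3)
        dist = degree_distribution(g)
        assert dist.to_dict() == {1: 2, 2: 1}


class TestPoissonComparison:
    def test_intercept_only_closed_form(self):
        import statsmodels.api as sm

        y = np.array([1.0, 2.0, 3.0])
        fit = sm.GLM(y, np.ones((3, 1)), family=sm.families.Poisson()).fit()
        assert fit.params[0] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_two_group_closed_form(self):
        res = poisson_glm_compare([1, 2, 2], [2, 2, 2])
        assert res.coef == pytest.approx(np.log(2.0 / (5.0 / 3.0)), abs=1e-8)

    def test_identical_groups_zero_coefficient(self):
        res = poisson_glm_compare([1, 2, 3], [1, 2, 3])
        assert res.coef == pytest.approx(0.0, abs=1e-10)
        assert res.z == pytest.approx(0.0, abs=1e-8)

    def test_zero_degree_group_refused(self):
        with pytest.raises(NetworkError, match="zero"):
            poisson_glm_compare([0, 0], [1, 2])


class TestGroupDegrees:
    def test_two_clade_network_assignment(self):
        # two clades joined by one long edge: the inter-group split exists
        rng = np.random.default_rng(11)
        tree = Tree.from_newick(
            "(((a1:1,a2:1):1,a3:2):5,((b1:1,b2:1):1,b3:2):5);"
        )
        dist = tree_metric(tree)
        system = neighbor_net(dist)
        graph, taxon_node = build_splits_graph(system)
        gmap = {t: ("A" if t.startswith("a") else "B") for t in dist.index}
        degs = group_degrees(graph, taxon_node, gmap, system)
        assert set(degs) == {"A", "B"}
        # each side of a 3-taxon clade subtree: 3 leaves + 2 internals
        assert len(degs["A"]) == len(degs["B"]) == 5
        assert sorted(degs["A"]) == sorted(degs["B"])


class TestDistancesAndIO:
    def test_identical_taxa_distance_zero_and_symmetry(self):
        aln = make_alignment({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACCTACGA"})
        d = genetic_distances(aln, model="JC")
        assert d.loc["a", "b"] == 0.0
        assert np.allclose(d.to_numpy(), d.to_numpy().T)

    def test_simulated_distance_tracks_divergence(self):
        from introphy.simulate import LocusLayout, assemble_dataset
        from introphy.calibration import study_model

        model = study_model()
        ds = assemble_dataset(model, LocusLayout(60, 1000), seed=17)
        d = genetic_distances(ds.alignment, model="JC")
        # P1 vs O1 diverged 9.5 Mya = 1.9e6 generations; expected distance
        # ~ 2 mu t + 2 * (coalescent depth) * mu ~ 0.038 + 4 Ne mu
        t_gen = 1.9e6
        expected = 2 * model.mutation_rate * t_gen + 4 * 1e5 * model.mutation_rate
        assert d.loc["P1", "O1"] == pytest.approx(expected, rel=0.15)

    def test_phylip_square_round_trip(self, tmp_path):
        from introphy.network import read_distance_matrix, write_phylip_distances

        path = tmp_path / "d.phy"
        write_phylip_distances(BOX, path)
        back = read_distance_matrix(path)
        assert list(back.index) == list(BOX.index)
        assert np.allclose(back.to_numpy(), BOX.to_numpy())

    def test_nexus_splits_block_round_trippable_text(self, tmp_path):
        system = neighbor_net(BOX)
        path = tmp_path / "s.nex"
        write_nexus_splits(system, path)
        text = path.read_text()
        assert text.startswith("#NEXUS")
        assert "BEGIN Splits;" in text
        assert "nsplits=2" in text
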
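"""NJ reconstruction, bootstrap support and monophyly scoring."""

import math

import networkx as nx
import numpy as np
import pytest

from barcodegap.distance import DistanceMatrix
from barcodegap.simulate import SimulationConfig, simulate
from barcodegap.tree import (
    bipartitions,
    bootstrap,
    monophyly,
    neighbor_joining,
    newick_string,
    read_newick,
    write_newick,
)

from conftest import make_matrix, random_additive_tree, spanning_subtree_is_exclusive


def dm_from(values, ids, species=None):
    species = species or ids
    return DistanceMatrix(ids=ids, species=species, values=np.array(values, dtype=float))


class TestNeighborJoining:
    def test_four_taxon_additive_split_and_lengths(self):
        # tip branch lengths A:1 B:2 C:3 D:4 joined by a central edge of 1
        ids = ["A", "B", "C", "D"]
        d = [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ]
        tree = neighbor_joining(dm_from(d, ids))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        tt = tree.tip_tip_distances()
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert tt[a, b] == pytest.approx(d[i][j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        d = [[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]]
        tree = neighbor_joining(dm_from(d, ids))
        tt = tree.tip_tip_distances()
        assert tt["A", "B"] == pytest.approx(0.3)
        assert tt["A", "C"] == pytest.approx(0.4)
        assert tt["B", "C"] == pytest.approx(0.5)

    def test_recovers_random_additive_topologies(self):
        """NJ is exact on additive matrices: 50 random 5-8 taxon trees."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(5, 9))
            labels, d, expected_splits = random_additive_tree(n, rng)
            tree = neighbor_joining(dm_from(d, labels))
            assert bipartitions(tree) == expected_splits

    def test_two_clean_clusters_form_an_edge(self):
        ids = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        d = np.full((6, 6), 0.2)
        d[:3, :3] = 0.01
        d[3:, 3:] = 0.01
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(dm_from(d, ids))
        assert frozenset({"b0", "b1", "b2"}) in bipartitions(tree)

    def test_undefined_entries_rejected(self):
        d = [[0, np.nan, 0.1], [np.nan, 0, 0.1], [0.1, 0.1, 0]]
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(dm_from(d, ["a", "b", "c"]))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm_from([[0, 0.1], [0.1, 0]], ["a", "b"]))


class TestNewickIO:
    def test_read_four_tip_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((a,b),(c,d));\n")
        tree = read_newick(p)
        assert {t.name for t in tree.tips()} == {"a", "b", "c", "d"}

    def test_round_trip_preserves_bipartitions(self, tmp_path):
        rng = np.random.default_rng(19)
        labels, d, _ = random_additive_tree(7, rng)
        tree = neighbor_joining(dm_from(d, labels))
        path = tmp_path / "nj.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert bipartitions(back) == bipartitions(tree)

    def test_duplicate_tips_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((a,a),(c,d));\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_newick(p)

    def test_unresolvable_tip_labels_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((a,b),(c,d));\n")
        with pytest.raises(ValueError, match="not resolvable"):
            read_newick(p, expected_ids={"a", "b", "c"})

    def test_supports_written_as_internal_labels(self, tmp_path):
        m, _ = simulate(SimulationConfig(n_species=4, individuals_per_species=3,
                                         length=400, seed=3))
        tree, _ = bootstrap(m, n_reps=20, seed=5)
        path = tmp_path / "bs.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        sups = [
            getattr(n, "support", None)
            for n in back.traverse(include_self=False)
            if not n.is_tip()
        ]
        assert any(s is not None for s in sups)
        assert all(s is None or 0 <= s <= 100 for s in sups)


class TestBootstrap:
    def test_zero_reps_returns_plain_tree(self):
        m, _ = simulate(SimulationConfig(n_species=3, individuals_per_species=2,
                                         length=200, seed=1))
        tree, info = bootstrap(m, n_reps=0)
        assert info.n_replicates == 0
        assert all(
            getattr(n, "support", None) is None
            for n in tree.traverse(include_self=False)
        )

    def test_identical_seeds_identical_supports(self):
        m, _ = simulate(SimulationConfig(n_species=4, individuals_per_species=3,
                                         length=300, seed=2))

        def run():
            tree, _ = bootstrap(m, n_reps=30, seed=99)
            return sorted(
                n.support
                for n in tree.traverse(include_self=False)
                if getattr(n, "support", None) is not None
            )

        assert run() == run()

    def test_seed_required(self):
        m, _ = simulate(SimulationConfig(n_species=3, individuals_per_species=2,
                                         length=100, seed=4))
        with pytest.raises(ValueError, match="seed"):
            bootstrap(m, n_reps=5)

    def test_clean_clusters_get_full_support(self):
        """Two internally identical, mutually divergent clusters: no column
        resample can break the cluster edge, so its support is 100."""
        rng = np.random.default_rng(7)
        seq_a = "".join(rng.choice(list("ACGT"), size=200))
        # diverge cluster B at ~20% of sites by transversion to be safe
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        seq_b = "".join(
            flip[c] if rng.random() < 0.2 else c for c in seq_a
        )
        rows = [(f"x_a|{i}", "x_a", seq_a) for i in range(5)] + [
            (f"y_b|{i}", "y_b", seq_b) for i in range(5)
        ]
        m = make_matrix(rows)
        tree, info = bootstrap(m, n_reps=50, seed=11)
        cluster = frozenset(f"y_b|{i}" for i in range(5))
        supports = {
            frozenset(t.name for t in n.tips()): getattr(n, "support", None)
            for n in tree.traverse(include_self=False)
            if not n.is_tip()
        }
        # the cluster edge appears on one side or the other
        all_tips = frozenset(r[0] for r in rows)
        found = [
            s
            for side, s in supports.items()
            if side in (cluster, all_tips - cluster) and s is not None
        ]
        assert found and all(s == 100.0 for s in found)
        assert info.n_skipped == 0


class TestMonophyly:
    def _tree(self, newick, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text(newick)
        return read_newick(p)

    def test_both_species_monophyletic(self, tmp_path):
        t = self._tree("((a1:1,a2:1):1,(b1:1,b2:1):1);", tmp_path)
        rep = monophyly(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert rep.per_species == {"A": (2, "yes"), "B": (2, "yes")}
        assert rep.discrimination_rate_individuals == 1.0
        assert rep.discrimination_rate_species == 1.0

    def test_interleaved_species_not_monophyletic(self, tmp_path):
        t = self._tree("((a1:1,b1:1):1,(a2:1,b2:1):1);", tmp_path)
        rep = monophyly(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert rep.per_species["A"] == (2, "no")
        assert rep.per_species["B"] == (2, "no")
        assert rep.discrimination_rate_individuals == 0.0

    def test_unlabelled_tip_errors(self, tmp_path):
        t = self._tree("((a1,a2),(b1,b2));", tmp_path)
        with pytest.raises(ValueError, match="b2"):
            monophyly(t, {"a1": "A", "a2": "A", "b1": "B"})

    def test_singleton_policy_flips_rates(self, tmp_path):
        t = self._tree("((a1:1,a2:1):1,(b1:1,c1:1):1);", tmp_path)
        labels = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        inc = monophyly(t, labels, singleton_policy="discriminated")
        exc = monophyly(t, labels, singleton_policy="not_discriminated")
        assert inc.discrimination_rate_individuals == 1.0
        assert exc.discrimination_rate_individuals == 0.5
        assert inc.n_singletons == 2

    def test_verdicts_invariant_under_rerooting(self, tmp_path):
        rng = np.random.default_rng(43)
        labels_pool = ["A", "B", "C"]
        for _ in range(20):
            labels, d, _ = random_additive_tree(8, rng)
            tree = neighbor_joining(
                DistanceMatrix(ids=labels, species=labels, values=d)
            )
            species = {t: labels_pool[int(rng.integers(0, 3))] for t in labels}
            base = monophyly(tree, species).per_species
            tip = labels[int(rng.integers(0, len(labels)))]
            rerooted = tree.root_at(tree.find(tip).parent)
            assert monophyly(rerooted, species).per_species == base

    def test_agrees_with_spanning_subtree_oracle(self):
        """100 random trees with random species labels: edge-bipartition
        scoring equals the graph-theoretic exclusivity check."""
        rng = np.random.default_rng(47)
        for _ in range(100):
            n = int(rng.integers(5, 9))
            labels, d, _ = random_additive_tree(n, rng)
            tree = neighbor_joining(
                DistanceMatrix(ids=labels, species=labels, values=d)
            )
            species = {t: f"S{int(rng.integers(0, 3))}" for t in labels}
            rep = monophyly(tree, species)

            g = nx.Graph()
            for node in tree.traverse(include_self=True):
                node_id = id(node)
                if node.is_tip():
                    g.add_node(node.name)
                for child in node.children:
                    a = node.name if node.is_tip() else f"n{id(node)}"
                    b = child.name if child.is_tip() else f"n{id(child)}"
                    g.add_edge(a, b)
            all_tips = set(labels)
            for sp, (n_ind, status) in rep.per_species.items():
                tips = {t for t, s in species.items() if s == sp}
                if n_ind == 1:
                    assert status == "singleton"
                    continue
                expected = spanning_subtree_is_exclusive(g, tips, all_tips)
                assert (status == "yes") == expected
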
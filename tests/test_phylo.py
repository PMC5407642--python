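import math
import random

import numpy as np
import pytest

import _oracles
from plantmir.phylo import (
    DistanceMatrix,
    Msa,
    bootstrap_consensus,
    distance_matrix,
    k2p_distance,
    neighbor_joining,
    protein_distance,
)


class TestK2P:
    def test_identical_rows(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_value(self):
        # P = 0.1 (10 transitions), Q = 0.05 (5 transversions) over 100 sites
        row_i = "A" * 100
        row_j = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert k2p_distance(row_i, row_j) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.17018, abs=5e-6)

    def test_saturation_flagged_infinite(self):
        assert k2p_distance("A" * 100, "G" * 50 + "A" * 50) == math.inf

    def test_pairwise_gap_exclusion(self):
        assert k2p_distance("AC-T", "ACG-") == 0.0

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError):
            k2p_distance("--", "AA")

    def test_symmetry(self):
        rng = random.Random(3)
        for _ in range(10):
            a = "".join(rng.choice("ACGT-") for _ in range(60))
            b = "".join(rng.choice("ACGT-") for _ in range(60))
            try:
                assert k2p_distance(a, b) == k2p_distance(b, a)
            except ValueError:
                pass


class TestProteinDistance:
    def test_identical(self):
        assert protein_distance("MKV", "MKV", "p-distance") == 0.0
        assert protein_distance("MKV", "MKV", "poisson") == 0.0

    def test_poisson_correction(self):
        assert protein_distance("A" * 9 + "C", "A" * 10, "poisson") == pytest.approx(
            -math.log(0.9), abs=1e-9
        )
        assert -math.log(0.9) == pytest.approx(0.10536, abs=5e-6)

    def test_total_divergence(self):
        assert protein_distance("AAAA", "CCCC", "p-distance") == 1.0
        assert protein_distance("AAAA", "CCCC", "poisson") == math.inf


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        ids = ["A", "B", "C", "D"]
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(ids, m))
        splits = tree.bipartitions()
        assert set(splits) == {frozenset({"C", "D"})}
        assert splits[frozenset({"C", "D"})] == pytest.approx(1.0)
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        # cross-check topology against the all-topology least-squares oracle
        best_splits, resid, _ = _oracles.ls_best_topology(m)
        assert best_splits == {frozenset({2, 3})}
        assert resid < 1e-9

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["x", "y", "z"], m))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"x": 0.5, "y": 1.5, "z": 2.5})

    def test_deterministic_on_equidistant_matrix(self):
        m = np.ones((4, 4)) - np.eye(4)
        ids = list("ABCD")
        t1 = neighbor_joining(DistanceMatrix(ids, m.copy())).to_newick()
        t2 = neighbor_joining(DistanceMatrix(ids, m.copy())).to_newick()
        assert t1 == t2

    def test_infinite_entry_names_pair(self):
        m = np.array([[0, 1, math.inf], [1, 0, 1], [math.inf, 1, 0]])
        with pytest.raises(ValueError, match="A.*C"):
            neighbor_joining(DistanceMatrix(["A", "B", "C"], m))

    def test_recovers_random_additive_trees(self):
        """NJ returns the generating topology and exact branch lengths;
        the all-topology least-squares oracle confirms the optimum."""
        rng = random.Random(19)
        for trial in range(8):
            n = rng.choice([4, 5, 5, 6, 6, 7])
            names, D, true_splits = _random_additive(rng, n)
            tree = neighbor_joining(DistanceMatrix(names, D))
            got = {
                frozenset(sorted(s)): l for s, l in tree.bipartitions().items()
            }
            assert set(got) == set(true_splits), trial
            for s, l in true_splits.items():
                assert got[s] == pytest.approx(l, abs=1e-9)
            idx_splits, resid, _ = _oracles.ls_best_topology(D)
            name_order = names
            oracle_named = {
                frozenset(name_order[i] for i in s) for s in idx_splits
            }
            assert oracle_named == set(true_splits)
            assert resid < 1e-8


def _random_additive(rng, n):
    """Random additive tree; returns (names, distance matrix, split->length)."""
    names = [chr(65 + i) for i in range(n)]
    nodes = {i: None for i in range(n)}
    # build random topology on node ids; track adjacency with lengths
    import collections

    adj = collections.defaultdict(dict)
    avail = list(range(n))
    next_id = n
    while len(avail) > 3:
        i, j = sorted(rng.sample(avail, 2))
        u = next_id
        next_id += 1
        adj[u][i] = adj[i][u] = rng.randint(1, 9)
        adj[u][j] = adj[j][u] = rng.randint(1, 9)
        avail.remove(i)
        avail.remove(j)
        avail.append(u)
    hub = next_id
    for k in avail:
        adj[hub][k] = adj[k][hub] = rng.randint(1, 9)
    D = np.zeros((n, n))
    for a in range(n):
        dist = {a: 0}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for b in range(n):
            D[a, b] = dist[b]
    splits = {}
    anchor = 0
    edges = {(u, v) for u in adj for v in adj[u] if u < v}
    for u, v in edges:
        side = _reach(adj, u, v)
        leaf_side = {x for x in side if x < n}
        if 1 < len(leaf_side) < n - 1:
            key = (
                leaf_side if anchor not in leaf_side else set(range(n)) - leaf_side
            )
            splits[frozenset(names[i] for i in key)] = adj[u][v]
    return names, D, splits


def _reach(adj, start, block):
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y != block and y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


class TestBootstrapConsensus:
    def test_unanimous_split_is_certain(self):
        """An alignment whose every column supports one split gives 100%."""
        rows = ["AAW", "AAW", "CCW", "CCW"]
        msa = Msa(["a", "b", "c", "d"], [r * 10 for r in rows], alphabet="protein")
        tree = bootstrap_consensus(msa, 100, seed=2, model="p-distance")
        assert tree.support_of(frozenset({"a", "b"})) == 100.0
        assert tree.support_of(frozenset({"c", "d"})) == 100.0

    def test_fixed_seed_reproducible(self):
        rows = ["AAGGCCTTACGT", "AAGGCCTTACGC", "GAGGCCTTTCGT", "GAGGCCTTTCGA"]
        msa = Msa(["a", "b", "c", "d"], rows)
        t1 = bootstrap_consensus(msa, 150, seed=11).to_newick()
        t2 = bootstrap_consensus(msa, 150, seed=11).to_newick()
        assert t1 == t2

    def test_noise_alignment_collapses(self):
        """Random noise yields sub-100 supports and collapsed weak edges."""
        rng = random.Random(6)
        rows = [
            "".join(rng.choice("ADEFGHIKLMNPQRSTVWY") for _ in range(40))
            for _ in range(5)
        ]
        msa = Msa([f"t{i}" for i in range(5)], rows, alphabet="protein")
        tree = bootstrap_consensus(msa, 200, seed=3, model="p-distance")
        supports = []

        def walk(node):
            for c in node.children:
                if c.children:
                    supports.append(c.support)
                walk(c)

        walk(tree.root)
        assert all(s >= 50.0 for s in supports)  # collapse rule applied
        # independent replicate count: rebuild supports by hand
        base = msa.complete_deletion()
        rng2 = np.random.default_rng(3)
        counts = {}
        for _ in range(200):
            rep = base.resample_columns(rng2)
            dm = distance_matrix(rep, deletion="pairwise", model="p-distance")
            t = neighbor_joining(dm)
            for s in t.bipartitions():
                counts[s] = counts.get(s, 0) + 1
        for split, support in [
            (s, c / 2.0) for s, c in counts.items() if c / 2.0 >= 50.0
        ]:
            assert tree.support_of(split) == pytest.approx(support)

    def test_taxon_order_invariance(self):
        rows = ["AAW" * 8, "AAW" * 8, "CCW" * 8, "CCW" * 8]
        ids = ["a", "b", "c", "d"]
        m1 = Msa(ids, rows, alphabet="protein")
        perm = [2, 0, 3, 1]
        m2 = Msa([ids[i] for i in perm], [rows[i] for i in perm], alphabet="protein")
        t1 = bootstrap_consensus(m1, 80, seed=4, model="p-distance")
        t2 = bootstrap_consensus(m2, 80, seed=4, model="p-distance")
        assert t1.support_of(frozenset({"a", "b"})) == t2.support_of(
            frozenset({"a", "b"})
        )


class TestNewick:
    def test_round_trip_through_dendropy(self):
        ids = list("ABCDE")
        rng = random.Random(8)
        m = np.zeros((5, 5))
        for i in range(5):
            for j in range(i + 1, 5):
                m[i, j] = m[j, i] = rng.randint(2, 20)
        tree = neighbor_joining(DistanceMatrix(ids, m))
        newick = tree.to_newick()
        import dendropy

        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(ids)
        total = sum(
            e.length for e in parsed.edges() if e.length is not None
        )
        my_total = _total_length(tree.root)
        assert total == pytest.approx(my_total, abs=1e-6)

    def test_cross_check_against_dendropy_nj(self):
        """Same topology as dendropy's independent NJ implementation."""
        import dendropy

        ids = list("ABCDEF")
        rng = random.Random(21)
        names, D, _ = _random_additive(rng, 6)
        tree = neighbor_joining(DistanceMatrix(names, D))
        csv = "," + ",".join(names) + "\n"
        for i, n in enumerate(names):
            csv += n + "," + ",".join(str(D[i, j]) for j in range(6)) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        taxa = set(names)
        d_splits = set()
        for edge in dtree.preorder_edge_iter():
            if edge.head_node and edge.head_node.child_nodes():
                labels = frozenset(
                    l.taxon.label for l in edge.head_node.leaf_iter()
                )
                if 1 < len(labels) < len(taxa) - 1:
                    anchor = min(taxa)
                    key = labels if anchor not in labels else frozenset(taxa - labels)
                    if 1 < len(key) < len(taxa):
                        d_splits.add(key)
        assert d_splits == set(tree.bipartitions())


def _total_length(node):
    total = node.length or 0.0
    for c in node.children:
        total += _total_length(c)
    return total
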
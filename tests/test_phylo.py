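"""Tests for complete deletion, Poisson distances, NJ and bootstrap supports.

The NJ correctness oracle is the canonical one: generate a random unrooted
binary tree with known branch lengths, derive its additive leaf-to-leaf
distance matrix by path sums, and require exact recovery of topology, total
length and all patristic distances.
"""

import itertools
import math
import random

import numpy as np
import pytest

from drbselect.errors import MatrixError, NoDataError, SaturationError
from drbselect.phylo import (
    DistanceMatrix,
    bootstrap_supports,
    complete_deletion,
    nj_tree,
    poisson_distance,
    poisson_matrix,
    read_newick,
    tree_bipartitions,
    write_newick,
)


# ---------------------------------------------------------------------------
# random additive tree oracle
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree as adjacency {node: {nbr: length}};
    leaves are 'T0'..'T{n-1}'."""
    adj = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def drop_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    nxt_internal = [0]

    def new_internal():
        nxt_internal[0] += 1
        return f"I{nxt_internal[0]}"

    center = new_internal()
    for i in range(3):
        add_edge(center, f"T{i}", rng.uniform(0.1, 1.0))
    for i in range(3, n_taxa):
        edges = [
            (u, v) for u in adj for v in adj[u] if u < v
        ]
        u, v = edges[rng.randrange(len(edges))]
        w = adj[u][v]
        drop_edge(u, v)
        mid = new_internal()
        split = rng.uniform(0.2, 0.8)
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, f"T{i}", rng.uniform(0.1, 1.0))
    return adj


def path_distances(adj, leaves):
    import heapq

    out = {}
    for src in leaves:
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, math.inf):
                continue
            for v, w in adj[u].items():
                nd = d + w
                if nd < dist.get(v, math.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        out[src] = dist
    n = len(leaves)
    m = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            m[i, j] = out[a][b]
    np.fill_diagonal(m, 0.0)
    return m


def oracle_bipartitions(adj, leaves):
    ref = min(leaves)
    out = set()
    for u in adj:
        for v in adj[u]:
            if u < v and u.startswith("I") and v.startswith("I"):
                # leaves on v's side after cutting (u, v)
                seen, stack = {u, v}, [v]
                side = set()
                while stack:
                    x = stack.pop()
                    for y in adj[x]:
                        if y in seen or (x, y) == (v, u):
                            continue
                        seen.add(y)
                        if y.startswith("T"):
                            side.add(y)
                        else:
                            stack.append(y)
                if ref in side:
                    side = set(leaves) - side
                if 2 <= len(side) <= len(leaves) - 2:
                    out.add(frozenset(side))
    return out


def patristic_matrix(phylo_tree, labels):
    pdm = phylo_tree.tree.phylogenetic_distance_matrix()
    tns = phylo_tree.tree.taxon_namespace
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(
            tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
        )
        m[i, j] = m[j, i] = d
    return m


# ---------------------------------------------------------------------------
# complete deletion & Poisson distance
# ---------------------------------------------------------------------------

class TestCompleteDeletion:
    def test_no_missing_is_identity(self):
        filtered, kept = complete_deletion(["FLY", "FLL"])
        assert filtered == ["FLY", "FLL"]
        assert kept == (1, 2, 3)

    def test_column_with_x_dropped_for_all(self):
        filtered, kept = complete_deletion(["FLXKY", "FLLKY", "FLAKY"])
        assert filtered == ["FLKY", "FLKY", "FLKY"]
        assert kept == (1, 2, 4, 5)

    def test_output_length_is_all_present_count(self):
        rng = random.Random(3)
        seqs = [
            "".join(rng.choice("ACDEFX-") for _ in range(40)) for _ in range(5)
        ]
        filtered, kept = complete_deletion(seqs)
        expected = sum(
            all(s[i] not in "X-" for s in seqs) for i in range(40)
        )
        assert all(len(f) == expected for f in filtered)
        assert len(kept) == expected

    def test_everything_removed(self):
        with pytest.raises(NoDataError):
            complete_deletion(["X", "A"])


class TestPoissonDistance:
    def test_identical(self):
        assert poisson_distance("FLY", "FLY") == 0.0

    def test_closed_form(self):
        seq_a = "A" * 10
        seq_b = "C" + "A" * 9  # p = 0.1
        assert poisson_distance(seq_a, seq_b) == pytest.approx(-math.log(0.9))

    def test_dominates_p(self):
        for k in range(1, 9):
            seq_b = "C" * k + "A" * (10 - k)
            assert poisson_distance("A" * 10, seq_b) >= k / 10

    def test_saturation(self):
        with pytest.raises(SaturationError):
            poisson_distance("AAA", "CCC")

    def test_matrix_names_saturated_pair(self):
        with pytest.raises(SaturationError, match="x2"):
            poisson_matrix(["x1", "x2", "x3"], ["AAA", "CCC", "AAC"])


# ---------------------------------------------------------------------------
# NJ
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        m = DistanceMatrix(
            labels=("A", "B", "C"),
            values=np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]]),
        )
        result = nj_tree(m)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in result.tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)
        assert result.total_length == pytest.approx(sum(lengths.values()))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_additive_recovery(self, n_taxa):
        rng = random.Random(n_taxa)
        for _ in range(10):
            adj = random_additive_tree(n_taxa, rng)
            leaves = sorted(l for l in adj if l.startswith("T"))
            m = path_distances(adj, leaves)
            result = nj_tree(DistanceMatrix(labels=tuple(leaves), values=m))
            assert result.bipartitions() == oracle_bipartitions(adj, leaves)
            total = sum(w for u in adj for v, w in adj[u].items() if u < v)
            assert result.total_length == pytest.approx(total)
            np.testing.assert_allclose(
                patristic_matrix(result, leaves), m, atol=1e-9
            )

    def test_permutation_invariance(self, tmp_path):
        rng = random.Random(99)
        adj = random_additive_tree(6, rng)
        leaves = sorted(l for l in adj if l.startswith("T"))
        m = path_distances(adj, leaves)
        perm = list(range(len(leaves)))
        rng.shuffle(perm)
        t1 = nj_tree(DistanceMatrix(labels=tuple(leaves), values=m))
        t2 = nj_tree(
            DistanceMatrix(
                labels=tuple(leaves[i] for i in perm), values=m[np.ix_(perm, perm)]
            )
        )
        p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
        write_newick(t1, p1)
        write_newick(t2, p2)
        assert p1.read_text() == p2.read_text()

    def test_agrees_with_skbio_topology(self):
        """Independent cross-check against scikit-bio's NJ on a noisy
        (non-additive) matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        n = 7
        labels = [f"T{i}" for i in range(n)]
        base = random_additive_tree(n, random.Random(5))
        m = path_distances(base, sorted(l for l in base if l.startswith("T")))
        noise = rng.uniform(0, 0.02, size=(n, n))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        m_noisy = m + noise
        m_noisy = (m_noisy + m_noisy.T) / 2  # exact float symmetry
        mine = nj_tree(DistanceMatrix(labels=tuple(labels), values=m_noisy))
        ref = skbio.tree.nj(skbio.DistanceMatrix(m_noisy, ids=labels))
        ref_biparts = set()
        all_labels = set(labels)
        ref_label = min(all_labels)
        for node in ref.non_tips():
            side = {t.name for t in node.tips()}
            if ref_label in side:
                side = all_labels - side
            if 2 <= len(side) <= n - 2:
                ref_biparts.add(frozenset(side))
        assert mine.bipartitions() == ref_biparts

    def test_rejects_bad_matrix(self):
        with pytest.raises(MatrixError):
            DistanceMatrix(labels=("a", "b"), values=np.array([[0, 1], [2, 0]]))
        with pytest.raises(MatrixError):
            DistanceMatrix(labels=("a", "b"), values=np.array([[0, -1], [-1, 0]]))


# ---------------------------------------------------------------------------
# bootstrap supports and newick round-trip
# ---------------------------------------------------------------------------

def two_clade_residues(rng, n_per_clade=5, length=60, divergence=30):
    base_a = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))
    base_b = list(base_a)
    for i in rng.sample(range(length), divergence):
        base_b[i] = rng.choice([c for c in "ACDEFGHIKLMNPQRSTVWY" if c != base_a[i]])
    base_b = "".join(base_b)
    labels, seqs = [], []
    for k, base in (("a", base_a), ("b", base_b)):
        for i in range(n_per_clade):
            s = list(base)
            pos = rng.sample(range(length), 2)
            for p in pos:
                s[p] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
            labels.append(f"{k}{i}")
            seqs.append("".join(s))
    return labels, seqs


class TestBootstrapSupports:
    def test_separating_edge_has_high_support(self):
        rng = random.Random(17)
        labels, seqs = two_clade_residues(rng)
        tree = bootstrap_supports(labels, seqs, replicates=100, seed=4)
        clade_b = frozenset(l for l in labels if l.startswith("b"))
        assert clade_b in tree.supports
        assert tree.supports[clade_b] >= 95.0

    def test_supports_bounded(self):
        rng = random.Random(23)
        labels, seqs = two_clade_residues(rng)
        tree = bootstrap_supports(labels, seqs, replicates=50, seed=9)
        assert all(0.0 <= v <= 100.0 for v in tree.supports.values())

    def test_fixed_seed_deterministic(self):
        rng = random.Random(31)
        labels, seqs = two_clade_residues(rng)
        t1 = bootstrap_supports(labels, seqs, replicates=50, seed=12)
        t2 = bootstrap_supports(labels, seqs, replicates=50, seed=12)
        assert t1.supports == t2.supports


class TestNewickRoundTrip:
    def test_three_taxon_parseable(self, tmp_path):
        m = DistanceMatrix(
            labels=("A", "B", "C"),
            values=np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        path = tmp_path / "t.nwk"
        write_newick(nj_tree(m), path)
        text = path.read_text().strip()
        assert text.endswith(";")
        back = read_newick(path)
        assert set(back.leaf_labels) == {"A", "B", "C"}

    def test_total_length_and_topology_preserved(self, tmp_path):
        rng = random.Random(41)
        adj = random_additive_tree(7, rng)
        leaves = sorted(l for l in adj if l.startswith("T"))
        m = path_distances(adj, leaves)
        tree = nj_tree(DistanceMatrix(labels=tuple(leaves), values=m))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        # branch lengths are serialized at 6 decimals; the summed rounding
        # error over ~2n-3 edges stays well under 1e-5
        assert back.total_length == pytest.approx(tree.total_length, abs=1e-5)
        assert back.bipartitions() == tree.bipartitions()

    def test_supports_survive_roundtrip(self, tmp_path):
        rng = random.Random(43)
        labels, seqs = two_clade_residues(rng)
        tree = bootstrap_supports(labels, seqs, replicates=40, seed=2)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.supports is not None
        for bp, value in back.supports.items():
            assert tree.supports[bp] == pytest.approx(value, abs=0.5)
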
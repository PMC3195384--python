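"""Poisson-corrected amino-acid distances, Neighbor-Joining and bootstrap.

The tree pipeline mirrors the classic distance workflow for protein-coding
MHC alignments: translate, drop every column with a gap or missing residue in
any sequence (complete deletion), compute Poisson-corrected distances
d = -ln(1 - p), agglomerate with the Saitou–Nei Neighbor-Joining algorithm,
and attach bootstrap supports by resampling residue columns.

NJ ties in the Q-criterion are broken on the lexicographically smallest pair
of cluster representatives (the smallest leaf label in each cluster), so the
optimal tree and its total branch length are byte-reproducible.  Negative NJ
branch lengths are clamped to zero with the deficit logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .errors import MatrixError, NoDataError, SaturationError

logger = logging.getLogger(__name__)

_MISSING_AA = {"-", "X"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with ordered taxon labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise MatrixError("matrix shape does not match label count")
        if not np.all(np.isfinite(v)):
            raise MatrixError("matrix contains non-finite values")
        if np.any(v < 0):
            raise MatrixError("matrix contains negative distances")
        if not np.allclose(v, v.T):
            raise MatrixError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise MatrixError("matrix diagonal is not zero")
        object.__setattr__(self, "values", v)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class PhyloTree:
    """An unrooted NJ tree with branch lengths and optional bootstrap supports.

    ``supports`` maps each internal-edge bipartition (canonical leaf-label
    frozenset) to a bootstrap percentage in [0, 100].
    """

    tree: dendropy.Tree
    total_length: float
    supports: dict[frozenset, float] | None = None

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.tree)


# ---------------------------------------------------------------------------
# alignment filtering and distances
# ---------------------------------------------------------------------------

def complete_deletion(residues: list[str]) -> tuple[list[str], tuple[int, ...]]:
    """Remove every column containing a gap or X in *any* sequence.

    Returns the filtered strings and the retained 1-based column positions.
    """
    if len({len(r) for r in residues}) > 1:
        raise NoDataError("residue strings differ in length")
    keep = [
        i
        for i in range(len(residues[0]))
        if not any(seq[i] in _MISSING_AA for seq in residues)
    ]
    if not keep:
        raise NoDataError("complete deletion removed every column")
    filtered = ["".join(seq[i] for i in keep) for seq in residues]
    return filtered, tuple(i + 1 for i in keep)


def poisson_distance(residues_a: str, residues_b: str) -> float:
    """Poisson-corrected amino-acid distance d = -ln(1 - p)."""
    if len(residues_a) != len(residues_b) or not residues_a:
        raise NoDataError("residue strings must have equal nonzero length")
    p = sum(a != b for a, b in zip(residues_a, residues_b)) / len(residues_a)
    if p >= 1.0:
        raise SaturationError("all residues differ: Poisson distance undefined")
    return -np.log(1.0 - p)


def poisson_matrix(labels: list[str], residues: list[str]) -> DistanceMatrix:
    """All-pairs Poisson distance matrix; saturated pairs raise, naming them."""
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = poisson_distance(residues[i], residues[j])
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=tuple(labels), values=values)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------

def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("clamped negative branch length %.6g at %s", length, context)
        return 0.0
    return length


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei Neighbor-Joining on a distance matrix.

    At each step the pair minimizing Q_ij = (r-2)·d_ij - R_i - R_j is joined;
    ties go to the lexicographically smallest pair of cluster representatives.
    Returns an unrooted tree (trifurcating central node) with total length.
    """
    n = len(matrix.labels)
    if n < 3:
        raise MatrixError(f"need >= 3 taxa for NJ, got {n}")
    tns = dendropy.TaxonNamespace(list(matrix.labels))

    # active clusters: representative label -> (node, row index in D)
    nodes: dict[str, dendropy.Node] = {}
    for lab in matrix.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes[lab] = node
    # all iteration is in label-sorted order so the result is exactly
    # invariant under permutation of the input matrix
    reps = sorted(matrix.labels)
    D = {a: {b: float(matrix.values[i, j]) for j, b in enumerate(matrix.labels)}
         for i, a in enumerate(matrix.labels)}

    total_length = 0.0
    while len(reps) > 3:
        r = len(reps)
        R = {a: sum(D[a][b] for b in reps if b != a) for a in reps}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = reps[ii], reps[jj]
                q = (r - 2) * D[a][b] - R[a] - R[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
                    best_pair = tuple(sorted((a, b)))
        a, b = best_pair
        dab = D[a][b]
        la = _clamp(0.5 * dab + (R[a] - R[b]) / (2.0 * (r - 2)), f"join({a},{b})")
        lb = _clamp(dab - (0.5 * dab + (R[a] - R[b]) / (2.0 * (r - 2))), f"join({a},{b})")
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        total_length += la + lb

        new_rep = min(a, b)
        new_dist = {
            c: 0.5 * (D[a][c] + D[b][c] - dab) for c in reps if c not in (a, b)
        }
        for c in list(new_dist):
            D[c][new_rep] = new_dist[c]
        D[new_rep] = new_dist
        D[new_rep][new_rep] = 0.0
        reps = [c for c in reps if c not in (a, b)] + [new_rep]
        reps.sort()
        nodes[new_rep] = parent

    a, b, c = sorted(reps)
    la = _clamp(0.5 * (D[a][b] + D[a][c] - D[b][c]), "final")
    lb = _clamp(0.5 * (D[a][b] + D[b][c] - D[a][c]), "final")
    lc = _clamp(0.5 * (D[a][c] + D[b][c] - D[a][b]), "final")
    center = dendropy.Node()
    for rep, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[rep])
        nodes[rep].edge.length = length
    total_length += la + lb + lc

    tree = dendropy.Tree(seed_node=center, taxon_namespace=tns)
    tree.is_rooted = False
    return PhyloTree(tree=tree, total_length=total_length)


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------

def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial leaf bipartitions, each canonicalized to the side *not*
    containing the alphabetically first taxon."""
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(all_labels)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(frozenset(side))
    return out


def bootstrap_supports(
    labels: list[str],
    residues: list[str],
    replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ point tree with bootstrap supports from residue-column resampling.

    Each internal edge of the point tree is annotated with the percentage of
    replicate trees containing the same bipartition; supports are also written
    onto the dendropy internal-node labels for newick export.  Deterministic
    for a fixed seed.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    point = nj_tree(poisson_matrix(labels, residues))
    target = point.bipartitions()
    counts = dict.fromkeys(target, 0)
    n_cols = len(residues[0])
    children = np.random.SeedSequence(seed).spawn(replicates)
    for child in children:
        rng = np.random.default_rng(child)
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = ["".join(seq[c] for c in cols) for seq in residues]
        rep_tree = nj_tree(poisson_matrix(labels, resampled))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * k / replicates for bp, k in counts.items()}

    all_labels = set(labels)
    ref = min(all_labels)
    for node in point.tree.preorder_node_iter():
        if node is point.tree.seed_node or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in side:
            side = all_labels - side
        bp = frozenset(side)
        if bp in supports:
            node.label = f"{supports[bp]:g}"
    point.supports = supports
    return point


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write newick with 6-decimal branch lengths and supports as internal
    node labels."""
    text = tree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
    )
    Path(path).write_text(text)


def read_newick(path: str | Path) -> PhyloTree:
    """Read a newick file back into a :class:`PhyloTree`, recomputing total
    length and harvesting supports from internal-node labels."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    total = sum(
        e.length for e in tree.preorder_edge_iter() if e.length is not None
    )
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(all_labels)
    supports: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf() or node.label is None:
            continue
        try:
            value = float(node.label)
        except ValueError:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            supports[frozenset(side)] = value
    return PhyloTree(
        tree=tree, total_length=float(total), supports=supports or None
    )
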
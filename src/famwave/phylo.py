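"""Protein phylogenetics: JTT distances, neighbor joining, bootstrap
consensus, outgroup rooting and reciprocal-best-hit ortholog pairing.

Gene trees are :class:`dendropy.Tree` objects; bootstrap supports (0-100)
are stored as internal-node labels, the convention used when writing
Newick.  Distances are JTT maximum-likelihood distances in amino-acid
substitutions per site (see :mod:`famwave.jtt`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import jtt

__all__ = [
    "ProteinAlignment",
    "DistanceMatrix",
    "jtt_ml_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_consensus",
    "root_with_outgroup",
    "reciprocal_best_hits",
    "RBHPair",
]

_ALPHABET = set(jtt.AA_ORDER) | {"-"}


@dataclass(frozen=True)
class ProteinAlignment:
    """Aligned protein rows (20-letter alphabet plus ``-`` gaps)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows differ in length")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"row {rid!r} has invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "ProteinAlignment":
        return cls(tuple(seqs), tuple(s.upper() for s in seqs.values()))


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with saturation flags."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    saturated: np.ndarray = field(default=None)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)


def jtt_ml_distance(row_a: str, row_b: str, method: str = "jtt") -> float:
    """Pairwise distance in substitutions per site, pairwise gap deletion.

    ``method`` is ``"jtt"`` (ML under the JTT model, Brent-optimised to
    1e-6) or ``"poisson"`` (Poisson-corrected p-distance fallback).
    Estimates are capped at 10.0 substitutions/site.
    """
    counts = jtt.pair_counts(row_a, row_b)
    if method == "jtt":
        d, _ = jtt.ml_distance_from_counts(counts)
    elif method == "poisson":
        d, _ = jtt.poisson_distance_from_counts(counts)
    else:
        raise ValueError(f"unknown method {method!r}")
    return d


def distance_matrix(aln: ProteinAlignment, method: str = "jtt") -> DistanceMatrix:
    n = len(aln)
    mat = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            counts = jtt.pair_counts(aln.rows[i], aln.rows[j])
            if method == "jtt":
                d, s = jtt.ml_distance_from_counts(counts)
            else:
                d, s = jtt.poisson_distance_from_counts(counts)
            mat[i, j] = mat[j, i] = d
            sat[i, j] = sat[j, i] = s
    return DistanceMatrix(tuple(aln.ids), mat, sat)


# -- neighbor joining -----------------------------------------------------


def _nj_core(d: np.ndarray, labels: list[str]):
    """Saitou-Nei agglomeration.

    Returns (children, edge_len, leaf_label) describing a tree over integer
    node ids: leaves are 0..n-1, internal nodes are appended; the last node
    is the (trifurcating) root.  Ties in the Q criterion are broken by the
    lexicographically smallest pair of sorted-leaf-label cluster keys, so
    the result is invariant under permutation of the input order.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    children: dict[int, list[int]] = {}
    edge_len: dict[int, float] = {}
    keys = {i: (labels[i],) for i in range(n)}
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def dd(i, j):
        return dist[(i, j) if i < j else (j, i)]

    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dd(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dd(i, j) - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                cand = (q, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = dd(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, shifting the deficit to the sister edge
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        u = next_id
        next_id += 1
        children[u] = [i, j]
        edge_len[i] = li
        edge_len[j] = lj
        keys[u] = tuple(sorted(keys[i] + keys[j]))
        new_d = {}
        for k in active:
            if k in (i, j):
                continue
            new_d[k] = 0.5 * (dd(i, k) + dd(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]
        for k, v in new_d.items():
            dist[(k, u) if k < u else (u, k)] = v

    a, b, c = sorted(active, key=lambda i: keys[i])
    root = next_id
    children[root] = [a, b, c]
    edge_len[a] = max(0.0, 0.5 * (dd(a, b) + dd(a, c) - dd(b, c)))
    edge_len[b] = max(0.0, 0.5 * (dd(a, b) + dd(b, c) - dd(a, c)))
    edge_len[c] = max(0.0, 0.5 * (dd(a, c) + dd(b, c) - dd(a, b)))
    return children, edge_len, root


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted NJ tree (trifurcating seed node) from a distance matrix."""
    d = dm.matrix
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix has nonzero diagonal")
    labels = list(dm.labels)
    children, edge_len, root = _nj_core(d, labels)

    tns = dendropy.TaxonNamespace(labels)
    n = len(labels)

    def build(i: int) -> dendropy.Node:
        node = dendropy.Node()
        if i < n:
            node.taxon = tns.get_taxon(labels[i])
        else:
            for c in children[i]:
                child = build(c)
                child.edge.length = edge_len[c]
                node.add_child(child)
        return node

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=build(root))
    tree.is_rooted = False
    return tree


# -- bootstrap + consensus ------------------------------------------------


def _splits_of(children, root, n, labels) -> set[frozenset]:
    """Non-trivial splits as frozensets of the side not containing labels[0]."""
    full = frozenset(labels)
    out = set()

    def leafset(i):
        if i < n:
            return frozenset([labels[i]])
        s = frozenset()
        for c in children[i]:
            s |= leafset(c)
        return s

    memo = {}

    def rec(i):
        if i < n:
            memo[i] = frozenset([labels[i]])
            return memo[i]
        s = frozenset()
        for c in children[i]:
            s |= rec(c)
        memo[i] = s
        return s

    rec(root)
    ref = labels[0]
    for i, s in memo.items():
        if i >= n and i != root and 1 < len(s) < len(full) - 1:
            side = s if ref not in s else full - s
            if 0 < len(side) < len(full):
                out.add(side)
    return out


def _bootstrap_counts(aln: ProteinAlignment, n_reps: int, seed: int):
    codes = np.stack([jtt.encode(r) for r in aln.rows])
    n, length = codes.shape
    labels = list(aln.ids)
    rng = np.random.default_rng(seed)
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    split_counts: Counter = Counter()
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        a = codes[:, cols]
        counts = np.empty((len(pair_idx), 20, 20))
        for p, (i, j) in enumerate(pair_idx):
            ri, rj = a[i], a[j]
            ok = (ri < 20) & (rj < 20)
            if not ok.any():
                raise ValueError(f"no shared sites between {labels[i]} and {labels[j]} in a replicate")
            counts[p] = np.bincount(
                ri[ok] * 20 + rj[ok], minlength=400
            ).reshape(20, 20)
        dvec = jtt.grid_ml_distances(counts)
        d = np.zeros((n, n))
        for p, (i, j) in enumerate(pair_idx):
            d[i, j] = d[j, i] = dvec[p]
        children, _, root = _nj_core(d, labels)
        for s in _splits_of(children, root, n, labels):
            split_counts[s] += 1
    return split_counts


def bootstrap_consensus(
    aln: ProteinAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> dendropy.Tree:
    """Majority-rule consensus of NJ trees over column-resampled replicates.

    Splits with frequency >= ``threshold`` are kept; internal-node labels
    carry ``round(100 * frequency)`` as bootstrap support.  The returned
    tree is unrooted (trifurcating seed node) and has no branch lengths.
    """
    if len(aln) < 3:
        raise ValueError("alignment must have at least 3 rows")
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    split_counts = _bootstrap_counts(aln, n_reps, seed)
    labels = list(aln.ids)
    ref = labels[0]
    keep = {
        s: c / n_reps
        for s, c in split_counts.items()
        if c / n_reps >= threshold
    }
    # splits at >=50% frequency are pairwise compatible -> laminar family
    clusters = sorted(keep, key=len, reverse=True)
    rest = [l for l in labels if l != ref]

    tns = dendropy.TaxonNamespace(labels)
    top = dendropy.Node()  # subtree holding everything but the reference
    node_of = {frozenset(rest): top}
    for s in clusters:
        parent = node_of[frozenset(rest)]
        best = None
        for t, nd in node_of.items():
            if s < t and (best is None or len(t) < len(best)):
                best, parent = t, nd
        nd = dendropy.Node()
        nd.label = str(round(100 * keep[s]))
        parent.add_child(nd)
        node_of[s] = nd
    for leaf in rest:
        best = None
        parent = node_of[frozenset(rest)]
        for t, nd in node_of.items():
            if leaf in t and (best is None or len(t) < len(best)):
                best, parent = t, nd
        lf = dendropy.Node(taxon=tns.get_taxon(leaf))
        parent.add_child(lf)
    seed_node = dendropy.Node()
    seed_node.add_child(dendropy.Node(taxon=tns.get_taxon(ref)))
    for child in list(top.child_nodes()):
        seed_node.add_child(child)
    if top.label:
        seed_node.label = top.label
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed_node)
    tree.is_rooted = False
    return tree


# -- rooting --------------------------------------------------------------


def _support_map(tree: dendropy.Tree) -> dict[frozenset, str]:
    full = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.label is None:
            continue
        s = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 1 < len(s) < len(full):
            out[s] = nd.label
            out[full - s] = nd.label
    return out


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the edge subtending ``outgroup`` (midpoint of that edge).

    Bootstrap supports are preserved per bipartition: after rerooting each
    internal node is relabelled with the support of the (unrooted) split it
    subtends in the input tree.
    """
    t = tree.clone(depth=1)
    leaf = None
    for lf in t.leaf_node_iter():
        if lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup leaf {outgroup!r} not in tree")
    supports = _support_map(t)
    length = leaf.edge.length
    if length is None:
        t.reroot_at_edge(leaf.edge, update_bipartitions=False)
    else:
        t.reroot_at_edge(
            leaf.edge,
            length1=length / 2.0,
            length2=length / 2.0,
            update_bipartitions=False,
        )
    t.is_rooted = True
    full = frozenset(l.taxon.label for l in t.leaf_node_iter())
    for nd in t.preorder_node_iter():
        if nd.is_leaf():
            continue
        s = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 1 < len(s) < len(full):
            nd.label = supports.get(s)
        elif nd is not t.seed_node:
            nd.label = None
    return t


# -- reciprocal best hits -------------------------------------------------


@dataclass(frozen=True)
class RBHPair:
    id_a: str
    id_b: str
    score: float
    tie_broken: bool = False


def _make_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # affine gaps: a run of k gaps costs 11 + k
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def reciprocal_best_hits(
    set_a: dict[str, str], set_b: dict[str, str]
) -> list[RBHPair]:
    """Ortholog pairing by mutual best global-alignment score.

    Every cross pair is scored by global alignment (BLOSUM62, affine gap
    open 11 / extend 1); a pair is kept iff each sequence is the other's
    unique maximal-score hit.  Score ties are broken by lexicographic id
    and the resulting pairs flagged ``tie_broken``.
    """
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    aligner = _make_aligner()
    ids_a = sorted(set_a)
    ids_b = sorted(set_b)
    scores = np.empty((len(ids_a), len(ids_b)))
    for i, ia in enumerate(ids_a):
        for j, ib in enumerate(ids_b):
            scores[i, j] = aligner.score(set_a[ia], set_b[ib])

    def best(row):
        m = row.max()
        hits = np.nonzero(row == m)[0]
        return hits[0], len(hits) > 1  # ids are sorted -> lexicographic tie-break

    best_a = [best(scores[i]) for i in range(len(ids_a))]
    best_b = [best(scores[:, j]) for j in range(len(ids_b))]
    pairs = []
    for i, (j, tie_a) in enumerate(best_a):
        jb, tie_b = best_b[j]
        if jb == i:
            pairs.append(
                RBHPair(ids_a[i], ids_b[j], float(scores[i, j]), tie_a or tie_b)
            )
    return pairs
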
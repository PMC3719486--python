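"""Distances, neighbor joining, bootstrap consensus, rooting, RBH."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from famwave import jtt
from famwave.phylo import (
    DistanceMatrix,
    ProteinAlignment,
    bootstrap_consensus,
    distance_matrix,
    jtt_ml_distance,
    neighbor_joining,
    reciprocal_best_hits,
    root_with_outgroup,
)

AA = jtt.AA_ORDER


def _tree_splits(tree):
    full = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = sorted(full)[0]
    splits = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        s = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 1 < len(s) < len(full) - 1:
            splits.add(s if ref not in s else full - s)
    return splits


def _random_additive(rng, n):
    """Random binary tree over n leaves -> (labels, additive matrix)."""
    labels = [f"L{i}" for i in range(n)]
    clusters = [{labels[i]: 0.0} for i in range(n)]
    d = {frozenset((a, b)): 0.0 for a in labels for b in labels if a != b}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        ei, ej = rng.uniform(0.1, 2.0, size=2)
        a, b = clusters[i], clusters[j]
        for la, da in a.items():
            for lb, db in b.items():
                d[frozenset((la, lb))] = da + ei + db + ej
        merged = {l: v + ei for l, v in a.items()}
        merged.update({l: v + ej for l, v in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = d[frozenset((labels[i], labels[j]))]
    return tuple(labels), mat


def _path_distances(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    tax = {l: tree.taxon_namespace.get_taxon(l) for l in labels}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(tax[labels[i]], tax[labels[j]])
    return out


# -- JTT distances --------------------------------------------------------


def test_identical_rows_have_zero_distance():
    row = AA * 5
    assert jtt_ml_distance(row, row) == 0.0


def test_single_mismatch_exceeds_p_distance():
    row = AA * 5
    other = "C" + row[1:]
    d = jtt_ml_distance(row, other)
    assert d > 0.01  # ML correction exceeds the observed proportion 1/100


@given(st.integers(0, 10_000))
def test_jtt_distance_symmetric_and_bounded_below_by_p(seed):
    rng = np.random.default_rng(seed)
    n = 60
    a = "".join(rng.choice(list(AA + "-"), size=n))
    b = "".join(rng.choice(list(AA + "-"), size=n))
    enc_a, enc_b = jtt.encode(a), jtt.encode(b)
    ok = (enc_a < 20) & (enc_b < 20)
    if not ok.any():
        return
    d_ab = jtt_ml_distance(a, b)
    d_ba = jtt_ml_distance(b, a)
    # symmetric up to the 1e-6-ish Brent tolerance (flat optimum when deep)
    assert d_ab == pytest.approx(d_ba, rel=1e-5, abs=1e-6)
    counts = jtt.pair_counts(a, b)
    p = jtt.p_distance_from_counts(counts)
    assert d_ab >= p - 1e-9
    if p == 0:
        assert d_ab == 0.0


def test_no_shared_sites_is_an_error():
    with pytest.raises(ValueError, match="no shared sites"):
        jtt_ml_distance("A--", "-CC")


def test_saturated_distance_is_capped_and_flagged():
    rng = np.random.default_rng(1)
    aln = ProteinAlignment(
        ("x", "y"),
        (
            "".join(rng.choice(list(AA), size=50)),
            "".join(rng.choice(list(AA), size=50)),
        ),
    )
    dm = distance_matrix(aln)
    assert dm.matrix[0, 1] <= jtt.SATURATION_CAP
    if dm.matrix[0, 1] == jtt.SATURATION_CAP:
        assert dm.saturated[0, 1]


def test_grid_distances_track_brent_distances():
    rng = np.random.default_rng(0)
    rows = []
    base = "".join(rng.choice(list(AA), size=120))
    for k in (2, 6, 15, 30):
        row = list(base)
        idx = rng.choice(120, size=k, replace=False)
        for i in idx:
            row[i] = AA[rng.integers(20)]
        rows.append("".join(row))
    counts = np.stack([jtt.pair_counts(base, r) for r in rows])
    grid = jtt.grid_ml_distances(counts)
    for g, r in zip(grid, rows):
        exact, _ = jtt.ml_distance_from_counts(jtt.pair_counts(base, r))
        assert g == pytest.approx(exact, rel=0.02, abs=1e-4)


# -- neighbor joining -----------------------------------------------------


def test_nj_recovers_four_leaf_additive_tree_exactly():
    labels = ("A", "B", "C", "D")
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = neighbor_joining(DistanceMatrix(labels, d))
    assert _tree_splits(tree) == {frozenset({"C", "D"})} or _tree_splits(
        tree
    ) == {frozenset({"A", "B"})}
    assert np.allclose(_path_distances(tree, labels), d, atol=1e-9)


def test_nj_three_leaves_uses_three_point_formulas():
    labels = ("A", "B", "C")
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = neighbor_joining(DistanceMatrix(labels, d))
    assert np.allclose(_path_distances(tree, labels), d, atol=1e-9)


def test_nj_additivity_on_random_trees():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(4, 9))
        labels, mat = _random_additive(rng, n)
        tree = neighbor_joining(DistanceMatrix(labels, mat))
        assert np.allclose(_path_distances(tree, labels), mat, atol=1e-9)


def test_nj_matches_dendropy_on_additive_matrix():
    """Independent cross-check against dendropy's NJ implementation."""
    import io as _io

    import dendropy

    rng = np.random.default_rng(7)
    labels, mat = _random_additive(rng, 7)
    mine = neighbor_joining(DistanceMatrix(labels, mat))
    csv = "," + ",".join(labels) + "\n"
    for i, l in enumerate(labels):
        csv += l + "," + ",".join(str(x) for x in mat[i]) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=_io.StringIO(csv), taxon_namespace=dendropy.TaxonNamespace(list(labels))
    )
    theirs = pdm.nj_tree()
    assert _tree_splits(mine) == _tree_splits(theirs)


def test_nj_invariant_under_label_permutation():
    rng = np.random.default_rng(3)
    labels, mat = _random_additive(rng, 6)
    t1 = neighbor_joining(DistanceMatrix(labels, mat))
    perm = rng.permutation(len(labels))
    labels2 = tuple(labels[i] for i in perm)
    mat2 = mat[np.ix_(perm, perm)]
    t2 = neighbor_joining(DistanceMatrix(labels2, mat2))
    assert _tree_splits(t1) == _tree_splits(t2)


def test_nj_rejects_asymmetric_matrix():
    d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
    with pytest.raises(ValueError, match="symmetric"):
        neighbor_joining(DistanceMatrix(("A", "B", "C"), d))


# -- bootstrap consensus --------------------------------------------------

_SEP_ALN = ProteinAlignment(
    ("A", "B", "C", "D"),
    ("AAAAAAAA", "AAAAAAAA", "CCCCCCCC", "CCCCCCCC"),
)


def test_perfect_separation_gives_support_100():
    tree = bootstrap_consensus(_SEP_ALN, n_reps=200, seed=0)
    supports = {
        frozenset(l.taxon.label for l in nd.leaf_iter()): int(nd.label)
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd.label is not None
    }
    assert supports.get(frozenset({"C", "D"})) == 100


def test_bootstrap_deterministic_for_fixed_seed():
    t1 = bootstrap_consensus(_SEP_ALN, n_reps=50, seed=4)
    t2 = bootstrap_consensus(_SEP_ALN, n_reps=50, seed=4)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


def test_consensus_supports_respect_threshold():
    rng = np.random.default_rng(0)
    rows = tuple(
        "".join(rng.choice(list(AA), size=40)) for _ in range(5)
    )
    tree = bootstrap_consensus(
        ProteinAlignment(tuple("ABCDE"), rows), n_reps=100, seed=1
    )
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and nd.label is not None:
            assert int(nd.label) >= 50


def test_supports_stable_under_alignment_duplication():
    doubled = ProteinAlignment(
        _SEP_ALN.ids, tuple(r + r for r in _SEP_ALN.rows)
    )
    t1 = bootstrap_consensus(_SEP_ALN, n_reps=100, seed=2)
    t2 = bootstrap_consensus(doubled, n_reps=100, seed=2)

    def cd_support(tree):
        for nd in tree.preorder_node_iter():
            if not nd.is_leaf() and nd.label is not None:
                if {l.taxon.label for l in nd.leaf_iter()} == {"C", "D"}:
                    return int(nd.label)

    assert cd_support(t1) == cd_support(t2) == 100


def test_too_few_rows_rejected():
    with pytest.raises(ValueError):
        bootstrap_consensus(ProteinAlignment(("a", "b"), ("AA", "AC")), 10, 0)


# -- rooting --------------------------------------------------------------


def _four_leaf_tree():
    labels = ("W", "X", "Y", "Z")
    d = np.array(
        [[0, 2, 5, 5], [2, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], float
    )
    return neighbor_joining(DistanceMatrix(labels, d))


def test_outgroup_becomes_child_of_root():
    tree = root_with_outgroup(_four_leaf_tree(), "X")
    root_children = tree.seed_node.child_nodes()
    assert len(root_children) == 2
    leaf_sets = [
        frozenset(l.taxon.label for l in c.leaf_iter()) for c in root_children
    ]
    assert frozenset({"X"}) in leaf_sets
    assert frozenset({"W", "Y", "Z"}) in leaf_sets


def test_rooting_preserves_total_branch_length():
    unrooted = _four_leaf_tree()
    total = sum(
        e.length for e in unrooted.preorder_edge_iter() if e.length
    )
    rooted = root_with_outgroup(unrooted, "Y")
    total2 = sum(e.length for e in rooted.preorder_edge_iter() if e.length)
    assert total2 == pytest.approx(total, abs=1e-9)


def test_rooting_idempotent_on_topology():
    r1 = root_with_outgroup(_four_leaf_tree(), "X")
    r2 = root_with_outgroup(r1, "X")
    assert _tree_splits(r1) == _tree_splits(r2)


def test_rooting_preserves_supports():
    tree = bootstrap_consensus(_SEP_ALN, n_reps=100, seed=0)
    rooted = root_with_outgroup(tree, "A")
    supports = {
        frozenset(l.taxon.label for l in nd.leaf_iter()): nd.label
        for nd in rooted.preorder_node_iter()
        if not nd.is_leaf() and nd.label is not None
    }
    assert supports.get(frozenset({"C", "D"})) == "100"


def test_missing_outgroup_is_an_error():
    with pytest.raises(ValueError, match="not in tree"):
        root_with_outgroup(_four_leaf_tree(), "Q")


# -- reciprocal best hits -------------------------------------------------


def test_rbh_identity_pairing():
    seqs = {"a": "MKLVWPRT", "b": "MKAVWQRT", "c": "MYLVWPGT"}
    pairs = reciprocal_best_hits(seqs, dict(seqs))
    assert {(p.id_a, p.id_b) for p in pairs} == {(k, k) for k in seqs}


def test_rbh_is_a_matching():
    rng = np.random.default_rng(5)
    sa = {f"a{i}": "".join(rng.choice(list(AA), size=30)) for i in range(5)}
    sb = {f"b{i}": "".join(rng.choice(list(AA), size=30)) for i in range(5)}
    pairs = reciprocal_best_hits(sa, sb)
    assert len({p.id_a for p in pairs}) == len(pairs)
    assert len({p.id_b for p in pairs}) == len(pairs)


def test_rbh_rejects_non_mutual_best():
    # B1's best hit is A2, so A1-B1 must not pair even though B1 is A1's best
    a = {"A1": "MKLWWWWCCC", "A2": "MKLWWWWRRR"}
    b = {"B1": "MKLWWWWRRC"}
    pairs = reciprocal_best_hits(a, b)
    assert all(p.id_a != "A1" for p in pairs)
    assert {(p.id_a, p.id_b) for p in pairs} == {("A2", "B1")}


def test_rbh_singletons_pair():
    pairs = reciprocal_best_hits({"x": "MKL"}, {"y": "MKL"})
    assert len(pairs) == 1 and pairs[0].id_a == "x" and pairs[0].id_b == "y"


def test_rbh_empty_set_is_an_error():
    with pytest.raises(ValueError):
        reciprocal_best_hits({}, {"y": "MKL"})
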
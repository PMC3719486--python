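"""Birth-death simulator: bookkeeping, closed-form limits, determinism."""

import math

import numpy as np
import pytest

from famwave import synthetic
from famwave.pipeline import two_leaf_tree
from famwave.synthetic import Region, SimParams, Wave, simulate_family
from famwave.trees import SpeciesTree


def _species_splits(stree):
    return {
        frozenset(stree.leaves_under(n))
        for n in stree.internal
        if n != stree.root
    }


def _gene_splits_as_species(tree, species_of):
    full = frozenset(species_of[l.taxon.label] for l in tree.leaf_node_iter())
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        s = frozenset(species_of[l.taxon.label] for l in nd.leaf_iter())
        if 1 < len(s) < len(full):
            out.add(s)
    return out


def test_no_events_gives_one_gene_per_species_and_congruent_tree(species_tree):
    params = SimParams(dup_rate=0.0, loss_rate=0.0, seed=5)
    tree, truth = simulate_family(species_tree, params)
    per_species = {}
    for g, sp in truth.gene_species.items():
        per_species[sp] = per_species.get(sp, 0) + 1
    assert per_species == {sp: 1 for sp in species_tree.leaves}
    for ev in truth.events.values():
        assert not ev.duplications and not ev.losses
    gene_splits = _gene_splits_as_species(tree, truth.gene_species)
    clades_of_species_tree = {
        frozenset(species_tree.leaves_under(n))
        for n in species_tree.preorder()
    }
    assert gene_splits <= clades_of_species_tree
    assert len(gene_splits) >= len(species_tree.internal) - 2


def test_event_bookkeeping_invariant(species_tree):
    for seed in range(25):
        params = SimParams(dup_rate=0.5, loss_rate=0.25, seed=seed)
        _, truth = simulate_family(species_tree, params)
        for parent, child, _ in species_tree.branches():
            ev = truth.events[child]
            assert truth.lineage_counts.get(child, 0) == (
                truth.lineage_counts.get(parent, 0)
                + len(ev.duplications)
                - len(ev.losses)
            )


def test_pure_birth_mean_matches_closed_form():
    # E[N(T)] = exp(lambda * T) for a pure-birth process
    stree = SpeciesTree.from_newick("(A:2,B:2)R;")
    lam, T = 0.5, 2.0
    counts = []
    for seed in range(1000):
        params = SimParams(dup_rate=lam, loss_rate=0.0, seed=seed)
        _, truth = simulate_family(stree, params)
        for sp in ("A", "B"):
            counts.append(
                sum(1 for s in truth.gene_species.values() if s == sp)
            )
    counts = np.asarray(counts, float)
    expected = math.exp(lam * T)
    se = counts.std(ddof=1) / math.sqrt(len(counts))
    assert abs(counts.mean() - expected) < 3 * se


def test_pure_death_leaves_zero_or_one_copy(species_tree):
    for seed in range(20):
        params = SimParams(dup_rate=0.0, loss_rate=0.6, seed=seed)
        _, truth = simulate_family(species_tree, params)
        per_species = {}
        for sp in truth.gene_species.values():
            per_species[sp] = per_species.get(sp, 0) + 1
        assert all(v == 1 for v in per_species.values())


def test_extinct_family_is_explicit(species_tree):
    params = SimParams(dup_rate=0.0, loss_rate=50.0, seed=0)
    tree, truth = simulate_family(species_tree, params)
    assert tree is None
    assert truth.empty
    assert truth.gene_species == {}


def test_same_seed_reproduces_everything(species_tree):
    params = SimParams(dup_rate=0.4, loss_rate=0.1, seed=11)
    t1, truth1 = simulate_family(species_tree, params)
    t2, truth2 = simulate_family(species_tree, params)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
    assert truth1.to_json() == truth2.to_json()
    s1 = synthetic.evolve_sequences(t1, params)
    s2 = synthetic.evolve_sequences(t2, params)
    assert s1 == s2
    l1, c1 = synthetic.place_loci(truth1.placement_input(), params)
    l2, c2 = synthetic.place_loci(truth2.placement_input(), params)
    assert l1 == l2 and c1 == c2
    e1 = synthetic.simulate_expression(truth1.categories, params)
    e2 = synthetic.simulate_expression(truth2.categories, params)
    assert e1.equals(e2)


def test_wave_multiplies_duplication_rate():
    stree = SpeciesTree.from_newick("(A:1,B:1)R;")
    plain = wave = 0
    for seed in range(150):
        p0 = SimParams(dup_rate=0.3, loss_rate=0.0, seed=seed)
        _, t0 = simulate_family(stree, p0)
        p1 = SimParams(
            dup_rate=0.3,
            loss_rate=0.0,
            waves=(Wave("A", 8.0, 0.5),),
            seed=seed,
        )
        _, t1 = simulate_family(stree, p1)
        plain += len(t0.events["A"].duplications)
        wave += len(t1.events["A"].duplications)
    assert wave > 2 * plain


# -- sequences ------------------------------------------------------------


def test_zero_branch_lengths_give_identical_sequences():
    tree = two_leaf_tree("a", "b", 0.0, 0.0)
    params = SimParams(seed=3)
    seqs = synthetic.evolve_sequences(tree, params)
    assert seqs["a"] == seqs["b"]
    assert len(seqs["a"]) == params.n_codons * 3


def test_no_stop_codons_ever():
    tree = two_leaf_tree("a", "b", 1.5, 1.5)
    params = SimParams(
        n_codons=300, regions=(), background_omega=2.0, seed=9
    )
    seqs = synthetic.evolve_sequences(tree, params)
    for s in seqs.values():
        for i in range(0, len(s), 3):
            assert s[i: i + 3] not in synthetic.STOP_CODONS


def test_region_beyond_cds_is_an_error():
    tree = two_leaf_tree("a", "b", 0.1, 0.1)
    params = SimParams(
        n_codons=100, regions=(Region("big", 0, 150, 1.0),), seed=0
    )
    with pytest.raises(ValueError, match="exceeds"):
        synthetic.evolve_sequences(tree, params)


def test_region_omega_ordering_monte_carlo():
    """Purifying region estimates below 1 below positive region (50 reps)."""
    from famwave.kaks import region_kaks

    tree = two_leaf_tree("a", "b", 0.15, 0.15)
    ordered = 0
    n = 50
    for seed in range(n):
        params = SimParams(
            n_codons=210,
            regions=(Region("A", 0, 105, 0.2), Region("B", 105, 210, 2.0)),
            seed=seed,
        )
        seqs = synthetic.evolve_sequences(tree, params)
        ra = region_kaks(seqs["a"], seqs["b"], (0, 105))
        rb = region_kaks(seqs["a"], seqs["b"], (105, 210))
        if ra.ratio_defined and rb.ratio_defined and ra.ratio < rb.ratio:
            ordered += 1
    assert ordered >= int(0.9 * n)


# -- loci -----------------------------------------------------------------


def test_single_gene_family_yields_one_locus_no_clusters():
    params = SimParams(seed=0)
    loci, clusters = synthetic.place_loci({"A": [("A_g001", None)]}, params)
    assert len(loci) == 1 and clusters == []


def test_tandem_probability_zero_yields_no_clusters():
    from famwave.tandem import find_tandem_clusters

    params = SimParams(tandem_prob=0.0, seed=1)
    genes = {"A": [("g1", None), ("g2", "g1"), ("g3", "g2"), ("g4", "g1")]}
    loci, clusters = synthetic.place_loci(genes, params)
    assert clusters == []
    assert find_tandem_clusters(loci) == []


def test_empty_gene_list_rejected():
    with pytest.raises(ValueError):
        synthetic.place_loci({}, SimParams(seed=0))


# -- expression -----------------------------------------------------------


def test_expression_requires_positive_sigma():
    with pytest.raises(ValueError):
        SimParams(expr_sigma=0.0)


def test_expression_needs_two_samples():
    with pytest.raises(ValueError):
        synthetic.simulate_expression({"g": "stable"}, SimParams(seed=0), n_samples=1)


def test_expression_power_at_large_delta():
    """delta = 3 sigma with n >= 10 per group rejects nearly always."""
    from famwave.expression import ExpressionMatrix, group_mean_test

    cats = {f"s{i}": "stable" for i in range(12)}
    cats.update({f"u{i}": "unstable" for i in range(12)})
    rejected = 0
    n = 60
    for seed in range(n):
        params = SimParams(expr_delta=3.0, expr_sigma=1.0, seed=seed)
        df = synthetic.simulate_expression(cats, params, n_samples=12)
        _, p = group_mean_test(ExpressionMatrix(df, log2=True), cats)
        if p < 0.05:
            rejected += 1
    assert rejected > 0.95 * n
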
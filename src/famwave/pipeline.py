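"""End-to-end drivers: simulate a multi-family study, infer the phylogeny,
classify genes, and score recovery against ground truth.

The study generator emulates the statistical structure of a large F-box
subfamily screen: several independent gene families (deeply diverged from
each other, hence unresolvable deep structure) where each family is either
conserved across species (one ortholog per species: stable), a
species-specific expansion (unstable paralogs), or a lone gene (singleton),
plus a single outgroup gene in the alga used for rooting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import clades, phylo, synthetic
from .trees import SpeciesTree, default_species_tree

__all__ = [
    "StudyData",
    "simulate_study",
    "classify_study",
    "two_leaf_tree",
    "PUBLISHED_FBA_COUNTS",
    "published_tally",
]

_HEAVY_LOSS = 80.0  # per-branch loss rate that guarantees extinction off-path


def _confine_to(stree: SpeciesTree, species: str) -> dict:
    """Loss-rate dict exterminating the family everywhere but on the
    root-to-``species`` path."""
    rates = {"default": _HEAVY_LOSS}
    for node in stree.path_to_root(species):
        rates[node] = 0.0
    return rates


@dataclass
class StudyData:
    species_tree: SpeciesTree
    cds: dict[str, str]
    proteins: dict[str, str]
    alignment: dict[str, str]  # padded: common block + family-specific block
    species_map: dict[str, str]
    true_categories: dict[str, str]
    family_of: dict[str, str]
    outgroup_gene: str
    families: dict[str, tuple[dendropy.Tree, synthetic.SimTruth]] = field(
        default_factory=dict
    )


def simulate_study(
    seed: int = 0,
    n_codons: int = 150,
    common_codons: int = 40,
    stable_species_sets: int = 7,
    unstable_hosts: tuple[str, ...] = ("Atha", "Osat", "Ptri", "Atha"),
    singleton_hosts: tuple[str, ...] = ("Smoe", "Vvin", "Sbic"),
    expansion_rate: float = 6.0,
    kappa: float = 2.0,
    time_scale: float = 0.12,
    stem_length: float = 1.2,
    domain_omega: float = 0.4,
) -> StudyData:
    """Simulate a gene set with known stable/unstable/singleton structure.

    Families are mutually independent (independent root sequences), so
    between-family divergence is saturated while within-family divergence
    follows the species tree -- the regime in which supported clades are
    exactly the families.  True categories derive from each family's
    realised species span.

    The study alignment mimics a multi-domain superfamily alignment: the
    first ``common_codons`` columns are a homologous, conserved N-terminal
    domain shared by all families (evolved from one ancestral domain with
    short family stems, under purifying selection), while each family's
    C-terminal target domain is family-specific and occupies its own
    column block with gaps elsewhere.  Cross-family distances therefore
    rest on the short, clock-like common domain alone: they are all nearly
    equal, so the deep backbone is an unresolved star that earns little
    bootstrap support -- the regime of real superfamily trees -- while
    families themselves are crisply supported by their private domains.
    """
    stree = default_species_tree()
    regions = (
        synthetic.Region("fbox", 0, common_codons, domain_omega),
        synthetic.Region("cterm", common_codons, n_codons, 1.2),
    )
    base = int(seed) % (2**31 - 100000)
    study_rng = np.random.default_rng([base, 9999])
    n_sense = len(synthetic.SENSE_CODONS)
    shared_domain = study_rng.integers(0, n_sense, size=common_codons)
    fam_idx = 0
    cds: dict[str, str] = {}
    species_map: dict[str, str] = {}
    true_cat: dict[str, str] = {}
    family_of: dict[str, str] = {}
    families: dict[str, tuple] = {}
    outgroup_gene = None

    def add_family(params: synthetic.SimParams, fam: str):
        tree, truth = synthetic.simulate_family(stree, params)
        if truth.empty:
            return
        domain = synthetic.mutate_codons(
            shared_domain, stem_length, params, regions[0].omega, study_rng
        )
        specific = study_rng.integers(0, n_sense, size=n_codons - common_codons)
        root = np.concatenate([domain, specific])
        # sequence divergence accrues at time_scale substitutions per unit
        # of species-tree time (families are tight, the backbone is not)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * time_scale
        seqs = synthetic.evolve_sequences(tree, params, root_codons=root)
        for gene, seq in seqs.items():
            new = f"{gene}{fam}"
            cds[new] = seq
            species_map[new] = truth.gene_species[gene]
            true_cat[new] = truth.categories[gene]
            family_of[new] = fam
        families[fam] = (tree, truth)

    # conserved families: one ortholog per land-plant species
    for _ in range(stable_species_sets):
        fam_idx += 1
        params = synthetic.SimParams(
            dup_rate=0.0,
            loss_rate={"default": 0.0, "Cocc": _HEAVY_LOSS},
            n_codons=n_codons,
            regions=regions,
            kappa=kappa,
            seed=base + fam_idx,
        )
        add_family(params, f"F{fam_idx:02d}")

    # species-specific expansions: burst on one terminal branch
    for host in unstable_hosts:
        fam_idx += 1
        params = synthetic.SimParams(
            dup_rate={host: expansion_rate},
            loss_rate=_confine_to(stree, host),
            n_codons=n_codons,
            regions=regions,
            kappa=kappa,
            seed=base + fam_idx,
        )
        add_family(params, f"F{fam_idx:02d}")

    # lone genes
    for host in singleton_hosts:
        fam_idx += 1
        params = synthetic.SimParams(
            dup_rate=0.0,
            loss_rate=_confine_to(stree, host),
            n_codons=n_codons,
            regions=regions,
            kappa=kappa,
            seed=base + fam_idx,
        )
        add_family(params, f"F{fam_idx:02d}")

    # the algal outgroup gene used for rooting
    fam_idx += 1
    params = synthetic.SimParams(
        dup_rate=0.0,
        loss_rate=_confine_to(stree, "Cocc"),
        n_codons=n_codons,
        regions=regions,
        kappa=kappa,
        seed=base + fam_idx,
    )
    add_family(params, f"F{fam_idx:02d}")
    for gene, sp in species_map.items():
        if sp == "Cocc":
            outgroup_gene = gene

    from .io import translate_cds

    proteins = translate_cds(cds)
    # padded study alignment: common block, then one block per family
    fam_ids = sorted({f for f in family_of.values()})
    block = n_codons - common_codons
    width = common_codons + block * len(fam_ids)
    fam_offset = {
        f: common_codons + i * block for i, f in enumerate(fam_ids)
    }
    alignment = {}
    for gene, prot in proteins.items():
        off = fam_offset[family_of[gene]]
        alignment[gene] = (
            prot[:common_codons]
            + "-" * (off - common_codons)
            + prot[common_codons:]
            + "-" * (width - off - block)
        )
    return StudyData(
        species_tree=stree,
        cds=cds,
        proteins=proteins,
        alignment=alignment,
        species_map=species_map,
        true_categories=true_cat,
        family_of=family_of,
        outgroup_gene=outgroup_gene,
        families=families,
    )


def classify_study(
    study: StudyData,
    n_boot: int = 1000,
    seed: int = 0,
    min_support: float = 40,
) -> tuple[clades.CladeAssignment, float]:
    """Bootstrap NJ consensus -> outgroup rooting -> clade classification.

    Returns the classified assignment and the fraction of non-outgroup
    genes whose inferred category matches the simulated truth.
    """
    aln = phylo.ProteinAlignment.from_dict(study.alignment)
    consensus = phylo.bootstrap_consensus(aln, n_reps=n_boot, seed=seed)
    rooted = phylo.root_with_outgroup(consensus, study.outgroup_gene)
    ca = clades.extract_supported_clades(
        rooted, min_support=min_support, outgroup=study.outgroup_gene
    )
    ca = clades.classify_genes(ca, study.species_map)
    scored = [
        g for g in study.true_categories if g != study.outgroup_gene
    ]
    hits = sum(
        1 for g in scored if ca.categories.get(g) == study.true_categories[g]
    )
    return ca, hits / len(scored)


def two_leaf_tree(
    name_a: str, name_b: str, t_a: float, t_b: float
) -> dendropy.Tree:
    """Two-gene tree (an ortholog pair) for sequence simulation."""
    tns = dendropy.TaxonNamespace([name_a, name_b])
    root = dendropy.Node()
    for name, t in ((name_a, t_a), (name_b, t_b)):
        child = dendropy.Node(taxon=tns.get_taxon(name))
        child.edge.length = t
        root.add_child(child)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


def write_bundle(
    out_dir, params: synthetic.SimParams, stree: SpeciesTree | None = None
) -> int:
    """Simulate one family and write the fixture bundle.

    Files: proteins.faa, cds.fna, genetree.nwk, speciestree.nwk, loci.bed,
    expression.tsv (raw intensities, 2**log2-value) and truth.json.
    Returns the number of extant genes (0 for an extinct family, in which
    case only speciestree.nwk and truth.json are written).
    """
    import json
    from pathlib import Path

    from . import io as fio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stree is None:
        stree = default_species_tree()
    tree, truth = synthetic.simulate_family(stree, params)
    (out / "speciestree.nwk").write_text(stree.to_newick() + "\n")
    truth_doc = json.loads(truth.to_json())
    if truth.empty:
        truth_doc["tandem_clusters"] = []
        (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
        return 0
    cds = synthetic.evolve_sequences(tree, params)
    loci, clusters = synthetic.place_loci(truth.placement_input(), params)
    expr = synthetic.simulate_expression(
        truth.categories, params, clade_map=truth.gene_clade
    )
    fio.write_fasta(cds, out / "cds.fna")
    fio.write_fasta(fio.translate_cds(cds), out / "proteins.faa")
    fio.write_gene_tree(tree, out / "genetree.nwk")
    fio.write_bed(loci, out / "loci.bed")
    fio.write_expression_tsv((2.0 ** expr).round(4), out / "expression.tsv")
    truth_doc["tandem_clusters"] = [sorted(c) for c in clusters]
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    return len(truth.gene_species)


# -- published per-species classification (study input data) --------------

#: Per-species (unstable, stable, singleton) counts for the eight species
#: of the FBA-protein screen; used for bookkeeping summaries.
PUBLISHED_FBA_COUNTS: dict[str, tuple[int, int, int]] = {
    "Arabidopsis thaliana": (203, 4, 4),
    "Vitis vinifera": (2, 3, 1),
    "Populus trichocarpa": (9, 30, 8),
    "Oryza sativa": (2, 36, 1),
    "Sorghum bicolor": (0, 34, 3),
    "Selaginella moellendorffii": (0, 1, 2),
    "Physcomitrella patens": (0, 7, 0),
    "Coccomyxa sp. C-169": (0, 0, 1),
}


def published_tally(
    counts: dict[str, tuple[int, int, int]] | None = None,
) -> pd.DataFrame:
    """Expand per-species category counts to genes and tally them.

    Routes the published (or user-supplied) counts through
    :func:`famwave.clades.tally_by_species` so totals and percentages are
    computed by the same code path as simulated data.
    """
    if counts is None:
        counts = PUBLISHED_FBA_COUNTS
    categories: dict[str, str] = {}
    species_map: dict[str, str] = {}
    for sp, (n_unstable, n_stable, n_singleton) in counts.items():
        for cat, n in (
            ("unstable", n_unstable),
            ("stable", n_stable),
            ("singleton", n_singleton),
        ):
            for i in range(n):
                gene = f"{sp}|{cat}|{i}"
                categories[gene] = cat
                species_map[gene] = sp
    return clades.tally_by_species(categories, species_map)
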
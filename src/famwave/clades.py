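"""Supported-clade extraction and stable/unstable/singleton classification.

A rooted gene tree with bootstrap supports is decomposed into maximal
supported clades: walking from the root, the first node on any root-to-leaf
path whose support is strictly greater than ``min_support`` and which holds
at least two leaves defines a clade; its descendants are not split further.
Leaves covered by no such node are singletons.  Clades spanning two or more
species are evolutionarily *stable*, single-species clades of two or more
genes are *unstable* (lineage-specific expansions), and uncovered genes are
*singletons*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import pandas as pd

__all__ = [
    "Clade",
    "CladeAssignment",
    "extract_supported_clades",
    "classify_genes",
    "tally_by_species",
    "apply_clade_overrides",
]

CATEGORIES = ("unstable", "stable", "singleton")


@dataclass(frozen=True)
class Clade:
    clade_id: str
    genes: frozenset
    support: float
    species: frozenset = frozenset()


@dataclass
class CladeAssignment:
    clades: dict[str, Clade]
    singletons: frozenset
    min_support: float
    outgroup: str | None = None
    categories: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> set:
        out = set(self.singletons)
        for c in self.clades.values():
            out |= c.genes
        return out

    def clade_of(self) -> dict[str, str]:
        out = {}
        for cid, c in self.clades.items():
            for g in c.genes:
                out[g] = cid
        for g in self.singletons:
            out[g] = f"singleton:{g}"
        return out


def _support_of(node: dendropy.Node) -> float:
    if node.label is None:
        return 0.0
    try:
        return float(node.label)
    except ValueError:
        return 0.0


def extract_supported_clades(
    tree: dendropy.Tree, min_support: float = 40, outgroup: str | None = None
) -> CladeAssignment:
    """Maximal supported clades of a rooted gene tree.

    Missing supports count as 0; the threshold is strict (a node with
    support exactly ``min_support`` does not define a clade).  If
    ``outgroup`` is given that leaf is excluded before extraction.
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    work = tree
    if outgroup is not None:
        if outgroup not in leaves:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        work = tree.clone(depth=1)
        taxon = work.taxon_namespace.get_taxon(outgroup)
        work.prune_taxa([taxon], suppress_unifurcations=True)

    clades: dict[str, Clade] = {}
    singles: set[str] = set()
    counter = [0]

    def visit(node: dendropy.Node):
        if node.is_leaf():
            singles.add(node.taxon.label)
            return
        n_leaves = sum(1 for _ in node.leaf_iter())
        if _support_of(node) > min_support and n_leaves >= 2:
            counter[0] += 1
            genes = frozenset(l.taxon.label for l in node.leaf_iter())
            cid = f"c{counter[0]:02d}"
            clades[cid] = Clade(cid, genes, _support_of(node))
            return
        for child in node.child_nodes():
            visit(child)

    visit(work.seed_node)
    return CladeAssignment(
        clades=clades,
        singletons=frozenset(singles),
        min_support=min_support,
        outgroup=outgroup,
    )


def classify_genes(
    ca: CladeAssignment, species_map: dict[str, str]
) -> CladeAssignment:
    """Fill in per-gene categories from clade species spans."""
    for g in ca.genes:
        if g not in species_map:
            raise ValueError(f"gene {g!r} has no species mapping")
    categories: dict[str, str] = {}
    clades: dict[str, Clade] = {}
    for cid, c in ca.clades.items():
        species = frozenset(species_map[g] for g in c.genes)
        cat = "stable" if len(species) >= 2 else "unstable"
        for g in c.genes:
            categories[g] = cat
        clades[cid] = replace(c, species=species)
    for g in ca.singletons:
        categories[g] = "singleton"
    if ca.outgroup is not None:
        categories[ca.outgroup] = "singleton"
    return CladeAssignment(
        clades=clades,
        singletons=ca.singletons,
        min_support=ca.min_support,
        outgroup=ca.outgroup,
        categories=categories,
    )


def tally_by_species(
    ca_or_categories, species_map: dict[str, str]
) -> pd.DataFrame:
    """Per-species category counts with totals and rounded percentages.

    Accepts a classified :class:`CladeAssignment` or a plain
    ``{gene: category}`` mapping.  The outgroup (if any) appears as its own
    singleton row.
    """
    if isinstance(ca_or_categories, CladeAssignment):
        categories = ca_or_categories.categories
    else:
        categories = dict(ca_or_categories)
    if not categories:
        raise ValueError("no categorised genes")
    rows: dict[str, dict[str, int]] = {}
    for g, cat in categories.items():
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r} for gene {g!r}")
        sp = species_map[g]
        rows.setdefault(sp, {c: 0 for c in CATEGORIES})
        rows[sp][cat] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df = df[list(CATEGORIES)]
    df["total"] = df.sum(axis=1)
    for c in CATEGORIES:
        df[f"pct_{c}"] = (100.0 * df[c] / df["total"]).round().astype(int)
    return df.sort_index()


def apply_clade_overrides(
    ca: CladeAssignment, overrides: dict[str, str]
) -> CladeAssignment:
    """Re-assign genes to curator-named clades (escape hatch for cases the
    support rule cannot reproduce).  Overridden genes leave their original
    clade/singleton slot and join (or create) the named clade; supports of
    created clades are reported as NaN."""
    clade_genes: dict[str, set] = {cid: set(c.genes) for cid, c in ca.clades.items()}
    supports = {cid: c.support for cid, c in ca.clades.items()}
    singles = set(ca.singletons)
    for gene, cid in overrides.items():
        for members in clade_genes.values():
            members.discard(gene)
        singles.discard(gene)
        clade_genes.setdefault(cid, set()).add(gene)
        supports.setdefault(cid, float("nan"))
    clades = {}
    for cid, members in clade_genes.items():
        if len(members) >= 2:
            clades[cid] = Clade(cid, frozenset(members), supports[cid])
        else:
            singles |= members
    return CladeAssignment(
        clades=clades,
        singletons=frozenset(singles),
        min_support=ca.min_support,
        outgroup=ca.outgroup,
    )
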
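"""Species trees with named ancestor nodes.

A :class:`SpeciesTree` is a rooted tree whose leaves are species and whose
internal nodes carry ancestor labels (``N0``, ``N1``, ...).  It is the
coordinate system for gain/loss reconstruction and for the gene-family
simulator: branch lengths are in arbitrary time units (for the bundled
default tree, roughly proportional to divergence time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["SpeciesTree", "DEFAULT_SPECIES_TREE_NEWICK", "default_species_tree"]

#: Eight-species analysis tree: one green alga outgroup (Cocc), a bryophyte
#: (Ppat) and a lycophyte (Smoe), two monocots (Osat, Sbic) and three eudicots
#: (Vvin, Ptri, Atha).  Ancestor labels: N0 Chloroplastida, N1 land plants,
#: NV vascular plants, N2 angiosperms, N3 monocots, N4 eudicots, ND rosid
#: crown.  Depths are ultrametric with a root-to-tip height of 1.05.
DEFAULT_SPECIES_TREE_NEWICK = (
    "(Cocc:1.05,(Ppat:0.85,(Smoe:0.65,((Osat:0.325,Sbic:0.325)N3:0.125,"
    "((Ptri:0.2,Atha:0.2)ND:0.125,Vvin:0.325)N4:0.125)N2:0.2)NV:0.2)N1:0.2)N0;"
)


@dataclass
class SpeciesNode:
    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    length: float = 0.0  # length of the edge above this node

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted species tree with uniquely named nodes.

    Invariants enforced on construction: exactly one root, unique node names,
    every internal node has at least two children.
    """

    def __init__(self, nodes: dict[str, SpeciesNode], root: str):
        self.nodes = nodes
        self.root = root
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        nodes: dict[str, SpeciesNode] = {}
        counter = 0
        names: dict[int, str] = {}
        for nd in tree.preorder_node_iter():
            if nd.taxon is not None:
                name = nd.taxon.label
            elif nd.label:
                name = nd.label
            else:
                name = f"_anc{counter}"
                counter += 1
            names[id(nd)] = name
        root_name = None
        for nd in tree.preorder_node_iter():
            name = names[id(nd)]
            parent = names[id(nd.parent_node)] if nd.parent_node else None
            if parent is None:
                root_name = name
            if name in nodes:
                raise ValueError(f"duplicate node name {name!r}")
            nodes[name] = SpeciesNode(
                name=name,
                parent=parent,
                length=float(nd.edge.length or 0.0),
            )
            if parent is not None:
                nodes[parent].children.append(name)
        return cls(nodes, root_name)

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0].name != self.root:
            raise ValueError("species tree must have exactly one root")
        for n in self.nodes.values():
            if n.children and len(n.children) < 2:
                raise ValueError(f"internal node {n.name!r} has <2 children")

    # -- queries ----------------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        return [n.name for n in self._preorder() if n.is_leaf]

    @property
    def internal(self) -> list[str]:
        return [n.name for n in self._preorder() if not n.is_leaf]

    def _preorder(self):
        stack = [self.nodes[self.root]]
        while stack:
            nd = stack.pop()
            yield nd
            for c in reversed(nd.children):
                stack.append(self.nodes[c])

    def preorder(self) -> list[str]:
        return [n.name for n in self._preorder()]

    def branches(self) -> list[tuple[str, str, float]]:
        """All (parent, child, length) edges in preorder."""
        return [
            (n.parent, n.name, n.length)
            for n in self._preorder()
            if n.parent is not None
        ]

    def path_to_root(self, name: str) -> list[str]:
        """Node names from ``name`` up to and including the root."""
        if name not in self.nodes:
            raise KeyError(f"unknown node {name!r}")
        out = [name]
        while self.nodes[out[-1]].parent is not None:
            out.append(self.nodes[out[-1]].parent)
        return out

    def mrca(self, names) -> str:
        """Most recent common ancestor of a non-empty set of node names."""
        names = list(names)
        if not names:
            raise ValueError("empty name set")
        for nm in names:
            if nm not in self.nodes:
                raise KeyError(f"unknown species {nm!r}")
        paths = [self.path_to_root(nm) for nm in names]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common node = first along any path from the leaf upward
        for nm in paths[0]:
            if nm in common:
                return nm
        raise AssertionError("unreachable: root is always common")

    def leaves_under(self, name: str) -> set[str]:
        out = set()
        stack = [name]
        while stack:
            nd = self.nodes[stack.pop()]
            if nd.is_leaf:
                out.add(nd.name)
            else:
                stack.extend(nd.children)
        return out

    def to_newick(self) -> str:
        def fmt(name: str) -> str:
            nd = self.nodes[name]
            if nd.is_leaf:
                core = name
            else:
                core = "(" + ",".join(fmt(c) for c in nd.children) + ")" + name
            if nd.parent is None:
                return core
            return f"{core}:{nd.length:g}"

        return fmt(self.root) + ";"


def default_species_tree() -> SpeciesTree:
    """The bundled eight-species tree (see module docstring)."""
    return SpeciesTree.from_newick(DEFAULT_SPECIES_TREE_NEWICK)
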
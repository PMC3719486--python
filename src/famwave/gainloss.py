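"""Dollo reconstruction of ancestral gene counts and per-branch gains/losses.

Each clade is treated as a character gained exactly once, at the most
recent common ancestor of the species it spans, and present (one ancestral
copy) at every node on the paths from that origin down to each retaining
species; it is lost on any branch where it disappears.  Ancestral node
counts are the number of clades present; terminal branches additionally
absorb within-species copy-number expansion, so that the conservation
identity ``count(child) = count(parent) + gains - losses`` holds on every
branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .trees import SpeciesTree

__all__ = ["FamilyHistory", "map_clade_origin", "reconstruct_history"]


@dataclass
class FamilyHistory:
    counts: dict[str, int]            # node -> ancestral/extant gene count
    gains: dict[str, int]             # child node -> gains on its branch
    losses: dict[str, int]            # child node -> losses on its branch
    origins: dict[str, str]           # clade id -> origin node

    def as_frame(self, stree: SpeciesTree) -> pd.DataFrame:
        rows = []
        for parent, child, _ in stree.branches():
            rows.append(
                {
                    "parent": parent,
                    "child": child,
                    "count_parent": self.counts[parent],
                    "count_child": self.counts[child],
                    "gains": self.gains[child],
                    "losses": self.losses[child],
                }
            )
        return pd.DataFrame(rows)

    def total_gains(self) -> int:
        return sum(self.gains.values())

    def total_losses(self) -> int:
        return sum(self.losses.values())


def map_clade_origin(species: set, stree: SpeciesTree) -> str:
    """Origin node of a clade = MRCA of its species (the leaf itself for a
    single-species clade)."""
    species = set(species)
    if not species:
        raise ValueError("clade species set is empty")
    leaves = set(stree.leaves)
    unknown = species - leaves
    if unknown:
        raise ValueError(f"unknown species {sorted(unknown)}")
    return stree.mrca(species)


def reconstruct_history(
    clade_species: dict[str, set],
    extant_counts: dict[str, int],
    stree: SpeciesTree,
) -> FamilyHistory:
    """Dollo gain/loss reconstruction.

    ``clade_species`` maps clade id -> species retaining the clade
    (singletons are one-gene clades).  ``extant_counts`` gives observed
    copy numbers per species; within-species expansion beyond one copy per
    clade is attributed to the terminal branch.
    """
    origins = {cid: map_clade_origin(sp, stree) for cid, sp in clade_species.items()}

    # presence: nodes on the union of paths origin -> retaining leaf
    present: dict[str, set] = {name: set() for name in stree.preorder()}
    for cid, species in clade_species.items():
        origin = origins[cid]
        for sp in species:
            path = stree.path_to_root(sp)
            for node in path[: path.index(origin) + 1]:
                present[node].add(cid)

    counts: dict[str, int] = {}
    for name in stree.preorder():
        if stree.nodes[name].is_leaf:
            n_clades = len(present[name])
            n = extant_counts.get(name, 0)
            if n < n_clades:
                raise ValueError(
                    f"extant count {n} for {name!r} is below its {n_clades} clades"
                )
            counts[name] = n
        else:
            counts[name] = len(present[name])

    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    for parent, child, _ in stree.branches():
        if stree.nodes[child].is_leaf:
            inherited = {
                cid for cid in present[parent] if child in clade_species[cid]
            }
            gains[child] = counts[child] - len(inherited)
            losses[child] = len(present[parent] - inherited)
        else:
            gains[child] = sum(1 for cid, o in origins.items() if o == child)
            losses[child] = len(present[parent] - present[child])
        if counts[child] != counts[parent] + gains[child] - losses[child]:
            raise AssertionError(
                f"conservation identity violated on branch {parent}->{child}"
            )
    return FamilyHistory(counts=counts, gains=gains, losses=losses, origins=origins)
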
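"""File I/O: FASTA, Newick with bootstrap labels, BED, TSV tables."""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd

from .synthetic import GeneLocus

__all__ = [
    "read_fasta",
    "write_fasta",
    "translate_cds",
    "read_gene_tree",
    "write_gene_tree",
    "read_bed",
    "write_bed",
    "read_species_map",
    "write_species_map",
    "read_expression_tsv",
    "write_expression_tsv",
]


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def translate_cds(cds: dict[str, str]) -> dict[str, str]:
    """Translate gap-free CDS to protein (standard code)."""
    from Bio.Seq import Seq

    return {name: str(Seq(seq).translate()).rstrip("*") for name, seq in cds.items()}


def read_gene_tree(path_or_string, rooted: bool | None = None) -> dendropy.Tree:
    """Read Newick; internal node labels are bootstrap supports."""
    src = str(path_or_string)
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if Path(src).exists():
        tree = dendropy.Tree.get(path=src, **kwargs)
    else:
        tree = dendropy.Tree.get(data=src, **kwargs)
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def write_gene_tree(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
    )


def read_bed(path) -> list[GeneLocus]:
    """BED (0-based half-open): chrom, start, end, name[, score, strand]."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            loci.append(GeneLocus(name, chrom, start, end, strand))
    return loci


def write_bed(loci: list[GeneLocus], path) -> None:
    with open(path, "w") as fh:
        for l in sorted(loci, key=lambda x: (x.chrom, x.start)):
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.gene}\t0\t{l.strand}\n")


def read_species_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "species"])
    return dict(zip(df["gene"], df["species"]))


def write_species_map(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene, sp in sorted(mapping.items()):
            fh.write(f"{gene}\t{sp}\n")


def read_expression_tsv(path):
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
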
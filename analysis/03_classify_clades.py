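"""Classify genes into stable / unstable / singleton categories from the
bootstrap tree and tabulate them per species, alongside the published
per-species table for comparison.

Reads results/genetree.nwk etc. if step 02 ran with the same --out;
otherwise regenerates the study from the seed.
"""

import argparse
from pathlib import Path

from famwave import io as fio
from famwave.clades import classify_genes, extract_supported_clades, tally_by_species
from famwave.pipeline import classify_study, published_tally, simulate_study


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--boot", type=int, default=1000)
    ap.add_argument("--min-support", type=float, default=40)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = simulate_study(seed=args.seed)
    tree_path = args.out / "genetree.nwk"
    if tree_path.exists():
        tree = fio.read_gene_tree(tree_path, rooted=True)
        ca = extract_supported_clades(
            tree, min_support=args.min_support, outgroup=study.outgroup_gene
        )
        ca = classify_genes(ca, study.species_map)
        scored = [g for g in study.true_categories if g != study.outgroup_gene]
        acc = sum(
            ca.categories.get(g) == study.true_categories[g] for g in scored
        ) / len(scored)
    else:
        ca, acc = classify_study(
            study, n_boot=args.boot, seed=args.seed, min_support=args.min_support
        )

    tally = tally_by_species(ca, study.species_map)
    tally.to_csv(args.out / "classification_tally.tsv", sep="\t")
    print(f"{len(ca.clades)} supported clades, {len(ca.singletons)} singletons")
    print(f"category recovery vs simulation truth: {100 * acc:.1f}%")
    print(tally.to_string())

    pub = published_tally()
    pub.to_csv(args.out / "published_tally.tsv", sep="\t")
    print(
        "\npublished screen bookkeeping: "
        f"A. thaliana total {pub.loc['Arabidopsis thaliana', 'total']} "
        f"({pub.loc['Arabidopsis thaliana', 'pct_unstable']}% unstable); "
        f"stable genes across species: {pub['stable'].sum()}"
    )


if __name__ == "__main__":
    main()
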
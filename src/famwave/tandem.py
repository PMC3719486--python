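"""Tandem-duplication cluster detection from gene coordinates.

Two genes are tandemly arranged when the intergenic gap between them
(next start minus previous end, on the same chromosome) is strictly less
than ``max_gap`` (default 10 kb).  Chains link transitively: A-B-C form
one cluster even if A and C are farther apart (single linkage).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthetic import GeneLocus

__all__ = ["GeneLocus", "find_tandem_clusters", "tandem_stats"]

DEFAULT_MAX_GAP = 10_000


def find_tandem_clusters(
    loci: list[GeneLocus], max_gap: int = DEFAULT_MAX_GAP
) -> list[frozenset]:
    """Single-linkage tandem clusters (>= 2 genes) per chromosome.

    Overlapping loci count as gap 0; the threshold is strict (a gap of
    exactly ``max_gap`` does not link).  Output order is deterministic
    (by chromosome, then position) and independent of input order.
    """
    if not loci:
        raise ValueError("locus list is empty")
    ids = [l.gene for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in loci")
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    clusters = []
    for chrom in sorted(by_chrom):
        chain: list[str] = []
        prev_end: int | None = None
        for l in sorted(by_chrom[chrom], key=lambda x: (x.start, x.end, x.gene)):
            if prev_end is not None and max(0, l.start - prev_end) < max_gap:
                chain.append(l.gene)
                prev_end = max(prev_end, l.end)
            else:
                if len(chain) >= 2:
                    clusters.append(frozenset(chain))
                chain = [l.gene]
                prev_end = l.end
        if len(chain) >= 2:
            clusters.append(frozenset(chain))
    return clusters


def tandem_stats(
    clusters: list[frozenset],
    categories: dict[str, str],
    clade_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-category tandem fractions, plus the cross-clade share.

    For each category: genes in clusters / genes, with the percentage
    rounded to the nearest integer.  When ``clade_map`` is given, the
    report includes the fraction of clustered genes whose cluster spans
    two or more sequence clades.
    """
    clustered = set().union(*clusters) if clusters else set()
    for g in clustered:
        if g not in categories:
            raise ValueError(f"clustered gene {g!r} has no category")
    rows = []
    cats = sorted(set(categories.values()))
    for cat in cats:
        genes = [g for g, c in categories.items() if c == cat]
        n_clustered = sum(1 for g in genes if g in clustered)
        rows.append(
            {
                "category": cat,
                "clustered": n_clustered,
                "total": len(genes),
                "pct": round(100.0 * n_clustered / len(genes)) if genes else 0,
            }
        )
    df = pd.DataFrame(rows).set_index("category")
    if clade_map is not None:
        cross = 0
        for cl in clusters:
            spans = {clade_map[g] for g in cl if g in clade_map}
            if len(spans) >= 2:
                cross += len(cl)
        df.attrs["cross_clade_fraction"] = (
            cross / len(clustered) if clustered else 0.0
        )
    return df
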
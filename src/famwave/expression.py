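"""Expression preprocessing, UPGMA clustering and clade/expression
concordance.

Intensities are log2-transformed, genes are clustered with average
linkage (UPGMA) on euclidean or correlation (1 - Pearson r) distance, the
stable-vs-unstable mean contrast uses a pooled-variance Student t-test,
and concordance between sequence clades and expression clusters is
measured with the adjusted Rand index plus per-clade co-clustering
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ExpressionMatrix",
    "preprocess_log2",
    "upgma_cluster",
    "Dendrogram",
    "group_mean_test",
    "clade_coherence",
    "CoherenceResult",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with a log2-transform flag."""

    values: pd.DataFrame
    log2: bool = False

    def __post_init__(self):
        if self.values.shape[1] < 2:
            raise ValueError("need at least two samples")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def preprocess_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of positive intensities; refuses to run twice."""
    if m.log2:
        raise ValueError("double transform: matrix is already log2 scaled")
    bad = (m.values <= 0)
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(f"nonpositive intensity at gene {gene!r}, sample {sample!r}")
    return ExpressionMatrix(np.log2(m.values), log2=True)


@dataclass
class Dendrogram:
    """UPGMA dendrogram over genes (scipy linkage encoding).

    ``linkage[:, 2]`` holds the cophenetic merge distances; the ultrametric
    node heights are half of those (two genes at distance d join at height
    d/2).
    """

    labels: list[str]
    linkage: np.ndarray
    metric: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2] / 2.0

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering into k groups (gene -> cluster id)."""
        if k < 1 or k > len(self.labels):
            raise ValueError("k out of range")
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def upgma_cluster(m: ExpressionMatrix, metric: str = "euclidean") -> Dendrogram:
    """Average-linkage clustering of genes.

    ``metric`` is ``euclidean`` or ``correlation`` (1 - Pearson r).  Genes
    are sorted by label first so tie-breaking is deterministic.
    """
    if len(m.genes) < 2:
        raise ValueError("need at least two genes")
    df = m.values.sort_index()
    if metric == "correlation":
        sd = df.std(axis=1, ddof=0)
        flat = sd[sd == 0]
        if len(flat):
            raise ValueError(
                f"zero-variance gene {flat.index[0]!r} with correlation metric"
            )
        d = pdist(df.values, metric="correlation")
    elif metric == "euclidean":
        d = pdist(df.values, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    z = hierarchy.linkage(d, method="average")
    return Dendrogram(labels=list(df.index), linkage=z, metric=metric)


def group_mean_test(
    m: ExpressionMatrix,
    categories: dict[str, str],
    group_a: str = "stable",
    group_b: str = "unstable",
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test on per-gene mean expression, group_a minus group_b.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    means = m.values.mean(axis=1)
    a = means[[g for g in m.genes if categories.get(g) == group_a]]
    b = means[[g for g in m.genes if categories.get(g) == group_b]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two genes")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


@dataclass
class CoherenceResult:
    ari: float
    per_clade: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False


def clade_coherence(
    clade_map: dict[str, str], dendrogram: Dendrogram, k: int
) -> CoherenceResult:
    """Concordance of sequence clades with a k-cluster expression cut.

    Returns the adjusted Rand index between the two partitions and, per
    clade, the fraction of its gene pairs that land in the same expression
    cluster.  A single-clade (or single-cluster) comparison is flagged
    degenerate and its ARI reported as NaN.
    """
    from sklearn.metrics import adjusted_rand_score

    if k < 2 or k > len(dendrogram.labels):
        raise ValueError("k out of range")
    genes = [g for g in dendrogram.labels if g in clade_map]
    if not genes:
        raise ValueError("no genes shared between clades and dendrogram")
    cut = dendrogram.cut(k)
    expr_part = [cut[g] for g in genes]
    clade_part = [clade_map[g] for g in genes]

    per_clade: dict[str, float] = {}
    for cid in sorted(set(clade_part)):
        members = [g for g in genes if clade_map[g] == cid]
        if len(members) < 2:
            continue
        same = total = 0
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                total += 1
                if cut[members[i]] == cut[members[j]]:
                    same += 1
        per_clade[cid] = same / total

    degenerate = len(set(clade_part)) < 2 or len(set(expr_part)) < 2
    ari = float("nan") if degenerate else float(
        adjusted_rand_score(clade_part, expr_part)
    )
    return CoherenceResult(ari=ari, per_clade=per_clade, degenerate=degenerate)
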
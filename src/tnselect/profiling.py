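"""Correlation-threshold clustering of gene phenotypic profiles.

Genes whose fitness fingerprints across many stress/challenge conditions
correlate above a threshold (r > 0.9 by default) are grouped together:
an edge joins two genes when their Pearson correlation exceeds the
threshold and clusters are the connected components of that graph.  An
average-linkage leaf ordering is also emitted for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PhenotypeMatrix",
    "profile_correlation",
    "correlation_cluster",
    "ClusterResult",
    "plot_heatmap",
]


@dataclass
class PhenotypeMatrix:
    """Genes x conditions matrix of per-condition scores (log2 fold changes).

    Missing values are NaN and are pairwise-deleted in correlations.
    """

    values: pd.DataFrame  # index = gene ids, columns = condition labels

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene labels")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate condition labels")

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


def profile_correlation(
    matrix: PhenotypeMatrix, gene_a: str, gene_b: str, *, min_shared: int = 3
) -> float:
    """Pearson r between two genes' profiles over shared observed conditions.

    Returns NaN (missing similarity) when fewer than ``min_shared``
    conditions are observed in both profiles or either has zero variance.
    """
    a = matrix.values.loc[gene_a].to_numpy(dtype=float)
    b = matrix.values.loc[gene_b].to_numpy(dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < min_shared:
        return float("nan")
    a, b = a[mask], b[mask]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class ClusterResult:
    assignments: pd.DataFrame  # gene_id, cluster_id
    correlations: pd.DataFrame  # genes x genes Pearson r
    leaf_order: list[str]  # average-linkage ordering for heatmap rows

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for _, row in self.assignments.iterrows():
            out.setdefault(row["cluster_id"], []).append(row["gene_id"])
        return out


def correlation_cluster(
    matrix: PhenotypeMatrix,
    r_threshold: float = 0.9,
    *,
    linkage_method: str = "single",
    min_shared: int = 3,
) -> ClusterResult:
    """Group genes whose profiles correlate above ``r_threshold``.

    An edge joins genes with r > r_threshold; with the default
    ``single`` linkage behaviour, clusters are the connected components of
    that graph; ``complete`` linkage instead requires every within-cluster
    pair to exceed the threshold.  Cluster ids are the smallest member
    gene_id, so labelling is deterministic and row-order invariant.
    """
    if len(matrix.genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    genes = list(matrix.genes)
    n = len(genes)
    corr = np.full((n, n), np.nan)
    np.fill_diagonal(corr, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            r = profile_correlation(matrix, genes[i], genes[j], min_shared=min_shared)
            corr[i, j] = corr[j, i] = r

    adjacency = np.nan_to_num(corr, nan=-np.inf) > r_threshold
    if linkage_method == "complete":
        components = _complete_linkage_groups(adjacency)
    else:
        components = _connected_components(adjacency)

    assignments = []
    for comp in components:
        label = min(genes[i] for i in comp)
        for i in comp:
            assignments.append({"gene_id": genes[i], "cluster_id": label})
    assign_df = (
        pd.DataFrame(assignments).sort_values("gene_id").reset_index(drop=True)
    )

    # average-linkage dendrogram ordering on correlation distance for display
    if n > 2:
        dist = 1.0 - np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2  # enforce symmetry against float jitter
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        leaf_order = [genes[i] for i in hierarchy.leaves_list(link)]
    else:
        leaf_order = genes
    corr_df = pd.DataFrame(corr, index=genes, columns=genes)
    return ClusterResult(assignments=assign_df, correlations=corr_df, leaf_order=leaf_order)


def plot_heatmap(matrix: PhenotypeMatrix, result: ClusterResult, path=None):
    """Render the profile matrix as a heatmap in dendrogram leaf order.

    Thin display layer over the tested clustering contract; returns the
    matplotlib figure, optionally saving it to ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.values.loc[result.leaf_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * len(matrix.conditions)), max(3, 0.3 * len(ordered)))
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(ordered)), ordered.index)
    ax.set_xticks(range(len(matrix.conditions)), matrix.conditions, rotation=90)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def _connected_components(adjacency: np.ndarray) -> list[list[int]]:
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    components = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.flatnonzero(adjacency[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        components.append(sorted(comp))
    return components


def _complete_linkage_groups(adjacency: np.ndarray) -> list[list[int]]:
    """Greedy complete-linkage grouping: a gene joins a group only if it
    exceeds the threshold with every member."""
    n = adjacency.shape[0]
    groups: list[list[int]] = []
    for i in range(n):
        for grp in groups:
            if all(adjacency[i, j] for j in grp):
                grp.append(i)
                break
        else:
            groups.append([i])
    return groups
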
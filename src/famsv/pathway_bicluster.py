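"""Bi-clustering of the binary gene x pathway membership matrix.

Enriched pathways typically share member genes; hierarchically clustering
both axes of the 0/1 membership matrix reveals blocks of functionally
related pathways and the gene groups driving them.  Each axis is
clustered independently with average linkage over Jaccard distance, and
the dendrograms are cut into a configured number of flat clusters
(defaults: 9 pathway clusters, 8 gene clusters).

Leaves are put in a canonical order (by membership pattern, then name)
before linkage, so the clustering is deterministic and invariant to row
or column permutations of the input — including in the presence of tied
merge heights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger("famsv")


def build_membership(pathways, query_genes) -> pd.DataFrame:
    """Binary genes x pathways membership matrix restricted to the query.

    ``pathways`` is an iterable of objects with ``name`` (or ``term_id``)
    and ``genes``.  All-zero rows and columns are pruned with a log
    message, as they carry no co-membership information.
    """
    cols = {}
    for pw in pathways:
        name = getattr(pw, "name", None) or pw.term_id
        cols[name] = [1 if g in pw.genes else 0 for g in query_genes]
    df = pd.DataFrame(cols, index=list(query_genes), dtype=np.int8)
    empty_rows = df.index[df.sum(axis=1) == 0]
    empty_cols = df.columns[df.sum(axis=0) == 0]
    if len(empty_rows) or len(empty_cols):
        logger.info("pruning %d all-zero genes and %d all-zero pathways "
                    "from membership matrix", len(empty_rows), len(empty_cols))
    return df.drop(index=empty_rows, columns=empty_cols)


def binary_distance(u, v) -> float:
    """Jaccard distance 1 - |u and v| / |u or v| between binary vectors."""
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError("vectors differ in length")
    union = np.logical_or(u, v).sum()
    if union == 0:
        raise ValueError("Jaccard distance undefined for two all-zero vectors")
    return float(1.0 - np.logical_and(u, v).sum() / union)


@dataclass
class BiclusterResult:
    """Flat labels and linkage trees for both axes.

    ``gene_labels`` / ``pathway_labels`` map names to 1-based cluster ids;
    ``gene_linkage`` / ``pathway_linkage`` are scipy linkage matrices over
    the canonically ordered leaves ``gene_order`` / ``pathway_order``.
    """

    gene_labels: pd.Series
    pathway_labels: pd.Series
    gene_linkage: np.ndarray
    pathway_linkage: np.ndarray
    gene_order: list[str]
    pathway_order: list[str]


def _axis_cluster(df: pd.DataFrame, k: int, method: str):
    if k > len(df):
        raise ValueError(f"k={k} exceeds {len(df)} leaves")
    # canonical leaf order: by binary pattern then name -> permutation-invariant
    keys = sorted(df.index, key=lambda i: (tuple(df.loc[i].to_numpy()), str(i)))
    mat = df.loc[keys].to_numpy(dtype=bool)
    if len(keys) == 1:
        return pd.Series([1], index=keys), np.empty((0, 4)), keys
    dist = pdist(mat, metric="jaccard")
    Z = linkage(dist, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=keys), Z, keys


def bicluster(matrix: pd.DataFrame, k_pathways: int = 9, k_genes: int = 8,
              method: str = "average") -> BiclusterResult:
    """Cluster genes (rows) and pathways (columns) independently.

    The matrix must be binary with no all-zero row or column (use
    :func:`build_membership`).  Cuts use scipy's ``maxclust`` criterion;
    cutting at ``k-1`` merges exactly two of the ``k``-cut clusters.
    """
    arr = matrix.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("membership matrix must be binary")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("membership matrix has an all-zero row or column; "
                         "prune with build_membership first")
    gene_labels, gz, gorder = _axis_cluster(matrix, k_genes, method)
    pw_labels, pz, porder = _axis_cluster(matrix.T, k_pathways, method)
    return BiclusterResult(gene_labels, pw_labels, gz, pz, gorder, porder)


def plot_heatmap(matrix: pd.DataFrame, result: BiclusterResult, path=None):
    """Membership heatmap with both dendrogram orderings (visual aid)."""
    from scipy.cluster.hierarchy import leaves_list
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = ([result.gene_order[i] for i in leaves_list(result.gene_linkage)]
            if len(result.gene_linkage) else result.gene_order)
    cols = ([result.pathway_order[i] for i in leaves_list(result.pathway_linkage)]
            if len(result.pathway_linkage) else result.pathway_order)
    fig, ax = plt.subplots(figsize=(max(4, len(cols) * 0.4),
                                    max(4, len(rows) * 0.25)))
    ax.imshow(matrix.loc[rows, cols].to_numpy(), cmap="Greys", aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
    ax.set_yticks(range(len(rows)), rows, fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


__all__ = ["build_membership", "binary_distance", "bicluster",
           "BiclusterResult", "plot_heatmap"]
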
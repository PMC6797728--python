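"""Variable-gene selection, Spearman kNN clustering and cluster statistics.

Variable genes are chosen by a dropout score: after normalizing each cell's
counts to sum to one and ordering genes by mean normalized expression, a
gene's detection fraction f_g is compared with the maximum detection
fraction f_g_max in a 25-gene rolling window centered on it,

    ds_g = |f_g - f_g_max| / sqrt(f_g_max).

Genes with low detection relative to similarly expressed neighbours are
candidate markers of subpopulations.  Cells are then clustered by Louvain
community detection on a k-nearest-neighbour graph built from cell-cell
Spearman correlation over the selected genes.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .matrix import MoleculeMatrix

log = logging.getLogger(__name__)


@dataclass
class DropoutScores:
    table: pd.DataFrame  # index gene: f, f_max, ds; in window order
    window: int

    @property
    def ds(self) -> pd.Series:
        return self.table["ds"]


@dataclass
class ClusterLabeling:
    labels: pd.Series  # cell -> cluster id (int)
    cluster_info: pd.DataFrame = field(default_factory=pd.DataFrame)
    # cluster_info columns filled in by later stages: size, is_t,
    # cd4_cd8_logratio

    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.labels.to_numpy())

    def members(self, cid) -> np.ndarray:
        return np.flatnonzero(self.labels.to_numpy() == cid)


def dropout_scores(mm: MoleculeMatrix, window: int = 25) -> DropoutScores:
    """Dropout score per gene over the cells of ``mm``.

    Gene ordering uses the descending mean of sum-to-one normalized
    expression (ties broken by gene identifier); the rolling window is
    truncated at the ends of the ordering and includes the gene itself.
    """
    counts = sp.csr_matrix(mm.counts, dtype=float)
    lib = mm.library_sizes().astype(float)
    lib[lib == 0] = 1.0
    norm = sp.diags(1.0 / lib) @ counts
    mean_norm = np.asarray(norm.mean(axis=0)).ravel()
    f = np.asarray((counts > 0).mean(axis=0)).ravel()

    order = np.lexsort((mm.genes.to_numpy(), -mean_norm))
    f_ord = f[order]
    w = min(window, len(f_ord))
    half = w // 2
    n = len(f_ord)
    fmax_ord = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        fmax_ord[i] = f_ord[lo:hi].max()
    with np.errstate(divide="ignore", invalid="ignore"):
        ds_ord = np.where(fmax_ord > 0,
                          np.abs(f_ord - fmax_ord) / np.sqrt(fmax_ord), 0.0)
    table = pd.DataFrame({"f": f_ord, "f_max": fmax_ord, "ds": ds_ord,
                          "mean_norm": mean_norm[order]},
                         index=mm.genes[order])
    return DropoutScores(table=table, window=window)


def select_hvgs(scores: DropoutScores, abs_thresh: float = 0.15,
                sd_mult: float = 6.0) -> pd.Index:
    """Genes with ds above ``abs_thresh`` or above mean + ``sd_mult``*SD."""
    ds = scores.table["ds"]
    adaptive = ds.mean() + sd_mult * ds.std(ddof=0)
    sel = scores.table.index[(ds > abs_thresh) | (ds > adaptive)]
    if len(sel) == 0:
        raise ValueError("no variable genes selected; review ds thresholds")
    return pd.Index(sorted(sel))


def spearman_correlation(values: np.ndarray) -> np.ndarray:
    """Cell-by-cell Spearman correlation (rows = cells)."""
    ranks = stats.rankdata(values, axis=1)
    return np.corrcoef(ranks)


def spearman_knn_louvain(mm: MoleculeMatrix, genes: pd.Index, k: int = 20,
                         seed: int = 0, min_cluster_size: int = 0,
                         weighted: bool = True) -> ClusterLabeling:
    """Louvain communities on a Spearman kNN graph over selected genes.

    Edge weights are the Spearman correlations clipped at zero (set
    ``weighted=False`` for an unweighted graph).  Undersized clusters (if
    ``min_cluster_size`` > 0) are reassigned to the large cluster with the
    highest mean correlation.  Deterministic given ``seed``.
    """
    n = mm.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    sub = mm.subset_genes(genes)
    corr = spearman_correlation(sub.counts.toarray())
    np.fill_diagonal(corr, -np.inf)
    nn = np.argpartition(-corr, kth=k - 1, axis=1)[:, :k]

    edges, weights = [], []
    for i in range(n):
        for j in nn[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            edges.append((a, b))
            weights.append(max(corr[a, b], 0.0) if weighted else 1.0)
    df = pd.DataFrame({"e": edges, "w": weights}).groupby("e")["w"].max()
    g = igraph.Graph(n=n, edges=list(df.index), edge_attrs={"weight": df.values})

    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight")
    labels = np.asarray(part.membership)

    if min_cluster_size > 0:
        sizes = np.bincount(labels)
        small = np.flatnonzero(sizes < min_cluster_size)
        large = np.flatnonzero(sizes >= min_cluster_size)
        if len(large) and len(small):
            np.fill_diagonal(corr, 0.0)
            for cid in small:
                cells_small = np.flatnonzero(labels == cid)
                means = [corr[np.ix_(cells_small,
                                     np.flatnonzero(labels == lc))].mean()
                         for lc in large]
                labels[cells_small] = large[int(np.argmax(means))]
    # relabel to consecutive ids ordered by size (largest first)
    ids, counts = np.unique(labels, return_counts=True)
    remap = {old: new for new, old in
             enumerate(ids[np.argsort(-counts, kind="stable")])}
    labels = np.array([remap[v] for v in labels])
    info = pd.DataFrame({"size": np.bincount(labels)})
    info.index.name = "cluster"
    return ClusterLabeling(labels=pd.Series(labels, index=mm.cells,
                                            name="cluster"),
                           cluster_info=info)


def cd4_cd8_ratio(mm: MoleculeMatrix, size_factors: np.ndarray,
                  clusters: ClusterLabeling, cd4_gene: str = "CD4",
                  cd8_gene: str = "CD8A") -> pd.Series:
    """Per-cluster log2 ratio of normalized CD4 vs CD8A expression.

    For each gene the per-cluster mean of log2(normalized counts + 1) is
    divided by the all-cell mean of the same statistic; the reported value
    is log2 of the CD4 statistic over the CD8A statistic.
    """
    norm = mm.normalized(size_factors)
    out = {}
    stats_ = {}
    for gene in (cd4_gene, cd8_gene):
        v = np.log2(np.asarray(norm[:, mm.gene_index(gene)].todense()).ravel()
                    + 1.0)
        global_mean = v.mean()
        if global_mean == 0:
            raise ValueError(f"zero global mean expression for {gene}")
        stats_[gene] = (v, global_mean)
    labels = clusters.labels.to_numpy()
    for cid in clusters.cluster_ids():
        sel = labels == cid
        a = stats_[cd4_gene][0][sel].mean() / stats_[cd4_gene][1]
        b = stats_[cd8_gene][0][sel].mean() / stats_[cd8_gene][1]
        with np.errstate(divide="ignore"):
            out[cid] = np.log2(a / b) if b > 0 else np.inf
    res = pd.Series(out, name="cd4_cd8_logratio")
    clusters.cluster_info["cd4_cd8_logratio"] = res
    return res


def binomial_markers(mm: MoleculeMatrix, clusters: ClusterLabeling,
                     fc_min: float = 2.0, p_max: float = 0.05) -> pd.DataFrame:
    """Cluster markers by a binomial detection test.

    For each gene and cluster, the in-cluster detection count is tested
    against the out-of-cluster detection fraction (pseudocount 1/n cells)
    as the null rate; fold change compares detection fractions with the
    same pseudocount.  Genes passing ``fc_min`` and ``p_max`` are reported
    under the cluster where their fold enrichment is maximal.
    """
    det = (mm.counts > 0).astype(np.int64)
    labels = clusters.labels.to_numpy()
    n = mm.n_cells
    pseudo = 1.0 / n
    rows = []
    for cid in clusters.cluster_ids():
        sel = labels == cid
        n_in = int(sel.sum())
        if n_in < 3:
            log.warning("cluster %s has <3 cells; skipped", cid)
            continue
        k_in = np.asarray(det[sel].sum(axis=0)).ravel()
        k_out = np.asarray(det[~sel].sum(axis=0)).ravel()
        n_out = n - n_in
        f_in = k_in / n_in
        f_out = k_out / n_out if n_out else np.zeros_like(k_in, dtype=float)
        null = np.minimum(f_out + pseudo, 1.0)
        p = stats.binom.sf(k_in - 1, n_in, null)
        fc = (f_in + pseudo) / (f_out + pseudo)
        rows.append(pd.DataFrame({"cluster": cid, "gene": mm.genes,
                                  "fc": fc, "p": p}))
    if not rows:
        return pd.DataFrame(columns=["cluster", "gene", "fc", "p"])
    table = pd.concat(rows, ignore_index=True)
    passing = table[(table["fc"] > fc_min) & (table["p"] < p_max)]
    best = passing.loc[passing.groupby("gene", sort=False)["fc"].idxmax()]
    return (best.sort_values(["cluster", "fc"], ascending=[True, False])
            .reset_index(drop=True))
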
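"""Reference embedding, query projection and diffusion trajectories.

The reference atlas is a 2-D UMAP of reference cells under a Spearman
dissimilarity: expression vectors over the highly variable genes are
rank-transformed per cell, and Pearson correlation distance on ranks (the
definition of Spearman correlation) drives the embedding.  Query cells are
mapped into the frozen embedding with the fitted transform, then assigned
to the nearest (tissue, condition, lineage) centroid by Euclidean
distance.

Activation trajectories are diffusion components of the factor cell-score
matrix: a Gaussian kernel w_ij = exp(-d_ij^2 / eps^2) on Euclidean
distances with bandwidth eps (default 4), normalized to a Markov matrix;
DC1/DC2 are the eigenvectors with the second- and third-largest
eigenvalues, each scaled elementwise by the top eigenvector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla
from scipy import stats

from .matrix import MoleculeMatrix

log = logging.getLogger(__name__)


@dataclass
class ReferenceEmbedding:
    coordinates: pd.DataFrame  # reference cells x (umap1, umap2)
    hvgs: pd.Index
    reducer: object = field(repr=False, default=None)
    metric: str = "one-minus-spearman"
    seed: int = 0


@dataclass
class TrajectoryResult:
    components: pd.DataFrame  # cells x (DC1, DC2)
    eigenvalues: np.ndarray
    bandwidth: float


def _rank_matrix(mm: MoleculeMatrix, hvgs: pd.Index) -> np.ndarray:
    sub = mm.subset_genes(hvgs)
    return stats.rankdata(sub.counts.toarray(), axis=1)


def _intersect_hvgs(mm: MoleculeMatrix, hvgs: pd.Index) -> pd.Index:
    present = pd.Index(hvgs)[pd.Index(hvgs).isin(mm.genes)]
    # genes can drop out of a query for lack of expression
    expressed = present[np.asarray(
        (mm.subset_genes(present).counts > 0).sum(axis=0)).ravel() > 0]
    if len(expressed) < len(hvgs):
        log.warning("%d of %d variable genes eliminated (absent or "
                    "unexpressed)", len(hvgs) - len(expressed), len(hvgs))
    return expressed


def embed_reference(mm: MoleculeMatrix, hvgs: pd.Index, seed: int = 0,
                    n_neighbors: int = 15, min_dist: float = 0.1
                    ) -> ReferenceEmbedding:
    """Fit the 2-D reference embedding (deterministic given ``seed``)."""
    import umap  # deferred: numba compilation is expensive

    if mm.n_cells < 50:
        raise ValueError("reference embedding needs at least 50 cells")
    use = _intersect_hvgs(mm, hvgs)
    if len(use) == 0:
        raise ValueError("no variable genes present in the reference")
    ranks = _rank_matrix(mm, use)
    reducer = umap.UMAP(n_components=2, metric="correlation",
                        n_neighbors=n_neighbors, min_dist=min_dist,
                        random_state=seed)
    coords = reducer.fit_transform(ranks)
    return ReferenceEmbedding(
        coordinates=pd.DataFrame(coords, index=mm.cells,
                                 columns=["umap1", "umap2"]),
        hvgs=use, reducer=reducer, seed=seed)


def project_query(ref: ReferenceEmbedding, query: MoleculeMatrix) -> pd.DataFrame:
    """Map query cells into the frozen reference embedding (no refit)."""
    if ref.reducer is None:
        raise ValueError("reference has no fitted transform state")
    missing = ref.hvgs[~ref.hvgs.isin(query.genes)]
    if len(missing) == len(ref.hvgs):
        raise ValueError("query shares no genes with the reference HVGs")
    genes = ref.hvgs[ref.hvgs.isin(query.genes)]
    if len(missing):
        log.warning("%d reference HVGs missing from the query; using %d",
                    len(missing), len(genes))
    sub = query.subset_genes(ref.hvgs) if len(missing) == 0 else None
    if sub is None:
        # refit-free fallback is not possible with missing genes: the
        # transform expects the training dimensionality, so pad with zeros
        dense = np.zeros((query.n_cells, len(ref.hvgs)))
        pos = pd.Index(ref.hvgs).get_indexer(genes)
        dense[:, pos] = query.subset_genes(genes).counts.toarray()
        ranks = stats.rankdata(dense, axis=1)
    else:
        ranks = stats.rankdata(sub.counts.toarray(), axis=1)
    zero_info = np.flatnonzero(ranks.std(axis=1) == 0)
    if len(zero_info):
        log.warning("%d query cells carry no information over the HVGs",
                    len(zero_info))
    coords = ref.reducer.transform(ranks)
    return pd.DataFrame(coords, index=query.cells, columns=["umap1", "umap2"])


def build_centroids(ref: ReferenceEmbedding, groups: pd.Series) -> pd.DataFrame:
    """Centroid embedding position per reference group.

    ``groups`` maps reference cell id -> group label (e.g.
    ``"lung|rest|CD4"``); every nonempty group yields one centroid.
    """
    g = groups.loc[ref.coordinates.index]
    cent = ref.coordinates.groupby(g).mean()
    cent["n"] = ref.coordinates.groupby(g).size()
    return cent.sort_index()


def assign_centroids(centroids: pd.DataFrame,
                     query_coords: pd.DataFrame) -> pd.Series:
    """Nearest-centroid assignment by Euclidean distance.

    Ties are broken by lexicographic group name (centroids are kept in
    sorted order, and the first minimum wins).
    """
    if centroids.empty:
        raise ValueError("no centroids")
    c = centroids[["umap1", "umap2"]].to_numpy()
    q = query_coords[["umap1", "umap2"]].to_numpy()
    d = np.linalg.norm(q[:, None, :] - c[None, :, :], axis=2)
    idx = np.argmin(d, axis=1)  # first (lexicographically smallest) minimum
    return pd.Series(centroids.index.to_numpy()[idx],
                     index=query_coords.index, name="assigned_group")


def assignment_counts(assignments: pd.Series, source: pd.Series) -> pd.DataFrame:
    """Query-source x reference-group count matrix (the heatmap summary)."""
    return (pd.crosstab(source.loc[assignments.index], assignments)
            .sort_index().sort_index(axis=1))


def projection_histogram(coords: pd.DataFrame, bins: int = 30,
                         extent=None) -> np.ndarray:
    """Normalized 2-D histogram of projected cells (comparable across
    query sets of different size)."""
    x, y = coords["umap1"].to_numpy(), coords["umap2"].to_numpy()
    rng = None if extent is None else [extent[:2], extent[2:]]
    h, _, _ = np.histogram2d(x, y, bins=bins, range=rng)
    return h / max(len(coords), 1)


def diffusion_components(cell_scores: pd.DataFrame, bandwidth: float = 4.0,
                         n_components: int = 2) -> TrajectoryResult:
    """Diffusion components of a factor cell-score matrix.

    Gaussian kernel on Euclidean distances, row-normalized to a Markov
    matrix whose spectrum is computed through the symmetric conjugate.
    The returned DCs are the 2nd and 3rd eigenvectors scaled elementwise
    by the top one (which absorbs the stationary density).
    """
    x = cell_scores.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 30:
        raise ValueError("need at least 30 cells for diffusion components")
    sq = (x**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0)
    w = np.exp(-d2 / bandwidth**2)
    rowsum = w.sum(axis=1)
    if np.any(rowsum <= n * np.finfo(float).tiny):
        raise ValueError("kernel graph disconnected; increase the bandwidth")
    inv_sqrt = 1.0 / np.sqrt(rowsum)
    sym = w * inv_sqrt[:, None] * inv_sqrt[None, :]
    k = n_components + 1
    # deterministic start vector; a constant v0 would be nearly parallel to
    # the top eigenvector and degenerate the Krylov space
    v0 = np.random.default_rng(0).standard_normal(n)
    vals, vecs = spla.eigsh(sym, k=k, which="LA", v0=v0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    top = vecs[:, 0]
    if top[np.argmax(np.abs(top))] < 0:
        vecs = -vecs
        top = vecs[:, 0]
    comps = {}
    for i in range(1, k):
        v = vecs[:, i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        comps[f"DC{i}"] = v / top
    return TrajectoryResult(
        components=pd.DataFrame(comps, index=cell_scores.index),
        eigenvalues=vals, bandwidth=bandwidth)
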
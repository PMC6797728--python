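"""Factor-based expression-module discovery.

A nonnegative factor model decomposes the molecular count matrix into
cell scores and gene scores for K latent factors.  The engine is a
pluggable contract; the default is Poisson nonnegative matrix
factorization (multiplicative updates minimizing generalized
Kullback-Leibler / Poisson deviance).  K is selected per dataset as the
largest value in 6..12 whose maximum pairwise overlap of top-300 gene
lists is *not* significant under a hypergeometric test (population = the
unfiltered gene count) — larger K would split programs into redundant
factors.  Factors from all samples are then clustered into cross-sample
expression modules on the Pearson correlation of their gene-score vectors
over the union of each factor's 50 highest- and lowest-scoring genes;
clusters with mean pairwise correlation above 0.25 are reported as
modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import NMF

from .matrix import MoleculeMatrix

log = logging.getLogger(__name__)


@dataclass
class FactorModel:
    sample: str
    k: int
    gene_scores: pd.DataFrame  # genes x K
    cell_scores: pd.DataFrame  # cells x K
    n_unfiltered_genes: int  # population size for the overlap test

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if (self.gene_scores.to_numpy() < 0).any() or (
                self.cell_scores.to_numpy() < 0).any():
            raise ValueError("factor scores must be nonnegative")


@dataclass
class Module:
    members: list  # (sample, factor name)
    mean_correlation: float
    top_genes: pd.Series  # ranked by mean gene score across members


@dataclass
class ModuleSet:
    modules: list
    cut_distance: float
    linkage: np.ndarray = field(repr=False, default=None)


def filter_genes_for_factorization(mm: MoleculeMatrix,
                                   annotation: pd.DataFrame | None = None,
                                   blacklist: pd.Index | None = None,
                                   min_cell_frac: float = 0.001,
                                   biotypes=("protein_coding", "TR_C_gene",
                                             "IG_C_gene"),
                                   exclude_mito: bool = True) -> pd.Index:
    """Coding genes, off-blacklist, detected in >= ``min_cell_frac`` cells.

    Mitochondrial genes are excluded by default: per-cell mitochondrial
    content is a technical axis that would otherwise claim a factor.
    """
    keep = pd.Series(True, index=mm.genes)
    if annotation is not None and "biotype" in annotation:
        bt = annotation["biotype"].reindex(mm.genes)
        keep &= bt.isin(biotypes).to_numpy()
    if blacklist is not None:
        keep &= ~mm.genes.isin(blacklist)
    if exclude_mito:
        if annotation is not None and "is_mito" in annotation:
            keep &= ~annotation["is_mito"].reindex(mm.genes, fill_value=False
                                                   ).to_numpy()
        else:
            keep &= ~mm.genes.str.startswith("MT-")
    det_frac = np.asarray((mm.counts > 0).mean(axis=0)).ravel()
    keep &= det_frac >= min_cell_frac
    return mm.genes[keep]


def factorize(mm: MoleculeMatrix, k: int, seed: int = 0,
              max_iter: int = 300, tol: float = 1e-4,
              engine=None) -> FactorModel:
    """Fit a K-factor nonnegative model to the (pre-filtered) counts.

    ``engine`` may be any callable ``(counts, k, seed) -> (cell_scores,
    gene_scores)`` returning nonnegative arrays; the default is Poisson
    NMF via multiplicative updates.
    """
    if k >= min(mm.n_cells, mm.n_genes):
        raise ValueError("K must be smaller than both matrix dimensions")
    counts = mm.counts.astype(float)
    if engine is None:
        model = NMF(n_components=k, solver="mu", beta_loss="kullback-leibler",
                    init="random", random_state=seed, max_iter=max_iter,
                    tol=tol)
        w = model.fit_transform(counts)
        h = model.components_
    else:
        w, h = engine(counts, k, seed)
    names = [f"F{i}" for i in range(k)]
    sample = mm.samples[0] if mm.samples else "merged"
    return FactorModel(
        sample=sample, k=k,
        gene_scores=pd.DataFrame(np.asarray(h).T, index=mm.genes, columns=names),
        cell_scores=pd.DataFrame(np.asarray(w), index=mm.cells, columns=names),
        n_unfiltered_genes=mm.n_genes)


def ensemble_reconstruction(mm: MoleculeMatrix, k: int, seed: int = 0,
                            n_restarts: int = 3, engine=None) -> pd.DataFrame:
    """Per-cell normalized model reconstruction, averaged over restarts.

    Plain Poisson NMF is not identifiable: correlated factor pairs can
    split a cell's mass arbitrarily, which injects restart-dependent
    variance into raw cell scores.  Projecting scores back through the
    gene loadings (W @ H, normalized per cell) cancels exactly degenerate
    splits, and averaging a few restarts suppresses the rest.  The result
    is the denoised program composition used for trajectory distances.
    """
    recons = []
    for r in range(n_restarts):
        model = factorize(mm, k, seed=seed + r, engine=engine)
        rec = model.cell_scores.to_numpy() @ model.gene_scores.to_numpy().T
        total = rec.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        recons.append(rec / total)
    return pd.DataFrame(np.mean(recons, axis=0), index=mm.cells,
                        columns=mm.genes)


def cell_score_proportions(model: FactorModel) -> pd.DataFrame:
    """Cell scores normalized to sum to one per cell.

    Raw cell scores scale with sequencing depth; proportions expose the
    composition of programs within each cell and are the natural input for
    distance-based trajectory analysis.
    """
    total = model.cell_scores.sum(axis=1)
    total[total == 0] = 1.0
    return model.cell_scores.div(total, axis=0)


def top_genes(gene_scores: pd.DataFrame, factor: str, n: int) -> pd.Index:
    """Top-n genes of a factor; ties at the boundary broken by gene id."""
    col = gene_scores[factor]
    order = np.lexsort((gene_scores.index.to_numpy(), -col.to_numpy()))
    return gene_scores.index[order[:n]]


def k_overlap(model: FactorModel, top_n: int = 300) -> int:
    """Maximum pairwise overlap of the top-``top_n`` gene lists (N_K)."""
    if model.k < 2:
        raise ValueError("need at least two factors")
    n = top_n
    if len(model.gene_scores) < top_n:
        n = len(model.gene_scores)
        log.warning("only %d genes available; top_n lowered to %d",
                    n, n)
    sets = [set(top_genes(model.gene_scores, f, n))
            for f in model.gene_scores.columns]
    best = 0
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            best = max(best, len(sets[i] & sets[j]))
    return best


def overlap_pvalue(n_k: int, population_genes: int, draws: int = 300) -> float:
    """Hypergeometric upper tail P[X >= N_K], both draw sizes = ``draws``."""
    if not 0 <= n_k <= draws or draws > population_genes:
        raise ValueError("inconsistent overlap sizes")
    return float(stats.hypergeom.sf(n_k - 1, population_genes, draws, draws))


def select_k_from_pvalues(pvals: dict, p_cut: float = 0.05) -> int:
    """Largest K whose overlap p-value is >= ``p_cut``.

    If every candidate shows significant overlap the smallest tested K is
    returned with a warning.
    """
    if not pvals:
        raise ValueError("no candidate factorizations")
    ok = [k for k, p in pvals.items() if p >= p_cut]
    if ok:
        return max(ok)
    k_min = min(pvals)
    log.warning("all K in %s show significant factor overlap; "
                "falling back to K=%d", sorted(pvals), k_min)
    return k_min


def select_k(models: dict, p_cut: float = 0.05, top_n: int = 300) -> int:
    """Largest K whose top-gene overlap is *not* significant.

    ``models`` maps K -> FactorModel.
    """
    if not models:
        raise ValueError("no candidate factorizations")
    pvals = {k: overlap_pvalue(k_overlap(m, top_n), m.n_unfiltered_genes,
                               min(top_n, len(m.gene_scores)))
             for k, m in models.items()}
    return select_k_from_pvalues(pvals, p_cut)


def cluster_factor_modules(models: list, top_bottom_n: int = 50,
                           corr_min: float = 0.25,
                           min_top_genes: int = 50) -> ModuleSet:
    """Cross-sample expression modules from >= 2 factor models.

    The gene universe is the union over factors of the ``top_bottom_n``
    highest- and lowest-scoring genes; factors are clustered by
    average-linkage on 1 - Pearson r, and the tree is cut at the distance
    that maximizes the number of clusters whose mean pairwise correlation
    exceeds ``corr_min`` (smallest such distance on ties).
    """
    if len(models) < 2:
        raise ValueError("module discovery needs at least two factor models")
    cols = {}
    universe: set = set()
    for m in models:
        for f in m.gene_scores.columns:
            key = (m.sample, f)
            cols[key] = m.gene_scores[f]
            col = m.gene_scores[f]
            order = np.lexsort((m.gene_scores.index.to_numpy(),
                                -col.to_numpy()))
            universe.update(m.gene_scores.index[order[:top_bottom_n]])
            universe.update(m.gene_scores.index[order[-top_bottom_n:]])
    genes = pd.Index(sorted(universe))
    mat = pd.DataFrame({k: v.reindex(genes).fillna(0.0)
                        for k, v in cols.items()})
    if mat.shape[1] < 2:
        return ModuleSet(modules=[], cut_distance=0.0)
    corr = np.corrcoef(mat.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = hierarchy.linkage(dist[np.triu_indices_from(dist, k=1)],
                          method="average")

    def qualifying(cut: float):
        lab = hierarchy.fcluster(z, t=cut, criterion="distance")
        mods = []
        for cid in np.unique(lab):
            members = np.flatnonzero(lab == cid)
            if len(members) < 2:
                continue
            sub = corr[np.ix_(members, members)]
            mean_r = sub[np.triu_indices_from(sub, k=1)].mean()
            if mean_r > corr_min:
                mods.append((members, mean_r))
        return mods

    candidates = sorted(set(np.nextafter(z[:, 2], np.inf)))
    best_cut, best_mods, best_key = 0.0, [], (0, 0)
    for cut in candidates:
        mods = qualifying(cut)
        # most qualifying clusters; ties broken toward the cut that pulls
        # the most factors into qualifying clusters (complete modules)
        key = (len(mods), sum(len(m) for m, _ in mods))
        if key > best_key:
            best_cut, best_mods, best_key = cut, mods, key

    keys = list(mat.columns)
    modules = []
    for members, mean_r in best_mods:
        mk = [keys[i] for i in members]
        mean_scores = mat.iloc[:, members].mean(axis=1)
        ranked = mean_scores.sort_values(ascending=False)
        modules.append(Module(members=mk, mean_correlation=float(mean_r),
                              top_genes=ranked.head(min_top_genes)))
    modules.sort(key=lambda m: -m.mean_correlation)
    return ModuleSet(modules=modules, cut_distance=best_cut, linkage=z)


def cd4_cd8_bias(model: FactorModel, cd4_mask: np.ndarray,
                 cd8_mask: np.ndarray, clamp: float = 10.0) -> pd.Series:
    """Per-factor log2 ratio of mean cell score in CD4 vs CD8 cells."""
    cd4_mask = np.asarray(cd4_mask, bool)
    cd8_mask = np.asarray(cd8_mask, bool)
    if (cd4_mask & cd8_mask).any():
        raise ValueError("CD4 and CD8 masks overlap")
    if not cd4_mask.any() or not cd8_mask.any():
        raise ValueError("both masks must select at least one cell")
    scores = model.cell_scores.to_numpy()
    m4 = scores[cd4_mask].mean(axis=0)
    m8 = scores[cd8_mask].mean(axis=0)
    with np.errstate(divide="ignore"):
        bias = np.log2(m4 / m8)
    bias = np.clip(np.nan_to_num(bias, nan=0.0, posinf=clamp, neginf=-clamp),
                   -clamp, clamp)
    return pd.Series(bias, index=model.cell_scores.columns, name="cd4_cd8_bias")
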
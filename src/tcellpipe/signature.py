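"""Tissue-resident T-cell signature derivation and scoring.

Effector-memory (TEM) cells are gated by confident CCL5 detection: the
reads-per-molecule distribution of CCL5 is bimodal (chimeric low-read
detections vs genuine expression) and cells are positive only above the
per-sample density minimum.  Tissue signatures are genes elevated more
than two-fold toward tissue (adjusted rank-sum p < 0.05) in *every*
configured tissue-donor x blood-donor comparison.  Per-cell signature
scores are the mean log2(normalized + 1) over signature genes, and blood
cells scoring within one SD of the tissue mean are flagged as
tissue-like outliers.  A classic (unweighted) preranked GSEA with gene
label permutations quantifies signature enrichment in external rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import fold_change_epsilon, wilcoxon_de
from .matrix import MoleculeMatrix
from .tcell_id import NoBimodalityError, find_rpm_threshold

log = logging.getLogger(__name__)


def gate_ccl5(mm: MoleculeMatrix, gene: str = "CCL5") -> pd.Index:
    """Cells positive for ``gene`` above the per-sample RPM density minimum.

    Falls back to any-detection for samples whose RPM distribution for the
    gene is unimodal.
    """
    gi = mm.gene_index(gene)
    counts = np.asarray(mm.counts[:, gi].todense()).ravel()
    rpm = np.asarray(mm.rpm[:, gi].todense()).ravel()
    positive = np.zeros(mm.n_cells, bool)
    for sample in mm.samples:
        sel = mm.cell_sample == sample
        det = sel & (counts > 0)
        try:
            thr = find_rpm_threshold(rpm[det])
        except (NoBimodalityError, ValueError) as exc:
            log.warning("sample %s: %s; gating %s on any detection",
                        sample, exc, gene)
            thr = 0.0
        positive |= det & (rpm > thr)
    return mm.cells[positive]


def pairwise_de(mm: MoleculeMatrix, size_factors: np.ndarray,
                group_a: pd.Index, group_b: pd.Index,
                exclude_genes: pd.Index | None = None,
                min_cells: int = 10) -> pd.DataFrame:
    """Rank-sum DE of cell group A vs B on pooled-normalized expression.

    Blacklisted genes are excluded before testing; the fold-change
    pseudocount is one molecule at the median library size.
    """
    ia = mm.cells.get_indexer(group_a)
    ib = mm.cells.get_indexer(group_b)
    if (ia < 0).any() or (ib < 0).any():
        raise KeyError("group contains cells absent from the matrix")
    if len(ia) < min_cells or len(ib) < min_cells:
        raise ValueError(f"both groups need >= {min_cells} cells")
    genes = mm.genes
    if exclude_genes is not None:
        genes = genes[~genes.isin(exclude_genes)]
    sub = mm.subset_genes(genes)
    norm = sub.normalized(size_factors)
    eps = fold_change_epsilon(mm.library_sizes())
    return wilcoxon_de(norm[ia].toarray(), norm[ib].toarray(), genes, eps)


def derive_signature(comparisons: dict, fc_min: float = 2.0,
                     p_max: float = 0.05) -> dict:
    """Per-tissue signatures from all pairwise tissue-vs-blood comparisons.

    ``comparisons`` maps tissue -> list of DE tables (fold toward tissue).
    A gene enters a tissue's signature iff it passes ``p_adj < p_max`` and
    ``fold > fc_min`` in every comparison of that tissue.  The combined
    signature is the union over tissues.
    """
    out = {}
    for tissue, tables in comparisons.items():
        if not tables:
            raise ValueError(f"tissue {tissue!r} has no comparisons")
        passing = None
        for i, de in enumerate(tables):
            if de is None:
                raise ValueError(f"missing comparison {i} for {tissue!r}")
            hits = set(de.index[(de["p_adj"] < p_max)
                                & (de["fold_change"] > fc_min)])
            passing = hits if passing is None else passing & hits
        out[tissue] = pd.Index(sorted(passing))
    out["combined"] = pd.Index(sorted(set().union(
        *[set(v) for k, v in out.items() if k != "combined"])))
    return out


def signature_score(mm: MoleculeMatrix, size_factors: np.ndarray,
                    signature: pd.Index) -> pd.Series:
    """Mean log2(normalized + 1) over signature genes, per cell."""
    sig = pd.Index(signature)
    present = sig[sig.isin(mm.genes)]
    if len(present) == 0:
        raise ValueError("signature empty after intersecting the matrix")
    sub = mm.subset_genes(present)
    norm = sub.normalized(size_factors)
    score = np.log2(norm.toarray() + 1.0).mean(axis=1)
    return pd.Series(score, index=mm.cells, name="signature_score")


def flag_blood_outliers(blood_scores: pd.Series,
                        tissue_scores: pd.Series) -> pd.Index:
    """Blood cells scoring within one SD below the tissue mean (or above)."""
    if blood_scores.empty or tissue_scores.empty:
        raise ValueError("both score sets must be nonempty")
    thr = tissue_scores.mean() - tissue_scores.std(ddof=0)
    return blood_scores.index[blood_scores >= thr]


# ---------------------------------------------------------------------------
# classic preranked GSEA


@dataclass
class GseaResult:
    es: float
    p: float
    n_perm: int


def _es_from_positions(pos: np.ndarray, n: int, m: int) -> float:
    """Classic running-sum enrichment score from sorted hit positions."""
    pos = np.sort(pos)
    j = np.arange(1, m + 1)
    after = j / m - (pos + 1 - j) / (n - m)  # running sum right after hit j
    before = (j - 1) / m - (pos - (j - 1)) / (n - m)  # just before hit j
    hi = after.max()
    lo = min(before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def preranked_gsea(ranked_genes: pd.Index, gene_set, n_perm: int = 10_000,
                   seed: int = 0) -> GseaResult:
    """Classic (unweighted) preranked GSEA with gene-label permutations.

    ``ranked_genes`` is the full universe ordered by the ranking metric
    (best first).  The p-value is the one-sided fraction of permutations
    whose |ES| reaches the observed |ES| on the observed sign, with the
    usual add-one correction.
    """
    universe = pd.Index(ranked_genes)
    hits = universe.get_indexer(pd.Index(gene_set))
    hits = hits[hits >= 0]
    if len(hits) == 0:
        raise ValueError("gene set empty after intersecting the ranking")
    n, m = len(universe), len(hits)
    if m >= n:
        raise ValueError("gene set must be a strict subset of the universe")
    es = _es_from_positions(hits, n, m)

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        perm_es[i] = _es_from_positions(
            rng.choice(n, size=m, replace=False), n, m)
    # one-sided within the observed sign, against same-sign permutations
    if es >= 0:
        pool = perm_es[perm_es >= 0]
        count = int((pool >= es).sum())
    else:
        pool = perm_es[perm_es < 0]
        count = int((pool <= es).sum())
    p = (count + 1) / (len(pool) + 1)
    return GseaResult(es=es, p=p, n_perm=n_perm)
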
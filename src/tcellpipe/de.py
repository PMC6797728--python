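"""Wilcoxon rank-sum differential expression shared by several stages."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fold_change_epsilon(library_sizes: np.ndarray) -> float:
    """Pseudocount for fold changes: one molecule at the median depth."""
    med = float(np.median(library_sizes))
    return 1.0 / med if med > 0 else 1.0


def wilcoxon_de(group_a: np.ndarray, group_b: np.ndarray, genes: pd.Index,
                epsilon: float = 1e-3) -> pd.DataFrame:
    """Per-gene rank-sum test of A vs B on normalized expression.

    ``group_a``/``group_b`` are dense cells x genes arrays.  Fold change is
    (mean_A + eps) / (mean_B + eps); p-values are Benjamini-Hochberg
    corrected across the genes tested.  Genes constant across both groups
    get p = 1.
    """
    if group_a.shape[1] != len(genes) or group_b.shape[1] != len(genes):
        raise ValueError("gene dimension mismatch")
    stat, p = stats.ranksums(group_a, group_b, axis=0)
    const = (np.ptp(group_a, axis=0) == 0) & (np.ptp(group_b, axis=0) == 0) & (
        group_a[0] == group_b[0])
    p = np.where(const, 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    mean_a = group_a.mean(axis=0)
    mean_b = group_b.mean(axis=0)
    fc = (mean_a + epsilon) / (mean_b + epsilon)
    return pd.DataFrame({
        "gene": genes, "mean_a": mean_a, "mean_b": mean_b,
        "fold_change": fc, "log2_fc": np.log2(fc), "p": p, "p_adj": p_adj,
    }).set_index("gene")
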
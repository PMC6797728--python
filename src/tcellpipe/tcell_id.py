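"""Computational identification of T cells, cross-talk aware.

Clusters enriched for both CD3D and TRAC are flagged as T-cell clusters.
A blacklist of genes highly specific to contaminating cell types is
derived from all (T, non-T) cluster pairs within each sample (rank-sum
p_adj < 0.001 and >10-fold enrichment toward the non-T cluster), minus a
whitelist of genes positively enriched in any T-cell cluster.  Because
PCR-recombination chimeras place low-read molecules under wrong barcodes,
a blacklisted gene only counts as *detected* in a cell when its mean reads
per molecule exceed a per-sample threshold: the minimum between the two
modes of the (bimodal) reads-per-molecule distribution in the
highest-coverage sample h, scaled to every other sample s as

    T_s = T_h * (RPM_s / RPM_h).

The per-cell blacklist fraction b_c (share of blacklist genes confidently
detected) is then bimodal; a Gaussian fitted to the T-cluster cells sets a
cutoff at two SD above its mean.  Cells above the cutoff, and all cells of
non-T clusters, are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterLabeling
from .de import fold_change_epsilon, wilcoxon_de
from .matrix import MoleculeMatrix

log = logging.getLogger(__name__)


class NoBimodalityError(ValueError):
    """Raised when a reads-per-molecule distribution has a single mode."""


@dataclass
class BlacklistDerivation:
    blacklist: pd.DataFrame  # initial; index gene: best p_adj, best fold, source
    whitelist: pd.Index
    final: pd.Index  # blacklist minus whitelist


def flag_t_clusters(mm: MoleculeMatrix, size_factors: np.ndarray,
                    clusters: ClusterLabeling,
                    markers=("CD3D", "TRAC")) -> pd.Series:
    """Flag clusters whose mean normalized expression of every marker
    exceeds the sample-wide mean."""
    norm = mm.normalized(size_factors)
    cols = {}
    for g in markers:
        cols[g] = np.asarray(norm[:, mm.gene_index(g)].todense()).ravel()
    labels = clusters.labels.to_numpy()
    flags = {}
    for cid in clusters.cluster_ids():
        sel = labels == cid
        flags[cid] = all(cols[g][sel].mean() > cols[g].mean() for g in markers)
    res = pd.Series(flags, name="is_t")
    clusters.cluster_info["is_t"] = res
    return res


def derive_blacklist(per_sample: list, p_black: float = 0.001,
                     fc_black: float = 10.0, p_white: float = 0.05,
                     fc_white: float = 1.0) -> BlacklistDerivation:
    """Blacklist/whitelist from per-sample (matrix, size factors, clusters).

    ``per_sample`` is a list of (sample_name, MoleculeMatrix, size_factors,
    ClusterLabeling) with ``is_t`` flags already set on the clusters.
    Every (T, non-T) cluster pair in every sample contributes one rank-sum
    comparison, BH-corrected within the pair.
    """
    black_rows = []
    white: set = set()
    any_pair = False
    for sample, mm, sf, clusters in per_sample:
        if "is_t" not in clusters.cluster_info:
            raise ValueError(f"sample {sample}: T flags missing")
        eps = fold_change_epsilon(mm.library_sizes())
        norm = mm.normalized(sf).toarray()
        labels = clusters.labels.to_numpy()
        info = clusters.cluster_info
        t_ids = info.index[info["is_t"]]
        nt_ids = info.index[~info["is_t"]]
        for t_id in t_ids:
            a = norm[labels == t_id]
            for nt_id in nt_ids:
                any_pair = True
                b = norm[labels == nt_id]
                de = wilcoxon_de(b, a, mm.genes, eps)  # fold toward non-T
                hits = de[(de["p_adj"] < p_black) & (de["fold_change"] > fc_black)]
                for g, row in hits.iterrows():
                    black_rows.append((g, row["p_adj"], row["fold_change"],
                                       sample, t_id, nt_id))
                up_t = de[(de["p_adj"] < p_white) & (de["fold_change"] < 1.0 / fc_white)]
                white.update(up_t.index)
    if not any_pair:
        log.warning("no (T, non-T) cluster pairs found; empty blacklist")
    if black_rows:
        tab = pd.DataFrame(black_rows, columns=["gene", "p_adj", "fold",
                                                "sample", "t_cluster",
                                                "nt_cluster"])
        best = tab.loc[tab.groupby("gene")["fold"].idxmax()].set_index("gene")
    else:
        best = pd.DataFrame(columns=["p_adj", "fold", "sample", "t_cluster",
                                     "nt_cluster"])
    whitelist = pd.Index(sorted(white))
    final = pd.Index(sorted(set(best.index) - set(whitelist)))
    return BlacklistDerivation(blacklist=best, whitelist=whitelist, final=final)


def find_rpm_threshold(rpm_values: np.ndarray, grid_size: int = 512,
                       min_values: int = 100, min_peak_frac: float = 0.02,
                       max_valley_frac: float = 0.8) -> float:
    """Minimum-density point between the two largest modes of log(RPM).

    A second mode only counts when its density reaches ``min_peak_frac``
    of the main mode and the valley between the two drops below
    ``max_valley_frac`` of the smaller peak — kernel-estimate wiggles on a
    unimodal distribution do not qualify.  Raises
    :class:`NoBimodalityError` when no such pair exists; callers may fall
    back to a configured quantile.
    """
    v = np.asarray(rpm_values, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) < min_values:
        raise ValueError(f"need at least {min_values} RPM values, got {len(v)}")
    x = np.log(v)
    if np.ptp(x) == 0:
        raise NoBimodalityError("reads-per-molecule values are constant")
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if dens[0] > dens[1]:
        peaks = np.r_[0, peaks]
    if dens[-1] > dens[-2]:
        peaks = np.r_[peaks, grid_size - 1]
    peaks = peaks[dens[peaks] >= min_peak_frac * dens.max()]
    # best significant pair among the largest peaks
    peaks = peaks[np.argsort(dens[peaks])][::-1][:5]
    best = None
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            lo, hi = sorted((int(peaks[i]), int(peaks[j])))
            valley = dens[lo:hi + 1].min()
            smaller = min(dens[lo], dens[hi])
            if valley <= max_valley_frac * smaller:
                height = dens[lo] + dens[hi]
                if best is None or height > best[0]:
                    cut = lo + int(np.argmin(dens[lo:hi + 1]))
                    best = (height, cut)
    if best is None:
        raise NoBimodalityError("reads-per-molecule density is unimodal")
    return float(np.exp(grid[best[1]]))


def extrapolate_threshold(t_h: float, rpm_h: float, rpm_s: float) -> float:
    """Scale the highest-coverage sample's RPM threshold to sample s."""
    if t_h <= 0 or rpm_h <= 0 or rpm_s <= 0:
        raise ValueError("thresholds and RPM values must be positive")
    return t_h * (rpm_s / rpm_h)


def sample_rpm_thresholds(mm: MoleculeMatrix,
                          fallback_quantile: float = 0.1) -> dict:
    """Per-sample T_s from the highest-coverage sample's bimodal split.

    The highest-coverage sample h is the one with maximal RPM_s.  If its
    RPM distribution is unimodal (artifact-free data), the configured
    quantile of its per-(cell, gene) RPM values is used instead, with a
    warning.
    """
    if not mm.sample_rpm:
        raise ValueError("sample RPM statistics missing")
    h = max(mm.sample_rpm, key=mm.sample_rpm.get)
    rpm_h = mm.sample_rpm[h]
    sub = mm.select_sample(h)
    values = sub.rpm.data
    try:
        t_h = find_rpm_threshold(values)
    except NoBimodalityError:
        t_h = float(np.quantile(values, fallback_quantile))
        log.warning("sample %s RPM distribution unimodal; falling back to "
                    "the %.0f%% quantile (T_h=%.3g)", h,
                    100 * fallback_quantile, t_h)
    return {s: extrapolate_threshold(t_h, rpm_h, rpm_s)
            for s, rpm_s in mm.sample_rpm.items()}


def blacklist_fraction(mm: MoleculeMatrix, blacklist: pd.Index,
                       thresholds: dict) -> pd.Series:
    """b_c: fraction of blacklist genes detected above T_s in each cell."""
    if len(blacklist) == 0:
        log.warning("empty blacklist; b_c = 0 for all cells")
        return pd.Series(0.0, index=mm.cells, name="b_c")
    idx = mm.genes.get_indexer(blacklist)
    idx = idx[idx >= 0]
    t_s = np.array([thresholds[s] for s in mm.cell_sample])
    sub_counts = mm.counts[:, idx].tocoo()
    sub_rpm = mm.rpm[:, idx].tocoo()
    ok = sub_rpm.data > t_s[sub_rpm.row]
    hits = np.bincount(sub_rpm.row[ok & (sub_counts.data > 0)],
                       minlength=mm.n_cells)
    return pd.Series(hits / len(blacklist), index=mm.cells, name="b_c")


def identify_t_cells(mm: MoleculeMatrix, clusters_by_sample: dict,
                     b_c: pd.Series, sd_cutoff: float = 2.0,
                     min_fit_cells: int = 20) -> pd.Index:
    """Surviving T-cell barcodes after the b_c Gaussian cutoff.

    ``clusters_by_sample`` maps sample -> ClusterLabeling with ``is_t``
    flags.  Per sample a Gaussian is moment-fitted to b_c over T-cluster
    cells; cells above mean + ``sd_cutoff``*SD and all non-T-cluster cells
    are discarded.  With fewer than ``min_fit_cells`` T-cluster cells the
    fit is refused and all T-cluster cells are kept (warning).
    """
    kept = []
    for sample, clusters in clusters_by_sample.items():
        info = clusters.cluster_info
        t_ids = set(info.index[info["is_t"]])
        cell_ids = clusters.labels.index
        in_t = clusters.labels.isin(t_ids).to_numpy()
        b = b_c.loc[cell_ids].to_numpy()
        t_cells = cell_ids[in_t]
        if len(t_cells) < min_fit_cells:
            log.warning("sample %s: only %d T-cluster cells; keeping all "
                        "without a b_c cutoff", sample, len(t_cells))
            kept.append(t_cells)
            continue
        mu = b[in_t].mean()
        sd = b[in_t].std(ddof=0)
        cutoff = mu + sd_cutoff * sd
        kept.append(cell_ids[in_t & (b <= cutoff)])
    return pd.Index(np.concatenate([k.to_numpy() for k in kept]))
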
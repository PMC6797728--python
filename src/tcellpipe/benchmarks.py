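"""Ground-truth benchmarks of the pipeline on the default synthetic cohort.

Every function here regenerates its inputs from the study-like generator
defaults and measures one aspect of the pipeline against the planted
truth: artifact correction fidelity, variable-gene recovery, T-cell
identification precision/recall, blacklist recovery, tissue-signature
recovery, expression-module recovery, activation-trajectory fidelity and
projection accuracy.  The acceptance script and the acceptance test suite
are thin wrappers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import dropout_scores, select_hvgs, spearman_knn_louvain
from .factors import (ensemble_reconstruction, factorize,
                      filter_genes_for_factorization, k_overlap,
                      overlap_pvalue, select_k_from_pvalues)
from .matrix import MoleculeMatrix
from .normalize import pooled_size_factors
from .projection import (assign_centroids, build_centroids,
                         diffusion_components, embed_reference,
                         project_query)
from .qc import compute_cell_qc, filter_cells
from .signature import derive_signature, gate_ccl5, pairwise_de
from .simulate import default_config, simulate_dataset
from .swap import collapse_umis, resolve_swaps
from .tcell_id import (blacklist_fraction, derive_blacklist, flag_t_clusters,
                       identify_t_cells, sample_rpm_thresholds)


@dataclass
class CohortRun:
    """All intermediate artifacts of one default-cohort pipeline run."""

    cfg: object
    truth: object
    mm: MoleculeMatrix  # post-QC, all cells
    per_sample: list  # (sample, matrix, size factors, clusters)
    hvg_union: pd.Index
    blacklist_derivation: object
    thresholds: dict
    b_c: pd.Series
    t_cells: pd.Index
    mm_t: MoleculeMatrix  # T cells only
    truth_t: pd.DataFrame


def run_default_cohort(seed: int, cells_per_sample: int = 2000,
                       n_samples: int = 6) -> CohortRun:
    """Simulate the default cohort and run the stages through T-cell
    identification."""
    cfg = default_config(seed=seed, cells_per_sample=cells_per_sample,
                         n_samples=n_samples)
    addresses, truth = simulate_dataset(cfg)
    mm = collapse_umis(resolve_swaps(addresses),
                       gene_index=pd.Index(cfg.gene_names))
    kept = filter_cells(compute_cell_qc(mm))
    mm = mm.subset_cells(mm.cells.isin(kept))
    per_sample, hvgs = [], set()
    for sample in mm.samples:
        sub = mm.select_sample(sample)
        hv = select_hvgs(dropout_scores(sub))
        hvgs.update(hv)
        clusters = spearman_knn_louvain(sub, hv, k=20, seed=seed)
        sf = pooled_size_factors(sub, clusters)
        flag_t_clusters(sub, sf, clusters)
        per_sample.append((sample, sub, sf, clusters))
    deriv = derive_blacklist(per_sample)
    thresholds = sample_rpm_thresholds(mm)
    b_c = blacklist_fraction(mm, deriv.final, thresholds)
    t_cells = identify_t_cells(mm, {s: c for s, _, _, c in per_sample}, b_c)
    mm_t = mm.subset_cells(mm.cells.isin(t_cells))
    return CohortRun(cfg=cfg, truth=truth, mm=mm, per_sample=per_sample,
                     hvg_union=pd.Index(sorted(hvgs)),
                     blacklist_derivation=deriv, thresholds=thresholds,
                     b_c=b_c, t_cells=t_cells, mm_t=mm_t,
                     truth_t=truth.cells.loc[mm_t.cells])


# ---------------------------------------------------------------------------
# swap correction


def swap_retention_rate(seed: int, cells_per_sample: int = 300,
                        n_samples: int = 4, rpm_mean: float = 60.0,
                        min_reads: int = 50) -> float:
    """Fraction of well-supported genuine molecules that keep their true
    sample after swap resolution, on a deeply sequenced cohort (1% swap)."""
    cfg = default_config(seed=seed, cells_per_sample=cells_per_sample,
                         n_samples=n_samples)
    for s in cfg.samples:
        s.rpm_mean = rpm_mean
    addresses, truth = simulate_dataset(cfg)
    resolved = resolve_swaps(addresses)
    art = truth.artifacts
    genuine = art[(~art["is_chimera"])
                  & (art["sample"] == art["true_sample"])]
    mol = truth.molecules
    strong = mol[mol["reads"] >= min_reads]
    strong_keys = pd.MultiIndex.from_frame(
        strong[["sample", "barcode", "umi", "gene"]].astype(
            {"sample": str, "gene": str}))
    surviving = pd.MultiIndex.from_frame(
        resolved[["sample", "barcode", "umi", "gene"]])
    return float(strong_keys.isin(surviving).mean())


# ---------------------------------------------------------------------------
# variable genes


def hvg_marker_recovery(run: CohortRun) -> float:
    """Fraction of planted within-sample bimodal markers (T-subset plus
    contaminant markers) recovered in the per-sample HVG union."""
    gs = run.truth.gene_sets
    planted = set(gs["t_subset_markers"]) | set(gs["contaminant_markers"])
    return len(planted & set(run.hvg_union)) / len(planted)


# ---------------------------------------------------------------------------
# T-cell identification


def tcell_scores(run: CohortRun) -> dict:
    truth = run.truth.cells.loc[run.mm.cells]
    pred = run.mm.cells.isin(run.t_cells)
    true_t = truth["is_t"].to_numpy()
    tp = (pred & true_t).sum()
    gs = run.truth.gene_sets
    final = set(run.blacklist_derivation.final)
    return {
        "precision": float(tp / max(pred.sum(), 1)),
        "recall": float(tp / max(true_t.sum(), 1)),
        "blacklist_recovery": len(final & set(gs["contaminant_markers"]))
        / len(gs["contaminant_markers"]),
        "t_subset_markers_blacklisted": len(
            final & set(gs["t_subset_markers"])),
    }


def bc_monotone_in_threshold(run: CohortRun) -> bool:
    """b_c never increases when every per-sample threshold is raised."""
    lo = blacklist_fraction(run.mm, run.blacklist_derivation.final,
                            run.thresholds)
    hi = blacklist_fraction(run.mm, run.blacklist_derivation.final,
                            {s: 2 * t for s, t in run.thresholds.items()})
    ok = bool((hi <= lo + 1e-12).all())
    return ok and bool(lo.between(0, 1).all())


# ---------------------------------------------------------------------------
# tissue signature


def signature_comparisons(run: CohortRun) -> tuple[dict, np.ndarray]:
    """Four-way pairwise DE tables per tissue on resting CCL5+ TEM cells."""
    mm_t, meta = run.mm_t, run.truth_t
    clusters = spearman_knn_louvain(
        mm_t, run.hvg_union[run.hvg_union.isin(mm_t.genes)],
        k=12, seed=run.cfg.seed, min_cluster_size=100)
    sf = pooled_size_factors(mm_t, clusters)
    tem = pd.Index(gate_ccl5(mm_t)).intersection(
        meta.index[meta["condition"] == "rest"])
    blood = sorted(set(meta.loc[meta["tissue"] == "blood", "sample"]))
    comparisons = {}
    for tissue in sorted(set(meta["tissue"]) - {"blood"}):
        tables = []
        for ts in sorted(set(meta.loc[meta["tissue"] == tissue, "sample"])):
            a = tem[(meta.loc[tem, "sample"] == ts).to_numpy()]
            for bs in blood:
                b = tem[(meta.loc[tem, "sample"] == bs).to_numpy()]
                tables.append(pairwise_de(
                    mm_t, sf, a, b,
                    exclude_genes=run.blacklist_derivation.final))
        comparisons[tissue] = tables
    return comparisons, sf


def signature_jaccard(run: CohortRun, comparisons: dict | None = None) -> dict:
    """Jaccard of each recovered tissue signature against the planted
    tissue-elevated genes (shared program plus per-tissue markers)."""
    if comparisons is None:
        comparisons, _ = signature_comparisons(run)
    sigs = derive_signature(comparisons)
    gs = run.truth.gene_sets
    shared = set(gs["tissue_signature"])
    out = {}
    for tissue, recovered in sigs.items():
        if tissue == "combined":
            planted = set().union(shared, *[
                gs[k] for k in gs if k.startswith("tissue_markers:")])
        else:
            planted = shared | set(gs.get(f"tissue_markers:{tissue}", []))
        rec = set(recovered)
        out[tissue] = len(rec & planted) / len(rec | planted)
    return out


# ---------------------------------------------------------------------------
# factors and trajectory


def trajectory_gradient_correlations(run: CohortRun, n_restarts: int = 3
                                     ) -> list:
    """|Spearman rho| between DC1 and the planted activation coordinate,
    for every (sample, lineage) trajectory.

    K is selected on the highest-coverage library with the top-gene
    overlap rule and shared across libraries.
    """
    seed = run.cfg.seed
    h = max(run.mm_t.sample_rpm, key=run.mm_t.sample_rpm.get)
    sub_h = run.mm_t.select_sample(h)
    genes_h = filter_genes_for_factorization(sub_h, run.cfg.gene_annotation,
                                             run.blacklist_derivation.final)
    fsub_h = sub_h.subset_genes(genes_h)
    pvals = {}
    for k in range(6, 13):
        m = factorize(fsub_h, k, seed=seed)
        pvals[k] = overlap_pvalue(
            k_overlap(m), m.n_unfiltered_genes,
            min(300, len(m.gene_scores)))
    k_sel = select_k_from_pvalues(pvals)

    rhos = []
    for sample in run.mm_t.samples:
        sub = run.mm_t.select_sample(sample)
        genes = filter_genes_for_factorization(
            sub, run.cfg.gene_annotation, run.blacklist_derivation.final)
        fsub = sub.subset_genes(genes)
        recon = ensemble_reconstruction(fsub, k_sel, seed=seed,
                                        n_restarts=n_restarts)
        meta = run.truth.cells.loc[recon.index]
        for lineage in ("CD4", "CD8"):
            mask = (meta["lineage"] == lineage).to_numpy()
            if mask.sum() < 30:
                continue
            traj = diffusion_components(recon.loc[mask], bandwidth=4.0)
            grad = meta.loc[mask, "gradient_t"]
            on_grad = grad.notna().to_numpy()
            rho = stats.spearmanr(
                traj.components["DC1"].to_numpy()[on_grad],
                grad.to_numpy()[on_grad]).statistic
            rhos.append(abs(float(rho)))
    return rhos


# ---------------------------------------------------------------------------
# projection


def projection_accuracy(run: CohortRun, holdout_frac: float = 0.2) -> dict:
    """Held-out reference cells assigned to their true (tissue, condition,
    lineage) group via (tissue, condition, subset) centroids."""
    seed = run.cfg.seed
    mm_t, meta = run.mm_t, run.truth_t
    merged_hv = select_hvgs(dropout_scores(mm_t))
    hvgs = pd.Index(sorted(set(run.hvg_union) | set(merged_hv)))
    hvgs = hvgs[hvgs.isin(mm_t.genes)]
    rng = np.random.default_rng(seed)
    hold = rng.random(mm_t.n_cells) < holdout_frac
    ref = mm_t.subset_cells(~hold)
    query = mm_t.subset_cells(hold)
    fine = meta["tissue"] + "|" + meta["condition"] + "|" + meta["cell_type"]
    emb = embed_reference(ref, hvgs, seed=seed)
    centroids = build_centroids(emb, fine.loc[ref.cells])
    assign = assign_centroids(centroids, project_query(emb, query))

    lineage_of = {ct.name: ct.lineage for ct in run.cfg.cell_types}

    def coarsen(labels):
        out = []
        for lab in labels:
            tissue, cond, subset = lab.split("|")
            out.append(f"{tissue}|{cond}|{lineage_of[subset]}")
        return np.array(out)

    coarse_truth = (meta["tissue"] + "|" + meta["condition"] + "|"
                    + meta["lineage"]).loc[query.cells].to_numpy()
    acc = float((coarsen(assign.to_numpy()) == coarse_truth).mean())

    # exhaustive nearest-centroid oracle on the same coordinates
    qxy = project_query(emb, query)  # deterministic transform
    c = centroids[["umap1", "umap2"]].to_numpy()
    d = np.linalg.norm(qxy.to_numpy()[:, None, :] - c[None], axis=2)
    oracle = centroids.index.to_numpy()[np.argmin(d, axis=1)]
    return {"accuracy": acc,
            "oracle_agreement": float((oracle == assign.to_numpy()).mean())}
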
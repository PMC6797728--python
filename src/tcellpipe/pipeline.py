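"""End-to-end orchestration of the artifact-aware T-cell pipeline.

Stage order: simulate (or load) addresses -> index-swap resolution -> UMI
collapse -> per-cell QC -> per-sample clustering -> blacklist-based T-cell
identification -> merged clustering with CD4/CD8 ratios -> tissue
signature -> factor modules -> reference projection -> activation
trajectory.  Each run writes TSV/MTX/JSON artifacts plus a manifest
recording parameters, seeds, input hashes and per-stage cell/gene counts.

Cell-level metadata (tissue, condition, lineage) used for projection
centroids plays the role of the experimental design labels that accompany
each library in a real study; here they come from the generator's truth
table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .cluster import (ClusterLabeling, binomial_markers, cd4_cd8_ratio,
                      dropout_scores, select_hvgs, spearman_knn_louvain)
from .factors import (FactorModel, cd4_cd8_bias, cluster_factor_modules,
                      ensemble_reconstruction, factorize,
                      filter_genes_for_factorization, select_k)
from .matrix import MoleculeMatrix
from .normalize import pooled_size_factors
from .projection import (assign_centroids, assignment_counts, build_centroids,
                         diffusion_components, embed_reference, project_query)
from .qc import compute_cell_qc, filter_cells
from .signature import (derive_signature, flag_blood_outliers, gate_ccl5,
                        pairwise_de, signature_score)
from .simulate import SimConfig, simulate_dataset
from .swap import collapse_umis, resolve_swaps
from .tcell_id import (blacklist_fraction, derive_blacklist, flag_t_clusters,
                       identify_t_cells, sample_rpm_thresholds)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage toggles and thresholds, defaulting to the study values."""

    sim: SimConfig | None = None  # synthetic input
    addresses_path: str | None = None  # or a pre-made address table
    outdir: str = "run"
    seed: int = 0
    # swap correction
    majority_frac: float = 0.8
    umi_merge: bool = False
    # qc
    do_qc: bool = True
    mito_max: float = 0.10
    ratio_max: float = 1.5
    sd_window: float = 2.5
    # per-sample clustering
    hvg_window: int = 25
    hvg_abs_thresh: float = 0.15
    hvg_sd_mult: float = 6.0
    knn_k: int = 20
    # T-cell identification
    do_tcell_id: bool = True
    p_black: float = 0.001
    fc_black: float = 10.0
    p_white: float = 0.05
    b_c_sd_cutoff: float = 2.0
    # merged clustering
    merged_k: int = 12
    min_cluster_size: int = 100
    # tissue signature
    do_signature: bool = True
    sig_fc_min: float = 2.0
    sig_p_max: float = 0.05
    # factors
    do_factors: bool = True
    k_min: int = 6
    k_max: int = 12
    overlap_top_n: int = 300
    module_top_bottom_n: int = 50
    module_corr_min: float = 0.25
    factor_samples: list | None = None  # default: every sample
    # projection / trajectory
    do_projection: bool = True
    do_trajectory: bool = True
    trajectory_bandwidth: float = 4.0


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    matrix: MoleculeMatrix | None = None
    t_cells: pd.Index | None = None
    merged_clusters: ClusterLabeling | None = None
    size_factors: np.ndarray | None = None
    blacklist: pd.Index | None = None
    signatures: dict | None = None
    factor_models: dict | None = None
    modules: object | None = None
    embedding: object | None = None
    assignments: pd.Series | None = None
    trajectories: dict | None = None
    truth: object | None = None
    hvgs: pd.Index | None = None
    cell_lineage: pd.Series | None = None
    centroids: pd.DataFrame | None = None


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def _per_sample_clustering(mm: MoleculeMatrix, cfg: PipelineConfig):
    """Per-sample HVGs, Louvain clusters, size factors and T flags."""
    out = []
    hvg_union: set = set()
    for sample in mm.samples:
        sub = mm.select_sample(sample)
        scores = dropout_scores(sub, window=cfg.hvg_window)
        hvgs = select_hvgs(scores, cfg.hvg_abs_thresh, cfg.hvg_sd_mult)
        hvg_union.update(hvgs)
        clusters = spearman_knn_louvain(sub, hvgs, k=cfg.knn_k, seed=cfg.seed)
        sf = pooled_size_factors(sub, clusters)
        flag_t_clusters(sub, sf, clusters)
        out.append((sample, sub, sf, clusters))
    return out, pd.Index(sorted(hvg_union))


def run_pipeline(cfg: PipelineConfig, truth=None) -> PipelineResult:
    """Execute all enabled stages in dependency order."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "parameters": _config_dict(cfg),
                      "seed": cfg.seed, "counts": {}}

    def stage(name, **info):
        manifest["stages"].append(name)
        manifest["counts"][name] = info
        log.info("stage %s: %s", name, info)

    # --- input ------------------------------------------------------------
    if cfg.sim is not None:
        addresses, truth = simulate_dataset(cfg.sim)
        truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t")
    elif cfg.addresses_path:
        addresses = tio.read_addresses(cfg.addresses_path)
    else:
        raise ValueError("either sim config or addresses_path is required")
    manifest["input_hash"] = _hash_frame(
        addresses[["sample", "barcode", "umi", "gene", "reads"]])
    stage("input", rows=len(addresses))

    # --- swap correction + collapse ---------------------------------------
    resolved = resolve_swaps(addresses, cfg.majority_frac)
    stage("swap_correct", rows_in=len(addresses), rows_out=len(resolved))
    gene_index = (pd.Index(cfg.sim.gene_names) if cfg.sim is not None else None)
    mm = collapse_umis(resolved, umi_merge=cfg.umi_merge,
                       gene_index=gene_index)
    stage("collapse", cells=mm.n_cells, genes=mm.n_genes)

    # --- qc ----------------------------------------------------------------
    if cfg.do_qc:
        qc = compute_cell_qc(mm)
        kept = filter_cells(qc, cfg.mito_max, cfg.ratio_max, cfg.sd_window)
        qc.to_csv(outdir / "qc_report.tsv", sep="\t")
        mm = mm.subset_cells(mm.cells.isin(kept))
        stage("qc", cells_in=len(qc), cells_out=mm.n_cells)

    # --- per-sample clustering + T-cell identification ----------------------
    per_sample, hvg_union = _per_sample_clustering(mm, cfg)
    stage("per_sample_clustering",
          clusters={s: int(c.cluster_info.shape[0])
                    for s, _, _, c in per_sample},
          hvg_union=len(hvg_union))

    blacklist = pd.Index([])
    result = PipelineResult(outdir=outdir, manifest=manifest, truth=truth)
    if cfg.do_tcell_id:
        deriv = derive_blacklist(per_sample, cfg.p_black, cfg.fc_black,
                                 cfg.p_white)
        blacklist = deriv.final
        thresholds = sample_rpm_thresholds(mm)
        b_c = blacklist_fraction(mm, blacklist, thresholds)
        clusters_by_sample = {s: c for s, _, _, c in per_sample}
        t_cells = identify_t_cells(mm, clusters_by_sample, b_c,
                                   cfg.b_c_sd_cutoff)
        b_c.to_frame().to_csv(outdir / "blacklist_fraction.tsv", sep="\t")
        pd.Series(sorted(blacklist)).to_csv(
            outdir / "blacklist.tsv", sep="\t", index=False, header=["gene"])
        pd.Series(sorted(deriv.whitelist)).to_csv(
            outdir / "whitelist.tsv", sep="\t", index=False, header=["gene"])
        mm = mm.subset_cells(mm.cells.isin(t_cells))
        stage("tcell_id", blacklist=len(blacklist),
              whitelist=len(deriv.whitelist), t_cells=mm.n_cells)
        result.blacklist = blacklist
        result.t_cells = t_cells
    else:
        stage("tcell_id_skipped")

    # --- merged clustering --------------------------------------------------
    # extend the per-sample union with cohort-level variable genes: the
    # dropout score applied once across samples exposes tissue and
    # condition programs that are uniform within any one library
    merged_scores = dropout_scores(mm, window=cfg.hvg_window)
    try:
        merged_hvgs = select_hvgs(merged_scores, cfg.hvg_abs_thresh,
                                  cfg.hvg_sd_mult)
    except ValueError:
        merged_hvgs = pd.Index([])
    hvg_all = pd.Index(sorted(set(hvg_union) | set(merged_hvgs)))
    hvg_all = hvg_all[hvg_all.isin(mm.genes)]
    result.hvgs = hvg_all
    merged_k = min(cfg.merged_k, mm.n_cells - 1)
    clusters = spearman_knn_louvain(mm, hvg_all, k=merged_k, seed=cfg.seed,
                                    min_cluster_size=cfg.min_cluster_size)
    sf = pooled_size_factors(mm, clusters)
    ratios = cd4_cd8_ratio(mm, sf, clusters)
    markers = binomial_markers(mm, clusters)
    clusters.labels.to_frame().to_csv(outdir / "merged_clusters.tsv", sep="\t")
    markers.to_csv(outdir / "cluster_markers.tsv", sep="\t", index=False)
    stage("merged_clustering", clusters=len(clusters.cluster_ids()))
    result.matrix = mm
    result.merged_clusters = clusters
    result.size_factors = sf

    cell_lineage = clusters.labels.map(
        lambda c: "CD4" if ratios.loc[c] > 0 else "CD8")
    result.cell_lineage = cell_lineage

    meta = None
    if truth is not None:
        meta = truth.cells.loc[truth.cells.index.intersection(mm.cells)]

    # --- tissue signature ----------------------------------------------------
    if cfg.do_signature and meta is not None:
        result.signatures = _signature_stage(cfg, mm, sf, blacklist, meta,
                                             outdir, stage)

    # --- factor models -------------------------------------------------------
    if cfg.do_factors:
        models: dict[str, FactorModel] = {}
        fsubs: dict[str, MoleculeMatrix] = {}
        f_samples = cfg.factor_samples or mm.samples
        for sample in f_samples:
            sub = mm.select_sample(sample)
            genes = filter_genes_for_factorization(
                sub, cfg.sim.gene_annotation if cfg.sim is not None else None,
                blacklist)
            fsub = sub.subset_genes(genes)
            fsubs[sample] = fsub
            cands = {k: factorize(fsub, k, seed=cfg.seed)
                     for k in range(cfg.k_min, cfg.k_max + 1)}
            k_sel = select_k(cands, top_n=cfg.overlap_top_n)
            model = cands[k_sel]
            lin = cell_lineage.loc[sub.cells].to_numpy()
            bias = cd4_cd8_bias(model, lin == "CD4", lin == "CD8")
            model.gene_scores.to_csv(
                outdir / f"factors_{sample}_gene_scores.tsv", sep="\t")
            bias.to_frame().to_csv(outdir / f"factors_{sample}_bias.tsv",
                                   sep="\t")
            models[sample] = model
        modules = (cluster_factor_modules(list(models.values()),
                                          cfg.module_top_bottom_n,
                                          cfg.module_corr_min)
                   if len(models) >= 2 else None)
        if modules is not None:
            rows = [{"module": i, "n_factors": len(m.members),
                     "mean_r": m.mean_correlation,
                     "top_genes": ",".join(m.top_genes.index[:10])}
                    for i, m in enumerate(modules.modules)]
            pd.DataFrame(rows).to_csv(outdir / "modules.tsv", sep="\t",
                                      index=False)
        stage("factors", selected_k={s: m.k for s, m in models.items()},
              modules=0 if modules is None else len(modules.modules))
        result.factor_models = models
        result.modules = modules

        # --- trajectory ------------------------------------------------------
        if cfg.do_trajectory:
            result.trajectories = {}
            for sample, model in models.items():
                recon = ensemble_reconstruction(fsubs[sample], model.k,
                                                seed=cfg.seed)
                lin = cell_lineage.loc[recon.index]
                for lineage in ("CD4", "CD8"):
                    cs = recon.loc[(lin == lineage).to_numpy()]
                    if len(cs) < 30:
                        continue
                    traj = diffusion_components(cs, cfg.trajectory_bandwidth)
                    traj.components.to_csv(
                        outdir / f"trajectory_{sample}_{lineage}.tsv",
                        sep="\t")
                    result.trajectories[(sample, lineage)] = traj
            stage("trajectory", computed=len(result.trajectories))

    # --- projection ----------------------------------------------------------
    if cfg.do_projection and meta is not None:
        ref_mask = (meta["tissue"] != "blood").to_numpy()
        query_mask = ~ref_mask
        if ref_mask.sum() >= 50 and query_mask.sum() > 0:
            ref_mm = mm.subset_cells(ref_mask)
            query_mm = mm.subset_cells(query_mask)
            emb = embed_reference(ref_mm, hvg_all, seed=cfg.seed)
            # centroid units follow the clustering: one centroid per
            # (tissue, condition, cluster) combination of the reference
            groups = (meta["tissue"] + "|" + meta["condition"] + "|c"
                      + clusters.labels.loc[meta.index].astype(str))
            centroids = build_centroids(emb, groups.loc[ref_mm.cells])
            result.centroids = centroids
            qcoords = project_query(emb, query_mm)
            assign = assign_centroids(centroids, qcoords)
            counts = assignment_counts(
                assign, pd.Series(query_mm.cell_sample, index=query_mm.cells))
            emb.coordinates.to_csv(outdir / "reference_umap.tsv", sep="\t")
            qcoords.to_csv(outdir / "query_umap.tsv", sep="\t")
            counts.to_csv(outdir / "projection_counts.tsv", sep="\t")
            stage("projection", reference=ref_mm.n_cells,
                  query=query_mm.n_cells)
            result.embedding = emb
            result.assignments = assign

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    return result


def _signature_stage(cfg, mm, sf, blacklist, meta, outdir, stage):
    """CCL5 gating, 4-way pairwise DE per tissue, scores and outliers."""
    ccl5 = gate_ccl5(mm)
    resting = meta.index[(meta["condition"] == "rest")]
    tem = pd.Index(ccl5).intersection(resting)
    tissues = sorted(set(meta["tissue"]) - {"blood"})
    blood_samples = sorted(set(meta.loc[meta["tissue"] == "blood", "sample"]))
    comparisons: dict = {}
    for tissue in tissues:
        t_samples = sorted(set(meta.loc[meta["tissue"] == tissue, "sample"]))
        tables = []
        for ts in t_samples:
            a = tem[(meta.loc[tem, "sample"] == ts).to_numpy()]
            for bs in blood_samples:
                b = tem[(meta.loc[tem, "sample"] == bs).to_numpy()]
                tables.append(pairwise_de(mm, sf, a, b,
                                          exclude_genes=blacklist))
        comparisons[tissue] = tables
    sigs = derive_signature(comparisons, cfg.sig_fc_min, cfg.sig_p_max)
    for tissue, genes in sigs.items():
        pd.Series(sorted(genes)).to_csv(
            outdir / f"signature_{tissue}.tsv", sep="\t", index=False,
            header=["gene"])
    outliers = pd.Index([])
    if len(sigs["combined"]):
        score = signature_score(mm, sf, sigs["combined"])
        blood_cells = meta.index[meta["tissue"] == "blood"].intersection(tem)
        tissue_cells = tem.difference(blood_cells)
        if len(blood_cells) and len(tissue_cells):
            outliers = flag_blood_outliers(score.loc[blood_cells],
                                           score.loc[tissue_cells])
        score.to_frame().to_csv(outdir / "signature_scores.tsv", sep="\t")
    stage("signature", tem_cells=len(tem),
          sizes={t: len(g) for t, g in sigs.items()},
          blood_outliers=len(outliers))
    return sigs


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    if cfg.sim is not None:
        d["sim"] = {"samples": [s.name for s in cfg.sim.samples],
                    "cells_per_sample": cfg.sim.cells_per_sample,
                    "n_genes": cfg.sim.n_genes, "seed": cfg.sim.seed,
                    "swap_rate": cfg.sim.swap_rate,
                    "chimera_rate": cfg.sim.chimera_rate}
    return d
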
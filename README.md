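# tcellpipe

An artifact-aware analysis pipeline for multiplexed droplet scRNA-seq of
human T cells across blood and tissue sites, together with a
ground-truthed synthetic-data generator that emulates the data structure
the pipeline assumes.

Droplet libraries multiplexed on patterned flow cells suffer two molecular
artifacts that corrupt naive count matrices: **index swapping**, where a
fraction of reads is reassigned between sample indices so the same
(barcode, UMI, gene) address appears in several samples, and **PCR
recombination chimeras**, where a molecule is duplicated under a wrong
cell barcode with anomalously few supporting reads.  When the cells of
interest are T cells purified from tissues, a third problem follows:
contaminating cell types (B cells, myeloid cells, epithelium) and
doublets must be removed computationally without discarding genuine
T-cell diversity.

`tcellpipe` implements the full workflow:

1. **Swap resolution** — for each address pooled across sample indices,
   the index holding strictly more than 80% of its reads keeps the
   address; ambiguous addresses are removed everywhere.  UMIs are then
   collapsed into molecules with per-(cell, gene) mean reads-per-molecule
   (RPM) statistics.
2. **Cell QC** — mitochondrial fraction > 10%, gene-body/exon ratio
   > 1.5, or mean RPM / molecules-per-gene beyond 2.5 SD of the library
   mean.
3. **Variable genes and clustering** — dropout score
   `ds_g = |f_g − f_g^max| / √f_g^max` over a 25-gene rolling window of
   expression-matched genes (selected at `ds > 0.15` or
   `ds > ⟨ds⟩ + 6σ`), Spearman kNN graph, Louvain communities, and
   cluster-stratified pooled size-factor normalization.
4. **T-cell identification** — clusters enriched for both CD3D and TRAC
   are T clusters; a blacklist of contaminant-specific genes (rank-sum
   `p_adj < 0.001`, >10-fold toward any non-T cluster, minus a whitelist
   of T-enriched genes) is counted per cell above a chimera-aware RPM
   threshold `T_s = T_h · RPM_s / RPM_h`; cells above two SD of the
   fitted per-library blacklist-fraction Gaussian, and all non-T-cluster
   cells, are discarded.
5. **Tissue signatures** — CCL5⁺ effector-memory cells gated at the RPM
   density minimum; genes more than two-fold up (adjusted p < 0.05)
   toward tissue in *all* tissue-donor × blood-donor comparisons;
   per-cell signature scores and blood outlier flags; classic preranked
   GSEA with 10,000 gene-label permutations.
6. **Expression modules** — a pluggable nonnegative Poisson factor model
   (default: KL-NMF), K selected in 6–12 by the hypergeometric top-300
   gene-overlap rule, and cross-sample modules from average-linkage
   clustering of factor gene scores (mean pairwise r > 0.25), with
   per-factor CD4/CD8 bias.
7. **Projection and trajectories** — a Spearman-metric UMAP reference
   atlas with a frozen transform for query cells, nearest-centroid
   assignment per (tissue, condition, subset) group, and diffusion
   components (Gaussian kernel, bandwidth 4) of factor-model cell scores
   as activation-trajectory coordinates.

The synthetic generator plants every structure the stages rely on — swap
and chimera artifacts, seven T subsets plus three contaminant types,
doublets, dead cells, a shared tissue-residency program, per-tissue
markers, and a continuous activation gradient — and records full ground
truth, so every stage is scored against known answers.  See
`docs/methods.md` for models, parameters and design decisions.

## Worked example

```python
from tcellpipe import PipelineConfig, default_config, run_pipeline

cfg = PipelineConfig(
    sim=default_config(seed=5, cells_per_sample=400, n_samples=3),
    outdir="run", seed=5, k_min=6, k_max=7, min_cluster_size=30)
result = run_pipeline(cfg)
print(result.manifest["counts"])
```

which prints (one line per stage; all outputs are also written as
TSV/MTX/JSON under `run/`):

```
{'input': {'rows': 605899},
 'swap_correct': {'rows_in': 605899, 'rows_out': 548993},
 'collapse': {'cells': 1200, 'genes': 2000},
 'qc': {'cells_in': 1200, 'cells_out': 1082},
 'per_sample_clustering': {'clusters': {'blood_A': 12, 'blood_B': 12,
                                        'lung_D1': 11}, 'hvg_union': 238},
 'tcell_id': {'blacklist': 61, 'whitelist': 185, 't_cells': 535},
 'merged_clustering': {'clusters': 9},
 'signature': {'tem_cells': 144, 'sizes': {'lung': 16, 'combined': 16},
               'blood_outliers': 0},
 'factors': {'selected_k': {'blood_A': 6, 'blood_B': 6, 'lung_D1': 6},
             'modules': 5},
 'trajectory': {'computed': 6},
 'projection': {'reference': 179, 'query': 356}}
```

Reading the numbers: 605,899 address rows lose ~9% of rows to
swap-ambiguity resolution; 1,200 barcodes collapse to a 2,000-gene
molecule matrix; QC removes 118 cells (dead/high-intron/outlying
coverage); per-library clustering finds 11–12 communities whose CD3D/TRAC
enrichment drives a 61-gene contaminant blacklist; 535 cells survive
T-cell identification at this small scale; the lung-vs-blood comparison
recovers a 16-gene signature; each library is factorized at the selected
K = 6; and the blood query cells are projected onto the lung reference
with per-group assignment counts in `run/projection_counts.tsv`.

The same pipeline is exercised at study scale (6 libraries × 2,000
cells) by the benchmark helpers in `tcellpipe.benchmarks`, which score
every stage against the generator's ground truth.

A command-line interface mirrors the stages:

```bash
tcellpipe simulate --out sim --seed 1 --cells-per-sample 2000
tcellpipe swap-correct --in sim/addresses.tsv.gz --out matrix
tcellpipe qc --in matrix --out qc --mito-max 0.10 --sd 2.5
tcellpipe cluster --in matrix --out clusters --k 20 --seed 1
tcellpipe run-all --out run --seed 1
```

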
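"""Per-cell quality filters applied before any analysis.

Cells are removed when more than 10% of their molecules are mitochondrial,
when the ratio of gene-body to exclusively-exonic molecules exceeds 1.5
(a signature of nuclear or degraded RNA), or when their mean reads per
molecule or mean molecules per gene deviates by more than 2.5 standard
deviations from the sample mean.  SD statistics come from the pre-filter
population of each sample (single pass).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import MoleculeMatrix

log = logging.getLogger(__name__)


def compute_cell_qc(mm: MoleculeMatrix,
                    mito_genes: list[str] | None = None) -> pd.DataFrame:
    """Per-cell QC metrics: mito_fraction, genebody_exon_ratio, mean_rpm,
    mean_molecules_per_gene.

    ``mito_genes`` defaults to genes whose name starts with ``MT-``.  The
    gene-body/exon ratio needs the exonic molecule counts the generator
    (or upstream aligner) records in ``cell_meta``; without them the ratio
    is reported as 1.0.
    """
    if mm.n_cells == 0:
        raise ValueError("empty molecule matrix")
    if mito_genes is None:
        mito_genes = [g for g in mm.genes if str(g).startswith("MT-")]
    mito_idx = mm.genes.get_indexer(pd.Index(mito_genes))
    mito_idx = mito_idx[mito_idx >= 0]

    molecules = mm.library_sizes().astype(float)
    empty = molecules == 0
    if empty.any():
        log.warning("%d cells with zero molecules excluded from QC",
                    int(empty.sum()))

    mito = (np.asarray(mm.counts[:, mito_idx].sum(axis=1)).ravel()
            if len(mito_idx) else np.zeros(mm.n_cells))
    reads = np.asarray(mm.counts.multiply(mm.rpm).sum(axis=1)).ravel()
    genes_detected = np.diff(mm.counts.indptr)

    with np.errstate(divide="ignore", invalid="ignore"):
        mito_fraction = np.where(molecules > 0, mito / molecules, np.nan)
        mean_rpm = np.where(molecules > 0, reads / molecules, np.nan)
        mean_mpg = np.where(genes_detected > 0,
                            molecules / genes_detected, np.nan)
    ratio = np.ones(mm.n_cells)
    if mm.cell_meta is not None and "exonic_molecules" in mm.cell_meta:
        exonic = mm.cell_meta["exonic_molecules"].to_numpy().astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(exonic > 0, molecules / exonic, np.inf)

    qc = pd.DataFrame({
        "sample": mm.cell_sample,
        "mito_fraction": mito_fraction,
        "genebody_exon_ratio": ratio,
        "mean_rpm": mean_rpm,
        "mean_molecules_per_gene": mean_mpg,
    }, index=mm.cells)
    return qc.loc[~empty]


def filter_cells(qc: pd.DataFrame, mito_max: float = 0.10,
                 ratio_max: float = 1.5, sd_window: float = 2.5) -> pd.Index:
    """Return the barcodes that pass all QC rules.

    Deviation rules are two-sided and per sample, with mean/SD computed on
    the unfiltered population.  Samples with fewer than 10 cells are
    refused (too few cells for a meaningful SD).
    """
    keep = np.ones(len(qc), dtype=bool)
    keep &= qc["mito_fraction"].to_numpy() <= mito_max
    keep &= qc["genebody_exon_ratio"].to_numpy() <= ratio_max
    for sample, sub in qc.groupby("sample", observed=True, sort=False):
        if len(sub) < 10:
            raise ValueError(
                f"sample {sample!r} has only {len(sub)} cells; "
                "QC deviation statistics need at least 10")
        loc = qc.index.get_indexer(sub.index)
        for col in ("mean_rpm", "mean_molecules_per_gene"):
            v = sub[col].to_numpy()
            mu, sd = np.nanmean(v), np.nanstd(v)
            keep[loc] &= np.abs(v - mu) <= sd_window * sd
    return qc.index[keep]
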
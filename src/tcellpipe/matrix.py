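"""Molecule-level count container shared by every pipeline stage.

A :class:`MoleculeMatrix` holds UMI-collapsed molecular counts (cells x
genes) together with a parallel matrix of mean reads-per-molecule (RPM) for
each (cell, gene) entry and a per-sample scalar RPM.  The RPM side-car is
what makes chimera-aware detection thresholds possible downstream, so it is
carried as a first-class citizen rather than recomputed from raw reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

CELL_SEP = "|"  # cell ids are "<sample><CELL_SEP><barcode>"


def make_cell_id(sample: str, barcode: str) -> str:
    return f"{sample}{CELL_SEP}{barcode}"


@dataclass
class MoleculeMatrix:
    """UMI counts with read-support statistics.

    Attributes
    ----------
    counts
        CSR matrix of molecule (UMI) counts, cells x genes.
    rpm
        CSR matrix with the same sparsity pattern: mean reads per molecule
        for each nonzero (cell, gene).  Entries are >= 1.
    cells
        Cell identifiers, ``"<sample>|<barcode>"``.
    genes
        Gene identifiers.
    cell_sample
        Sample id per cell (parallel to ``cells``).
    sample_rpm
        Mean reads per molecule for each sample (total reads / total
        molecules over the whole sample).
    cell_meta
        Optional per-cell annotations (e.g. exonic molecule counts from the
        generator).  Indexed like ``cells``.
    """

    counts: sp.csr_matrix
    rpm: sp.csr_matrix
    cells: pd.Index
    genes: pd.Index
    cell_sample: np.ndarray
    sample_rpm: dict = field(default_factory=dict)
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.rpm = sp.csr_matrix(self.rpm)
        if self.counts.shape != self.rpm.shape:
            raise ValueError("counts and rpm shapes differ")
        if self.counts.shape[0] != len(self.cells):
            raise ValueError("cell index length mismatch")
        if self.counts.shape[1] != len(self.genes):
            raise ValueError("gene index length mismatch")
        self.cells = pd.Index(self.cells)
        self.genes = pd.Index(self.genes)
        self.cell_sample = np.asarray(self.cell_sample)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def samples(self) -> list:
        seen: dict = {}
        for s in self.cell_sample:
            seen.setdefault(s, None)
        return list(seen)

    def gene_index(self, gene: str) -> int:
        idx = self.genes.get_indexer([gene])[0]
        if idx < 0:
            raise KeyError(f"gene {gene!r} not present")
        return int(idx)

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, mask_or_index) -> "MoleculeMatrix":
        """Restrict to a boolean mask or positional index over cells."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        meta = None
        if self.cell_meta is not None:
            meta = self.cell_meta.iloc[idx]
        return MoleculeMatrix(
            counts=self.counts[idx],
            rpm=self.rpm[idx],
            cells=self.cells[idx],
            genes=self.genes,
            cell_sample=self.cell_sample[idx],
            sample_rpm=dict(self.sample_rpm),
            cell_meta=meta,
        )

    def subset_genes(self, genes) -> "MoleculeMatrix":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0])
            raise KeyError(f"genes not present: {missing[:5]}")
        return MoleculeMatrix(
            counts=self.counts[:, idx],
            rpm=self.rpm[:, idx],
            cells=self.cells,
            genes=pd.Index(genes),
            cell_sample=self.cell_sample,
            sample_rpm=dict(self.sample_rpm),
            cell_meta=self.cell_meta,
        )

    def select_sample(self, sample) -> "MoleculeMatrix":
        return self.subset_cells(self.cell_sample == sample)

    def normalized(self, size_factors: np.ndarray) -> sp.csr_matrix:
        """Counts divided per cell by its size factor (CSR, float)."""
        sf = np.asarray(size_factors, dtype=float)
        if sf.shape[0] != self.n_cells:
            raise ValueError("size factor length mismatch")
        if np.any(sf <= 0):
            raise ValueError("size factors must be positive")
        d = sp.diags(1.0 / sf)
        return sp.csr_matrix(d @ self.counts)


def concatenate(parts: list[MoleculeMatrix]) -> MoleculeMatrix:
    """Stack matrices that share a gene index (cells are concatenated)."""
    if not parts:
        raise ValueError("nothing to concatenate")
    genes = parts[0].genes
    for p in parts[1:]:
        if not p.genes.equals(genes):
            raise ValueError("gene indices differ between parts")
    sample_rpm: dict = {}
    for p in parts:
        sample_rpm.update(p.sample_rpm)
    metas = [p.cell_meta for p in parts]
    meta = pd.concat(metas) if all(m is not None for m in metas) else None
    return MoleculeMatrix(
        counts=sp.vstack([p.counts for p in parts], format="csr"),
        rpm=sp.vstack([p.rpm for p in parts], format="csr"),
        cells=pd.Index(np.concatenate([p.cells.to_numpy() for p in parts])),
        genes=genes,
        cell_sample=np.concatenate([p.cell_sample for p in parts]),
        sample_rpm=sample_rpm,
        cell_meta=meta,
    )
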
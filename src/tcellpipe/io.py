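"""Standard-format I/O: address TSVs, MatrixMarket matrices, gene lists."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import CELL_SEP, MoleculeMatrix
from .simulate import BARCODE, EXONIC, GENE, READS, SAMPLE, UMI

ADDRESS_DTYPES = {SAMPLE: str, BARCODE: str, UMI: np.int64, GENE: str,
                  READS: np.int64}


def write_addresses(df: pd.DataFrame, path) -> None:
    """Address table as (optionally gzipped) TSV."""
    df.to_csv(path, sep="\t", index=False)


def read_addresses(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={SAMPLE: str, BARCODE: str,
                                            GENE: str})
    missing = [c for c in (SAMPLE, BARCODE, UMI, GENE, READS)
               if c not in df.columns]
    if missing:
        raise ValueError(f"address table missing columns: {missing}")
    if EXONIC in df.columns:
        df[EXONIC] = df[EXONIC].astype(bool)
    return df


def write_molecule_matrix(mm: MoleculeMatrix, outdir) -> None:
    """MTX (1-based MatrixMarket) + barcodes/genes TSV + rpm sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "counts.mtx", sp.coo_matrix(mm.counts))
    pd.Series(mm.cells).to_csv(outdir / "barcodes.tsv", sep="\t",
                               index=False, header=False)
    pd.Series(mm.genes).to_csv(outdir / "genes.tsv", sep="\t",
                               index=False, header=False)
    coo = sp.coo_matrix(mm.rpm)
    pd.DataFrame({"cell": mm.cells[coo.row], "gene": mm.genes[coo.col],
                  "rpm": coo.data}).to_csv(outdir / "rpm.tsv", sep="\t",
                                           index=False)
    meta = {"sample_rpm": {str(k): float(v)
                           for k, v in mm.sample_rpm.items()}}
    (outdir / "matrix_meta.json").write_text(json.dumps(meta, indent=1))
    if mm.cell_meta is not None:
        mm.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")


def read_molecule_matrix(indir) -> MoleculeMatrix:
    indir = Path(indir)
    raw = scipy.io.mmread(indir / "counts.mtx")
    if getattr(raw, "dtype", None) == np.dtype(object):  # empty matrix
        raw = raw.astype(np.float64)
    counts = sp.csr_matrix(raw)
    cells = pd.Index(pd.read_csv(indir / "barcodes.tsv", sep="\t",
                                 header=None)[0].astype(str), name="cell")
    genes = pd.Index(pd.read_csv(indir / "genes.tsv", sep="\t",
                                 header=None)[0].astype(str), name="gene")
    if counts.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match sidecars "
            f"({len(cells)} barcodes, {len(genes)} genes)")
    rpm_tab = pd.read_csv(indir / "rpm.tsv", sep="\t")
    ci = cells.get_indexer(rpm_tab["cell"].astype(str))
    gi = genes.get_indexer(rpm_tab["gene"].astype(str))
    if (ci < 0).any() or (gi < 0).any():
        raise ValueError("rpm sidecar refers to unknown cells or genes")
    rpm = sp.csr_matrix((rpm_tab["rpm"].to_numpy(dtype=float),
                         (ci.astype(int), gi.astype(int))),
                        shape=counts.shape)
    meta_path = indir / "matrix_meta.json"
    sample_rpm = {}
    if meta_path.exists():
        sample_rpm = json.loads(meta_path.read_text()).get("sample_rpm", {})
    cm_path = indir / "cell_meta.tsv"
    cell_meta = (pd.read_csv(cm_path, sep="\t", index_col=0)
                 if cm_path.exists() else None)
    cell_sample = np.array([c.split(CELL_SEP, 1)[0] for c in cells])
    return MoleculeMatrix(counts, rpm, cells, genes, cell_sample,
                          sample_rpm, cell_meta)


def write_gene_set(genes, path, stats: pd.DataFrame | None = None) -> None:
    if stats is not None:
        stats.loc[list(genes)].to_csv(path, sep="\t")
    else:
        pd.Series(sorted(genes)).to_csv(path, sep="\t", index=False,
                                        header=["gene"])


def read_gene_set(path) -> pd.Index:
    df = pd.read_csv(path, sep="\t")
    col = "gene" if "gene" in df.columns else df.columns[0]
    return pd.Index(df[col].astype(str))
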
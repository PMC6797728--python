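"""Index-swap resolution and UMI collapse.

Index swapping on patterned flow cells moves a fraction of reads between
multiplexed sample indices, so the same address (cell barcode, UMI, gene)
appears in several samples.  For each address pooled across samples, the
sample holding strictly more than ``majority_frac`` (default 80%) of its
reads keeps the address; if no sample passes, the address is removed from
every sample.  Surviving addresses are then collapsed one molecule per
distinct (sample, barcode, UMI, gene), recording the mean reads per
molecule (RPM) per (cell, gene) and per sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import MoleculeMatrix, make_cell_id
from .simulate import BARCODE, EXONIC, GENE, READS, SAMPLE, UMI

ADDRESS_COLS = [BARCODE, UMI, GENE]


def resolve_swaps(addresses: pd.DataFrame,
                  majority_frac: float = 0.8) -> pd.DataFrame:
    """Resolve swapped addresses by strict read-majority voting.

    Rows whose (barcode, UMI, gene) address has a sample holding strictly
    more than ``majority_frac`` of the pooled reads survive in that sample
    only; ambiguous addresses are dropped from all samples.  The winner
    keeps only its own rows — sub-majority reads observed in other samples
    are discarded, not re-credited.
    """
    if not 0 < majority_frac < 1:
        raise ValueError("majority_frac must be in (0, 1)")
    if addresses.empty:
        return addresses.copy()

    grp = addresses.groupby(ADDRESS_COLS, observed=True, sort=False)
    total = grp[READS].transform("sum").to_numpy()
    winner = grp[READS].transform("max").to_numpy()
    is_max = addresses[READS].to_numpy() == winner
    n_max = (grp[READS].transform(lambda r: (r == r.max()).sum()).to_numpy()
             if majority_frac < 0.5 else np.ones_like(total))
    # a row survives iff it is the unique strict-majority holder
    keep = is_max & (n_max == 1) & (winner > majority_frac * total)
    return addresses.loc[keep].reset_index(drop=True)


def _directional_umi_merge(df: pd.DataFrame, umi_len: int = 8) -> pd.DataFrame:
    """Merge hamming-distance-1 UMIs within (sample, barcode, gene).

    Conservative directional rule: a UMI is absorbed by a 1-mismatch
    neighbour whose read count is at least twice its own; reads are summed
    into the winner.  UMIs are integer-encoded, 2 bits per base.
    """
    df = df.sort_values(READS, ascending=False, kind="stable").reset_index(drop=True)
    key = df.groupby([SAMPLE, BARCODE, GENE], observed=True, sort=False).ngroup()
    umi = df[UMI].to_numpy().astype(np.int64)
    reads = df[READS].to_numpy().copy()
    index = {}
    parent = np.arange(len(df))
    for i in range(len(df)):
        k = (int(key.iloc[i]), int(umi[i]))
        merged = False
        for pos in range(umi_len):
            for b in range(4):
                nb = (umi[i] & ~(3 << (2 * pos))) | (b << (2 * pos))
                if nb == umi[i]:
                    continue
                j = index.get((k[0], int(nb)))
                if j is not None and reads[j] >= 2 * reads[i]:
                    reads[j] += reads[i]
                    parent[i] = j
                    merged = True
                    break
            if merged:
                break
        if not merged:
            index[k] = i
    keep = parent == np.arange(len(df))
    out = df.loc[keep].copy()
    out[READS] = reads[keep]
    return out.reset_index(drop=True)


def collapse_umis(addresses: pd.DataFrame, umi_merge: bool = False,
                  gene_index: pd.Index | None = None) -> MoleculeMatrix:
    """Collapse a swap-resolved address table into a molecule matrix.

    Each distinct (sample, barcode, UMI, gene) becomes one molecule; per
    (cell, gene) the mean RPM is total reads / molecules.  With
    ``umi_merge`` the directional hamming-1 merge is applied first.
    """
    df = addresses
    if umi_merge and not df.empty:
        df = _directional_umi_merge(df)

    if df.empty:
        genes = gene_index if gene_index is not None else pd.Index([], dtype=object)
        empty = sp.csr_matrix((0, len(genes)))
        return MoleculeMatrix(empty, empty.copy(), pd.Index([], dtype=object),
                              pd.Index(genes), np.array([], dtype=object))

    per_cg = (df.groupby([SAMPLE, BARCODE, GENE], observed=True, sort=True)
              .agg(molecules=(UMI, "size"), reads=(READS, "sum"),
                   **({"exonic": (EXONIC, "sum")} if EXONIC in df else {}))
              .reset_index())

    cell_ids = np.array([make_cell_id(s, b) for s, b in
                         zip(per_cg[SAMPLE], per_cg[BARCODE])])
    cells = pd.Index(pd.unique(cell_ids), name="cell")
    genes = (pd.Index(gene_index) if gene_index is not None
             else pd.Index(np.sort(per_cg[GENE].unique()), name="gene"))
    ci = cells.get_indexer(cell_ids)
    gi = genes.get_indexer(per_cg[GENE].to_numpy())
    if (gi < 0).any():
        raise ValueError("address table contains genes absent from gene_index")

    shape = (len(cells), len(genes))
    counts = sp.csr_matrix(
        (per_cg["molecules"].to_numpy(), (ci, gi)), shape=shape)
    rpm = sp.csr_matrix(
        (per_cg["reads"].to_numpy() / per_cg["molecules"].to_numpy(),
         (ci, gi)), shape=shape)

    cell_sample = pd.Series(
        {make_cell_id(s, b): s for s, b in zip(per_cg[SAMPLE], per_cg[BARCODE])}
    ).loc[cells].to_numpy()

    per_s = df.groupby(SAMPLE, observed=True)[READS].agg(["sum", "size"])
    sample_rpm = (per_s["sum"] / per_s["size"]).to_dict()

    meta = (pd.DataFrame({"total_molecules": np.bincount(ci, minlength=len(cells)),
                          }, index=cells))
    if "exonic" in per_cg:
        meta["exonic_molecules"] = np.bincount(
            ci, weights=per_cg["exonic"].to_numpy(),
            minlength=len(cells)).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sp.SparseEfficiencyWarning)
        return MoleculeMatrix(counts, rpm, cells, genes, cell_sample,
                              sample_rpm, meta)
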
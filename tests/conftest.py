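import numpy as np
import pandas as pd
import pytest

from tcellpipe import (collapse_umis, default_config, resolve_swaps,
                       simulate_dataset)
from tcellpipe.simulate import CellType, SampleSpec, SimConfig


@pytest.fixture(scope="session")
def small_cohort():
    """Compact four-library cohort with study-like artifact rates."""
    cfg = default_config(seed=3, cells_per_sample=300, n_samples=4)
    addresses, truth = simulate_dataset(cfg)
    return cfg, addresses, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    cfg, addresses, truth = small_cohort
    mm = collapse_umis(resolve_swaps(addresses),
                       gene_index=pd.Index(cfg.gene_names))
    return mm


def two_type_config(seed=0, n_cells=500, marker_fold=4.0, n_genes=60,
                    **overrides):
    """Minimal one-sample configuration with a single planted marker."""
    genes = ["MARK"] + [f"G{i:03d}" for i in range(n_genes - 1)]
    ann = pd.DataFrame({"biotype": "protein_coding", "is_mito": False},
                       index=pd.Index(genes, name="gene"))
    base = dict(
        samples=[SampleSpec("s1", "blood", 10.0, activated_fraction=0.0)],
        cell_types=[
            CellType("A", "CD4", 0.5, 300.0, {"MARK": marker_fold}),
            CellType("B", "CD8", 0.5, 300.0, {}),
        ],
        cells_per_sample=n_cells,
        n_genes=n_genes,
        seed=seed,
        swap_rate=0.0,
        chimera_rate=0.0,
        multiplet_rate=0.0,
        dead_fraction=0.0,
        high_intron_fraction=0.0,
        gene_names=genes,
        gene_annotation=ann,
    )
    base.update(overrides)
    return SimConfig(**base)


def matrix_from_counts(counts, genes=None, sample="s1", rpm_value=5.0,
                       samples=None):
    """Dense counts -> MoleculeMatrix with a flat RPM side-car."""
    import scipy.sparse as sp
    from tcellpipe import MoleculeMatrix

    counts = np.asarray(counts)
    n, m = counts.shape
    if genes is None:
        genes = [f"g{i}" for i in range(m)]
    if samples is None:
        samples = np.array([sample] * n)
    cells = pd.Index([f"{s}|b{i:04d}" for i, s in enumerate(samples)])
    rpm = np.where(counts > 0, rpm_value, 0.0)
    return MoleculeMatrix(sp.csr_matrix(counts), sp.csr_matrix(rpm), cells,
                          pd.Index(genes), np.asarray(samples),
                          sample_rpm={s: rpm_value for s in set(samples)})


def counts_from_truth(molecules, truth, genes):
    """Dense cells x genes molecule counts straight from truth molecules."""
    cells = truth.cells.index
    gi = pd.Index(genes)
    counts = np.zeros((len(cells), len(gi)), dtype=int)
    cell_key = (molecules["sample"].astype(str) + "|"
                + molecules["barcode"].astype(str))
    ci = cells.get_indexer(cell_key)
    gidx = gi.get_indexer(molecules["gene"].astype(str))
    np.add.at(counts, (ci, gidx), 1)
    return pd.DataFrame(counts, index=cells, columns=gi)
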
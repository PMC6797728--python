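"""Ground-truthed generator for multi-sample droplet scRNA-seq of T cells.

The generator emulates the data structure of a multiplexed droplet
experiment on T cells from blood and tissue sites, at the *address* level
(sample index, cell barcode, UMI, gene, read count), which is the unit on
which index-swapping and chimera correction operate:

* several sample indices sequenced together, with a configurable fraction
  of reads reassigned to a wrong sample index (index swapping);
* PCR-recombination chimeras: molecules cloned under a wrong cell barcode
  with anomalously low read support, giving the bimodal reads-per-molecule
  distribution the correction thresholds assume;
* T-cell subpopulations (CD4 naive/CM/TRM, Treg, CD8 TEM/TRM, TEMRA) plus
  contaminating B, myeloid and epithelial cells; doublet barcodes that
  co-encapsulate a T cell and a contaminant;
* planted tissue-elevated gene programs and a continuous activation
  gradient mixing resting and activated expression programs.

Expression follows a gamma-Poisson (negative binomial) model per gene and
cell type; reads per molecule are lognormal, with a separate low-mean
lognormal for chimeric molecules.  Every molecule and cell carries a truth
record so downstream stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import make_cell_id

SAMPLE, BARCODE, UMI, GENE, READS = "sample", "barcode", "umi", "gene", "reads"
EXONIC = "exonic"
UMI_LEN = 8
UMI_SPACE = 4**UMI_LEN

_BASES = np.array(list("ACGT"))


def umi_to_str(code: int) -> str:
    digits = [(code >> (2 * i)) & 3 for i in range(UMI_LEN)]
    return "".join(_BASES[digits])


def str_to_umi(s: str) -> int:
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    return sum(lut[ch] << (2 * i) for i, ch in enumerate(s))


@dataclass
class CellType:
    """One simulated population: lineage, abundance and marker program."""

    name: str
    lineage: str  # "CD4", "CD8" or "contaminant"
    frequency: float
    library_size: float  # mean molecules per cell
    markers: dict = field(default_factory=dict)  # gene -> fold elevation (>1)


@dataclass
class SampleSpec:
    """One sequencing library: a tissue site from one donor."""

    name: str
    tissue: str
    rpm_mean: float  # mean reads per genuine molecule (sequencing depth)
    activated_fraction: float = 0.5


@dataclass
class SimConfig:
    samples: list
    cell_types: list
    cells_per_sample: int = 2000
    n_genes: int = 2000
    seed: int = 0
    # artifact rates
    swap_rate: float = 0.01
    chimera_rate: float = 0.02
    chimera_rpm_mean: float = 1.3
    rpm_sigma: float = 0.35
    chimera_rpm_sigma: float = 0.25
    # biology
    dispersion: float = 0.15  # NB overdispersion (1/shape of the gamma)
    library_sigma: float = 0.25  # lognormal spread of per-cell library size
    multiplet_rate: float = 0.02
    dead_fraction: float = 0.05
    mito_beta: tuple = (2.0, 60.0)  # healthy-cell mito fraction
    dead_mito_beta: tuple = (20.0, 50.0)  # dead-cell mito fraction
    intron_ratio_mean: float = 1.15
    intron_ratio_sd: float = 0.08
    high_intron_fraction: float = 0.02
    high_intron_ratio: float = 1.9
    activation_gradient: float = 0.25  # fraction of activated cells on gradient
    activation_markers: dict = field(default_factory=dict)  # gene -> fold
    tissue_signature_genes: dict = field(default_factory=dict)  # gene -> fold
    tissue_markers: dict = field(default_factory=dict)  # tissue -> {gene: fold}
    exclusive_genes: frozenset = frozenset()  # zero unless a type's marker
    gene_names: list = field(default_factory=list)
    gene_annotation: pd.DataFrame | None = None  # gene, biotype, is_mito
    marker_base: float = 0.5  # baseline expression assigned to marker genes
    special_base: dict = field(default_factory=dict)  # gene -> baseline override
    pinned_genes: frozenset = frozenset()  # keep absolute rate across types

    def validate(self) -> None:
        if self.cells_per_sample <= 0 or self.n_genes <= 0:
            raise ValueError("cells_per_sample and n_genes must be positive")
        if not self.samples or not self.cell_types:
            raise ValueError("need at least one sample and one cell type")
        for r in (self.swap_rate, self.chimera_rate, self.multiplet_rate,
                  self.dead_fraction, self.activation_gradient,
                  self.high_intron_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        for ct in self.cell_types:
            for g, fold in ct.markers.items():
                if fold <= 1:
                    raise ValueError(f"marker fold must be > 1 ({ct.name}:{g})")
        freq = sum(ct.frequency for ct in self.cell_types)
        if not np.isclose(freq, 1.0, atol=1e-6):
            raise ValueError(f"cell type frequencies sum to {freq}, not 1")


@dataclass
class GroundTruth:
    """Truth records for every simulated cell, molecule and planted gene set."""

    cells: pd.DataFrame  # indexed by cell id
    molecules: pd.DataFrame  # the pre-artifact molecule table
    gene_sets: dict  # name -> list of genes
    gene_annotation: pd.DataFrame
    artifacts: pd.DataFrame | None = None  # per emitted row after artifacts


# ---------------------------------------------------------------------------
# default study-like configuration


def default_config(seed: int = 0, cells_per_sample: int = 2000,
                   n_genes: int = 2000, n_samples: int = 6) -> SimConfig:
    """Six-library cohort: two blood donors plus lung and bone marrow from
    two tissue donors, with study-like artifact rates (1% index swapping,
    2% chimeric molecules, 2% doublets, 5% dead cells)."""
    all_samples = [
        SampleSpec("blood_A", "blood", 12.0),
        SampleSpec("blood_B", "blood", 10.0),
        SampleSpec("lung_D1", "lung", 9.0),
        SampleSpec("lung_D2", "lung", 8.0),
        SampleSpec("bm_D1", "bone_marrow", 7.0),
        SampleSpec("bm_D2", "bone_marrow", 6.0),
    ]
    samples = all_samples[:n_samples]

    t_subsets = {
        "CD4_naive": ("CD4", 0.18), "CD4_CM": ("CD4", 0.14),
        "CD4_TRM": ("CD4", 0.12), "Treg": ("CD4", 0.08),
        "CD8_TEM": ("CD8", 0.16), "CD8_TRM": ("CD8", 0.12),
        "TEMRA": ("CD8", 0.10),
    }
    contaminants = {"Bcell": 0.04, "Myeloid": 0.03, "Epithelial": 0.03}
    ccl5_pos = {"CD8_TEM", "CD8_TRM", "TEMRA"}

    subset_markers = {t: [f"{t}_M{i:02d}" for i in range(16)] for t in t_subsets}
    contam_markers = {t: [f"{t}_M{i:02d}" for i in range(15)] for t in contaminants}
    tsig = [f"TSIG{i:02d}" for i in range(60)]
    lung_m = [f"LUNG_M{i:02d}" for i in range(15)]
    bm_m = [f"BM_M{i:02d}" for i in range(15)]
    act = [f"ACT{i:02d}" for i in range(60)]
    mito = [f"MT-{i}" for i in range(1, 9)]
    special = (["CD3D", "TRAC", "CD4", "CD8A", "CCL5", "SELL"]
               + sum(subset_markers.values(), []) + sum(contam_markers.values(), [])
               + tsig + lung_m + bm_m + act + mito)
    n_bg = n_genes - len(special)
    if n_bg < 100:
        raise ValueError("n_genes too small for the default gene universe")
    background = [f"G{i:04d}" for i in range(n_bg)]
    gene_names = special + background

    cell_types = []
    for name, (lineage, freq) in t_subsets.items():
        m = {"CD3D": 30.0, "TRAC": 30.0}
        m["CD4" if lineage == "CD4" else "CD8A"] = 12.0
        if name in ccl5_pos:
            m["CCL5"] = 60.0
        if name in ("CD4_naive", "CD4_CM"):
            m["SELL"] = 10.0
        for g in subset_markers[name]:
            m[g] = 12.0
        cell_types.append(CellType(name, lineage, freq, 400.0, m))
    for name, freq in contaminants.items():
        m = {g: 60.0 for g in contam_markers[name]}
        lib = 800.0 if name == "Epithelial" else 500.0
        cell_types.append(CellType(name, "contaminant", freq, lib, m))

    exclusive = frozenset(["CD3D", "TRAC", "CD4", "CD8A", "CCL5"]
                          + sum(subset_markers.values(), [])
                          + sum(contam_markers.values(), []))

    # a sprinkling of non-coding background genes for the biotype filter
    biotype = {}
    for i, g in enumerate(background):
        biotype[g] = "lincRNA" if i % 10 == 0 else "protein_coding"
    ann = pd.DataFrame({
        GENE: gene_names,
        "biotype": [biotype.get(g, "protein_coding") for g in gene_names],
        "is_mito": [g in set(mito) for g in gene_names],
    }).set_index(GENE)

    return SimConfig(
        samples=samples,
        cell_types=cell_types,
        cells_per_sample=cells_per_sample,
        n_genes=len(gene_names),
        seed=seed,
        activation_markers={g: 16.0 for g in act},
        tissue_signature_genes={g: 4.0 for g in tsig},
        tissue_markers={"lung": {g: 20.0 for g in lung_m},
                        "bone_marrow": {g: 20.0 for g in bm_m}},
        exclusive_genes=exclusive,
        gene_names=gene_names,
        gene_annotation=ann,
        special_base={"CD3D": 1.0, "TRAC": 1.0, "CCL5": 1.0, "SELL": 1.0,
                      "CD4": 1.0, "CD8A": 1.0},
        pinned_genes=frozenset({"CD3D", "TRAC", "CD4", "CD8A"}),
    )


def default_gene_sets(config: SimConfig) -> dict:
    """Planted gene sets recoverable from a default-style configuration."""
    sets: dict = {"tissue_signature": sorted(config.tissue_signature_genes),
                  "activation_program": sorted(
                      g for g in config.activation_markers
                      if g not in config.exclusive_genes)}
    for tissue, mk in config.tissue_markers.items():
        sets[f"tissue_markers:{tissue}"] = sorted(mk)
    contam, subset = [], []
    for ct in config.cell_types:
        own = [g for g in ct.markers
               if g in config.exclusive_genes
               and g not in ("CD3D", "TRAC", "CD4", "CD8A", "CCL5")]
        (contam if ct.lineage == "contaminant" else subset).extend(own)
    sets["contaminant_markers"] = sorted(set(contam))
    sets["t_subset_markers"] = sorted(set(subset))
    return sets


# ---------------------------------------------------------------------------
# expression profiles


def _base_expression(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    genes = pd.Index(config.gene_names)
    base = rng.lognormal(mean=-1.0, sigma=1.0, size=len(genes))
    marked = set()
    for ct in config.cell_types:
        marked.update(ct.markers)
    marked |= set(config.tissue_signature_genes) | set(config.activation_markers)
    for mk in config.tissue_markers.values():
        marked.update(mk)
    # markers get their own baseline spread so planted genes occupy the
    # whole expression range instead of bunching at one value
    for g in sorted(marked):
        if g in genes:
            base[genes.get_loc(g)] = (config.marker_base
                                      * rng.lognormal(0.0, 0.25))
    for g, v in config.special_base.items():
        if g in genes:
            base[genes.get_loc(g)] = v
    if config.gene_annotation is not None:
        base[config.gene_annotation["is_mito"].to_numpy()] = 0.0
    return base


def _type_rates(config: SimConfig, base: np.ndarray) -> dict:
    """Unnormalized expected expression per type (resting, no tissue term)."""
    genes = pd.Index(config.gene_names)
    excl = genes.isin(config.exclusive_genes)
    target = base.sum()
    out = {}
    for ct in config.cell_types:
        lam = base.copy()
        lam[excl] = 0.0
        for g, fold in ct.markers.items():
            if g in genes:
                lam[genes.get_loc(g)] = base[genes.get_loc(g)] * fold
        # equal profile totals: marker programs displace background mass
        # instead of inflating it, so relative expression of shared genes
        # (e.g. CD3D/TRAC) is comparable across types; pinned genes keep
        # their absolute rate and displacement falls on the rest
        pinned = genes.isin(config.pinned_genes)
        pin_mass = lam[pinned].sum()
        rest = lam[~pinned].sum()
        if rest > 0 and target > pin_mass:
            lam[~pinned] *= (target - pin_mass) / rest
        out[ct.name] = lam
    return out


def _fold_vector(genes: pd.Index, folds: dict) -> np.ndarray:
    v = np.ones(len(genes))
    for g, f in folds.items():
        if g in genes:
            v[genes.get_loc(g)] = f
    return v


# ---------------------------------------------------------------------------
# simulation


def simulate_truth(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw ground-truth molecules for every cell of every sample.

    Returns the molecule table (sample, barcode, umi, gene, reads, exonic)
    and the :class:`GroundTruth` record.  One RNG stream is derived per
    sample from the master seed, so adding samples leaves existing ones
    unchanged.  Deterministic given ``config.seed``.
    """
    config.validate()
    genes = pd.Index(config.gene_names)
    base = _base_expression(config, np.random.default_rng([config.seed, 7]))
    rates = _type_rates(config, base)
    act_fold = _fold_vector(genes, config.activation_markers)
    tsig_fold = _fold_vector(genes, config.tissue_signature_genes)
    mito_mask = (config.gene_annotation["is_mito"].to_numpy()
                 if config.gene_annotation is not None
                 else np.zeros(len(genes), bool))
    mito_idx = np.flatnonzero(mito_mask)
    type_by_name = {ct.name: ct for ct in config.cell_types}
    t_types = [ct for ct in config.cell_types if ct.lineage != "contaminant"]
    c_types = [ct for ct in config.cell_types if ct.lineage == "contaminant"]

    mol_parts, cell_parts = [], []
    for s_idx, spec in enumerate(config.samples):
        rng = np.random.default_rng([config.seed, 1000 + s_idx])
        n = config.cells_per_sample
        names = np.array([ct.name for ct in config.cell_types])
        probs = np.array([ct.frequency for ct in config.cell_types])
        ctype = rng.choice(names, size=n, p=probs)
        lineage = np.array([type_by_name[t].lineage for t in ctype])
        is_t = lineage != "contaminant"

        condition = np.where(is_t & (rng.random(n) < spec.activated_fraction),
                             "act", "rest")
        grad_t = np.full(n, np.nan)
        act_cells = np.flatnonzero(condition == "act")
        on_grad = act_cells[rng.random(len(act_cells))
                            < config.activation_gradient]
        grad_t[act_cells] = 1.0
        grad_t[on_grad] = rng.random(len(on_grad))

        is_multiplet = np.zeros(n, bool)
        if c_types:
            is_multiplet = is_t & (rng.random(n) < config.multiplet_rate)
        is_dead = rng.random(n) < config.dead_fraction
        mito_frac = rng.beta(*config.mito_beta, size=n)
        mito_frac[is_dead] = rng.beta(*config.dead_mito_beta,
                                      size=int(is_dead.sum()))
        intron_ratio = np.maximum(
            1.0, rng.normal(config.intron_ratio_mean,
                            config.intron_ratio_sd, size=n))
        hi = rng.random(n) < config.high_intron_fraction
        intron_ratio[hi] = np.maximum(
            1.5 + 1e-3, rng.normal(config.high_intron_ratio, 0.1,
                                   size=int(hi.sum())))

        tis_fold = np.ones(len(genes))
        if spec.tissue != "blood":
            tis_fold = tsig_fold * _fold_vector(
                genes, config.tissue_markers.get(spec.tissue, {}))

        counts = np.zeros((n, len(genes)), dtype=np.int32)
        shape = 1.0 / config.dispersion
        for ct in config.cell_types:
            sel = np.flatnonzero(ctype == ct.name)
            if len(sel) == 0:
                continue
            lam = rates[ct.name][None, :].repeat(len(sel), axis=0)
            if ct.lineage != "contaminant":
                t = np.nan_to_num(grad_t[sel])[:, None]
                lam = lam * (1.0 + t * (act_fold[None, :] - 1.0)) * tis_fold
                # pinned genes keep a constant expected share in every T
                # cell: condition and tissue programs displace background
                # mass, not the TCR module
                pinned = genes.isin(config.pinned_genes)
                if pinned.any():
                    target = rates[ct.name].sum()
                    pin_vals = rates[ct.name][pinned]
                    lam[:, pinned] = pin_vals
                    rest = lam[:, ~pinned].sum(axis=1, keepdims=True)
                    lam[:, ~pinned] *= (target - pin_vals.sum()) / rest
            p = lam / lam.sum(axis=1, keepdims=True)
            lib = ct.library_size * rng.lognormal(
                -config.library_sigma**2 / 2, config.library_sigma,
                size=len(sel))
            mu = lib[:, None] * p
            gmul = rng.gamma(shape, 1.0 / shape, size=mu.shape)
            counts[sel] = rng.poisson(mu * gmul).astype(np.int32)

        # doublets: add an independent contaminant transcriptome
        for i in np.flatnonzero(is_multiplet):
            ct = c_types[rng.integers(len(c_types))]
            lam = rates[ct.name]
            p = lam / lam.sum()
            lib = ct.library_size * rng.lognormal(
                -config.library_sigma**2 / 2, config.library_sigma)
            counts[i] += rng.poisson(lib * p).astype(np.int32)

        # mitochondrial molecules at the planted per-cell fraction
        if len(mito_idx):
            tot = counts.sum(axis=1)
            m_tot = rng.poisson(mito_frac / (1 - mito_frac) * tot)
            for i in np.flatnonzero(m_tot):
                mg = rng.integers(0, len(mito_idx), size=m_tot[i])
                np.add.at(counts[i], mito_idx[mg], 1)

        barcodes = np.array([f"BC{i:05d}" for i in range(n)])
        cell_parts.append(pd.DataFrame({
            SAMPLE: spec.name, BARCODE: barcodes, "cell_type": ctype,
            "lineage": lineage, "condition": condition,
            "tissue": spec.tissue, "is_dead": is_dead,
            "is_multiplet": is_multiplet,
            "is_t": is_t & ~is_multiplet,
            "gradient_t": np.where(np.isin(np.arange(n), on_grad),
                                   grad_t, np.nan),
            "mito_fraction": mito_frac, "intron_ratio": intron_ratio,
        }, index=pd.Index([make_cell_id(spec.name, b) for b in barcodes],
                          name="cell")))

        # expand counts to molecules
        cc, gg = np.nonzero(counts)
        k = counts[cc, gg]
        cell_rep = np.repeat(cc, k)
        gene_rep = np.repeat(gg, k)
        m = len(cell_rep)
        umi = rng.integers(0, UMI_SPACE, size=m, dtype=np.int64)
        sigma = config.rpm_sigma
        reads = np.maximum(1, np.rint(rng.lognormal(
            np.log(spec.rpm_mean) - sigma**2 / 2, sigma, size=m))).astype(np.int64)
        p_exonic = 1.0 / intron_ratio
        exonic = rng.random(m) < p_exonic[cell_rep]

        # merge UMI collisions within (cell, gene) so addresses are unique
        key = (cell_rep.astype(np.int64) * len(genes) + gene_rep) * UMI_SPACE + umi
        order = np.argsort(key, kind="stable")
        key, cell_rep, gene_rep, umi = (key[order], cell_rep[order],
                                        gene_rep[order], umi[order])
        reads, exonic = reads[order], exonic[order]
        first = np.ones(m, bool)
        first[1:] = key[1:] != key[:-1]
        grp = np.cumsum(first) - 1
        reads_agg = np.bincount(grp, weights=reads).astype(np.int64)
        keep = np.flatnonzero(first)
        mol_parts.append(pd.DataFrame({
            SAMPLE: spec.name,
            BARCODE: barcodes[cell_rep[keep]],
            UMI: umi[keep].astype(np.int64),
            GENE: genes.to_numpy()[gene_rep[keep]],
            READS: reads_agg,
            EXONIC: exonic[keep],
        }))

    molecules = pd.concat(mol_parts, ignore_index=True)
    molecules[SAMPLE] = molecules[SAMPLE].astype("category")
    molecules[GENE] = molecules[GENE].astype(
        pd.CategoricalDtype(categories=genes))
    cells = pd.concat(cell_parts)
    truth = GroundTruth(cells=cells, molecules=molecules,
                        gene_sets=default_gene_sets(config),
                        gene_annotation=(config.gene_annotation
                                         if config.gene_annotation is not None
                                         else pd.DataFrame(index=genes)))
    return molecules, truth


def apply_artifacts(molecules: pd.DataFrame, config: SimConfig,
                    truth: GroundTruth | None = None) -> pd.DataFrame:
    """Expand truth molecules into an artifact-bearing address table.

    A ``swap_rate`` fraction of reads is reassigned to a random other
    sample index (binomially per molecule, reads conserved); a
    ``chimera_rate`` fraction of molecules is cloned under a random other
    barcode of the same sample with reads drawn from the low-RPM chimera
    lognormal.  If ``truth`` is given its ``artifacts`` table is filled
    with the per-row true sample of origin and chimera flag.
    """
    config.validate()
    sample_names = [s.name for s in config.samples]
    rng = np.random.default_rng([config.seed, 999])

    reads = molecules[READS].to_numpy()
    n_mol = len(molecules)
    rows = [molecules.assign(**{
        "true_sample": molecules[SAMPLE].astype(str),
        "is_chimera": False})]

    if config.swap_rate > 0 and len(sample_names) > 1:
        swapped = rng.binomial(reads, config.swap_rate)
        src = np.flatnonzero(swapped)
        if len(src):
            rep = np.repeat(src, swapped[src])  # one row per swapped read
            samp_codes = pd.Categorical(molecules[SAMPLE]).codes[rep]
            shift = rng.integers(1, len(sample_names), size=len(rep))
            tgt = (samp_codes + shift) % len(sample_names)
            swap_df = pd.DataFrame({
                SAMPLE: np.asarray(sample_names, dtype=object)[tgt],
                BARCODE: molecules[BARCODE].to_numpy()[rep],
                UMI: molecules[UMI].to_numpy()[rep],
                GENE: molecules[GENE].to_numpy()[rep],
                READS: 1,
                EXONIC: molecules[EXONIC].to_numpy()[rep]
                if EXONIC in molecules else True,
                "true_sample": molecules[SAMPLE].astype(str).to_numpy()[rep],
                "is_chimera": False,
            })
            rows.append(swap_df)
        rows[0] = rows[0].assign(**{READS: reads - swapped})
        rows[0] = rows[0][rows[0][READS] > 0]

    if config.chimera_rate > 0:
        pick = np.flatnonzero(rng.random(n_mol) < config.chimera_rate)
        if len(pick):
            sigma = config.chimera_rpm_sigma
            c_reads = np.maximum(1, np.rint(rng.lognormal(
                np.log(config.chimera_rpm_mean) - sigma**2 / 2, sigma,
                size=len(pick)))).astype(np.int64)
            # wrong barcode within the same sample
            src_bc = molecules[BARCODE].to_numpy()[pick]
            offs = rng.integers(1, config.cells_per_sample, size=len(pick))
            bc_num = np.array([int(b[2:]) for b in src_bc])
            new_bc = (bc_num + offs) % config.cells_per_sample
            chim_df = pd.DataFrame({
                SAMPLE: molecules[SAMPLE].astype(str).to_numpy()[pick],
                BARCODE: np.array([f"BC{i:05d}" for i in new_bc]),
                UMI: rng.integers(0, UMI_SPACE, size=len(pick), dtype=np.int64),
                GENE: molecules[GENE].to_numpy()[pick],
                READS: c_reads,
                EXONIC: True,
                "true_sample": molecules[SAMPLE].astype(str).to_numpy()[pick],
                "is_chimera": True,
            })
            rows.append(chim_df)

    full = pd.concat(rows, ignore_index=True)
    agg = (full.groupby([SAMPLE, BARCODE, UMI, GENE], observed=True, sort=True)
           .agg(**{READS: (READS, "sum"), EXONIC: (EXONIC, "max"),
                   "true_sample": ("true_sample", "first"),
                   "is_chimera": ("is_chimera", "max")})
           .reset_index())
    agg[SAMPLE] = agg[SAMPLE].astype(str)
    agg[GENE] = agg[GENE].astype(str)
    if truth is not None:
        truth.artifacts = agg[[SAMPLE, BARCODE, UMI, GENE,
                               "true_sample", "is_chimera"]].copy()
    return agg[[SAMPLE, BARCODE, UMI, GENE, READS, EXONIC]].copy()


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Convenience wrapper: truth molecules plus artifact application."""
    molecules, truth = simulate_truth(config)
    addresses = apply_artifacts(molecules, config, truth)
    return addresses, truth
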
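"""Synthetic scRNA-seq generator with planted, recoverable structure.

Counts follow a negative-binomial model with log-normal library-size
variation. On top of the baseline the generator plants, with known labels:

* coexpression modules among a block of "regulator" genes, each driven by a
  per-cell latent factor that is correlated with an emitted clinical trait;
* a "low-score" cell subpopulation whose regulator genes are down-shifted,
  which the downstream set score must recover;
* malignant cells (a subset of the epithelial type) carrying a contiguous
  copy-number gain/loss block;
* ligand/receptor genes elevated in designated sender/receiver cell types;
* epithelial marker genes elevated in epithelial-lineage cells;
* a 13-gene mitochondrial block with realistic per-cell mitochondrial
  fractions plus a configurable set of "dying" cells that the QC cut removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .containers import CountMatrix

N_MITO = 13
N_CHROMS = 5
GENE_LENGTH = 1000  # 1 kb per pseudo-gene, laid end to end

# how strongly a module's latent factor moves its genes, in log2 units
# (a moderate transcriptional program: ~1.4-fold per factor SD)
MODULE_LOADING = 0.5
# log2 elevation of planted ligand/receptor genes in their designated types
LR_ELEVATION = 1.5
# log2 elevation of epithelial markers in epithelial-lineage cells
EPI_ELEVATION = 2.0


@dataclass
class SimConfig:
    """Simulation parameters; defaults define the package's study conditions."""

    n_cells: int = 1000
    n_genes: int = 1000
    n_cell_types: int = 4
    nb_mean: float = 2.0
    nb_dispersion: float = 0.5
    n_modules: int = 4
    module_size: int = 30
    module_trait_cor: float = 0.6
    malignant_fraction: float = 0.15
    # (chrom, start index on chrom, n genes, log2 fold); default sits on a
    # chromosome free of the regulator block so malignancy and score group
    # stay independent plants
    cnv_block: tuple = ("chr3", 0, 150, 1.0)
    score_shift: float = 1.0
    lr_pairs_planted: list = field(default_factory=list)  # (ligand, receptor, sender, receiver)
    survival_hr: float = 2.0
    censor_rate: float = 0.3
    seed: int = 0
    n_epithelial_markers: int = 10
    dying_fraction: float = 0.05
    lib_sigma: float = 0.3

    def validate(self):
        for name in ("n_cells", "n_genes", "n_cell_types", "n_modules", "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("malignant_fraction", "censor_rate", "dying_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1 <= self.module_trait_cor <= 1:
            raise ValueError("module_trait_cor must lie in [-1, 1]")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        if self.survival_hr <= 0:
            raise ValueError("survival_hr must be positive")
        n_special = N_MITO + self.n_modules * self.module_size + self.n_epithelial_markers
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {self.n_modules} modules of "
                f"{self.module_size} genes plus reserved blocks ({n_special} needed)"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cnv_block" in raw:
            raw["cnv_block"] = tuple(raw["cnv_block"])
        if "lr_pairs_planted" in raw:
            raw["lr_pairs_planted"] = [tuple(p) for p in raw["lr_pairs_planted"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the counts."""

    group: pd.Series  # per-cell {"high", "low"} latent score group
    gene_module: pd.Series  # per-gene module label ("grey" = none)
    malignant: pd.Series  # per-cell bool
    lr_pairs: list  # (ligand, receptor, sender_type, receiver_type)
    hazard_multiplier: pd.Series  # per-cell true hazard multiplier
    regulator_genes: list  # all module genes (the planted "regulator" set)
    epithelial_markers: list
    dying_cells: list  # cells given a high mitochondrial fraction
    traits: pd.DataFrame  # per-cell numeric covariates tied to module factors

TRAIT_NAMES = ["mutation", "stage", "origin", "smoking"]


def gene_names_for(n_genes: int) -> pd.Index:
    """Reserved ``MT-`` block first, then ``G0001``-style symbols."""
    mito = [f"MT-{i + 1}" for i in range(min(N_MITO, n_genes))]
    rest = [f"G{i + 1:04d}" for i in range(n_genes - len(mito))]
    return pd.Index(mito + rest)


def gene_coordinates(gene_names) -> pd.DataFrame:
    """Sequential 1 kb loci on 5 pseudo-chromosomes, 0-based half-open."""
    n = len(gene_names)
    per_chrom = int(np.ceil(n / N_CHROMS))
    chroms, starts = [], []
    for i in range(n):
        c, pos = divmod(i, per_chrom)
        chroms.append(f"chr{c + 1}")
        starts.append(pos * GENE_LENGTH)
    starts = np.array(starts)
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + GENE_LENGTH, "gene": list(gene_names)}
    )


def _nb_sample(rng, mean, dispersion):
    """NB with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_counts(config: SimConfig):
    """Draw a count matrix and its :class:`SyntheticTruth`.

    Deterministic: the same config (including seed) yields byte-identical
    output. Returns ``(CountMatrix, SyntheticTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes = config.n_cells, config.n_genes
    genes = gene_names_for(n_genes)
    cells = pd.Index([f"cell{i + 1:05d}" for i in range(n_cells)])
    coords = gene_coordinates(genes)

    mito_idx = np.arange(min(N_MITO, n_genes))
    next_free = len(mito_idx)
    module_idx = []
    gene_module = np.full(n_genes, "grey", dtype=object)
    for m in range(config.n_modules):
        idx = np.arange(next_free, next_free + config.module_size)
        module_idx.append(idx)
        gene_module[idx] = f"M{m + 1}"
        next_free += config.module_size
    epi_idx = np.arange(next_free, next_free + config.n_epithelial_markers)
    next_free += config.n_epithelial_markers
    regulator_idx = np.concatenate(module_idx) if module_idx else np.array([], dtype=int)

    # cell identities: types (type 1 = epithelial lineage), latent score group
    cell_type_codes = rng.integers(0, config.n_cell_types, size=n_cells)
    type_names = ["Epithelial"] + [f"Type{i}" for i in range(2, config.n_cell_types + 1)]
    cell_types = np.array(type_names, dtype=object)[cell_type_codes]
    group = np.where(rng.random(n_cells) < 0.5, "low", "high")

    epithelial = cell_type_codes == 0
    malignant = np.zeros(n_cells, dtype=bool)
    epi_cells = np.flatnonzero(epithelial)
    if config.malignant_fraction > 0 and len(epi_cells):
        n_mal = int(round(config.malignant_fraction * n_cells))
        n_mal = min(n_mal, len(epi_cells))
        malignant[rng.choice(epi_cells, size=n_mal, replace=False)] = True

    # per-gene baseline means with moderate spread, per-cell library factors
    base = config.nb_mean * np.exp(rng.normal(0.0, 0.5, size=n_genes))
    lib = np.exp(rng.normal(0.0, config.lib_sigma, size=n_cells))

    # log2 effects accumulate multiplicatively on the mean
    log2fx = np.zeros((n_cells, n_genes))

    # planted coexpression modules tied to emitted traits
    traits = {}
    rho = config.module_trait_cor
    for m, idx in enumerate(module_idx):
        z = rng.normal(size=n_cells)
        log2fx[:, idx] += MODULE_LOADING * z[:, None]
        noise = rng.normal(size=n_cells)
        traits[TRAIT_NAMES[m % len(TRAIT_NAMES)] + ("" if m < 4 else f"_{m + 1}")] = (
            rho * z + np.sqrt(max(0.0, 1 - rho**2)) * noise
        )

    # low-score subpopulation: regulator genes shifted down
    if len(regulator_idx):
        log2fx[np.ix_(group == "low", regulator_idx)] -= config.score_shift

    # malignant CNV block: contiguous genes on one chromosome scaled 2^log2_fold
    chrom, start, n_block, log2_fold = config.cnv_block
    on_chrom = np.flatnonzero(coords["chrom"].to_numpy() == chrom)
    if len(on_chrom) == 0 or start + n_block > len(on_chrom):
        raise ValueError(f"cnv_block {config.cnv_block} outside gene range")
    cnv_idx = on_chrom[start : start + n_block]
    if malignant.any():
        log2fx[np.ix_(malignant, cnv_idx)] += log2_fold

    # ligand/receptor elevation in designated sender/receiver types
    for ligand, receptor, sender, receiver in config.lr_pairs_planted:
        li, ri = genes.get_loc(ligand), genes.get_loc(receptor)
        log2fx[cell_types == sender, li] += LR_ELEVATION
        log2fx[cell_types == receiver, ri] += LR_ELEVATION

    # epithelial markers up in the epithelial lineage (incl. malignant cells)
    log2fx[np.ix_(epithelial, epi_idx)] += EPI_ELEVATION

    mean = lib[:, None] * base[None, :] * np.exp2(log2fx)

    # mitochondrial block: per-cell fraction Beta(2,30); "dying" cells Beta(8,10)
    mito_frac = rng.beta(2, 30, size=n_cells)
    n_dying = int(round(config.dying_fraction * n_cells))
    dying = rng.choice(n_cells, size=n_dying, replace=False) if n_dying else np.array([], int)
    if n_dying:
        mito_frac[dying] = rng.beta(8, 10, size=n_dying)
    non_mito_total = mean[:, len(mito_idx) :].sum(axis=1)
    mito_mean = mito_frac / (1 - mito_frac) * non_mito_total / max(len(mito_idx), 1)
    mean[:, mito_idx] = mito_mean[:, None]

    counts = _nb_sample(rng, mean, config.nb_dispersion)

    meta = pd.DataFrame(
        {
            "sample": np.where(group == "low", "S_low", "S_high"),
            "condition": group,
            "cell_type": np.where(malignant, "Malignant", cell_types),
        },
        index=cells,
    )
    for name, values in traits.items():
        meta[name] = values

    matrix = CountMatrix(sp.csr_matrix(counts), genes, cells, meta)
    truth = SyntheticTruth(
        group=pd.Series(group, index=cells),
        gene_module=pd.Series(gene_module, index=genes),
        malignant=pd.Series(malignant, index=cells),
        lr_pairs=list(config.lr_pairs_planted),
        hazard_multiplier=pd.Series(
            np.where(group == "low", config.survival_hr, 1.0), index=cells
        ),
        regulator_genes=list(genes[regulator_idx]),
        epithelial_markers=list(genes[epi_idx]),
        dying_cells=list(cells[dying]),
        traits=pd.DataFrame(traits, index=cells),
    )
    return matrix, truth


def generate_survival(groups, hr: float, censor_rate: float, seed: int) -> pd.DataFrame:
    """Exponential event times; hazard multiplied by ``hr`` for the low group.

    Censoring: each subject is independently censored with probability
    ``censor_rate``, at a uniform time before its event. Returns a table with
    columns ``time``, ``event`` (1 = observed), ``group``.
    """
    groups = pd.Series(groups)
    if len(groups) == 0:
        raise ValueError("empty group vector")
    if hr <= 0:
        raise ValueError("hr must be positive")
    rng = np.random.default_rng(seed)
    hazard = np.where(groups.to_numpy() == "low", hr, 1.0)
    times = rng.exponential(1.0 / hazard)
    event = np.ones(len(groups), dtype=int)
    censored = rng.random(len(groups)) < censor_rate
    times = np.where(censored, times * rng.random(len(groups)), times)
    event[censored] = 0
    return pd.DataFrame(
        {"time": times, "event": event, "group": groups.to_numpy()}, index=groups.index
    )


def simulate_module_expression(
    n_obs: int, n_modules: int, module_size: int, within_cor: float, seed: int,
    n_noise_genes: int = 0,
):
    """Gaussian expression with block-correlated modules, for network tests.

    Each module gene = sqrt(within_cor) * shared factor + sqrt(1-within_cor) *
    noise, giving expected within-module correlation ``within_cor``. Returns
    ``(DataFrame obs x genes, Series gene -> module label)``.
    """
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for m in range(n_modules):
        z = rng.normal(size=(n_obs, 1))
        eps = rng.normal(size=(n_obs, module_size))
        block = np.sqrt(within_cor) * z + np.sqrt(1 - within_cor) * eps
        cols.append(block)
        labels += [f"M{m + 1}"] * module_size
    if n_noise_genes:
        cols.append(rng.normal(size=(n_obs, n_noise_genes)))
        labels += ["grey"] * n_noise_genes
    X = np.concatenate(cols, axis=1)
    genes = [f"R{i + 1:04d}" for i in range(X.shape[1])]
    return (
        pd.DataFrame(X, columns=genes),
        pd.Series(labels, index=genes),
    )
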
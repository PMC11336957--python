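"""Synthetic single-cell generators.

Three scenarios are covered, mirroring the structure the method's experiments
assume:

* a cyclic base population — cell-type programs plus a circular cell-cycle
  program (each cycle gene varies as amplitude·sin(θ + offset) along a latent
  phase θ), standing in for FACS-staged mESC-like data;
* a virtual tumor — a second subclone created by doubling a random gene set,
  the merged cells split into two batches with Gaussian noise added to one;
* paired/unpaired two-modality data — an RNA domain and a gene-activity
  (ATAC-like) domain driven by the same latent type/cycle programs through a
  distinct random linear map, with extra dropout in the ATAC channel.

Generation is a pure function of :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AlignedPair, DomainDataset

TWO_PI = 2.0 * np.pi


@dataclass
class SimConfig:
    """Generator settings; all randomness derives from ``seed``.

    ``type_effect_size`` is the mean log-scale shift of a cell type's program
    genes; ``cycle_amplitude`` the peak deviation of cycle genes along the
    phase circle; ``noise_sd`` the additive Gaussian σ applied to the noisy
    batch in the virtual-tumor scenario; ``sparsity_atac`` the dropout
    probability of the gene-activity channel.
    """

    n_cells: int = 400
    n_genes: int = 200
    n_types: int = 3
    n_cycle_genes: int | None = None  # defaults to 20% of n_genes
    subclone_gene_fraction: float = 0.25
    noise_sd: float = 0.5
    type_effect_size: float = 3.0
    cycle_amplitude: float = 3.0
    base_expression: float = 5.0
    base_noise_sd: float = 1.0
    atac_noise_sd: float = 1.0
    sparsity_atac: float = 0.3
    atac_map: str = "random"
    type_gene_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_genes, self.n_types) <= 0:
            raise ValueError("counts must be positive")
        if self.n_cycle_genes is None:
            self.n_cycle_genes = max(1, int(0.2 * self.n_genes))
        if self.n_cycle_genes > self.n_genes:
            raise ValueError("n_cycle_genes cannot exceed n_genes")
        for p in (self.subclone_gene_fraction, self.sparsity_atac,
                  self.type_gene_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions/probabilities must lie in [0, 1]")
        if self.noise_sd < 0 or self.base_noise_sd < 0 or self.atac_noise_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.atac_map not in ("random", "identity"):
            raise ValueError("atac_map must be 'random' or 'identity'")


@dataclass
class SimTruth:
    """Ground truth aligned 1:1 with the generated cells."""

    cell_ids: list
    type_of_cell: np.ndarray
    phase_of_cell: np.ndarray
    batch_of_cell: np.ndarray | None = None
    subclone_of_cell: np.ndarray | None = None
    doubled_gene_set: list | None = None
    rna_signal: np.ndarray | None = field(default=None, repr=False)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _make_programs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Loading matrix (K+2)×genes: one row per type program, then the sin/cos
    cycle rows implementing amplitude·sin(θ + offset_g) on the cycle genes."""
    G = np.zeros((cfg.n_types + 2, cfg.n_genes))
    n_prog = max(1, int(cfg.type_gene_fraction * cfg.n_genes))
    order = rng.permutation(cfg.n_genes)
    for k in range(cfg.n_types):
        genes = order[k * n_prog:(k + 1) * n_prog]
        if len(genes) == 0:
            genes = order[[k % cfg.n_genes]]
        G[k, genes] = cfg.type_effect_size
    cyc = rng.choice(cfg.n_genes, size=cfg.n_cycle_genes, replace=False)
    offs = rng.uniform(0.0, TWO_PI, size=cfg.n_cycle_genes)
    G[cfg.n_types, cyc] = cfg.cycle_amplitude * np.cos(offs)   # multiplies sin θ
    G[cfg.n_types + 1, cyc] = cfg.cycle_amplitude * np.sin(offs)  # multiplies cos θ
    return G


def _factors(cfg: SimConfig, rng: np.random.Generator, n: int
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    types = rng.integers(cfg.n_types, size=n)
    theta = rng.uniform(0.0, TWO_PI, size=n)
    F = np.zeros((n, cfg.n_types + 2))
    F[np.arange(n), types] = 1.0
    F[:, cfg.n_types] = np.sin(theta)
    F[:, cfg.n_types + 1] = np.cos(theta)
    return F, types, theta


def _gene_ids(cfg: SimConfig) -> list[str]:
    return [f"gene{j:04d}" for j in range(cfg.n_genes)]


def generate_cyclic_base(cfg: SimConfig, _prefix: str = "cell"
                         ) -> tuple[DomainDataset, SimTruth]:
    """Expression = softplus(baseline + type program + cycle program + noise),
    with phase θ uniform on the circle and cells assigned to types uniformly."""
    rng = np.random.default_rng(cfg.seed)
    G = _make_programs(cfg, rng)
    F, types, theta = _factors(cfg, rng, cfg.n_cells)
    signal = cfg.base_expression + F @ G
    X = _softplus(signal + rng.normal(0.0, cfg.base_noise_sd, size=signal.shape)
                  if cfg.base_noise_sd > 0 else signal)
    cell_ids = [f"{_prefix}{i:05d}" for i in range(cfg.n_cells)]
    labels = np.array([f"type{t}" for t in types])
    ds = DomainDataset(matrix=X, cell_ids=cell_ids, gene_ids=_gene_ids(cfg),
                       labels=labels, modality="rna", role="source")
    truth = SimTruth(cell_ids=cell_ids, type_of_cell=labels,
                     phase_of_cell=theta, rna_signal=signal)
    return ds, truth


def generate_virtual_tumor(cfg: SimConfig) -> tuple[AlignedPair, SimTruth]:
    """Two subclones (the second with a random gene set doubled), merged,
    randomly split into two batches, Gaussian noise added to batch 2.

    Returns the two batches as an unpaired source/target pair (batch 1 keeps
    its type labels as the source) plus the full per-cell truth in merged
    order (subclone 1 cells first).
    """
    base, btruth = generate_cyclic_base(cfg, _prefix="vt")
    rng = np.random.default_rng((cfg.seed, 1))
    n_doubled = max(1, int(round(cfg.subclone_gene_fraction * cfg.n_genes)))
    doubled = sorted(rng.choice(cfg.n_genes, size=n_doubled, replace=False).tolist())
    X2 = base.matrix.copy()
    X2[:, doubled] *= 2.0

    X = np.vstack([base.matrix, X2])
    n = cfg.n_cells
    types = np.concatenate([btruth.type_of_cell, btruth.type_of_cell])
    theta = np.concatenate([btruth.phase_of_cell, btruth.phase_of_cell])
    subclone = np.array(["subclone1"] * n + ["subclone2"] * n)
    cell_ids = [f"vt{i:05d}" for i in range(2 * n)]
    batch = np.where(rng.random(2 * n) < 0.5, "batch1", "batch2")
    # guarantee both batches nonempty even at tiny n
    if (batch == "batch1").sum() == 0:
        batch[0] = "batch1"
    if (batch == "batch2").sum() == 0:
        batch[-1] = "batch2"
    noisy = batch == "batch2"
    if cfg.noise_sd > 0:
        X = X.astype(float)
        X[noisy] += rng.normal(0.0, cfg.noise_sd, size=(noisy.sum(), cfg.n_genes))

    genes = _gene_ids(cfg)
    i1 = np.flatnonzero(~noisy)
    i2 = np.flatnonzero(noisy)
    # the virtual tumor's classes of interest are the subclones: they play
    # the cell-type role during integration, with the cycle as confounder
    src = DomainDataset(matrix=X[i1], cell_ids=[cell_ids[i] for i in i1],
                        gene_ids=genes, labels=subclone[i1], modality="rna",
                        role="source")
    tgt = DomainDataset(matrix=X[i2], cell_ids=[cell_ids[i] for i in i2],
                        gene_ids=genes, labels=subclone[i2], modality="rna",
                        role="target")
    truth = SimTruth(cell_ids=cell_ids, type_of_cell=types, phase_of_cell=theta,
                     batch_of_cell=batch, subclone_of_cell=subclone,
                     doubled_gene_set=[genes[j] for j in doubled])
    return AlignedPair(source=src, target=tgt, paired=False), truth


def generate_multiomics(cfg: SimConfig, paired: bool
                        ) -> tuple[AlignedPair, SimTruth]:
    """A labeled RNA source and an unlabeled gene-activity target sharing the
    same latent cell-type and cell-cycle programs.

    The ATAC channel pushes the latent factors through a distinct random
    linear map (or the RNA map itself when ``atac_map="identity"``), adds
    Gaussian noise, clamps negatives to zero, and applies dropout at
    ``sparsity_atac``.  ``paired=True`` reuses the same cells for both
    domains; otherwise an independent cohort is drawn from the same mixture.
    Truth arrays cover source cells then target cells.
    """
    rna, rtruth = generate_cyclic_base(cfg, _prefix="rna")
    rng = np.random.default_rng((cfg.seed, 2))
    G_rna = _make_programs(cfg, np.random.default_rng(cfg.seed))  # replay RNA draw
    if cfg.atac_map == "identity":
        G_atac = G_rna
    else:
        # gene-activity scores are gene-wise proxies of expression: the
        # modality map rescales each gene's program loading by a random
        # positive factor (a random diagonal linear map), preserving gene
        # identity the way Signac-derived activity matrices do
        G_atac = G_rna * rng.lognormal(mean=0.0, sigma=0.5, size=cfg.n_genes)

    if paired:
        F = np.zeros((cfg.n_cells, cfg.n_types + 2))
        tcodes = np.array([int(t[4:]) for t in rtruth.type_of_cell])
        F[np.arange(cfg.n_cells), tcodes] = 1.0
        F[:, cfg.n_types] = np.sin(rtruth.phase_of_cell)
        F[:, cfg.n_types + 1] = np.cos(rtruth.phase_of_cell)
        types_t, theta_t = rtruth.type_of_cell, rtruth.phase_of_cell
    else:
        F, t_codes, theta_t = _factors(cfg, rng, cfg.n_cells)
        types_t = np.array([f"type{t}" for t in t_codes])

    signal = cfg.base_expression + F @ G_atac
    if cfg.atac_noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.atac_noise_sd, size=signal.shape)
    A = np.maximum(signal, 0.0)
    if cfg.sparsity_atac > 0:
        A = A * (rng.random(A.shape) >= cfg.sparsity_atac)

    cell_ids_t = (list(rna.cell_ids) if paired
                  else [f"atac{i:05d}" for i in range(cfg.n_cells)])
    tgt = DomainDataset(matrix=A, cell_ids=cell_ids_t, gene_ids=_gene_ids(cfg),
                        labels=None, modality="atac_gene_activity", role="target")
    truth = SimTruth(
        cell_ids=list(rna.cell_ids) + list(cell_ids_t),
        type_of_cell=np.concatenate([rtruth.type_of_cell, types_t]),
        phase_of_cell=np.concatenate([rtruth.phase_of_cell, theta_t]),
        rna_signal=rtruth.rna_signal)
    return AlignedPair(source=rna, target=tgt, paired=paired), truth
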
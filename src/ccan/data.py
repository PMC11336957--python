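"""Domain datasets, matrix I/O and run configuration.

A *domain* is one modality's cells×genes matrix: the labeled source domain is
scRNA-seq expression; the target domain is unlabeled scRNA-seq or a
scATAC-seq gene-activity matrix over the same gene universe.  Supported
on-disk formats are Matrix Market with genes.tsv/barcodes.tsv sidecars,
dense CSV/TSV, and H5AD (labels in ``obs["cell_type"]``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix, issparse

VALID_MODALITIES = ("rna", "atac_gene_activity")
VALID_ROLES = ("source", "target")
CPM_TARGET = 1.0e4


@dataclass
class DomainDataset:
    """One domain's cells×genes matrix with identifiers and optional labels.

    Parameters
    ----------
    matrix : cells×genes float array (expression or gene-activity units).
    cell_ids, gene_ids : unique string identifiers for rows / columns.
    labels : per-cell class identifiers; mandatory when ``role="source"``.
    modality : ``"rna"`` or ``"atac_gene_activity"``.
    role : ``"source"`` (labeled) or ``"target"``.
    """

    matrix: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None
    modality: str = "rna"
    role: str = "target"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells × genes)")
        if self.matrix.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but {len(self.cell_ids)} cell_ids"
            )
        if self.matrix.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but {len(self.gene_ids)} gene_ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains NaN or Inf entries")
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"modality must be one of {VALID_MODALITIES}")
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_cells:
                raise ValueError("labels length does not match cell count")
        if self.role == "source" and self.labels is None:
            raise ValueError("source domain requires labels")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, genes: list[str]) -> "DomainDataset":
        """Return a copy restricted to `genes`, in the given order."""
        col = {g: j for j, g in enumerate(self.gene_ids)}
        idx = [col[g] for g in genes]
        return replace(self, matrix=self.matrix[:, idx], gene_ids=list(genes))


@dataclass
class AlignedPair:
    """A source/target pair over an identical, identically ordered gene set."""

    source: DomainDataset
    target: DomainDataset
    paired: bool = False

    def __post_init__(self):
        if self.source.gene_ids != self.target.gene_ids:
            raise ValueError("source and target gene_ids differ (order matters)")
        if self.paired:
            if self.source.n_cells != self.target.n_cells:
                raise ValueError("paired mode requires equal cell counts")
            if self.target.labels is not None and self.source.labels is not None:
                if not np.array_equal(self.source.labels, self.target.labels):
                    raise ValueError("paired mode requires identical labels")


@dataclass
class RunConfig:
    """Hyperparameters of one training run.

    Defaults: batch size 64, encoder
    hidden dims [512, 256], classifier hidden dims [32, 16], 64-dimensional
    shared latent space, learning rate 1e-3, 1000 epochs.  The private
    (circular) embedding is one-dimensional so it reads directly as a
    cell-cycle pseudotime.
    """

    batch_size: int = 64
    encoder_dims: list[int] = field(default_factory=lambda: [512, 256])
    classifier_dims: list[int] = field(default_factory=lambda: [32, 16])
    latent_dim: int = 64
    private_dim: int = 1
    learning_rate: float = 1e-3
    epochs: int = 1000
    loss_weights: dict[str, float] = field(default_factory=lambda: {
        "recons": 1.0, "diff": 0.05, "mmd": 1.0, "class": 1.0, "ca": 0.1,
    })
    margin_m: float = 1.0
    mmd_bandwidths: list[float] = field(default_factory=lambda: [0.25, 0.5, 1.0, 2.0, 4.0])
    mmd_kernel: str = "gaussian"
    pretrain_fraction: float = 0.7
    circular_warmup_fraction: float = 0.25
    shared_decoder: bool = True
    self_training: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.batch_size <= 0 or self.latent_dim <= 0 or self.private_dim <= 0:
            raise ValueError("batch_size, latent_dim and private_dim must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if self.margin_m <= 0:
            raise ValueError("margin_m must be positive")
        if any(b <= 0 for b in self.mmd_bandwidths):
            raise ValueError("mmd_bandwidths must be positive")
        if any(w < 0 for w in self.loss_weights.values()):
            raise ValueError("loss weights must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "batch_size": self.batch_size,
            "encoder_dims": list(self.encoder_dims),
            "classifier_dims": list(self.classifier_dims),
            "latent_dim": self.latent_dim,
            "private_dim": self.private_dim,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "loss_weights": dict(self.loss_weights),
            "margin_m": self.margin_m,
            "mmd_bandwidths": list(self.mmd_bandwidths),
            "mmd_kernel": self.mmd_kernel,
            "pretrain_fraction": self.pretrain_fraction,
            "circular_warmup_fraction": self.circular_warmup_fraction,
            "shared_decoder": self.shared_decoder,
            "self_training": self.self_training,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_labels(labels_path: str, cell_ids: list[str]) -> np.ndarray:
    tab = pd.read_csv(labels_path, header=None, dtype=str, comment="#",
                      sep=None, engine="python")
    if tab.shape[1] < 2:
        raise ValueError("label file must have two columns: cell_id,label")
    mapping = dict(zip(tab.iloc[:, 0], tab.iloc[:, 1]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"label file missing cells: {missing[:10]}")
    return np.array([mapping[c] for c in cell_ids])


def load_domain(path: str, format: str, labels_path: str | None = None,
                role: str = "target", modality: str = "rna") -> DomainDataset:
    """Load one domain from disk and validate it.

    MTX matrices are stored genes×cells on disk (10x convention) with
    ``genes.tsv``/``barcodes.tsv`` sidecars next to the matrix file and are
    transposed on load; CSV stores cells in rows, genes in columns; H5AD uses
    ``X`` with labels in ``obs["cell_type"]`` when present.
    """
    if format == "csv":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        matrix = df.to_numpy(dtype=np.float64)
        cell_ids = [str(c) for c in df.index]
        gene_ids = [str(g) for g in df.columns]
        labels = None
    elif format == "mtx":
        m = mmread(path)
        matrix = np.asarray(m.todense() if issparse(m) else m, dtype=np.float64).T
        d = os.path.dirname(path)
        gene_ids = pd.read_csv(os.path.join(d, "genes.tsv"), sep="\t",
                               header=None)[0].astype(str).tolist()
        cell_ids = pd.read_csv(os.path.join(d, "barcodes.tsv"), sep="\t",
                               header=None)[0].astype(str).tolist()
        labels = None
    elif format == "h5ad":
        import anndata as ad
        a = ad.read_h5ad(path)
        X = a.X
        matrix = np.asarray(X.todense() if issparse(X) else X, dtype=np.float64)
        cell_ids = a.obs_names.astype(str).tolist()
        gene_ids = a.var_names.astype(str).tolist()
        labels = (a.obs["cell_type"].to_numpy().astype(str)
                  if "cell_type" in a.obs.columns else None)
    else:
        raise ValueError(f"unknown format: {format!r} (expected mtx, csv or h5ad)")

    if labels_path is not None:
        labels = _read_labels(labels_path, cell_ids)
    if role == "source" and labels is None:
        raise ValueError("source domain requires labels")
    return DomainDataset(matrix=matrix, cell_ids=cell_ids, gene_ids=gene_ids,
                         labels=labels, modality=modality, role=role)


def save_domain(ds: DomainDataset, path: str, format: str) -> None:
    """Write a domain to disk in `format` (inverse of :func:`load_domain`)."""
    if format == "csv":
        pd.DataFrame(ds.matrix, index=ds.cell_ids, columns=ds.gene_ids
                     ).to_csv(path, float_format="%.17g")
        if ds.labels is not None:
            lp = os.path.splitext(path)[0] + "_labels.csv"
            pd.DataFrame({"cell_id": ds.cell_ids, "label": ds.labels}
                         ).to_csv(lp, index=False, header=False)
    elif format == "mtx":
        mmwrite(path, coo_matrix(ds.matrix.T), precision=17)
        d = os.path.dirname(path)
        pd.Series(ds.gene_ids).to_csv(os.path.join(d, "genes.tsv"),
                                      sep="\t", index=False, header=False)
        pd.Series(ds.cell_ids).to_csv(os.path.join(d, "barcodes.tsv"),
                                      sep="\t", index=False, header=False)
    elif format == "h5ad":
        import anndata as ad
        obs = pd.DataFrame(index=pd.Index(ds.cell_ids, name="cell_id"))
        if ds.labels is not None:
            obs["cell_type"] = ds.labels.astype(str)
        a = ad.AnnData(X=ds.matrix, obs=obs,
                       var=pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene_id")))
        a.write_h5ad(path)
    else:
        raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# Alignment and preprocessing
# ---------------------------------------------------------------------------

def intersect_genes(source: DomainDataset, target: DomainDataset,
                    paired: bool = False) -> AlignedPair:
    """Subset both domains to the sorted intersection of their gene sets.

    Exact, case-sensitive symbol matching; the shared genes are ordered
    lexicographically so column k of either matrix refers to the same gene.
    """
    if source.n_cells == 0 or target.n_cells == 0:
        raise ValueError("both datasets must be nonempty")
    shared = sorted(set(source.gene_ids) & set(target.gene_ids))
    if not shared:
        raise ValueError("no shared genes")
    return AlignedPair(source=source.subset_genes(shared),
                       target=target.subset_genes(shared), paired=paired)


def preprocess(ds: DomainDataset, normalize: str = "none",
               scale: bool = False) -> DomainDataset:
    """Library-size normalisation and per-gene standardisation.

    ``log1p_cpm`` rescales each cell to a total of 1e4 then applies
    log(1 + x); ``scale`` centres each gene and divides by its standard
    deviation, leaving zero-variance genes at 0.
    """
    X = ds.matrix.copy()
    if normalize == "log1p_cpm":
        if np.any(X < 0):
            raise ValueError("log1p_cpm requires a nonnegative matrix")
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        X = np.log1p(X / totals * CPM_TARGET)
    elif normalize != "none":
        raise ValueError(f"unknown normalize option: {normalize!r}")
    if scale:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        X = X - mu
        nz = sd > 0
        X[:, nz] /= sd[nz]
        X[:, ~nz] = 0.0
    return replace(ds, matrix=X)
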
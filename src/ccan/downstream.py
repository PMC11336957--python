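"""Downstream analyses on a trained model: circular cell-cycle pseudotime,
discrete phase calls, cell-cycle effect removal, and integration embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import network as net
from .data import AlignedPair, DomainDataset

TWO_PI = 2.0 * np.pi


@dataclass
class PseudotimeResult:
    """Per-cell circular pseudotime in [0, 2π), optionally discretised into
    three cell-cycle stages by a 1-D Gaussian mixture."""

    pseudotime: np.ndarray
    cell_ids: list
    phase_call: np.ndarray | None = None
    gmm_means: np.ndarray | None = None
    gmm_weights: np.ndarray | None = None

    def __post_init__(self):
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if np.any(self.pseudotime < 0) or np.any(self.pseudotime >= TWO_PI):
            raise ValueError("pseudotime must lie in [0, 2π)")
        if self.gmm_weights is not None and not np.isclose(
                self.gmm_weights.sum(), 1.0, atol=1e-6):
            raise ValueError("gmm_weights must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cell_ids, "pseudotime": self.pseudotime})
        if self.phase_call is not None:
            df["phase"] = self.phase_call
        return df


@dataclass
class JointProfile:
    """Integration embedding: per-cell feature concatenation (paired) or
    row-stacked shared codes with domain-of-origin tags (unpaired)."""

    embedding: np.ndarray
    cell_ids: list
    domain_of_origin: np.ndarray
    mode: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.embedding,
                          columns=[f"dim{j}" for j in range(self.embedding.shape[1])])
        df.insert(0, "cell_id", self.cell_ids)
        df.insert(1, "domain", self.domain_of_origin)
        return df

    def save_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def load_csv(cls, path: str) -> "JointProfile":
        df = pd.read_csv(path, float_precision="round_trip")
        mode = ("paired_concat_features" if df["domain"].nunique() == 1
                and df["domain"].iloc[0] == "paired" else "unpaired_concat_cells")
        emb = df[[c for c in df.columns if c.startswith("dim")]].to_numpy(float)
        return cls(embedding=emb, cell_ids=df["cell_id"].tolist(),
                   domain_of_origin=df["domain"].to_numpy(), mode=mode)


def pseudotime(state, ds: DomainDataset) -> PseudotimeResult:
    """Map each cell's scalar private code onto the circle [0, 2π).

    The private embedding is the position along the circular manifold the
    sin/cos decoder branch models; modular reduction makes the 2π-periodicity
    of that branch explicit.
    """
    params = state.params if hasattr(state, "params") else state
    if params.cfg.private_dim != 1:
        raise ValueError("pseudotime extraction requires private_dim=1; "
                         "set RunConfig.private_dim = 1")
    zp = net.encode_private(params, ds.matrix, ds.role).value[:, 0]
    return PseudotimeResult(pseudotime=np.mod(zp, TWO_PI), cell_ids=list(ds.cell_ids))


def _cut_circle(values: np.ndarray) -> float:
    """Rotation that places the largest gap of the circular sample at 0."""
    s = np.sort(values)
    gaps = np.diff(s, append=s[0] + TWO_PI)
    j = int(np.argmax(gaps))
    return float(np.mod(s[j] + gaps[j] / 2.0, TWO_PI))  # middle of the empty arc


def call_phases(pt: PseudotimeResult, n_components: int = 3,
                max_iter: int = 500, seed: int = 0) -> PseudotimeResult:
    """Discretise pseudotime into {G1, S, G2M} with a 3-component 1-D GMM.

    The circle is first cut at the largest gap between sorted pseudotime
    values so the mixture is fitted on a linear coordinate; components are
    mapped to G1/S/G2M in ascending mean order — a labeling convention only,
    biological phase identity must come from marker genes.
    """
    from sklearn.mixture import GaussianMixture

    x = pt.pseudotime
    if len(np.unique(x)) < n_components:
        raise ValueError("need at least 3 distinct pseudotime values for a "
                         "3-component mixture (degenerate fit)")
    cut = _cut_circle(x)
    shifted = np.mod(x - cut, TWO_PI)
    gmm = GaussianMixture(n_components=n_components, covariance_type="full",
                          max_iter=max_iter, n_init=3, random_state=seed,
                          reg_covar=1e-6)
    gmm.fit(shifted.reshape(-1, 1))
    if not gmm.converged_:
        raise RuntimeError(
            f"EM failed to converge in {max_iter} iterations "
            f"(final log-likelihood lower bound {gmm.lower_bound_:.6g})")
    comp = gmm.predict(shifted.reshape(-1, 1))
    order = np.argsort(gmm.means_[:, 0])
    names = np.array(["G1", "S", "G2M"])
    rank = np.empty(n_components, dtype=int)
    rank[order] = np.arange(n_components)
    calls = names[rank[comp]]
    means = np.mod(gmm.means_[order, 0] + cut, TWO_PI)
    weights = gmm.weights_[order]
    return replace(pt, phase_call=calls, gmm_means=means, gmm_weights=weights)


def remove_cycle_effect(state, ds: DomainDataset) -> DomainDataset:
    """Subtract the circular pathway's contribution to the reconstruction.

    The decoder past its first layer is linear, so the circular component
    decomposes exactly: it is the decoder output with the acyclic branch
    zeroed minus the output with both branches zeroed (the bias path).  The
    corrected matrix keeps the input's shape and gene order.
    """
    params = state.params if hasattr(state, "params") else state
    zs = net.encode_shared(params, ds.matrix).value
    zp = net.encode_private(params, ds.matrix, ds.role).value
    circ_only = net.decode(params, zs, zp, ds.role, zero_acyclic=True).value
    bias_only = net.decode(params, zs, zp, ds.role,
                           zero_acyclic=True, zero_circular=True).value
    return replace(ds, matrix=ds.matrix - (circ_only - bias_only))


def joint_embedding(state, pair: AlignedPair) -> JointProfile:
    """Integration embedding of a trained model.

    Paired mode concatenates each cell's source and target shared codes
    (one row per cell pair, 2·latent_dim columns); unpaired mode stacks all
    cells from both domains in the shared space (latent_dim columns) with
    their domain of origin recorded.
    """
    params = state.params if hasattr(state, "params") else state
    z_ss = net.encode_shared(params, pair.source.matrix).value
    z_ts = net.encode_shared(params, pair.target.matrix).value
    if pair.paired:
        if pair.source.n_cells != pair.target.n_cells:
            raise ValueError("paired mode requires equal cell counts")
        return JointProfile(embedding=np.concatenate([z_ss, z_ts], axis=1),
                            cell_ids=list(pair.source.cell_ids),
                            domain_of_origin=np.full(pair.source.n_cells, "paired"),
                            mode="paired_concat_features")
    emb = np.concatenate([z_ss, z_ts], axis=0)
    ids = list(pair.source.cell_ids) + list(pair.target.cell_ids)
    origin = np.array(["source"] * pair.source.n_cells
                      + ["target"] * pair.target.n_cells)
    return JointProfile(embedding=emb, cell_ids=ids, domain_of_origin=origin,
                        mode="unpaired_concat_cells")


def circular_correlation(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Fisher–Lee circular correlation between two angle vectors.

    ρ = Σ sin(α−ᾱ)sin(β−β̄) / √(Σ sin²(α−ᾱ) Σ sin²(β−β̄)), where the means
    are circular means.  Invariant to rotation of either circle; reflection
    flips the sign, so |ρ| measures agreement up to rotation/reflection.
    """
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    abar = np.arctan2(np.sin(alpha).mean(), np.cos(alpha).mean())
    bbar = np.arctan2(np.sin(beta).mean(), np.cos(beta).mean())
    sa = np.sin(alpha - abar)
    sb = np.sin(beta - bbar)
    den = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
    return float((sa * sb).sum() / den) if den > 0 else 0.0
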
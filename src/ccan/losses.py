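"""Training objectives: reconstruction, orthogonality, MMD alignment,
cross-entropy classification, and the class-conditional cluster alignment
loss used during refinement.

All losses are implemented on the autodiff Tensor type so the same code path
is differentiated during training; plain ndarray inputs return plain floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

LOG_FLOOR = 1e-12


def _wrap(*arrays):
    tensors = [ag.as_tensor(a) for a in arrays]
    was_plain = not any(isinstance(a, Tensor) for a in arrays)
    return tensors, was_plain


def _out(t: Tensor, was_plain: bool):
    return float(t.value) if was_plain else t


@dataclass
class LossBreakdown:
    """Per-term loss values, their weights and the weighted total."""

    recons: float
    diff: float
    align_mmd: float
    align_ca: float
    classify: float
    weights: dict
    total: float
    tensor: object = field(default=None, repr=False, compare=False)

    def as_dict(self) -> dict:
        return {"recons": self.recons, "diff": self.diff,
                "align_mmd": self.align_mmd, "align_ca": self.align_ca,
                "classify": self.classify, "total": self.total}


@dataclass
class ClusterAlignConfig:
    """Margin and class set for the cluster alignment loss (squared-Euclidean
    distance; delta is the same-class indicator per source–target pair)."""

    margin_m: float = 1.0
    classes: list | None = None

    def __post_init__(self):
        if self.margin_m <= 0:
            raise ValueError("margin_m must be positive")


def loss_recons(X_s, Xhat_s, X_t, Xhat_t):
    """Per-cell-averaged squared Frobenius reconstruction error, summed over
    the two domains: (1/N_s)‖X_s−X̂_s‖² + (1/N_t)‖X_t−X̂_t‖²."""
    (xs, hs, xt, ht), plain = _wrap(X_s, Xhat_s, X_t, Xhat_t)
    if xs.shape != hs.shape or xt.shape != ht.shape:
        raise ValueError("reconstruction shape mismatch")
    ds = xs - hs
    dt = xt - ht
    val = (ds * ds).sum() * (1.0 / xs.shape[0]) + (dt * dt).sum() * (1.0 / xt.shape[0])
    return _out(val, plain)


def loss_diff(z_ss, z_sp, z_ts, z_tp):
    """Orthogonality penalty ‖z_ssᵀz_sp‖² + ‖z_tsᵀz_tp‖² pushing shared and
    private embeddings apart within each domain."""
    (ss, sp, ts, tp), plain = _wrap(z_ss, z_sp, z_ts, z_tp)
    if ss.shape[0] != sp.shape[0] or ts.shape[0] != tp.shape[0]:
        raise ValueError("row count mismatch between shared and private codes")
    a = ss.T @ sp
    b = ts.T @ tp
    return _out((a * a).sum() + (b * b).sum(), plain)


def _pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    aa = (a * a).sum(axis=1, keepdims=True)
    bb = (b * b).sum(axis=1, keepdims=True)
    return aa + bb.T - 2.0 * (a @ b.T)


def loss_mmd(z_ss, z_ts, bandwidths=(0.25, 0.5, 1.0, 2.0, 4.0),
             kernel: str = "gaussian"):
    """Squared maximum mean discrepancy between the two shared-code samples.

    The Gaussian kernel is summed over ``bandwidths`` × the median pairwise
    distance of the pooled sample (median heuristic, held constant under
    differentiation).  ``kernel="linear"`` gives the exact squared distance
    between sample means, handy for closed-form checks.
    """
    (zs, zt), plain = _wrap(z_ss, z_ts)
    if zs.shape[0] == 0 or zt.shape[0] == 0:
        raise ValueError("both domains must be nonempty")
    if zs.shape[1] != zt.shape[1]:
        raise ValueError("latent dimensions differ")
    if kernel == "linear":
        d = zs.mean(axis=0) - zt.mean(axis=0)
        return _out((d * d).sum(), plain)
    if kernel != "gaussian":
        raise ValueError(f"unknown kernel: {kernel!r}")
    D_ss = _pairwise_sq_dists(zs, zs)
    D_tt = _pairwise_sq_dists(zt, zt)
    D_st = _pairwise_sq_dists(zs, zt)
    pooled = np.concatenate([zs.value, zt.value], axis=0)
    pd = np.sqrt(np.maximum(_pairwise_sq_dists(
        Tensor(pooled), Tensor(pooled)).value, 0.0))
    sigma = np.median(pd[np.triu_indices_from(pd, k=1)]) if pooled.shape[0] > 1 else 1.0
    if sigma <= 0:
        sigma = 1.0
    total = None
    for b in bandwidths:
        gamma = 1.0 / (2.0 * (b * sigma) ** 2)
        term = (ag.exp(D_ss * (-gamma)).mean() + ag.exp(D_tt * (-gamma)).mean()
                - 2.0 * ag.exp(D_st * (-gamma)).mean())
        total = term if total is None else total + term
    return _out(total, plain)


def loss_class(labels_onehot, probs):
    """Mean negated cross-entropy −(1/N)Σᵢ Σₖ yᵢₖ log pᵢₖ with log clamped
    at 1e-12."""
    (y, p), plain = _wrap(labels_onehot, probs)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have matching shapes")
    ll = (y * ag.log(p, floor=LOG_FLOOR)).sum() * (-1.0 / y.shape[0])
    return _out(ll, plain)


def loss_cluster_align(z_ss, labels_s, z_ts, pseudolabels_t,
                       cfg: ClusterAlignConfig):
    """Class-conditional alignment: same-class source–target pairs are pulled
    together, different-class pairs pushed beyond margin m, and per-class
    centroids of the two domains matched:

        (1/(N_s·N_t)) Σᵢⱼ [δᵢⱼ·d(zᵢ,zⱼ) + (1−δᵢⱼ)·max(0, m−d(zᵢ,zⱼ))]
        + (1/K) Σₖ ‖λ_sᵏ − λ_tᵏ‖²,   d = squared Euclidean.
    """
    (zs, zt), plain = _wrap(z_ss, z_ts)
    labels_s = np.asarray(labels_s)
    pseudolabels_t = np.asarray(pseudolabels_t)
    if len(labels_s) != zs.shape[0] or len(pseudolabels_t) != zt.shape[0]:
        raise ValueError("label vectors must match code row counts")
    classes = (sorted(set(map(str, labels_s))) if cfg.classes is None
               else [str(c) for c in cfg.classes])
    ls = labels_s.astype(str)
    lt = pseudolabels_t.astype(str)
    for c in classes:
        if not np.any(ls == c):
            raise ValueError(f"class {c!r} has no source cells (centroid undefined)")
        if not np.any(lt == c):
            raise ValueError(
                f"class {c!r} has no target cells (centroid undefined); "
                "rerun label transfer or drop the class")
    unknown = set(lt) - set(classes)
    if unknown:
        raise ValueError(f"target pseudolabels outside source class set: {unknown}")

    D = _pairwise_sq_dists(zs, zt)
    delta = Tensor((ls[:, None] == lt[None, :]).astype(np.float64))
    hinge = ag.relu(Tensor(np.full(D.shape, cfg.margin_m)) - D)
    pair = (delta * D + (1.0 - delta) * hinge).sum() * (1.0 / (zs.shape[0] * zt.shape[0]))

    K = len(classes)
    Ms = np.zeros((K, zs.shape[0]))
    Mt = np.zeros((K, zt.shape[0]))
    for k, c in enumerate(classes):
        Ms[k, ls == c] = 1.0 / np.sum(ls == c)
        Mt[k, lt == c] = 1.0 / np.sum(lt == c)
    cd = Tensor(Ms) @ zs - Tensor(Mt) @ zt
    centroid = (cd * cd).sum() * (1.0 / K)
    return _out(pair + centroid, plain)


def total_loss(recons, diff, mmd, classify, ca, weights: dict,
               phase: str) -> LossBreakdown:
    """Weighted sum of the loss terms.

    Pretraining uses L_align = L_MMD; refinement adds the cluster alignment
    term (L_align = L_MMD + L_ca).  The returned breakdown records the
    effective weight of every term (ca weight is 0 during pretraining).
    """
    if phase not in ("pretrain", "refine"):
        raise ValueError(f"unknown phase: {phase!r}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")
    terms = {"recons": recons, "diff": diff, "mmd": mmd, "class": classify, "ca": ca}
    eff = {k: float(weights.get(k, 1.0)) for k in terms}
    if phase == "pretrain":
        eff["ca"] = 0.0
    total_t = None
    for k, v in terms.items():
        if eff[k] == 0.0:
            continue
        term = ag.as_tensor(v) * eff[k]
        total_t = term if total_t is None else total_t + term
    if total_t is None:
        total_t = Tensor(0.0)

    def f(x):
        return float(x.value) if isinstance(x, Tensor) else float(x)

    any_tensor = any(isinstance(v, Tensor) for v in terms.values())
    return LossBreakdown(recons=f(recons), diff=f(diff), align_mmd=f(mmd),
                         align_ca=f(ca), classify=f(classify), weights=eff,
                         total=float(total_t.value),
                         tensor=total_t if any_tensor else None)
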
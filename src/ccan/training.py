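"""The four-step training schedule.

Step 1 pretrains the domain separation network on reconstruction,
orthogonality, MMD alignment and source-side classification.  Step 2
transfers cell-type labels to the target domain through the classifier on
shared codes.  Step 3 refines the network with the cluster alignment loss
over class-balanced mini-batches (pseudolabels held fixed).  Step 4 freezes
the model, re-predicts target annotations and emits the joint profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from . import losses as L
from . import network as net
from .data import AlignedPair, DomainDataset, RunConfig
from .losses import ClusterAlignConfig, LossBreakdown
from .network import ModelParams


@dataclass
class TrainState:
    """Mutable state threaded through the training steps."""

    params: ModelParams
    cfg: RunConfig
    epoch: int = 0
    phase: str = "pretrain"
    pseudolabels_t: np.ndarray | None = None
    confidence_t: np.ndarray | None = None
    history: list = field(default_factory=list)
    rng: np.random.Generator | None = None


@dataclass
class BalancedBatch:
    """Per-class index lists for one mini-batch of each domain."""

    source_indices: dict
    target_indices: dict

    def flat_source(self) -> np.ndarray:
        return np.concatenate([self.source_indices[c] for c in sorted(self.source_indices)])

    def flat_target(self) -> np.ndarray:
        return np.concatenate([self.target_indices[c] for c in sorted(self.target_indices)])


def _onehot(labels: np.ndarray, classes: list) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(np.asarray(labels).astype(str)):
        out[r, idx[lab]] = 1.0
    return out


def _epoch_breakdown(params: ModelParams, pair: AlignedPair, cfg: RunConfig,
                     phase: str, labels_t: np.ndarray | None) -> LossBreakdown:
    """Full-data loss evaluation recorded once per epoch."""
    Xs, Xt = pair.source.matrix, pair.target.matrix
    z_ss = net.encode_shared(params, Xs)
    z_sp = net.encode_private(params, Xs, "source")
    z_ts = net.encode_shared(params, Xt)
    z_tp = net.encode_private(params, Xt, "target")
    recons = L.loss_recons(Xs, net.decode(params, z_ss, z_sp, "source").value,
                           Xt, net.decode(params, z_ts, z_tp, "target").value)
    diff = L.loss_diff(z_ss.value, z_sp.value, z_ts.value, z_tp.value)
    mmd = L.loss_mmd(z_ss.value, z_ts.value, cfg.mmd_bandwidths, cfg.mmd_kernel)
    y = _onehot(pair.source.labels, params.classes)
    cls = L.loss_class(y, net.classify(params, z_ss.value).probs)
    ca = 0.0
    if phase == "refine" and labels_t is not None:
        ca = L.loss_cluster_align(
            z_ss.value, pair.source.labels, z_ts.value, labels_t,
            ClusterAlignConfig(margin_m=cfg.margin_m, classes=params.classes))
    return L.total_loss(recons, diff, mmd, cls, ca, cfg.loss_weights, phase)


def _cycled(perm: np.ndarray, start: int, size: int) -> np.ndarray:
    idx = np.arange(start, start + size) % len(perm)
    return perm[idx]


def pretrain(pair: AlignedPair, cfg: RunConfig,
             epochs: int | None = None) -> TrainState:
    """Step 1: joint embedding and modality alignment.

    Optimises the weighted sum of reconstruction, orthogonality, MMD and
    source classification losses with Adam over shuffled mini-batches.
    Deterministic given ``cfg.seed``.  ``epochs`` defaults to
    ``round(cfg.epochs * cfg.pretrain_fraction)``.

    The first ``cfg.circular_warmup_fraction`` of the epochs train only the
    reconstruction through the circular pathway (acyclic branch zeroed), so
    the private embedding locks onto the dominant periodic structure before
    the higher-capacity shared branch competes for it; joint optimisation of
    all terms follows.
    """
    if pair.source.labels is None:
        raise ValueError("source domain requires labels")
    classes = sorted(set(map(str, pair.source.labels)))
    if len(classes) < 2:
        raise ValueError("source domain has a single class; classifier undefined")
    if epochs is None:
        epochs = int(round(cfg.epochs * cfg.pretrain_fraction))
    rng = np.random.default_rng(cfg.seed)
    params = net.init_params(pair.source.n_genes, classes, cfg, seed=cfg.seed)
    state = TrainState(params=params, cfg=cfg, rng=rng)
    if epochs == 0:
        return state

    opt = ag.Adam(params.parameters(), lr=cfg.learning_rate)
    Xs, Xt = pair.source.matrix, pair.target.matrix
    Y = _onehot(pair.source.labels, classes)
    n_steps = math.ceil(max(Xs.shape[0], Xt.shape[0]) / cfg.batch_size)
    n_warm = int(round(epochs * cfg.circular_warmup_fraction))
    Xc = _class_centered(Xs, np.asarray(pair.source.labels).astype(str))
    for epoch in range(epochs):
        perm_s = rng.permutation(Xs.shape[0])
        perm_t = rng.permutation(Xt.shape[0])
        for step in range(n_steps):
            ofs = step * cfg.batch_size
            i_s = _cycled(perm_s, ofs, min(cfg.batch_size, Xs.shape[0]))
            i_t = _cycled(perm_t, ofs, min(cfg.batch_size, Xt.shape[0]))
            opt.zero_grad()
            if epoch < n_warm:
                total = _warmup_loss(params, Xc[i_s])
            else:
                total = _step_loss(params, Xs[i_s], Y[i_s], Xt[i_t], cfg,
                                   phase="pretrain", labels_s=None,
                                   labels_t=None).tensor
            total.backward()
            opt.step()
        state.epoch += 1
        state.history.append(_epoch_breakdown(params, pair, cfg, "pretrain", None))
    return state


def _warmup_loss(params: ModelParams, Xb_centered):
    """Circular-only reconstruction of the class-centred source residual.

    Cell-cycle variation is within-type variation, so centring each source
    class removes the discrete type structure and leaves the periodic signal
    for the circular pathway to lock onto.  Both private encoders are warmed
    on the same residual (they share the decoder, which carries the circular
    gene loadings to the target domain); the acyclic branch is zeroed so the
    shared encoder cannot absorb the cycle during this phase.
    """
    xb = ag.Tensor(Xb_centered)
    z_sp = net.encode_private(params, Xb_centered, "source")
    z_tp = net.encode_private(params, Xb_centered, "target")
    zs = net.encode_shared(params, Xb_centered)
    xhat_s = net.decode(params, zs, z_sp, "source", zero_acyclic=True)
    xhat_t = net.decode(params, zs, z_tp, "target", zero_acyclic=True)
    return L.loss_recons(xb, xhat_s, xb, xhat_t)


def _class_centered(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    Xc = X.copy()
    for c in np.unique(labels):
        m = labels == c
        Xc[m] -= X[m].mean(axis=0)
    return Xc


def _step_loss(params: ModelParams, Xb_s, Yb_s, Xb_t, cfg: RunConfig,
               phase: str, labels_s, labels_t,
               Yb_t=None) -> LossBreakdown:
    z_ss = net.encode_shared(params, Xb_s)
    z_sp = net.encode_private(params, Xb_s, "source")
    z_ts = net.encode_shared(params, Xb_t)
    z_tp = net.encode_private(params, Xb_t, "target")
    xhat_s = net.decode(params, z_ss, z_sp, "source")
    xhat_t = net.decode(params, z_ts, z_tp, "target")
    recons = L.loss_recons(ag.Tensor(Xb_s), xhat_s, ag.Tensor(Xb_t), xhat_t)
    diff = L.loss_diff(z_ss, z_sp, z_ts, z_tp)
    mmd = L.loss_mmd(z_ss, z_ts, cfg.mmd_bandwidths, cfg.mmd_kernel)
    probs_s = ag.softmax(net.classify_logits(params, z_ss))
    cls = L.loss_class(ag.Tensor(Yb_s), probs_s)
    if Yb_t is not None and cfg.self_training:
        probs_t = ag.softmax(net.classify_logits(params, z_ts))
        cls = cls + L.loss_class(ag.Tensor(Yb_t), probs_t)
    ca = 0.0
    if phase == "refine":
        ca = L.loss_cluster_align(
            z_ss, labels_s, z_ts, labels_t,
            ClusterAlignConfig(margin_m=cfg.margin_m, classes=params.classes))
    return L.total_loss(recons, diff, mmd, cls, ca, cfg.loss_weights, phase)


def transfer_labels(state: TrainState, target: DomainDataset
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Step 2: pseudolabel each target cell by the classifier's argmax on its
    shared code (ties broken toward the lowest class index); also returns the
    max-probability confidence per cell."""
    out = net.classify(state.params, net.encode_shared(state.params, target.matrix).value)
    return out.predicted, out.probs.max(axis=1)


def balanced_batches(labels, batch_size: int, seed: int) -> list[dict]:
    """Class-balanced mini-batch index sets covering every cell ≥ once.

    Each batch draws floor(batch_size/K) cells per class (a remainder is
    assigned one-per-class by ascending class index).  Classes smaller than
    their quota are recycled (sampling with replacement across the epoch only
    as needed); no cell is discarded.
    """
    labels = np.asarray(labels).astype(str)
    classes = sorted(set(labels))
    K = len(classes)
    if batch_size < K:
        raise ValueError(f"batch_size {batch_size} < number of classes {K}")
    q, rem = divmod(batch_size, K)
    counts = {c: q + (1 if k < rem else 0) for k, c in enumerate(classes)}
    rng = np.random.default_rng(seed)
    members = {c: np.flatnonzero(labels == c) for c in classes}
    n_batches = max(math.ceil(len(members[c]) / counts[c]) for c in classes)
    streams = {}
    for c in classes:
        need = n_batches * counts[c]
        parts = []
        while sum(len(p) for p in parts) < need:
            parts.append(rng.permutation(members[c]))
        streams[c] = np.concatenate(parts)[:need]
    return [{c: streams[c][b * counts[c]:(b + 1) * counts[c]] for c in classes}
            for b in range(n_batches)]


def refine(state: TrainState, pair: AlignedPair, cfg: RunConfig,
           epochs: int | None = None) -> TrainState:
    """Step 3: continue optimisation with the cluster alignment term added to
    the alignment loss, over class-balanced mini-batches.

    In unpaired mode target pseudolabels from step 2 are required and held
    fixed; in paired mode the source labels stand in for both domains and no
    pseudolabel prediction is needed.
    """
    if epochs is None:
        epochs = cfg.epochs - int(round(cfg.epochs * cfg.pretrain_fraction))
    if pair.paired:
        labels_t = np.asarray(pair.source.labels).astype(str)
    elif state.pseudolabels_t is not None:
        labels_t = np.asarray(state.pseudolabels_t).astype(str)
    elif pair.target.labels is not None:
        labels_t = np.asarray(pair.target.labels).astype(str)
    else:
        raise ValueError("refine requires pseudolabels (run transfer_labels) "
                         "or a paired/labeled target")
    params = state.params
    missing = [c for c in params.classes if c not in set(labels_t)]
    if missing:
        raise ValueError(
            f"classes {missing} absent from target labels; centroids undefined. "
            "Consider more pretraining epochs or dropping the class from the source.")
    state.phase = "refine"
    state.pseudolabels_t = labels_t
    if epochs <= 0:
        return state

    rng = state.rng if state.rng is not None else np.random.default_rng(cfg.seed)
    opt = ag.Adam(params.parameters(), lr=cfg.learning_rate)
    Xs, Xt = pair.source.matrix, pair.target.matrix
    labels_s = np.asarray(pair.source.labels).astype(str)
    Y = _onehot(labels_s, params.classes)
    Yt = _onehot(labels_t, params.classes)
    for _ in range(epochs):
        seed_s = int(rng.integers(2 ** 31))
        seed_t = int(rng.integers(2 ** 31))
        bs = balanced_batches(labels_s, cfg.batch_size, seed_s)
        bt = balanced_batches(labels_t, cfg.batch_size, seed_t)
        n_batches = max(len(bs), len(bt))
        for b in range(n_batches):
            batch = BalancedBatch(source_indices=bs[b % len(bs)],
                                  target_indices=bt[b % len(bt)])
            i_s = batch.flat_source()
            i_t = batch.flat_target()
            opt.zero_grad()
            total = _step_loss(params, Xs[i_s], Y[i_s], Xt[i_t], cfg,
                               phase="refine", labels_s=labels_s[i_s],
                               labels_t=labels_t[i_t], Yb_t=Yt[i_t])
            total.tensor.backward()
            opt.step()
        state.epoch += 1
        state.history.append(_epoch_breakdown(params, pair, cfg, "refine", labels_t))
    return state


@dataclass
class FinalResult:
    """Frozen model, final target annotations and the joint profile."""

    params: ModelParams
    labels: np.ndarray
    confidence: np.ndarray
    joint: object  # downstream.JointProfile


def finalize(state: TrainState, pair: AlignedPair) -> FinalResult:
    """Step 4: freeze the model, re-predict target annotations with the
    refined weights, and build the integration embedding."""
    from .downstream import joint_embedding
    labels, conf = transfer_labels(state, pair.target)
    return FinalResult(params=state.params.copy(), labels=labels,
                       confidence=conf, joint=joint_embedding(state, pair))


def run_ccan(pair: AlignedPair, cfg: RunConfig,
             refine_rounds: int = 1) -> tuple[TrainState, FinalResult]:
    """Convenience wrapper running steps 1–4 end to end.

    ``refine_rounds`` > 1 repeats steps 2–3 (re-predicting pseudolabels
    between rounds); the default is a single pass.
    """
    state = pretrain(pair, cfg)
    n_refine = cfg.epochs - int(round(cfg.epochs * cfg.pretrain_fraction))
    per_round = max(1, n_refine // max(1, refine_rounds)) if n_refine > 0 else 0
    for _ in range(max(1, refine_rounds)):
        if not pair.paired:
            labels, conf = transfer_labels(state, pair.target)
            state.pseudolabels_t = labels
            state.confidence_t = conf
        state = refine(state, pair, cfg, epochs=per_round)
    return state, finalize(state, pair)


def disentanglement_ratio(params: ModelParams, pair: AlignedPair) -> float:
    """Normalized orthogonality ‖z_ssᵀ z_sp‖_F / (‖z_ss‖_F · ‖z_sp‖_F) of the
    source domain; lower means better shared/private separation."""
    z_ss = net.encode_shared(params, pair.source.matrix).value
    z_sp = net.encode_private(params, pair.source.matrix, "source").value
    num = np.linalg.norm(z_ss.T @ z_sp)
    den = np.linalg.norm(z_ss) * np.linalg.norm(z_sp)
    return float(num / den) if den > 0 else 0.0
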
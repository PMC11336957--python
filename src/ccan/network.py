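"""The cell cycle-aware domain separation network.

Each domain is encoded twice: a *shared* three-layer selu MLP (one function
for both domains) produces the domain-invariant code used for alignment and
classification, and a domain-specific *private* three-layer tanh MLP produces
the circular code that models cell-cycle progression.  The decoder's first
layer applies sin/cos to the private code (the circular branch) and a linear
map to the shared code (the acyclic branch); the remaining two layers are
linear, so the circular contribution to the reconstruction is an exactly
separable linear pathway.  A small selu MLP with softmax output classifies
cell types from shared codes only.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .data import DomainDataset, RunConfig


@dataclass
class EmbeddingSet:
    """Shared and private codes for both domains (z_ss, z_sp, z_ts, z_tp)."""

    z_ss: np.ndarray | None = None
    z_sp: np.ndarray | None = None
    z_ts: np.ndarray | None = None
    z_tp: np.ndarray | None = None


@dataclass
class ClassifierOutput:
    """Row-stochastic class probabilities plus argmax calls."""

    probs: np.ndarray
    predicted: np.ndarray
    classes: list

    def __post_init__(self):
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")


def _init_layer(rng: np.random.Generator, fan_in: int, fan_out: int) -> tuple[Tensor, Tensor]:
    bound = 1.0 / np.sqrt(fan_in)
    W = Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)), requires_grad=True)
    b = Tensor(np.zeros(fan_out), requires_grad=True)
    return W, b


def _mlp(rng, dims: list[int]) -> list[tuple[Tensor, Tensor]]:
    return [_init_layer(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]


@dataclass
class ModelParams:
    """All weights: shared/private encoders, decoder(s), classifier."""

    n_genes: int
    classes: list
    cfg: RunConfig
    shared_encoder: list = field(default_factory=list)
    private_encoder_source: list = field(default_factory=list)
    private_encoder_target: list = field(default_factory=list)
    decoder: dict = field(default_factory=dict)
    decoder_target: dict | None = None  # used only when cfg.shared_decoder=False
    classifier: list = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layers in (self.shared_encoder, self.private_encoder_source,
                       self.private_encoder_target, self.classifier):
            for W, b in layers:
                out += [W, b]
        for dec in (self.decoder, self.decoder_target):
            if dec is None:
                continue
            out += [dec["V_circular"], dec["V_acyclic"], dec["b0"]]
            for W, b in dec["linear"]:
                out += [W, b]
        return out

    def copy(self) -> "ModelParams":
        new = init_params(self.n_genes, self.classes, self.cfg)
        for p_new, p_old in zip(new.parameters(), self.parameters()):
            p_new.value = p_old.value.copy()
        return new


def _init_decoder(rng, cfg: RunConfig, n_genes: int) -> dict:
    h = list(reversed(cfg.encoder_dims))  # decoder mirrors the encoder
    d0 = h[0]
    bc = 1.0 / np.sqrt(2 * cfg.private_dim)
    ba = 1.0 / np.sqrt(cfg.latent_dim)
    return {
        "V_circular": Tensor(rng.uniform(-bc, bc, size=(2 * cfg.private_dim, d0)),
                             requires_grad=True),
        "V_acyclic": Tensor(rng.uniform(-ba, ba, size=(cfg.latent_dim, d0)),
                            requires_grad=True),
        "b0": Tensor(np.zeros(d0), requires_grad=True),
        "linear": _mlp(rng, h + [n_genes]),
    }


def init_params(n_genes: int, classes: list, cfg: RunConfig,
                seed: int | None = None) -> ModelParams:
    """Deterministic fan-in-uniform initialisation from a seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    enc = [n_genes] + list(cfg.encoder_dims)
    params = ModelParams(n_genes=n_genes, classes=sorted(set(map(str, classes))), cfg=cfg)
    params.shared_encoder = _mlp(rng, enc + [cfg.latent_dim])
    params.private_encoder_source = _mlp(rng, enc + [cfg.private_dim])
    params.private_encoder_target = _mlp(rng, enc + [cfg.private_dim])
    params.decoder = _init_decoder(rng, cfg, n_genes)
    if not cfg.shared_decoder:
        params.decoder_target = _init_decoder(rng, cfg, n_genes)
    params.classifier = _mlp(rng, [cfg.latent_dim] + list(cfg.classifier_dims)
                             + [len(params.classes)])
    return params


# ---------------------------------------------------------------------------
# Forward passes (operate on autodiff Tensors; ndarray inputs are wrapped)
# ---------------------------------------------------------------------------

def _run_mlp(layers, x: Tensor, activation) -> Tensor:
    """Apply layers with `activation` after all but the last (linear) layer."""
    for i, (W, b) in enumerate(layers):
        x = x @ W + b
        if i < len(layers) - 1:
            x = activation(x)
    return x


def encode_shared(params: ModelParams, X) -> Tensor:
    X = ag.as_tensor(X)
    if X.shape[1] != params.n_genes:
        raise ValueError(f"expected {params.n_genes} genes, got {X.shape[1]}")
    return _run_mlp(params.shared_encoder, X, ag.selu)


def encode_private(params: ModelParams, X, role: str) -> Tensor:
    X = ag.as_tensor(X)
    if X.shape[1] != params.n_genes:
        raise ValueError(f"expected {params.n_genes} genes, got {X.shape[1]}")
    layers = (params.private_encoder_source if role == "source"
              else params.private_encoder_target)
    return _run_mlp(layers, X, ag.tanh)


def encode(params: ModelParams, ds: DomainDataset) -> EmbeddingSet:
    """Encode one domain; fills the slice of the EmbeddingSet for its role."""
    zs = encode_shared(params, ds.matrix).value
    zp = encode_private(params, ds.matrix, ds.role).value
    if ds.role == "source":
        return EmbeddingSet(z_ss=zs, z_sp=zp)
    return EmbeddingSet(z_ts=zs, z_tp=zp)


def decode(params: ModelParams, shared, private, role: str = "source",
           zero_circular: bool = False, zero_acyclic: bool = False) -> Tensor:
    """Reconstruct expression from codes.

    The first layer is V_circular·[sin z_p ; cos z_p] + V_acyclic·z_s + b0;
    the two remaining layers are linear.  `zero_circular` / `zero_acyclic`
    null the corresponding branch's input contribution (used to isolate the
    circular pathway when removing cell-cycle effects).
    """
    dec = params.decoder
    if role == "target" and params.decoder_target is not None:
        dec = params.decoder_target
    zs = ag.as_tensor(shared)
    zp = ag.as_tensor(private)
    if zs.shape[1] != dec["V_acyclic"].shape[0]:
        raise ValueError(f"expected shared dim {dec['V_acyclic'].shape[0]}, "
                         f"got {zs.shape[1]}")
    if 2 * zp.shape[1] != dec["V_circular"].shape[0]:
        raise ValueError(f"expected private dim {dec['V_circular'].shape[0] // 2}, "
                         f"got {2 * zp.shape[1]}")
    h = Tensor(np.zeros((zs.shape[0], dec["b0"].shape[0]))) + dec["b0"]
    if not zero_circular:
        circ = ag.concat([ag.sin(zp), ag.cos(zp)], axis=1)
        h = h + circ @ dec["V_circular"]
    if not zero_acyclic:
        h = h + zs @ dec["V_acyclic"]
    return _linear_tail(dec, h)


def _linear_tail(dec: dict, h: Tensor) -> Tensor:
    for W, b in dec["linear"]:
        h = h @ W + b
    return h


def classify_logits(params: ModelParams, shared) -> Tensor:
    z = ag.as_tensor(shared)
    return _run_mlp(params.classifier, z, ag.selu)


def classify(params: ModelParams, shared) -> ClassifierOutput:
    """Cell-type probabilities from shared codes only (never private codes)."""
    probs = ag.softmax(classify_logits(params, shared)).value
    predicted = np.asarray([params.classes[i] for i in probs.argmax(axis=1)])
    return ClassifierOutput(probs=probs, predicted=predicted, classes=params.classes)


# ---------------------------------------------------------------------------
# Checkpointing: a flat binary archive with a JSON header
# ---------------------------------------------------------------------------

def _named_params(params: ModelParams):
    names, tensors = [], []

    def reg(prefix, layers):
        for i, (W, b) in enumerate(layers):
            names.extend([f"{prefix}.{i}.W", f"{prefix}.{i}.b"])
            tensors.extend([W, b])

    reg("shared", params.shared_encoder)
    reg("priv_s", params.private_encoder_source)
    reg("priv_t", params.private_encoder_target)
    for tag, dec in (("dec", params.decoder), ("dec_t", params.decoder_target)):
        if dec is None:
            continue
        names.extend([f"{tag}.V_circular", f"{tag}.V_acyclic", f"{tag}.b0"])
        tensors.extend([dec["V_circular"], dec["V_acyclic"], dec["b0"]])
        reg(f"{tag}.linear", dec["linear"])
    reg("clf", params.classifier)
    return names, tensors


def save_checkpoint(params: ModelParams, path: str) -> None:
    names, tensors = _named_params(params)
    header = json.dumps({"config": params.cfg.to_dict(),
                         "classes": list(params.classes),
                         "n_genes": params.n_genes})
    arrays = {n: t.value for n, t in zip(names, tensors)}
    np.savez(path, _header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> ModelParams:
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
        header = json.loads(bytes(z["_header"]).decode())
        cfg = RunConfig.from_dict(header["config"])
        params = init_params(header["n_genes"], header["classes"], cfg)
        names, tensors = _named_params(params)
        for n, t in zip(names, tensors):
            t.value = z[n].astype(np.float64)
    return params
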
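"""Neural cause-specific hazard models.

Both models map an ``(n, p)`` covariate matrix to an ``(n, E, T)`` tensor of
discrete-time cause-specific hazard probabilities through a sigmoid link.

The transformer treats the ``E x T`` output cells as a token sequence: each
token is the concatenation of a shared linear encoding of the covariates
with a learned embedding of its (cause, time) cell index, plus a sinusoidal
positional encoding.  A standard post-norm transformer encoder (multi-head
self-attention + feed-forward blocks with residual connections and layer
normalisation) contextualises the sequence, and a single linear read-out
per token produces the hazard logit of its cell.

The DeepHit-style baseline gives each cause an independent feed-forward
subnetwork with one 64-unit hidden layer (ReLU) emitting the T hazard
logits of that cause.  Unlike the original DeepHit it is trained purely on
the collapsed log-likelihood, with no ranking loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, layer_norm, linear, no_grad
from .data import HazardTensor

__all__ = [
    "TransformerConfig",
    "DeepHitConfig",
    "TransformerHazardModel",
    "DeepHitHazardModel",
    "count_parameters",
    "build_model",
    "save_model",
    "load_model",
]

_DTYPE = np.float32


@dataclass
class TransformerConfig:
    covariate_dim: int
    n_events: int
    horizon: int
    model_width: int = 64        # token dimension entering the encoder
    hidden_units: int = 64       # feed-forward width ("64-neuron hidden layers")
    n_encoder_layers: int = 2
    n_heads: int = 4
    dropout: float = 0.0         # benchmark setting: no dropout
    # discrete-time hazards are small probabilities; starting the sigmoid
    # near a typical event rate avoids wasting epochs deflating lambda ~ 0.5
    output_bias_init: float = -3.0
    kind: str = field(default="transformer", init=False)


@dataclass
class DeepHitConfig:
    covariate_dim: int
    n_events: int
    horizon: int
    hidden_units: int = 64
    output_bias_init: float = -3.0
    kind: str = field(default="deephit", init=False)


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> tuple[Tensor, Tensor]:
    """Kaiming-uniform weight + zero bias, as framework defaults would give."""
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(_DTYPE)
    b = np.zeros(fan_out, dtype=_DTYPE)
    return Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)


def _sinusoidal_encoding(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(_DTYPE)


class _EncoderLayer:
    """One self-attention + feed-forward block (post-norm, residual)."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        d, h = cfg.model_width, cfg.n_heads
        if d % h != 0:
            raise ValueError("model_width must be divisible by n_heads")
        self.d, self.h, self.dh = d, h, d // h
        self.wq, self.bq = _linear_init(rng, d, d)
        self.wk, self.bk = _linear_init(rng, d, d)
        self.wv, self.bv = _linear_init(rng, d, d)
        self.wo, self.bo = _linear_init(rng, d, d)
        self.w1, self.b1 = _linear_init(rng, d, cfg.hidden_units)
        self.w2, self.b2 = _linear_init(rng, cfg.hidden_units, d)
        self.g1 = Tensor(np.ones(d, dtype=_DTYPE), requires_grad=True)
        self.n1 = Tensor(np.zeros(d, dtype=_DTYPE), requires_grad=True)
        self.g2 = Tensor(np.ones(d, dtype=_DTYPE), requires_grad=True)
        self.n2 = Tensor(np.zeros(d, dtype=_DTYPE), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.wq, self.bq, self.wk, self.bk, self.wv, self.bv,
                self.wo, self.bo, self.w1, self.b1, self.w2, self.b2,
                self.g1, self.n1, self.g2, self.n2]

    def __call__(self, x: Tensor) -> Tensor:
        n, L, d = x.shape
        h, dh = self.h, self.dh

        def split(z: Tensor) -> Tensor:  # (n, L, d) -> (n, h, L, dh)
            return z.reshape(n, L, h, dh).transpose(0, 2, 1, 3)

        q = split(linear(x, self.wq, self.bq))
        k = split(linear(x, self.wk, self.bk))
        v = split(linear(x, self.wv, self.bv))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1) @ v                   # (n, h, L, dh)
        merged = attn.transpose(0, 2, 1, 3).reshape(n, L, d)
        x = layer_norm(x + linear(merged, self.wo, self.bo), self.g1, self.n1)
        ff = linear(linear(x, self.w1, self.b1).gelu(), self.w2, self.b2)
        return layer_norm(x + ff, self.g2, self.n2)


class TransformerHazardModel:
    """Transformer encoder over the E*T grid of (cause, time) tokens."""

    def __init__(self, config: TransformerConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.model_width
        if d % 2 != 0:
            raise ValueError("model_width must be even (split covariate/index halves)")
        self.d_cov = d // 2
        L = config.n_events * config.horizon
        self.w_in, self.b_in = _linear_init(rng, config.covariate_dim, self.d_cov)
        # learned embedding of each (cause, time) cell index
        self.cell_emb = Tensor(
            (0.02 * rng.standard_normal((L, d - self.d_cov))).astype(_DTYPE),
            requires_grad=True,
        )
        self.pos = _sinusoidal_encoding(L, d)
        self.layers = [_EncoderLayer(config, rng) for _ in range(config.n_encoder_layers)]
        self.w_out, self.b_out = _linear_init(rng, d, 1)
        self.b_out.data[:] = config.output_bias_init

    def parameters(self) -> list[Tensor]:
        params = [self.w_in, self.b_in, self.cell_emb, self.w_out, self.b_out]
        for layer in self.layers:
            params.extend(layer.parameters())
        return params

    def forward_tensor(self, covariates: Tensor) -> Tensor:
        """Differentiable forward pass; returns hazards as ``(n, E, T)`` Tensor."""
        cfg = self.config
        n = covariates.shape[0]
        L = cfg.n_events * cfg.horizon
        enc = linear(covariates, self.w_in, self.b_in)     # (n, d_cov)
        enc = enc.reshape(n, 1, self.d_cov).broadcast_to((n, L, self.d_cov))
        emb = self.cell_emb.reshape(1, L, -1).broadcast_to((n, L, self.cell_emb.shape[1]))
        x = concat([enc, emb], axis=-1) + Tensor(self.pos[None])
        for layer in self.layers:
            x = layer(x)
        logits = linear(x, self.w_out, self.b_out).reshape(n, cfg.n_events, cfg.horizon)
        return logits.sigmoid()

    def __call__(self, covariates: np.ndarray) -> HazardTensor:
        return _predict_chunked(self, covariates)


class DeepHitHazardModel:
    """Per-cause feed-forward subnetworks with one shared-width hidden layer."""

    def __init__(self, config: DeepHitConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.subnets = []
        for _ in range(config.n_events):
            w1, b1 = _linear_init(rng, config.covariate_dim, config.hidden_units)
            w2, b2 = _linear_init(rng, config.hidden_units, config.horizon)
            b2.data[:] = config.output_bias_init
            self.subnets.append((w1, b1, w2, b2))

    def parameters(self) -> list[Tensor]:
        return [p for net in self.subnets for p in net]

    def forward_tensor(self, covariates: Tensor) -> Tensor:
        outs = []
        n = covariates.shape[0]
        for w1, b1, w2, b2 in self.subnets:
            h = linear(covariates, w1, b1).relu()
            outs.append(linear(h, w2, b2).reshape(n, 1, self.config.horizon))
        return concat(outs, axis=1).sigmoid()

    def __call__(self, covariates: np.ndarray) -> HazardTensor:
        return _predict_chunked(self, covariates)


def _predict_chunked(model, covariates: np.ndarray, chunk: int = 1024) -> HazardTensor:
    """Inference in chunks, tape disabled, so memory stays modest."""
    covariates = np.asarray(covariates, dtype=_DTYPE)
    with no_grad():
        parts = [
            model.forward_tensor(Tensor(covariates[i: i + chunk])).data.astype(float)
            for i in range(0, covariates.shape[0], chunk)
        ]
    out = np.concatenate(parts, axis=0)
    return HazardTensor(np.clip(out, 1e-7, 1 - 1e-7), validate=False)


def count_parameters(model) -> int:
    """Exact number of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


def build_model(kind: str, covariate_dim: int, n_events: int, horizon: int,
                seed: int = 0, **kwargs):
    """Construct a hazard model by name ('transformer' or 'deephit')."""
    if kind == "transformer":
        return TransformerHazardModel(
            TransformerConfig(covariate_dim, n_events, horizon, **kwargs), seed=seed
        )
    if kind == "deephit":
        return DeepHitHazardModel(
            DeepHitConfig(covariate_dim, n_events, horizon, **kwargs), seed=seed
        )
    raise ValueError(f"unknown model kind: {kind!r}")


def save_model(model, path: str | Path) -> None:
    """Serialise parameters (npz-free, text-safe JSON) with a config manifest."""
    path = Path(path)
    cfg = asdict(model.config)
    params = [p.data.tolist() for p in model.parameters()]
    path.write_text(json.dumps({"config": cfg, "params": params}))


def load_model(path: str | Path):
    """Reload a model saved by :func:`save_model`."""
    blob = json.loads(Path(path).read_text())
    cfg = dict(blob["config"])
    kind = cfg.pop("kind")
    model = build_model(kind, **cfg)
    for p, saved in zip(model.parameters(), blob["params"]):
        p.data = np.asarray(saved, dtype=_DTYPE).reshape(p.data.shape)
    return model
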
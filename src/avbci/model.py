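"""Spatial-temporal attention CNN for single-trial ERP classification.

Four sequential modules over a (62 channels x 100 samples) epoch:

1. temporal filtering — (1, 50) convolution, zero-padded (24, 25) on the
   time axis so the 100-sample length is preserved, 16 filters, batch
   norm, ELU;
2. temporal attention (softmax probability weights over time points,
   shared squeeze bottleneck across filters) followed by a (1, 51)
   convolution without padding, halving time to 50, 32 filters, batch
   norm, ELU, dropout 0.5;
3. spatial (channel) attention followed by a (62, 1) spatial-filter
   convolution collapsing the channel axis, 4 filters, batch norm, ELU,
   (1, 5)/5 max pooling to 10 time points, dropout 0.5;
4. flatten (40 features) and a dense layer to 2 logits
   (target / nontarget), softmax for probabilities.

Ablation variants: CNN (both attentions removed), TA-CNN (temporal
only), SA-CNN (spatial only), STA-CNN (full).
"""

from __future__ import annotations

import json
import math
from collections import OrderedDict
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import nn

VARIANTS = ("CNN", "TA-CNN", "SA-CNN", "STA-CNN")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults reproduce the full model)."""

    n_channels: int = 62
    n_times: int = 100
    n_filters: tuple[int, int, int] = (16, 32, 4)
    temporal_kernel_1: int = 50
    temporal_kernel_2: int = 51
    pad1: tuple[int, int] = (24, 25)
    pool: int = 5
    dropout_p: float = 0.5
    attn_hidden_t: int | None = None   # default ceil(n_times / 2)
    attn_hidden_s: int | None = None   # default ceil(n_channels / 2)
    n_classes: int = 2
    variant: str = "STA-CNN"
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    elu_alpha: float = 1.0
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    @property
    def hidden_t(self) -> int:
        return self.attn_hidden_t or math.ceil(self.n_times / 2)

    @property
    def hidden_s(self) -> int:
        return self.attn_hidden_s or math.ceil(self.n_channels / 2)

    @property
    def time_after_conv2(self) -> int:
        t1 = self.n_times + sum(self.pad1) - self.temporal_kernel_1 + 1
        return t1 - self.temporal_kernel_2 + 1


class STACNN:
    """The network: builds layers from a config, tracks shapes/attention.

    ``forward`` records every layer's output shape in ``last_shapes``
    and the attention probability maps in ``last_attention`` (A_t over
    time, A_s over channels, each (batch, filters, axis)).
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = cfg = config or ModelConfig()
        rng = np.random.default_rng(cfg.init_seed)
        f1, f2, f3 = cfg.n_filters
        t1 = cfg.n_times + sum(cfg.pad1) - cfg.temporal_kernel_1 + 1
        t2 = t1 - cfg.temporal_kernel_2 + 1
        if t2 % cfg.pool:
            raise ValueError("pool size must divide the module-3 time length")
        self.use_temporal = cfg.variant in ("TA-CNN", "STA-CNN")
        self.use_spatial = cfg.variant in ("SA-CNN", "STA-CNN")

        self.conv1 = nn.Conv2d("conv1", 1, f1, (1, cfg.temporal_kernel_1),
                               pad=cfg.pad1, rng=rng)
        self.bn1 = nn.BatchNorm2d("bn1", f1, cfg.bn_eps, cfg.bn_momentum)
        self.temporal_attention = (
            nn.AxisAttention("attn_t", t1, cfg.hidden_t, pool_axis=2, rng=rng)
            if self.use_temporal else nn.Identity()
        )
        self.conv2 = nn.Conv2d("conv2", f1, f2, (1, cfg.temporal_kernel_2),
                               rng=rng)
        self.bn2 = nn.BatchNorm2d("bn2", f2, cfg.bn_eps, cfg.bn_momentum)
        self.spatial_attention = (
            nn.AxisAttention("attn_s", cfg.n_channels, cfg.hidden_s,
                             pool_axis=3, rng=rng)
            if self.use_spatial else nn.Identity()
        )
        self.conv3 = nn.Conv2d("conv3", f2, f3, (cfg.n_channels, 1), rng=rng)
        self.bn3 = nn.BatchNorm2d("bn3", f3, cfg.bn_eps, cfg.bn_momentum)
        self.pool = nn.MaxPoolTime(cfg.pool)
        self.dropout2 = nn.Dropout(cfg.dropout_p)
        self.dropout3 = nn.Dropout(cfg.dropout_p)
        n_flat = f3 * (t2 // cfg.pool)
        self.dense = nn.Linear("dense", n_flat, cfg.n_classes, rng=rng)
        elu = cfg.elu_alpha
        self._elus = [nn.ELU(elu), nn.ELU(elu), nn.ELU(elu)]

        # (name, layer) in forward order; attention layers may be Identity
        self._pipeline: list[tuple[str, nn.Layer]] = [
            ("conv1", self.conv1), ("bn1", self.bn1), ("elu1", self._elus[0]),
            ("temporal_attention", self.temporal_attention),
            ("conv2", self.conv2), ("bn2", self.bn2), ("elu2", self._elus[1]),
            ("dropout2", self.dropout2),
            ("spatial_attention", self.spatial_attention),
            ("conv3", self.conv3), ("bn3", self.bn3), ("elu3", self._elus[2]),
            ("maxpool", self.pool), ("dropout3", self.dropout3),
        ]
        self.last_shapes: OrderedDict[str, tuple] = OrderedDict()
        self.last_attention: dict[str, np.ndarray | None] = {
            "A_t": None, "A_s": None,
        }

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Epochs (B, 62, 100) -> logits (B, 2)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        cfg = self.config
        if x.ndim != 3 or x.shape[1:] != (cfg.n_channels, cfg.n_times):
            raise ValueError(
                f"expected (batch, {cfg.n_channels}, {cfg.n_times}) input, "
                f"got {x.shape}"
            )
        if train and rng is None:
            rng = np.random.default_rng(0)
        shapes = OrderedDict()
        shapes["input"] = x.shape[1:]
        h = x[:, None, :, :]              # reshape -> (B, 1, 62, 100)
        shapes["reshape"] = h.shape[1:]
        for name, layer in self._pipeline:
            h = layer.forward(h, train=train, rng=rng)
            shapes[name] = h.shape[1:]
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        shapes["flatten"] = h.shape[1:]
        logits = self.dense.forward(h, train=train, rng=rng)
        shapes["dense"] = logits.shape[1:]
        self.last_shapes = shapes
        self.last_attention = {
            "A_t": getattr(self.temporal_attention, "weights", None),
            "A_s": getattr(self.spatial_attention, "weights", None),
        }
        return logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.dense.backward(dlogits)
        g = g.reshape(self._flat_shape)
        for _, layer in reversed(self._pipeline):
            g = layer.backward(g)
        return g[:, 0, :, :]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities (B, 2); column 1 = target."""
        return nn.softmax(self.forward(x, train=False), axis=-1)

    # -- parameters / serialization -----------------------------------------

    def parameters(self) -> list[nn.Param]:
        seen: list[nn.Param] = []
        for _, layer in self._pipeline:
            seen.extend(layer.params())
        seen.extend(self.dense.params())
        return seen

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for name, bn in (("bn1", self.bn1), ("bn2", self.bn2),
                         ("bn3", self.bn3)):
            state[f"{name}.running_mean"] = bn.running_mean.copy()
            state[f"{name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value = state[p.name].astype(np.float32).copy()
        for name, bn in (("bn1", self.bn1), ("bn2", self.bn2),
                         ("bn3", self.bn3)):
            bn.running_mean = state[f"{name}.running_mean"].copy()
            bn.running_var = state[f"{name}.running_var"].copy()

    def save(self, path) -> None:
        """Single-file checkpoint: weights + config JSON."""
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "STACNN":
        with np.load(path) as data:
            cfg_json = bytes(data["__config__"]).decode()
            cfg_dict = json.loads(cfg_json)
            for key in ("n_filters", "pad1"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict))
            model.load_state_dict(
                {k: v for k, v in data.items() if k != "__config__"}
            )
        return model


def temporal_attention(T: np.ndarray, model: STACNN | None = None):
    """Apply a model's temporal-attention layer to feature maps.

    Returns ``(T_a, A_t)`` where ``A_t`` rows are probability vectors
    over time.  A fresh default model supplies the layer if none given.
    """
    model = model or STACNN()
    layer = model.temporal_attention
    if isinstance(layer, nn.Identity):
        raise ValueError("this variant has no temporal attention")
    out = layer.forward(np.asarray(T, dtype=np.float32))
    return out, layer.weights


def spatial_attention(S: np.ndarray, model: STACNN | None = None):
    """Apply a model's spatial-attention layer; returns ``(S_a, A_s)``."""
    model = model or STACNN()
    layer = model.spatial_attention
    if isinstance(layer, nn.Identity):
        raise ValueError("this variant has no spatial attention")
    out = layer.forward(np.asarray(S, dtype=np.float32))
    return out, layer.weights


def make_variant(name: str, config: ModelConfig | None = None) -> STACNN:
    """Build an ablation variant sharing the config (fresh weights)."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")
    cfg = replace(config or ModelConfig(), variant=name)
    return STACNN(cfg)
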
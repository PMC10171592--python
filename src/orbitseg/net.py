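"""Five-block encoder-decoder segmentation networks.

Two closely related architectures are provided:

``build_proposed``
    A VGG-16-family encoder (blocks of Conv-BN-ReLU, conv counts
    [2, 2, 3, 3, 3], widths [64, 128, 256, 512, 512]) whose decoder restores
    resolution by max-unpooling with the encoder's pooling indices *and*
    fuses, by channel concatenation, the counterpart encoder block's
    pre-pool feature map at every one of the five scales
    {1, 1/2, 1/4, 1/8, 1/16} of the input.  The bottleneck after the fifth
    pooling sits at 1/32.

``build_segnet``
    The same encoder and unpooling decoder but with no skip-feature
    concatenation — only the pooling indices cross over.

With the default configuration the two networks hold ~34.9M and ~29.4M
trainable parameters (34 vs 29 truncated millions); the gap is exactly the
widened first convolution of each decoder block that absorbs the
concatenated skip channels.

The module also exposes ``pool_with_indices`` / ``unpool`` as standalone
array operations (absolute flat indices) so the unpooling semantics can be
tested independently of any network.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .nn.layers import BatchNorm2d, Conv2d, MaxPool2d, MaxUnpool2d, Param, ReLU

__all__ = [
    "NetConfig",
    "pool_with_indices",
    "unpool",
    "EncoderDecoderNet",
    "build_proposed",
    "build_segnet",
    "count_parameters",
    "Checkpoint",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters shared by both networks."""

    in_channels: int = 1
    num_classes: int = 1
    conv_counts: tuple[int, ...] = (2, 2, 3, 3, 3)
    widths: tuple[int, ...] = (64, 128, 256, 512, 512)
    kernel: int = 3
    pool: int = 2
    skip_fusion: str = "concatenate"

    def __post_init__(self) -> None:
        if len(self.conv_counts) != len(self.widths):
            raise ValueError("conv_counts and widths must have equal length")
        if len(self.widths) != 5:
            raise ValueError("exactly five encoder/decoder blocks are required")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be strictly positive")
        if self.skip_fusion != "concatenate":
            raise ValueError(f"unsupported skip_fusion: {self.skip_fusion}")

    @property
    def depth(self) -> int:
        return len(self.widths)

    @property
    def divisor(self) -> int:
        return self.pool ** self.depth

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "num_classes": self.num_classes,
            "conv_counts": list(self.conv_counts),
            "widths": list(self.widths),
            "kernel": self.kernel,
            "pool": self.pool,
            "skip_fusion": self.skip_fusion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        return cls(
            in_channels=d["in_channels"],
            num_classes=d["num_classes"],
            conv_counts=tuple(d["conv_counts"]),
            widths=tuple(d["widths"]),
            kernel=d["kernel"],
            pool=d["pool"],
            skip_fusion=d["skip_fusion"],
        )


# ---------------------------------------------------------------------------
# Standalone pooling operations on 2D arrays (absolute flat indices)
# ---------------------------------------------------------------------------

def pool_with_indices(x: np.ndarray, pool: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pooling of a 2D array, recording argmax locations.

    Returns ``(pooled, indices)`` where ``indices`` holds, per output
    element, the flat row-major index of the window maximum in the *input*
    array.  Ties break to the first position in row-major scan order.
    """
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError("pool_with_indices expects a 2D array")
    h, w = x.shape
    if h % pool or w % pool:
        raise ValueError(f"spatial size ({h}, {w}) not divisible by pool {pool}")
    hp, wp = h // pool, w // pool
    xw = x.reshape(hp, pool, wp, pool).transpose(0, 2, 1, 3).reshape(hp, wp, pool * pool)
    local = xw.argmax(axis=2)
    pooled = np.take_along_axis(xw, local[..., None], axis=2)[..., 0]
    rows = (np.arange(hp)[:, None] * pool) + local // pool
    cols = (np.arange(wp)[None, :] * pool) + local % pool
    return pooled, rows * w + cols


def unpool(pooled: np.ndarray, indices: np.ndarray,
           out_size: tuple[int, int]) -> np.ndarray:
    """Scatter pooled values back to their recorded locations, zero-filling.

    The sum of the output equals the sum of ``pooled``.
    """
    pooled = np.asarray(pooled)
    indices = np.asarray(indices)
    if indices.shape != pooled.shape:
        raise ValueError("indices shape must match pooled shape")
    h, w = out_size
    flat = indices.ravel()
    if flat.size and (flat.min() < 0 or flat.max() >= h * w):
        raise ValueError("index outside the requested output size")
    out = np.zeros(h * w, dtype=pooled.dtype)
    out[flat] = pooled.ravel()
    return out.reshape(h, w)


# ---------------------------------------------------------------------------
# Network building blocks
# ---------------------------------------------------------------------------

class _ConvUnit:
    """Conv -> BN -> ReLU, or a bare conv for the final logits layer."""

    def __init__(self, name: str, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, bn_relu: bool = True):
        self.conv = Conv2d(name, in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm2d(name + ".bn", out_ch) if bn_relu else None
        self.relu = ReLU() if bn_relu else None

    def params(self) -> list[Param]:
        out = self.conv.params()
        if self.bn is not None:
            out += self.bn.params()
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        x = self.conv.forward(x, training)
        if self.bn is not None:
            x = self.bn.forward(x, training)
            x = self.relu.forward(x, training)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        if self.bn is not None:
            d = self.relu.backward(d)
            d = self.bn.backward(d)
        return self.conv.backward(d)


class _Stack:
    def __init__(self, units: list[_ConvUnit]):
        self.units = units

    def params(self) -> list[Param]:
        return [p for u in self.units for p in u.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for u in self.units:
            x = u.forward(x, training)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        for u in reversed(self.units):
            d = u.backward(d)
        return d


class EncoderDecoderNet:
    """Shared implementation of the proposed network and SegNet.

    ``use_skips`` toggles concatenation of encoder pre-pool features in the
    decoder; pooling indices always cross over.
    """

    def __init__(self, config: NetConfig, use_skips: bool, seed: int = 0):
        self.config = config
        self.use_skips = use_skips
        rng = np.random.default_rng(seed)
        widths = config.widths
        counts = config.conv_counts
        depth = config.depth

        self.enc_stacks: list[_Stack] = []
        self.enc_pools: list[MaxPool2d] = []
        in_ch = config.in_channels
        for b in range(depth):
            units = []
            for c in range(counts[b]):
                units.append(_ConvUnit(f"enc{b + 1}.conv{c + 1}", in_ch,
                                       widths[b], config.kernel, rng))
                in_ch = widths[b]
            self.enc_stacks.append(_Stack(units))
            self.enc_pools.append(MaxPool2d(config.pool))

        # Decoder blocks, deepest (level 5) first.  Block at level b restores
        # the pre-pool resolution of encoder block b; its last conv reduces to
        # the width of the next shallower level (or to num_classes at level 1,
        # as a bare conv producing logits).
        self.dec_unpools: list[MaxUnpool2d] = []
        self.dec_stacks: list[_Stack] = []
        for b in range(depth - 1, -1, -1):
            self.dec_unpools.append(MaxUnpool2d(config.pool))
            units = []
            in_ch = widths[b] * (2 if use_skips else 1)
            for c in range(counts[b]):
                last = c == counts[b] - 1
                if last and b > 0:
                    out_ch = widths[b - 1]
                elif last and b == 0:
                    out_ch = config.num_classes
                else:
                    out_ch = widths[b]
                units.append(_ConvUnit(f"dec{b + 1}.conv{c + 1}", in_ch, out_ch,
                                       config.kernel, rng,
                                       bn_relu=not (last and b == 0)))
                in_ch = out_ch
            self.dec_stacks.append(_Stack(units))

        self._skip_channels = list(widths)
        self._fwd_cache: dict | None = None

    # -- parameters --------------------------------------------------------

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for s in self.enc_stacks:
            out += s.params()
        for s in self.dec_stacks:
            out += s.params()
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for name, bn in self._batchnorms():
            state[name + ".running_mean"] = bn.running_mean.copy()
            state[name + ".running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value = np.array(state[p.name], dtype=np.float32)
            p.grad = np.zeros_like(p.value)
        for name, bn in self._batchnorms():
            bn.running_mean = np.array(state[name + ".running_mean"], dtype=np.float32)
            bn.running_var = np.array(state[name + ".running_var"], dtype=np.float32)

    def _batchnorms(self):
        for stack in self.enc_stacks + self.dec_stacks:
            for u in stack.units:
                if u.bn is not None:
                    yield u.bn.gamma.name.rsplit(".gamma", 1)[0], u.bn

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:  # (N, H, W)
            x = x[..., None]
        if x.ndim != 4:
            raise ValueError("input must be (H,W), (N,H,W) or (N,H,W,C)")
        n, h, w, c = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} channels, got {c}")
        if h % self.config.divisor or w % self.config.divisor:
            raise ValueError(
                f"spatial size ({h}, {w}) must be divisible by {self.config.divisor}")
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Return logits of the same spatial size as the input."""
        x = self._check_input(x)
        skips: list[np.ndarray] = []
        h = x
        for stack, pool in zip(self.enc_stacks, self.enc_pools):
            h = stack.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        # decoder, deepest level first
        for i, (unpool_layer, stack) in enumerate(zip(self.dec_unpools, self.dec_stacks)):
            level = self.config.depth - 1 - i
            h = unpool_layer.forward(h, self.enc_pools[level].indices, training)
            if self.use_skips:
                h = np.concatenate([h, skips[level]], axis=3)
            h = stack.forward(h, training)
        if training:
            self._fwd_cache = {"n_skip": [s.shape[3] for s in skips]}
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from a logits gradient."""
        if self._fwd_cache is None:
            raise RuntimeError("backward requires a prior forward(training=True)")
        depth = self.config.depth
        d_skip: dict[int, np.ndarray] = {}
        d = dlogits.astype(np.float32)
        for i in range(depth - 1, -1, -1):  # decoder blocks, shallow first
            level = depth - 1 - i
            d = self.dec_stacks[i].backward(d)
            if self.use_skips:
                c_unp = self._skip_channels[level]
                d_skip[level] = d[..., c_unp:]
                d = np.ascontiguousarray(d[..., :c_unp])
            d = self.dec_unpools[i].backward(d)
        for level in range(depth - 1, -1, -1):
            d = self.enc_pools[level].backward(d)
            if self.use_skips:
                d = d + d_skip[level]
            d = self.enc_stacks[level].backward(d)
        self._fwd_cache = None

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities at inference (BN in running-stats mode)."""
        z = self.forward(x, training=False)
        return 1.0 / (1.0 + np.exp(-z))


def build_proposed(config: NetConfig = NetConfig(), seed: int = 0) -> EncoderDecoderNet:
    """Unpooling decoder *plus* five-scale skip-feature concatenation."""
    return EncoderDecoderNet(config, use_skips=True, seed=seed)


def build_segnet(config: NetConfig = NetConfig(), seed: int = 0) -> EncoderDecoderNet:
    """SegNet baseline: unpooling decoder, pooling indices only."""
    return EncoderDecoderNet(config, use_skips=False, seed=seed)


def count_parameters(net: EncoderDecoderNet) -> int:
    """Total trainable scalars (conv weights + biases + BN affine params)."""
    return sum(p.size for p in net.parameters())


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """Serializable snapshot: weights + architecture + training metadata."""

    state: dict[str, np.ndarray]
    config: NetConfig
    use_skips: bool
    meta: dict = field(default_factory=dict)

    def build_net(self) -> EncoderDecoderNet:
        net = EncoderDecoderNet(self.config, use_skips=self.use_skips)
        net.load_state_dict(self.state)
        return net


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    header = json.dumps({
        "config": ckpt.config.to_dict(),
        "use_skips": ckpt.use_skips,
        "meta": ckpt.meta,
    })
    arrays = {k.replace(".", "__"): v for k, v in ckpt.state.items()}
    with open(path, "wb") as f:
        np.savez(f, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        state = {k.replace("__", "."): data[k] for k in data.files
                 if k != "__header__"}
    return Checkpoint(state=state,
                      config=NetConfig.from_dict(header["config"]),
                      use_skips=header["use_skips"],
                      meta=header.get("meta", {}))
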
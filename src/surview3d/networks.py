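"""Single- and dual-view 2D-to-3D encoder-decoder architectures.

Three subnetworks compose each model:

* **representation** — a 2D convolutional encoder that maps a topogram to a
  latent tensor. At full scale the data flow is
  ``1024x1024x1 -> 1024x1024x32 -> 512x512x64 -> 256x256x128 -> 128x128x256
  -> 64x64x512 -> 32x32x1024``, each arrow a conv block with batch
  normalization and ReLU (the first block preserves spatial size, the rest
  halve it and double the channels).
* **transformation** — a memory reshape of the latent tensor onto the 3D
  generation entry grid (``4x4x4`` at full scale, channels = residual
  dimension) followed by a single 1x1x1 convolution that mixes channels. The
  dual-view variant reshapes each view's latent and concatenates them along
  channels before the convolution, doubling its input channels.
* **generation** — a 3D transposed-convolutional decoder; each block doubles
  every spatial side and halves the channels
  (``4x4x4x1024 -> 8x8x8x512 -> ... -> 64x64x64x64``), and a final
  transposed-conv block with a sigmoid produces the ``128x128x128x1`` volume
  in [0, 1].

``NetworkScaleConfig.channel_divisor`` scales every channel count down
uniformly so the same graphs run at desk scale (e.g. divisor 8:
``128x128`` topograms to ``32x32x32`` volumes) on a single CPU.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

_FULL_LATENT_CHANNELS = 1024


@dataclass
class NetworkScaleConfig:
    """Uniform scale configuration for both architectures.

    ``gen_entry_size`` is the spatial side of the generation entry grid
    (4 at full scale); it must divide the latent element count and reach
    ``output_size`` by repeated doubling.
    """

    input_size: int = 128
    output_size: int = 32
    channel_divisor: int = 8
    depth: int = 6
    gen_entry_size: int = 2
    seed: int = 0

    @classmethod
    def full_scale(cls) -> "NetworkScaleConfig":
        return cls(input_size=1024, output_size=128, channel_divisor=1, depth=6, gen_entry_size=4)

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "NetworkScaleConfig":
        return cls(input_size=128, output_size=32, channel_divisor=8, depth=6, gen_entry_size=2, seed=seed)

    # -- derived quantities -------------------------------------------------
    @property
    def latent_size(self) -> int:
        return self.input_size // 2 ** (self.depth - 1)

    @property
    def latent_channels(self) -> int:
        return _FULL_LATENT_CHANNELS // self.channel_divisor

    @property
    def rep_channels(self) -> list[int]:
        return [
            (_FULL_LATENT_CHANNELS >> (self.depth - 1 - i)) // self.channel_divisor
            for i in range(self.depth)
        ]

    @property
    def latent_elements(self) -> int:
        return self.latent_size**2 * self.latent_channels

    def reshaped_channels(self, dual: bool = False) -> int:
        n = self.latent_elements * (2 if dual else 1)
        return n // self.gen_entry_size**3

    @property
    def n_gen_blocks(self) -> int:
        return int(math.log2(self.output_size // self.gen_entry_size))

    @property
    def gen_channels(self) -> list[int]:
        c0 = self.latent_channels
        outs = [c0 >> (i + 1) for i in range(self.n_gen_blocks - 1)]
        return outs + [1]

    def validate(self) -> list[str]:
        """Return a list of constraint violations (empty when valid)."""
        errors = []
        for name in ("input_size", "output_size", "channel_divisor", "depth", "gen_entry_size"):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be positive")
        if errors:
            return errors
        if self.input_size % 2 ** (self.depth - 1) != 0 or self.latent_size < 4:
            errors.append(
                f"input_size / 2^(depth-1) must be an integer >= 4, got {self.input_size / 2 ** (self.depth - 1)}"
            )
        if min(self.rep_channels) < 4:
            errors.append(
                f"channel_divisor {self.channel_divisor} leaves < 4 channels in the first block"
            )
        ratio = self.output_size / self.gen_entry_size
        if ratio < 2 or 2 ** int(math.log2(ratio)) != int(ratio):
            errors.append("output_size must be gen_entry_size times a power of 2 (>= 2)")
        if self.latent_elements % self.gen_entry_size**3 != 0:
            errors.append("latent element count is not divisible by the generation entry grid")
        if not errors and min(self.gen_channels[:-1] or [4]) < 1:
            errors.append("generation channel schedule collapses below 1 channel")
        return errors

    def require_valid(self) -> "NetworkScaleConfig":
        errors = self.validate()
        if errors:
            raise ValueError("invalid NetworkScaleConfig: " + "; ".join(errors))
        return self

    # -- audit helpers ------------------------------------------------------
    def shape_trace(self, dual: bool = False) -> list[tuple[str, tuple[int, ...]]]:
        """Per-stage output shapes (spatial..., channels), without allocating
        any weights — used to audit the graph against the stated data flows."""
        self.require_valid()
        trace: list[tuple[str, tuple[int, ...]]] = [("input", (self.input_size, self.input_size, 1))]
        side = self.input_size
        for i, ch in enumerate(self.rep_channels):
            if i > 0:
                side //= 2
            trace.append((f"representation_block{i + 1}", (side, side, ch)))
        e = self.gen_entry_size
        trace.append(("transform_reshape", (e, e, e, self.reshaped_channels(dual))))
        trace.append(("transform_conv1x1x1", (e, e, e, self.latent_channels)))
        for i, ch in enumerate(self.gen_channels):
            e *= 2
            trace.append((f"generation_block{i + 1}", (e, e, e, ch)))
        return trace

    def parameter_count(self, dual: bool = False) -> int:
        """Analytic parameter count of the full graph (conv + batchnorm)."""
        self.require_valid()
        n = 0
        ch = self.rep_channels
        rep = ch[0] * 1 * 9 + ch[0] + 2 * ch[0]  # first block: 3x3 conv + BN
        for cin, cout in zip(ch[:-1], ch[1:]):
            rep += cin * cout * 16 + cout + 2 * cout  # 4x4 stride-2 conv + BN
        n += rep * (2 if dual else 1)
        n += self.reshaped_channels(dual) * self.latent_channels + self.latent_channels
        cin = self.latent_channels
        for cout in self.gen_channels:
            n += cin * cout * 64 + cout  # 4x4x4 transposed conv
            cin = cout
        return n


@dataclass
class LatentTensor:
    """Output of a representation subnetwork: (latent_size, latent_size, C)."""

    grid: np.ndarray

    @property
    def shape(self):
        return self.grid.shape


@dataclass
class ReshapedLatent:
    """Generation entry tensor: (entry, entry, entry, C), channels last."""

    grid: np.ndarray

    @property
    def shape(self):
        return self.grid.shape


# ---------------------------------------------------------------------------
# Subnetworks
# ---------------------------------------------------------------------------

def _build_representation(config: NetworkScaleConfig, rng) -> nn.Sequential:
    layers: list[nn.Layer] = []
    cin = 1
    for i, cout in enumerate(config.rep_channels):
        if i == 0:
            layers.append(nn.Conv(rng, cin, cout, (3, 3), stride=1, pad=1))
        else:
            layers.append(nn.Conv(rng, cin, cout, (4, 4), stride=2, pad=1))
        layers.append(nn.BatchNorm(cout))
        layers.append(nn.ReLU())
        cin = cout
    return nn.Sequential(layers)


def _build_generation(config: NetworkScaleConfig, rng) -> nn.Sequential:
    layers: list[nn.Layer] = []
    cin = config.latent_channels
    chans = config.gen_channels
    for i, cout in enumerate(chans):
        layers.append(nn.ConvTranspose(rng, cin, cout, (4, 4, 4), stride=2, pad=1))
        layers.append(nn.Sigmoid() if i == len(chans) - 1 else nn.ReLU())
        cin = cout
    return nn.Sequential(layers)


class _Reshape:
    """Latent (N, C, s, s) -> entry grid (N, C', e, e, e), element preserving.

    The latent is viewed channels-last and flattened row-major onto the entry
    grid; the residual dimension becomes the channel axis.
    """

    def __init__(self, config: NetworkScaleConfig):
        self.s = config.latent_size
        self.c = config.latent_channels
        self.e = config.gen_entry_size
        self.cpre = config.reshaped_channels(dual=False)

    def forward(self, latent: np.ndarray) -> np.ndarray:
        n = latent.shape[0]
        e = self.e
        grid = latent.transpose(0, 2, 3, 1).reshape(n, e, e, e, self.cpre)
        return np.ascontiguousarray(grid.transpose(0, 4, 1, 2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n = g.shape[0]
        flat = g.transpose(0, 2, 3, 4, 1).reshape(n, self.s, self.s, self.c)
        return np.ascontiguousarray(flat.transpose(0, 3, 1, 2))


class SingleViewNetwork:
    """F1(X1) = Y_pred: one representation branch, transform, generation."""

    dual = False

    def __init__(self, config: NetworkScaleConfig):
        config.require_valid()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.representation = _build_representation(config, rng)
        self.reshape = _Reshape(config)
        self.transform_conv = nn.Conv(
            rng, config.reshaped_channels(dual=False), config.latent_channels, (1, 1, 1)
        )
        self.generation = _build_generation(config, rng)

    # -- plumbing -----------------------------------------------------------
    def modules(self):
        return [self.representation, self.transform_conv, self.generation]

    def layers(self) -> list[nn.Layer]:
        out = []
        for m in self.modules():
            out.extend(nn.iter_layers(m))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        latent = self.representation.forward(x, training)
        z = self.transform_conv.forward(self.reshape.forward(latent), training)
        return self.generation.forward(z, training)

    def backward(self, gy: np.ndarray) -> None:
        gz = self.generation.backward(gy)
        glatent = self.reshape.backward(self.transform_conv.backward(gz))
        self.representation.backward(glatent)

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                state[f"layer{i:03d}.{k}"] = v
            if isinstance(layer, nn.BatchNorm):
                state[f"layer{i:03d}.running_mean"] = layer.running_mean
                state[f"layer{i:03d}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i:03d}.{k}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = state[f"layer{i:03d}.running_mean"]
                layer.running_var[...] = state[f"layer{i:03d}.running_var"]

    def save(self, path) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.config)), __dual__=self.dual, **self.state_dict())


class DualViewNetwork(SingleViewNetwork):
    """F2(X1, X2) = Y_pred: two independent-weight representation branches
    whose reshaped latents are concatenated along channels before the 1x1x1
    convolution."""

    dual = True

    def __init__(self, config: NetworkScaleConfig):
        config.require_valid()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.representation = _build_representation(config, rng)
        self.representation2 = _build_representation(config, rng)
        self.reshape = _Reshape(config)
        self.transform_conv = nn.Conv(
            rng, config.reshaped_channels(dual=True), config.latent_channels, (1, 1, 1)
        )
        self.generation = _build_generation(config, rng)

    def modules(self):
        return [self.representation, self.representation2, self.transform_conv, self.generation]

    def forward(self, x1: np.ndarray, x2: np.ndarray | None = None, training: bool = False) -> np.ndarray:
        if x2 is None:
            raise ValueError("dual-view network requires two topograms")
        if x1.shape != x2.shape:
            raise ValueError(f"mismatched topogram shapes {x1.shape} vs {x2.shape}")
        l1 = self.representation.forward(x1, training)
        l2 = self.representation2.forward(x2, training)
        z_pre = np.concatenate([self.reshape.forward(l1), self.reshape.forward(l2)], axis=1)
        z = self.transform_conv.forward(z_pre, training)
        return self.generation.forward(z, training)

    def backward(self, gy: np.ndarray) -> None:
        gz = self.generation.backward(gy)
        g_pre = self.transform_conv.backward(gz)
        c = g_pre.shape[1] // 2
        self.representation.backward(self.reshape.backward(g_pre[:, :c]))
        self.representation2.backward(self.reshape.backward(g_pre[:, c:]))


def build_network(arch: str, config: NetworkScaleConfig):
    if arch == "single":
        return SingleViewNetwork(config)
    if arch == "dual":
        return DualViewNetwork(config)
    raise ValueError(f"arch must be 'single' or 'dual', got {arch!r}")


def load_network(path):
    """Load a checkpoint saved by ``SingleViewNetwork.save``."""
    with np.load(path, allow_pickle=False) as data:
        config = NetworkScaleConfig(**json.loads(str(data["__config__"])))
        dual = bool(data["__dual__"])
        net = DualViewNetwork(config) if dual else SingleViewNetwork(config)
        net.load_state_dict({k: data[k] for k in data.files if not k.startswith("__")})
    return net


# ---------------------------------------------------------------------------
# Functional API mirroring the subnetwork contracts
# ---------------------------------------------------------------------------

def _as_batch(topogram: np.ndarray) -> np.ndarray:
    t = np.asarray(topogram, dtype=np.float32)
    if t.ndim == 2:
        t = t[None, None]
    elif t.ndim == 3:
        t = t[None]
    return t


def representation_forward(topogram: np.ndarray, network: SingleViewNetwork) -> LatentTensor:
    """Run the (first) representation branch; returns the latent as a
    channels-last ``(s, s, C)`` grid."""
    latent = network.representation.forward(_as_batch(topogram), training=False)
    return LatentTensor(np.ascontiguousarray(latent[0].transpose(1, 2, 0)))


def transform_single(latent: LatentTensor, network: SingleViewNetwork) -> ReshapedLatent:
    lat = np.ascontiguousarray(latent.grid.transpose(2, 0, 1))[None]
    z = network.transform_conv.forward(network.reshape.forward(lat), training=False)
    return ReshapedLatent(np.ascontiguousarray(z[0].transpose(1, 2, 3, 0)))


def transform_dual(latent1: LatentTensor, latent2: LatentTensor, network: DualViewNetwork) -> ReshapedLatent:
    if latent1.shape != latent2.shape:
        raise ValueError("latents must share shape")
    lats = []
    for lt in (latent1, latent2):
        lat = np.ascontiguousarray(lt.grid.transpose(2, 0, 1))[None]
        lats.append(network.reshape.forward(lat))
    z = network.transform_conv.forward(np.concatenate(lats, axis=1), training=False)
    return ReshapedLatent(np.ascontiguousarray(z[0].transpose(1, 2, 3, 0)))


def generation_forward(z: ReshapedLatent, network: SingleViewNetwork) -> np.ndarray:
    zz = np.ascontiguousarray(z.grid.transpose(3, 0, 1, 2))[None]
    return network.generation.forward(zz, training=False)[0, 0]


def single_view_forward(topogram: np.ndarray, network: SingleViewNetwork) -> np.ndarray:
    """Full composition; returns the predicted normalized volume (D, D, D)."""
    return network.forward(_as_batch(topogram), training=False)[0, 0]


def dual_view_forward(x1: np.ndarray, x2: np.ndarray, network: DualViewNetwork) -> np.ndarray:
    return network.forward(_as_batch(x1), _as_batch(x2), training=False)[0, 0]
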
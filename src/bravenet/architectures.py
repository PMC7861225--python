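"""The four 3-D encoder-decoder segmentation networks.

Variants:

* ``unet`` — 4-level 3-D U-Net; each level applies conv -> ReLU -> BN
  twice (dropout after the first BN), 2x2x2 max-pooling between encoder
  levels, parameter-free nearest-neighbour up-sampling with skip
  concatenation in the decoder, two 1x1x1 "fully connected" bottom
  layers, and a final 1x1x1 convolution with sigmoid.  An initial
  batch-normalization layer standardizes the raw input, replacing any
  intensity pre-processing.
* ``context`` — adds a parameter-disjoint duplicate encoder fed by a
  2x-larger patch that is first 2x2x2 average-pooled to primary-patch
  dimensions (half resolution); bottoms are concatenated before the
  1x1x1 layers and both encoders' feature maps feed the decoder skips.
* ``ds`` — adds deep supervision: each intermediate decoder level is
  up-sampled to the output size and passed through its own 1x1x1
  convolution + sigmoid head.
* ``bravenet`` — context + deep supervision combined.

Channel width doubles per level from ``base_width``; with the default
base width of 32 the trainable-parameter totals land at ~6 million for
the baseline and ~10 million for the context-path variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import BatchNormState, Tensor

__all__ = [
    "ArchitectureConfig",
    "Network",
    "build_network",
    "count_trainable_parameters",
    "downsample_context",
    "save_network",
    "load_network",
]

VARIANTS = ("unet", "context", "ds", "bravenet")


@dataclass
class ArchitectureConfig:
    """Declarative description of one network variant."""

    variant: str = "bravenet"
    levels: int = 4
    base_width: int = 32
    kernel: tuple[int, int, int] = (3, 3, 3)
    pool: tuple[int, int, int] = (2, 2, 2)
    dropout_rate: float = 0.1
    primary_patch: tuple[int, int, int] = (64, 64, 8)
    context_patch: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        self.primary_patch = tuple(int(s) for s in self.primary_patch)
        if self.context_patch is None:
            self.context_patch = tuple(2 * s for s in self.primary_patch)
        else:
            self.context_patch = tuple(int(s) for s in self.context_patch)
        if self.context_patch != tuple(2 * s for s in self.primary_patch):
            raise ValueError("context_patch must be 2x primary_patch per axis")
        div = 2 ** (self.levels - 1)
        if any(s % div for s in self.primary_patch):
            raise ValueError(
                f"primary_patch {self.primary_patch} must be divisible by "
                f"2^(levels-1) = {div} on every axis"
            )

    @property
    def has_context(self) -> bool:
        return self.variant in ("context", "bravenet")

    @property
    def has_deep_supervision(self) -> bool:
        return self.variant in ("ds", "bravenet")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "levels": self.levels,
            "base_width": self.base_width,
            "kernel": list(self.kernel),
            "pool": list(self.pool),
            "dropout_rate": self.dropout_rate,
            "primary_patch": list(self.primary_patch),
            "context_patch": list(self.context_patch),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(
            variant=d["variant"],
            levels=int(d.get("levels", 4)),
            base_width=int(d.get("base_width", 32)),
            kernel=tuple(d.get("kernel", (3, 3, 3))),
            pool=tuple(d.get("pool", (2, 2, 2))),
            dropout_rate=float(d.get("dropout_rate", 0.1)),
            primary_patch=tuple(d.get("primary_patch", (64, 64, 8))),
            context_patch=tuple(d["context_patch"])
            if d.get("context_patch") else None,
        )


def _glorot_uniform(rng, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Network:
    """A realized network: parameter tensors plus the forward graph."""

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0,
                 dtype=np.float32):
        self.cfg = cfg
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        self.params: dict[str, Tensor] = {}
        self.bn_states: dict[str, BatchNormState] = {}
        self._rng = np.random.default_rng(self.seed)
        self._dropout_rng = np.random.default_rng(self.seed + 1)
        self._build()

    # -- parameter construction ----------------------------------------

    def _add_conv(self, name, c_in, c_out, kernel):
        k = int(np.prod(kernel))
        w = _glorot_uniform(self._rng, (c_out, c_in) + tuple(kernel),
                            c_in * k, c_out * k, self.dtype)
        self.params[f"{name}_w"] = Tensor(w, requires_grad=True)
        self.params[f"{name}_b"] = Tensor(
            np.zeros(c_out, dtype=self.dtype), requires_grad=True
        )

    def _add_bn(self, name, channels):
        self.params[f"{name}_gamma"] = Tensor(
            np.ones(channels, dtype=self.dtype), requires_grad=True
        )
        self.params[f"{name}_beta"] = Tensor(
            np.zeros(channels, dtype=self.dtype), requires_grad=True
        )
        self.bn_states[name] = BatchNormState(channels, dtype=self.dtype)

    def _add_level(self, prefix, c_in, width):
        self._add_conv(f"{prefix}_conv1", c_in, width, self.cfg.kernel)
        self._add_bn(f"{prefix}_bn1", width)
        self._add_conv(f"{prefix}_conv2", width, width, self.cfg.kernel)
        self._add_bn(f"{prefix}_bn2", width)

    def _add_encoder(self, tag):
        cfg = self.cfg
        self._add_bn(f"{tag}_input_bn", 1)
        c_in = 1
        for lvl in range(cfg.levels - 1):
            width = cfg.base_width * 2 ** lvl
            self._add_level(f"{tag}_enc{lvl}", c_in, width)
            c_in = width
        bottom = cfg.base_width * 2 ** (cfg.levels - 1)
        self._add_level(f"{tag}_bottom", c_in, bottom)

    def _build(self):
        cfg = self.cfg
        bottom = cfg.base_width * 2 ** (cfg.levels - 1)
        self._add_encoder("p")
        if cfg.has_context:
            self._add_encoder("c")
        fc_in = bottom * (2 if cfg.has_context else 1)
        self._add_conv("fc1", fc_in, bottom, (1, 1, 1))
        self._add_conv("fc2", bottom, bottom, (1, 1, 1))
        n_paths = 2 if cfg.has_context else 1
        up_in = bottom
        for lvl in range(cfg.levels - 2, -1, -1):
            width = cfg.base_width * 2 ** lvl
            c_in = up_in + n_paths * width
            self._add_level(f"dec{lvl}", c_in, width)
            up_in = width
            if cfg.has_deep_supervision and lvl > 0:
                self._add_conv(f"head{lvl}", width, 1, (1, 1, 1))
        self._add_conv("final", cfg.base_width, 1, (1, 1, 1))

    # -- forward graph --------------------------------------------------

    def _bn(self, name, x, train):
        return ad.batch_norm(
            x, self.params[f"{name}_gamma"], self.params[f"{name}_beta"],
            self.bn_states[name], train,
        )

    def _conv(self, name, x):
        return ad.conv3d(x, self.params[f"{name}_w"], self.params[f"{name}_b"])

    def _level(self, prefix, x, train):
        x = self._bn(f"{prefix}_bn1", ad.relu(self._conv(f"{prefix}_conv1", x)),
                     train)
        x = ad.dropout(x, self.cfg.dropout_rate, self._dropout_rng, train)
        x = self._bn(f"{prefix}_bn2", ad.relu(self._conv(f"{prefix}_conv2", x)),
                     train)
        return x

    def _encode(self, tag, x, train):
        x = self._bn(f"{tag}_input_bn", x, train)
        skips = []
        for lvl in range(self.cfg.levels - 1):
            x = self._level(f"{tag}_enc{lvl}", x, train)
            skips.append(x)
            x = ad.max_pool2(x)
        x = self._level(f"{tag}_bottom", x, train)
        return x, skips

    def forward(self, primary: Tensor, context: Tensor | None = None,
                train: bool = False) -> list[Tensor]:
        """Run the network; returns prediction heads, final head last.

        Inputs are (N, 1, X, Y, Z) tensors of raw intensities.
        """
        cfg = self.cfg
        p_bottom, p_skips = self._encode("p", primary, train)
        c_skips = None
        if cfg.has_context:
            if context is None:
                raise ValueError(f"variant {cfg.variant!r} needs a context patch")
            c_in = ad.avg_pool2(context)
            c_bottom, c_skips = self._encode("c", c_in, train)
            x = ad.concat([p_bottom, c_bottom], axis=1)
        else:
            x = p_bottom
        x = ad.relu(self._conv("fc1", x))
        x = ad.relu(self._conv("fc2", x))

        heads: list[Tensor] = []
        for lvl in range(cfg.levels - 2, -1, -1):
            x = ad.upsample_nearest(x, cfg.pool)
            cats = [x, p_skips[lvl]]
            if c_skips is not None:
                cats.append(c_skips[lvl])
            x = ad.concat(cats, axis=1)
            x = self._level(f"dec{lvl}", x, train)
            if cfg.has_deep_supervision and lvl > 0:
                up = ad.upsample_nearest(x, tuple(2 ** lvl for _ in range(3)))
                heads.append(ad.sigmoid(self._conv(f"head{lvl}", up)))
        heads.append(ad.sigmoid(self._conv("final", x)))
        return heads

    def predict_patches(self, primary: np.ndarray,
                        context: np.ndarray | None = None) -> np.ndarray:
        """Evaluation-mode forward on a (N, X, Y, Z) intensity batch,
        returning the final head's probabilities as (N, X, Y, Z)."""
        p = Tensor(np.asarray(primary, dtype=self.dtype)[:, None])
        c = None
        if self.cfg.has_context:
            c = Tensor(np.asarray(context, dtype=self.dtype)[:, None])
        heads = self.forward(p, c, train=False)
        return heads[-1].data[:, 0]

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(int(seed))


def build_network(cfg: ArchitectureConfig, seed: int = 0,
                  dtype=np.float32) -> Network:
    """Build one of the four variants with Glorot-uniform convolution
    weights; deterministic under `seed`."""
    return Network(cfg, seed=seed, dtype=dtype)


def count_trainable_parameters(net: Network) -> int:
    """Number of independently optimized scalars (kernels, biases, BN
    scale/shift)."""
    return int(sum(p.data.size for p in net.parameters()))


def downsample_context(patch: np.ndarray) -> np.ndarray:
    """2x2x2 average-pool (stride 2) of a 3-D patch: each output voxel is
    the mean of its 2x2x2 block."""
    patch = np.asarray(patch)
    if patch.ndim != 3:
        raise ValueError("expected a 3-D patch")
    if any(s % 2 for s in patch.shape):
        raise ValueError(f"all dimensions must be even, got {patch.shape}")
    X, Y, Z = patch.shape
    r = patch.reshape(X // 2, 2, Y // 2, 2, Z // 2, 2)
    return r.mean(axis=(1, 3, 5))


def save_network(net: Network, path) -> None:
    """Save parameters, BN running statistics and the config as .npz."""
    arrays = {f"param/{k}": v.data for k, v in net.params.items()}
    for name, st in net.bn_states.items():
        arrays[f"bnmean/{name}"] = st.running_mean
        arrays[f"bnvar/{name}"] = st.running_var
    arrays["config_json"] = np.array(
        json.dumps({"cfg": net.cfg.to_dict(), "seed": net.seed})
    )
    np.savez(str(path), **arrays)


def load_network(path) -> Network:
    with np.load(str(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["config_json"]))
        cfg = ArchitectureConfig.from_dict(meta["cfg"])
        net = Network(cfg, seed=int(meta.get("seed", 0)))
        for key in archive.files:
            if key.startswith("param/"):
                name = key[len("param/"):]
                net.params[name].data = archive[key].astype(net.dtype)
            elif key.startswith("bnmean/"):
                net.bn_states[key[len("bnmean/"):]].running_mean = archive[key]
            elif key.startswith("bnvar/"):
                net.bn_states[key[len("bnvar/"):]].running_var = archive[key]
    return net
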
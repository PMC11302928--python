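"""The G-Net encoder-decoder.

Topology
--------
For each encoder stage ``s`` with ``encoder_filters[s]`` filters::

    conv_block -> SE block -> (2x2 max-pool, except after the last stage)

The bottleneck applies spatial pyramid pooling followed by a self-attention
gate. The decoder mirrors the encoder: for each pooling step, nearest-neighbor
upsample by 2 and fuse (concatenate + convolve) with the matching encoder
stage's post-SE feature map; the fusion convolution width equals that stage's
encoder width. The head is a 1x1 convolution with ``n_classes`` filters and a
softmax over channels, so the output is a per-pixel probability map with the
input's spatial dimensions.

Skip connections come from the post-SE maps because squeeze-excitation is
applied immediately after each conv block — those are the features available
at each resolution. Upsampling is a nearest-neighbor resize rather than a
transposed convolution, avoiding deconvolution checkerboard overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import nn
from .blocks import ConvBlock, FusionBlock, SEBlock, SelfAttention2D, SPPBlock, SPPParams
from .exceptions import ConfigurationError, ShapeError

__all__ = ["GNetConfig", "GNet", "build_gnet", "forward", "count_params",
           "save_model", "load_model"]


@dataclass
class GNetConfig:
    """All architecture hyperparameters.

    ``input_size`` must be divisible by ``2 ** (len(encoder_filters) - 1)``
    so that every pooled map upsamples back to an exact match, and every SPP
    pool size must fit within the bottleneck resolution.
    """

    encoder_filters: tuple[int, ...] = (64, 128, 256)
    se_reduction: int = 16
    se_bias: bool = True
    spp_pool_sizes: tuple[int, ...] = (2, 4, 8)
    spp_filters_per_level: int = 256
    spp_include_input: bool = True
    n_classes: int = 4
    conv_kernel: int = 3
    input_channels: int = 1
    input_size: tuple[int, int] = (128, 128)

    def __post_init__(self):
        self.encoder_filters = tuple(int(f) for f in self.encoder_filters)
        self.spp_pool_sizes = tuple(int(p) for p in self.spp_pool_sizes)
        self.input_size = tuple(int(s) for s in self.input_size)
        if len(self.encoder_filters) == 0:
            raise ConfigurationError("encoder_filters must be non-empty")
        if any(b > a for a, b in zip(self.encoder_filters[1:],
                                     self.encoder_filters[:-1])):
            raise ConfigurationError(
                f"encoder_filters must be non-decreasing: {self.encoder_filters}")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.se_reduction < 1:
            raise ConfigurationError("se_reduction must be >= 1")
        factor = 2 ** (len(self.encoder_filters) - 1)
        h, w = self.input_size
        if h % factor or w % factor:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by {factor} "
                f"(= 2 ** (number of encoder stages - 1))")
        bh, bw = h // factor, w // factor
        for p in self.spp_pool_sizes:
            if p > bh or p > bw:
                raise ConfigurationError(
                    f"SPP pool size {p} exceeds bottleneck resolution "
                    f"({bh}, {bw}); shrink pool sizes or enlarge the input")

    @property
    def n_stages(self) -> int:
        return len(self.encoder_filters)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_filters"] = list(self.encoder_filters)
        d["spp_pool_sizes"] = list(self.spp_pool_sizes)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GNetConfig":
        return cls(**d)


class GNet(nn.Module):
    """Encoder-decoder segmentation network built from the package's blocks."""

    def __init__(self, config: GNetConfig | None = None, seed: int = 0):
        self.config = config if config is not None else GNetConfig()
        self.seed = int(seed)
        cfg = self.config
        rng = np.random.default_rng(self.seed)

        self.encoder_convs: list[ConvBlock] = []
        self.encoder_ses: list[SEBlock] = []
        c = cfg.input_channels
        for f in cfg.encoder_filters:
            self.encoder_convs.append(ConvBlock(c, f, cfg.conv_kernel, rng=rng))
            self.encoder_ses.append(
                SEBlock(f, cfg.se_reduction, use_bias=cfg.se_bias, rng=rng))
            c = f

        spp_params = SPPParams(pool_sizes=cfg.spp_pool_sizes,
                               filters_per_level=cfg.spp_filters_per_level,
                               include_input=cfg.spp_include_input)
        self.spp = SPPBlock(c, spp_params, rng=rng)
        c = self.spp.out_channels
        self.sa = SelfAttention2D(c, rng=rng)

        self.decoder_fusions: list[FusionBlock] = []
        for f in reversed(cfg.encoder_filters[:-1]):
            self.decoder_fusions.append(
                FusionBlock(c + f, f, cfg.conv_kernel, activation="relu", rng=rng))
            c = f

        self.head = nn.Conv2D(c, cfg.n_classes, kernel_size=1,
                              activation=None, rng=rng)
        self.parameter_count = self.count_params()

    # -- inference ----------------------------------------------------------
    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        cfg = self.config
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:  # (N, H, W) -> single channel
            x = x[..., None]
        expected = (*cfg.input_size, cfg.input_channels)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ShapeError(
                f"expected input batch of shape (N, {expected[0]}, "
                f"{expected[1]}, {expected[2]}), got {x.shape}")
        return x

    def forward_logits(self, x: nn.Tensor) -> nn.Tensor:
        """Full forward pass up to (but excluding) the softmax."""
        skips: list[nn.Tensor] = []
        h = x
        last = self.config.n_stages - 1
        for s, (conv, se) in enumerate(zip(self.encoder_convs, self.encoder_ses)):
            h = se(conv(h))
            skips.append(h)
            if s != last:
                h = nn.max_pool2d(h, 2)
        h = self.sa(self.spp(h))
        for fusion, skip in zip(self.decoder_fusions, reversed(skips[:-1])):
            target = (skip.shape[1], skip.shape[2])
            h = fusion([nn.upsample_nearest(h, target, 2), skip])
        return self.head(h)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return nn.softmax(self.forward_logits(x), axis=-1)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities for a batch of images (numpy in/out)."""
        x = self._check_batch(batch)
        return self.forward(nn.Tensor(x)).data

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Hard label masks via argmax (ties resolve to the lowest class)."""
        return np.argmax(self.predict_proba(batch), axis=-1)


def build_gnet(config: GNetConfig | None = None, seed: int = 0) -> GNet:
    """Instantiate a network with seeded He-normal initialization."""
    return GNet(config, seed=seed)


def forward(model: GNet, batch) -> list[np.ndarray]:
    """Run inference on a list of ``(H, W, C)`` images; one ProbMap each."""
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in batch])
    probs = model.predict_proba(arr)
    return [probs[i] for i in range(probs.shape[0])]


def count_params(model: GNet) -> int:
    return model.count_params()


# --------------------------------------------------------------------------
# serialization: weights as .npz next to a self-describing YAML config
# --------------------------------------------------------------------------

def _checkpoint_paths(path: str) -> tuple[str, str]:
    stem = path[:-4] if path.endswith(".npz") else path
    return stem + ".npz", stem + ".yaml"


def save_model(model: GNet, path: str) -> None:
    """Write weights to ``<stem>.npz`` and config to ``<stem>.yaml``."""
    npz, meta_path = _checkpoint_paths(str(path))
    np.savez(npz, **model.state_dict())
    with open(meta_path, "w") as fh:
        yaml.safe_dump({"config": model.config.to_dict(), "seed": model.seed}, fh)


def load_model(path: str) -> GNet:
    npz, meta_path = _checkpoint_paths(str(path))
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    model = GNet(GNetConfig.from_dict(meta["config"]), seed=meta.get("seed", 0))
    with np.load(npz) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
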
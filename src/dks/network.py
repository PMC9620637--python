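"""Network architectures for keypoint localization and the baseline
classifier.

* :class:`MSHNet` — a cascade of stacked hourglasses with *multiscale*
  supervision: inside each hourglass, the decoder feature maps at 1/8, 1/4
  and 1/2 of the input resolution are each projected to per-keypoint heatmaps
  by a 1x1 convolution (one channel per keypoint).  When anatomical-aware
  supervision is enabled, additional 1x1 heads at the finest supervised scale
  predict the pairwise and triplet co-occurrence maps.  With multiscale
  supervision disabled, only the finest scale carries a head and the model
  reduces to a vanilla stacked hourglass.

* :class:`RegNet` — a small fully convolutional refiner that upsamples each
  scale's heatmaps to full resolution, concatenates them along channels and
  fuses them into the final full-resolution heatmaps.

* :class:`BlackboxNet` — the non-interpretable baseline: shared VGG-style
  convolutional towers over the three views, global pooling, with the three
  mm-per-pixel scalars concatenated to the flattened feature vector before
  the fully connected layers, ending in a single P(transcatheter) sigmoid.

All builders take a seed for weight initialization and run on one CPU.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core import ViewId, schema_for
from .nnet import autograd as ag
from .nnet.layers import Conv2d, Linear, Module, ResBlock

__all__ = [
    "MSHNetConfig",
    "RegNetConfig",
    "BlackboxConfig",
    "MSHNet",
    "RegNet",
    "BlackboxNet",
    "build_mshnet",
    "build_regnet",
    "build_blackbox",
    "save_checkpoint",
    "load_checkpoint",
    "model_summary",
]

SUPERVISED_SCALES: tuple[float, ...] = (1 / 8, 1 / 4, 1 / 2)


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class MSHNetConfig:
    view: str = "A4C"
    n_stacks: int = 2
    base_channels: int = 64
    input_size: int = 256
    supervised_scales: tuple[float, ...] = SUPERVISED_SCALES
    aas_enabled: bool = True
    msh_enabled: bool = True
    hourglass_depth: int = 3  # 3 halvings: bottleneck at 1/8 of the input

    def __post_init__(self) -> None:
        if self.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8")
        if self.n_stacks < 1:
            raise ValueError("n_stacks must be >= 1")

    @property
    def n_keypoints(self) -> int:
        return schema_for(ViewId(self.view)).count

    @property
    def active_scales(self) -> tuple[float, ...]:
        """Scales that carry supervision heads."""
        if self.msh_enabled:
            return tuple(sorted(self.supervised_scales))
        return (max(self.supervised_scales),)

    @property
    def finest_scale(self) -> float:
        return max(self.supervised_scales)


@dataclass(frozen=True)
class RegNetConfig:
    view: str = "A4C"
    in_scales: tuple[float, ...] = SUPERVISED_SCALES
    mid_channels: int = 32

    @property
    def n_keypoints(self) -> int:
        return schema_for(ViewId(self.view)).count


@dataclass(frozen=True)
class BlackboxConfig:
    base_channels: int = 8
    input_size: int = 256
    n_views: int = 3
    scale_input: bool = True  # concatenate mm-per-pixel scalars before the FC
    hidden: int = 32


class Hourglass(Module):
    """Symmetric encoder-decoder with skip connections at every resolution.

    ``forward`` returns the full-resolution output feature and a dict of
    decoder features keyed by scale (1/2**depth ... 1), which the multiscale
    heads tap.
    """

    def __init__(self, depth: int, ch: int, rng: np.random.Generator):
        self.depth = depth
        self.skips = [ResBlock(ch, ch, rng) for _ in range(depth)]
        self.downs = [ResBlock(ch, ch, rng) for _ in range(depth)]
        self.bottom = ResBlock(ch, ch, rng)
        self.ups = [ResBlock(ch, ch, rng) for _ in range(depth)]

    def forward(self, x: ag.Tensor) -> tuple[ag.Tensor, dict[float, ag.Tensor]]:
        skips = []
        cur = x
        for d in range(self.depth):
            skips.append(self.skips[d](cur))
            cur = self.downs[d](ag.maxpool2(cur))
        cur = self.bottom(cur)
        feats: dict[float, ag.Tensor] = {1.0 / 2**self.depth: cur}
        for d in reversed(range(self.depth)):
            cur = self.ups[d](ag.upsample(cur, 2) + skips[d])
            feats[1.0 / 2**d] = cur
        return cur, feats


class MSHNet(Module):
    """Cascaded hourglasses with multiscale heatmap heads and optional
    anatomical-aware pair/triplet heads."""

    def __init__(self, cfg: MSHNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = cfg.base_channels
        k = cfg.n_keypoints
        schema = schema_for(ViewId(cfg.view))
        self.stem_conv = Conv2d(1, ch, 3, rng)
        self.stem_block = ResBlock(ch, ch, rng)
        self.hourglasses = [
            Hourglass(cfg.hourglass_depth, ch, rng) for _ in range(cfg.n_stacks)
        ]
        # 1x1 projection of each tapped decoder feature map to K heatmaps
        self.heads = [
            {f"{s:.6f}": Conv2d(ch, k, 1, rng, init_scale=0.1) for s in cfg.active_scales}
            for _ in range(cfg.n_stacks)
        ]
        self.inter = [
            ResBlock(ch, ch, rng) for _ in range(cfg.n_stacks - 1)
        ]
        if cfg.aas_enabled:
            # pair/triplet co-occurrence maps are a nonlinear (max) function
            # of the single-point maps, so the AAS heads get a hidden conv
            # before the 1x1 projection instead of a bare linear readout
            self.aas_hidden = [Conv2d(ch, 2 * ch, 3, rng) for _ in range(cfg.n_stacks)]
            self.pair_heads = [
                Conv2d(2 * ch, schema.n_pairs, 1, rng, init_scale=0.1)
                for _ in range(cfg.n_stacks)
            ]
            self.triplet_heads = [
                Conv2d(2 * ch, schema.n_triplets, 1, rng, init_scale=0.1)
                for _ in range(cfg.n_stacks)
            ]

    def forward(self, x: ag.Tensor) -> list[dict]:
        """x: (N, 1, H, W) in [0, 1].  Returns one dict per stack with
        ``heatmaps`` {scale: (N, K, sH, sW)}, and ``pairs``/``triplets`` at
        the finest supervised scale when AAS is enabled."""
        n, c, h, w = x.data.shape
        if c != 1 or h != self.cfg.input_size or w != self.cfg.input_size:
            raise ShapeError(
                f"expected (N, 1, {self.cfg.input_size}, {self.cfg.input_size}), "
                f"got {x.data.shape}"
            )
        cur = self.stem_block(ag.relu(self.stem_conv(x)))
        outputs = []
        for i, hg in enumerate(self.hourglasses):
            full, feats = hg(cur)
            out: dict = {
                "heatmaps": {
                    float(s): self.heads[i][f"{s:.6f}"](feats[float(s)])
                    for s in self.cfg.active_scales
                }
            }
            if self.cfg.aas_enabled:
                fine = ag.relu(self.aas_hidden[i](feats[self.cfg.finest_scale]))
                out["pairs"] = self.pair_heads[i](fine)
                out["triplets"] = self.triplet_heads[i](fine)
            outputs.append(out)
            if i < len(self.hourglasses) - 1:
                cur = self.inter[i](full)
        return outputs


class RegNet(Module):
    """Fully convolutional fusion of multiscale heatmaps into the final
    full-resolution prediction."""

    def __init__(self, cfg: RegNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        k = cfg.n_keypoints
        cin = k * len(cfg.in_scales)
        self.fuse1 = Conv2d(cin, cfg.mid_channels, 3, rng)
        self.fuse2 = Conv2d(cfg.mid_channels, k, 1, rng, init_scale=0.1)

    def forward(self, heatmaps: dict[float, ag.Tensor]) -> ag.Tensor:
        scales = sorted(heatmaps)
        if tuple(scales) != tuple(sorted(self.cfg.in_scales)):
            raise ShapeError(
                f"expected scales {sorted(self.cfg.in_scales)}, got {scales}"
            )
        k = self.cfg.n_keypoints
        full = max(
            int(round(heatmaps[s].data.shape[2] / s)) for s in scales
        )
        ups = []
        for s in scales:
            hm = heatmaps[s]
            if hm.data.shape[1] != k:
                raise ShapeError(
                    f"scale {s}: expected {k} channels, got {hm.data.shape[1]}"
                )
            factor = full // hm.data.shape[2]
            ups.append(ag.upsample(hm, factor) if factor > 1 else hm)
        fused = ag.concat(ups, axis=1)
        return self.fuse2(ag.relu(self.fuse1(fused)))


class _ViewTower(Module):
    """Shared-weight convolutional tower for one view (VGG-style)."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.c1 = Conv2d(1, ch, 3, rng)
        self.c2 = Conv2d(ch, 2 * ch, 3, rng)
        self.c3 = Conv2d(2 * ch, 2 * ch, 3, rng)

    def forward(self, x: ag.Tensor) -> ag.Tensor:
        y = ag.maxpool2(ag.relu(self.c1(x)))
        y = ag.maxpool2(ag.relu(self.c2(y)))
        y = ag.maxpool2(ag.relu(self.c3(y)))
        return ag.global_avg_pool(y)  # (N, 2*ch)


class BlackboxNet(Module):
    """Binary classifier mapping the three views (plus scales) to
    P(transcatheter)."""

    def __init__(self, cfg: BlackboxConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.tower = _ViewTower(cfg.base_channels, rng)  # weights shared
        feat = 2 * cfg.base_channels * cfg.n_views
        if cfg.scale_input:
            feat += cfg.n_views
        self.fc1 = Linear(feat, cfg.hidden, rng)
        self.fc2 = Linear(cfg.hidden, 1, rng)

    def forward(
        self, views: list[ag.Tensor], scales_mm_per_px: Optional[np.ndarray] = None
    ) -> ag.Tensor:
        """views: list of (N, 1, H, W) in fixed view order; scales: (N, 3)."""
        if len(views) != self.cfg.n_views:
            raise ValueError(f"expected {self.cfg.n_views} views, got {len(views)}")
        feats = [self.tower(v) for v in views]
        if self.cfg.scale_input:
            if scales_mm_per_px is None:
                raise ValueError("scale_input=True requires mm-per-pixel scalars")
            feats.append(ag.Tensor(np.asarray(scales_mm_per_px, dtype=np.float32)))
        fused = ag.concat(feats, axis=1)
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(fused))))


def build_mshnet(cfg: MSHNetConfig, seed: int = 0) -> MSHNet:
    return MSHNet(cfg, np.random.default_rng(seed))


def build_regnet(cfg: RegNetConfig, seed: int = 0) -> RegNet:
    return RegNet(cfg, np.random.default_rng(seed))


def build_blackbox(cfg: BlackboxConfig, seed: int = 0) -> BlackboxNet:
    return BlackboxNet(cfg, np.random.default_rng(seed))


_CONFIG_TYPES = {
    "MSHNetConfig": MSHNetConfig,
    "RegNetConfig": RegNetConfig,
    "BlackboxConfig": BlackboxConfig,
}
_MODEL_TYPES = {
    "MSHNetConfig": MSHNet,
    "RegNetConfig": RegNet,
    "BlackboxConfig": BlackboxNet,
}


def save_checkpoint(path: str | Path, model: Module, extra: Optional[dict] = None) -> None:
    """Single-file archive: config JSON + parameter arrays."""
    cfg = model.cfg
    meta = {
        "config_type": type(cfg).__name__,
        "config": _cfg_to_jsonable(cfg),
        "extra": extra or {},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = io.BytesIO()
        np.savez(buf, **model.state_dict())
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[Module, dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with np.load(io.BytesIO(zf.read("params.npz"))) as npz:
            state = {k: npz[k] for k in npz.files}
    cfg_cls = _CONFIG_TYPES[meta["config_type"]]
    cfg_raw = dict(meta["config"])
    for key in ("supervised_scales", "in_scales"):
        if key in cfg_raw:
            cfg_raw[key] = tuple(cfg_raw[key])
    cfg = cfg_cls(**cfg_raw)
    model = _MODEL_TYPES[meta["config_type"]](cfg, np.random.default_rng(0))
    model.load_state_dict(state)
    return model, meta["extra"]


def _cfg_to_jsonable(cfg) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def model_summary(model: Module) -> str:
    """Per-parameter shape listing with the total count."""
    lines = [f"{type(model).__name__}"]
    for name, p in model.named_parameters():
        lines.append(f"  {name:<40} {str(p.data.shape):<20} {p.data.size}")
    lines.append(f"  total parameters: {model.n_parameters()}")
    return "\n".join(lines)
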
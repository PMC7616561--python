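"""Multi-view 2D-to-3D voxel reconstruction networks and their cost accounting.

Four network variants are provided, spanning two axes:

* **tier** — ``fast`` (residual encoder of depth 18, 3³ decoder kernels, no
  refiner) vs ``accurate`` (depth-50 bottleneck encoder, 4³ decoder
  kernels, plus a 3D encoder–decoder refiner with skip connections);
* **variant** — ``parallel`` (a shared-weight decoder branch is run per
  view and the per-view coarse volumes are merged by context-aware fusion:
  a per-voxel softmax over learned score volumes) vs ``efficient`` (the
  per-view feature volumes are collapsed right after the encoder by a
  3-tap convolution along the view axis with a 3³ spatial kernel, shared
  across feature channels, so a single decoder branch serves any number of
  input views).

Every view is encoded by the same 2D residual encoder into a 256x2x2x2
feature volume; decoders upsample by transposed 3D convolutions, doubling
the spatial extent per stage up to the requested output resolution, and a
sigmoid maps voxel logits to occupancy probabilities in [0, 1].

``cost_report`` accounts parameters and theoretical multiply-add
operations per component, analytically from layer shapes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as ag

__all__ = ["NetworkSpec", "CostReport", "build_model", "cost_report", "ReconstructionModel"]


class CapacityError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture specification of one reconstruction network.

    ``backbone_depth`` and ``use_refiner`` are tied to the tier (18/no
    refiner for fast, 50/refiner for accurate) and are validated if given
    explicitly.  ``base_width`` scales the encoder channel counts; the
    decoder channel schedule is the per-stage output channels ending at the
    single occupancy channel, truncated from the front for smaller output
    resolutions.
    """

    tier: str = "fast"
    variant: str = "parallel"
    input_size_px: int = 64
    output_dim: int = 32
    backbone_depth: int | None = None
    use_refiner: bool | None = None
    max_views: int = 9
    base_width: int = 16
    decoder_channels: tuple[int, ...] = (128, 64, 32, 8, 1)
    seed: int = 0

    def resolved(self) -> "NetworkSpec":
        depth = self.backbone_depth if self.backbone_depth is not None else (18 if self.tier == "fast" else 50)
        refiner = self.use_refiner if self.use_refiner is not None else (self.tier == "accurate")
        spec = NetworkSpec(**{**self.__dict__, "backbone_depth": depth, "use_refiner": refiner})
        spec.validate()
        return spec

    def validate(self) -> None:
        if self.tier not in ("fast", "accurate"):
            raise ValueError(f"tier must be 'fast' or 'accurate', got {self.tier!r}")
        if self.variant not in ("parallel", "efficient"):
            raise ValueError(f"variant must be 'parallel' or 'efficient', got {self.variant!r}")
        if self.tier == "fast" and (self.backbone_depth != 18 or self.use_refiner):
            raise ValueError("fast tier requires backbone_depth 18 and no refiner")
        if self.tier == "accurate" and (self.backbone_depth != 50 or not self.use_refiner):
            raise ValueError("accurate tier requires backbone_depth 50 and a refiner")
        if self.output_dim not in (16, 32, 64):
            raise ValueError("output_dim must be one of 16, 32, 64")
        n = self.input_size_px
        if n < 32 or n & (n - 1):
            raise ValueError("input_size_px must be a power of two >= 32")
        if self.max_views < 1:
            raise ValueError("max_views must be >= 1")
        if self.decoder_channels[-1] != 1:
            raise ValueError("decoder channel schedule must end at 1")

    @property
    def decoder_kernel(self) -> int:
        return 3 if self.tier == "fast" else 4

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(dict(self.__dict__))

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        import yaml

        d = yaml.safe_load(text)
        d["decoder_channels"] = tuple(d.get("decoder_channels", (128, 64, 32, 8, 1)))
        return cls(**d)


# -- building blocks --------------------------------------------------------


class BasicBlock(nn.Module):
    def __init__(self, in_ch, out_ch, stride, *, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride, 1, rng=rng)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, 1, 1, rng=rng)
        self.down = nn.Conv2d(in_ch, out_ch, 1, stride, 0, rng=rng) if (stride != 1 or in_ch != out_ch) else None

    def forward(self, x):
        h = ag.relu(self.conv1(x))
        h = self.conv2(h)
        skip = x if self.down is None else self.down(x)
        return ag.relu(h + skip)

    def mac_count(self, s):
        macs = self.conv1.mac_count(s)
        mid = self.conv1.out_spatial(s)
        macs += self.conv2.mac_count(mid)
        if self.down is not None:
            macs += self.down.mac_count(s)
        return macs, self.conv2.out_spatial(mid)


class BottleneckBlock(nn.Module):
    expansion = 4

    def __init__(self, in_ch, width, stride, *, rng):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = nn.Conv2d(in_ch, width, 1, 1, 0, rng=rng)
        self.conv2 = nn.Conv2d(width, width, 3, stride, 1, rng=rng)
        self.conv3 = nn.Conv2d(width, out_ch, 1, 1, 0, rng=rng)
        self.down = nn.Conv2d(in_ch, out_ch, 1, stride, 0, rng=rng) if (stride != 1 or in_ch != out_ch) else None

    def forward(self, x):
        h = ag.relu(self.conv1(x))
        h = ag.relu(self.conv2(h))
        h = self.conv3(h)
        skip = x if self.down is None else self.down(x)
        return ag.relu(h + skip)

    def mac_count(self, s):
        macs = self.conv1.mac_count(s)
        s1 = self.conv1.out_spatial(s)
        macs += self.conv2.mac_count(s1)
        s2 = self.conv2.out_spatial(s1)
        macs += self.conv3.mac_count(s2)
        if self.down is not None:
            macs += self.down.mac_count(s)
        return macs, self.conv3.out_spatial(s2)


class Encoder(nn.Module):
    """Residual 2D encoder truncated before pooling, mapping each view to a
    256x2x2x2 feature volume."""

    FEATURE_SHAPE = (256, 2, 2, 2)

    def __init__(self, spec: NetworkSpec, *, rng):
        super().__init__()
        w = spec.base_width
        depth18 = spec.backbone_depth == 18
        blocks_per_stage = [2, 2, 2, 2] if depth18 else [3, 4, 6, 3]
        self.conv1 = nn.Conv2d(1, w, 3, 1, 1, rng=rng)
        stages: list[nn.Module] = []
        ch = w
        for i, nblocks in enumerate(blocks_per_stage):
            width = w * 2**i
            for b in range(nblocks):
                stride = 2 if (i > 0 and b == 0) else 1
                if depth18:
                    blk = BasicBlock(ch, width, stride, rng=rng)
                    ch = width
                else:
                    blk = BottleneckBlock(ch, width, stride, rng=rng)
                    ch = width * BottleneckBlock.expansion
                stages.append(blk)
        self.stages = stages
        for i, blk in enumerate(stages):
            setattr(self, f"block{i}", blk)
        # reduce to 2x2 spatial, 512 channels -> reshape to 256x2x2x2
        size = spec.input_size_px // 8
        head: list[nn.Module] = []
        while size > 2:
            nxt = 512 if size == 4 else 128
            head.append(nn.Conv2d(ch, nxt, 3, 2, 1, rng=rng))
            ch = nxt
            size //= 2
        if ch != 512:
            head.append(nn.Conv2d(ch, 512, 3, 1, 1, rng=rng))
        self.head = head
        for i, layer in enumerate(head):
            setattr(self, f"head{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        h = ag.relu(self.conv1(x))
        for blk in self.stages:
            h = blk(h)
        for layer in self.head:
            h = ag.relu(layer(h))
        b = h.shape[0]
        return h.reshape(b, *self.FEATURE_SHAPE)

    def mac_count(self, in_spatial):
        macs = self.conv1.mac_count(in_spatial)
        s = self.conv1.out_spatial(in_spatial)
        for blk in self.stages:
            m, s = blk.mac_count(s)
            macs += m
        for layer in self.head:
            macs += layer.mac_count(s)
            s = layer.out_spatial(s)
        return macs


class Decoder(nn.Module):
    """Transposed-3D-convolution decoder: 2 -> output_dim, one occupancy channel."""

    def __init__(self, spec: NetworkSpec, *, rng):
        super().__init__()
        k = spec.decoder_kernel
        opad = 1 if k == 3 else 0
        n_stages = int(math.log2(spec.output_dim // 2))
        channels = spec.decoder_channels[len(spec.decoder_channels) - n_stages :]
        self.deconvs: list[nn.ConvTranspose3d] = []
        ch = 256
        for i, c in enumerate(channels):
            layer = nn.ConvTranspose3d(ch, c, k, 2, 1, output_padding=opad, rng=rng)
            self.deconvs.append(layer)
            setattr(self, f"deconv{i}", layer)
            ch = c

    def forward(self, feat: Tensor) -> Tensor:
        h = feat
        for layer in self.deconvs[:-1]:
            h = ag.relu(layer(h))
        return self.deconvs[-1](h)  # logits, (B, 1, D, D, D)

    def mac_count(self, in_spatial=(2, 2, 2)):
        macs, s = 0, in_spatial
        for layer in self.deconvs:
            macs += layer.mac_count(s)
            s = layer.out_spatial(s)
        return macs


class Scorer(nn.Module):
    """Per-view quality-score volume for context-aware fusion."""

    def __init__(self, *, rng):
        super().__init__()
        self.conv1 = nn.Conv3d(1, 4, 3, 1, 1, rng=rng)
        self.conv2 = nn.Conv3d(4, 4, 3, 1, 1, rng=rng)
        self.conv3 = nn.Conv3d(4, 1, 3, 1, 1, rng=rng)

    def forward(self, coarse: Tensor) -> Tensor:
        h = ag.relu(self.conv1(coarse))
        h = ag.relu(self.conv2(h))
        return self.conv3(h)

    def mac_count(self, s):
        return self.conv1.mac_count(s) + self.conv2.mac_count(s) + self.conv3.mac_count(s)


class ViewFusion(nn.Module):
    """Collapse stacked per-view feature volumes into one.

    A 3-tap convolution along the view axis combined with a 3³ spatial
    kernel, one kernel shared across all feature channels (depthwise),
    zero-padded on the view axis, followed by the mean over the view
    extent — so any view count up to capacity is accepted.
    """

    KERNEL = (3, 3, 3, 3)  # (view, x, y, z)

    def __init__(self, *, rng):
        super().__init__()
        w = rng.normal(0.0, 0.05, size=self.KERNEL)
        w[1, 1, 1, 1] += 1.0  # near-identity init: start close to plain averaging
        self.weight = Tensor(w, requires_grad=True)

    def forward(self, feats: Tensor) -> Tensor:
        """(B, V, C, d, d, d) -> (B, C, d, d, d)."""
        b, v, c = feats.shape[:3]
        spatial = feats.shape[3:]
        xpad = ag.pad_axis(feats, 1, 1, 1)  # zero pad the view axis
        taps = []
        for dv in range(3):
            sl = xpad[:, dv : dv + v]
            flat = sl.reshape(b * v * c, 1, *spatial)
            wk = self.weight[dv].reshape(1, 1, 3, 3, 3)
            taps.append(ag.conv(flat, wk, None, 1, 1))
        summed = taps[0] + taps[1] + taps[2]
        return summed.reshape(b, v, c, *spatial).mean(axis=1)

    def mac_count(self, views: int, feat_shape=(256, 2, 2, 2)) -> int:
        c = feat_shape[0]
        vox = int(np.prod(feat_shape[1:]))
        return views * c * vox * 3 * 27


class Refiner(nn.Module):
    """3D encoder–decoder with a skip connection, refining the fused volume."""

    def __init__(self, *, rng):
        super().__init__()
        self.down1 = nn.Conv3d(1, 8, 4, 2, 1, rng=rng)
        self.down2 = nn.Conv3d(8, 16, 4, 2, 1, rng=rng)
        self.up1 = nn.ConvTranspose3d(16, 8, 4, 2, 1, rng=rng)
        self.up2 = nn.ConvTranspose3d(8, 1, 4, 2, 1, rng=rng)

    def forward(self, fused: Tensor) -> Tensor:
        d1 = ag.relu(self.down1(fused))
        d2 = ag.relu(self.down2(d1))
        u1 = ag.relu(self.up1(d2) + d1)  # skip connection
        return ag.sigmoid(self.up2(u1))

    def mac_count(self, s):
        macs = self.down1.mac_count(s)
        s1 = self.down1.out_spatial(s)
        macs += self.down2.mac_count(s1)
        s2 = self.down2.out_spatial(s1)
        macs += self.up1.mac_count(s2)
        macs += self.up2.mac_count(s1)
        return macs


class ReconstructionModel(nn.Module):
    """One of the four networks; forward maps view images to an occupancy volume."""

    def __init__(self, spec: NetworkSpec):
        super().__init__()
        spec = spec.resolved()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.encoder = Encoder(spec, rng=rng)
        self.decoder = Decoder(spec, rng=rng)
        if spec.variant == "parallel":
            self.scorer = Scorer(rng=rng)
            self.fusion = None
        else:
            self.fusion = ViewFusion(rng=rng)
            self.scorer = None
        self.refiner = Refiner(rng=rng) if spec.use_refiner else None

    def forward(self, images: np.ndarray) -> Tensor:
        """(B, V, H, W) or (V, H, W) intensity rasters in [0,1] -> (B, D, D, D)."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        b, v, h, w = images.shape
        if v < 1 or v > self.spec.max_views:
            raise CapacityError(f"view count {v} exceeds capacity {self.spec.max_views}")
        n = self.spec.input_size_px
        if (h, w) != (n, n):
            raise ValueError(f"expected {n}x{n} images, got {h}x{w}")
        d = self.spec.output_dim
        x = Tensor(images.reshape(b * v, 1, h, w))
        feats = self.encoder(x)  # (B*V, 256, 2, 2, 2)
        if self.spec.variant == "parallel":
            logits = self.decoder(feats)  # (B*V, 1, D, D, D)
            coarse = ag.sigmoid(logits)
            scores = self.scorer(coarse)
            coarse_v = coarse.reshape(b, v, d, d, d)
            scores_v = scores.reshape(b, v, d, d, d)
            weights = ag.softmax(scores_v, axis=1)
            fused = (weights * coarse_v).sum(axis=1)  # (B, D, D, D)
            fused = fused.reshape(b, 1, d, d, d)
        else:
            fv = feats.reshape(b, v, *Encoder.FEATURE_SHAPE)
            fused_feat = self.fusion(fv)
            fused = ag.sigmoid(self.decoder(fused_feat))
        out = self.refiner(fused) if self.refiner is not None else fused
        return out.reshape(b, d, d, d)


def build_model(spec: NetworkSpec) -> ReconstructionModel:
    return ReconstructionModel(spec)


# -- cost accounting --------------------------------------------------------


@dataclass
class CostReport:
    components: dict[str, dict[str, int]]
    views: int

    @property
    def total_parameters(self) -> int:
        return sum(c["parameter_count"] for c in self.components.values())

    @property
    def total_multiply_adds(self) -> int:
        return sum(c["multiply_add_count"] for c in self.components.values())

    def to_dict(self) -> dict:
        return {
            "views": self.views,
            "components": self.components,
            "totals": {
                "parameter_count": self.total_parameters,
                "multiply_add_count": self.total_multiply_adds,
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def cost_report(spec: NetworkSpec, views: int, model: ReconstructionModel | None = None) -> CostReport:
    """Analytic per-component parameter and multiply-add accounting.

    Convolution multiply-adds are output elements x kernel volume x input
    channels (input-centric for transposed convolutions); encoder and — for
    the parallel variant — decoder and scorer costs scale linearly with the
    number of views, while the efficient variant's single decoder branch
    does not.
    """
    if views < 1:
        raise ValueError("views must be >= 1")
    spec = spec.resolved()
    if model is None:
        model = build_model(spec)
    in_px = (spec.input_size_px,) * 2
    d3 = (spec.output_dim,) * 3
    comp: dict[str, dict[str, int]] = {}
    comp["encoder"] = {
        "parameter_count": model.encoder.num_parameters(),
        "multiply_add_count": views * model.encoder.mac_count(in_px),
    }
    dec_macs = model.decoder.mac_count()
    if spec.variant == "parallel":
        comp["decoder"] = {
            "parameter_count": model.decoder.num_parameters(),
            "multiply_add_count": views * dec_macs,
        }
        # score convs per view + per-voxel softmax-weighted combination
        comp["context_fusion"] = {
            "parameter_count": model.scorer.num_parameters(),
            "multiply_add_count": views * (model.scorer.mac_count(d3) + int(np.prod(d3))),
        }
        comp["view_fusion"] = {"parameter_count": 0, "multiply_add_count": 0}
    else:
        comp["decoder"] = {
            "parameter_count": model.decoder.num_parameters(),
            "multiply_add_count": dec_macs,
        }
        comp["view_fusion"] = {
            "parameter_count": model.fusion.num_parameters(),
            "multiply_add_count": model.fusion.mac_count(views),
        }
        comp["context_fusion"] = {"parameter_count": 0, "multiply_add_count": 0}
    if model.refiner is not None:
        comp["refiner"] = {
            "parameter_count": model.refiner.num_parameters(),
            "multiply_add_count": model.refiner.mac_count(d3),
        }
    else:
        comp["refiner"] = {"parameter_count": 0, "multiply_add_count": 0}
    return CostReport(components=comp, views=views)
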
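"""Dual-task encoder/decoder network for nucleus mask + boundary segmentation.

A shared residual/squeeze-excitation encoder feeds two parallel decoder
branches: a mask branch and a boundary branch.  The first three encoder
stages supply skip connections to the last three stages of both decoders;
the deepest feature enters each branch through a 2x2 transposed
convolution.  After every decoder stage the boundary feature is reduced by
a 1x1 convolution to a single-channel sigmoid gate that multiplies the mask
feature (dual-task feature fusion): the boundary branch literally gates
where the mask branch is allowed to keep signal.  Two 1x1-conv + sigmoid
heads emit mask and boundary probability maps at input resolution.

The fusion is realised as an element-wise (Hadamard) product with the
single-channel gate: a literal matrix product is shape-inconsistent across
the multi-channel stages, and the 1x1-conv + sigmoid placed before fusion
makes a multiplicative gate the coherent reading.  Channel widths follow
the U-Net convention (base 64, doubling per stage) and are configurable;
inputs whose sides are not divisible by 2^depth are reflect-padded and the
outputs cropped back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    MaxPool2d,
    Module,
    SEBlock,
    Tensor,
    concat,
)

__all__ = [
    "BlockSpec",
    "ModelConfig",
    "DualTaskOutput",
    "ResidualSEBlock",
    "EncoderBlock",
    "DecoderBlock",
    "FusionGate",
    "DualTaskNet",
    "build_encoder_block",
    "build_decoder_block",
    "default_mask_spec",
    "default_boundary_spec",
]

CONV_KINDS = ("dilated", "depthwise_separable")
KERNELS = (3, 5)
DILATIONS = (1, 2, 3)
STRIDES = (1, 2)
TAILS = ("se_attention", "maxpool3_s1", "none")


@dataclass(frozen=True)
class BlockSpec:
    """One decoder sub-block: a convolution plus an optional tail."""

    conv_kind: str
    kernel: int = 3
    dilation: int = 1
    stride: int = 1
    tail: str = "none"

    def __post_init__(self):
        if self.conv_kind not in CONV_KINDS:
            raise ValueError(f"conv_kind must be one of {CONV_KINDS}, got {self.conv_kind!r}")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be in {KERNELS}, got {self.kernel}")
        if self.dilation not in DILATIONS:
            raise ValueError(f"dilation must be in {DILATIONS}, got {self.dilation}")
        if self.dilation > 1 and self.conv_kind != "dilated":
            raise ValueError("dilation > 1 requires conv_kind='dilated'")
        if self.stride not in STRIDES:
            raise ValueError(f"stride must be in {STRIDES}, got {self.stride}")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}, got {self.tail!r}")


def default_mask_spec():
    """Search outcome for the mask decoder: dilated 3x3 (d=2, s=1) ->
    depthwise-separable 3x3 (s=1) -> SE-attention."""
    return [
        BlockSpec("dilated", kernel=3, dilation=2, stride=1),
        BlockSpec("depthwise_separable", kernel=3, stride=1, tail="se_attention"),
    ]


def default_boundary_spec():
    """Search outcome for the boundary decoder: dilated 3x3 (d=2, s=1) ->
    depthwise-separable 3x3 (s=1) -> max-pool 3x3 (s=1)."""
    return [
        BlockSpec("dilated", kernel=3, dilation=2, stride=1),
        BlockSpec("depthwise_separable", kernel=3, stride=1, tail="maxpool3_s1"),
    ]


def _specs_to_dicts(specs):
    return [asdict(s) for s in specs]


def _specs_from_dicts(items):
    return [BlockSpec(**d) if not isinstance(d, BlockSpec) else d for d in items]


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the dual-task network."""

    depth: int = 4
    base_channels: int = 64
    input_channels: int = 1
    se_reduction: int = 16
    mask_decoder_spec: list = field(default_factory=default_mask_spec)
    boundary_decoder_spec: list = field(default_factory=default_boundary_spec)

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")
        if self.input_channels not in (1, 3):
            raise ValueError("input_channels must be 1 or 3")
        self.mask_decoder_spec = _specs_from_dicts(self.mask_decoder_spec)
        self.boundary_decoder_spec = _specs_from_dicts(self.boundary_decoder_spec)

    def to_dict(self):
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class DualTaskOutput:
    """Per-pixel mask and boundary probabilities of one image."""

    mask_prob: np.ndarray
    boundary_prob: np.ndarray


class ResidualSEBlock(Module):
    """Residual sub-block: (conv-BN-ReLU-conv-BN-SE) + (conv-BN) side path."""

    def __init__(self, in_ch, out_ch, rng, se_reduction=16):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.se = SEBlock(out_ch, rng, reduction=se_reduction)
        self.side_conv = Conv2d(in_ch, out_ch, 3, rng)
        self.side_bn = BatchNorm2d(out_ch)

    def forward(self, x):
        main = self.bn1(self.conv1(x)).relu()
        main = self.se(self.bn2(self.conv2(main)))
        side = self.side_bn(self.side_conv(x))
        return main + side


class EncoderBlock(Module):
    """Two residual/SE sub-blocks followed by a 2x2 stride-2 max pool.

    ``forward`` returns ``(pre_pool, pooled)``; the pre-pool feature is the
    skip connection source.
    """

    def __init__(self, in_ch, out_ch, rng, se_reduction=16):
        super().__init__()
        self.rs1 = ResidualSEBlock(in_ch, out_ch, rng, se_reduction)
        self.rs2 = ResidualSEBlock(out_ch, out_ch, rng, se_reduction)
        self.pool = MaxPool2d(2, 2)

    def forward(self, x):
        pre = self.rs2(self.rs1(x))
        return pre, self.pool(pre)


class _DepthwiseSeparable(Module):
    """Depthwise conv + BN + ReLU, then pointwise 1x1 conv + BN + ReLU."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        super().__init__()
        self.dw = Conv2d(in_ch, in_ch, kernel, rng, stride=stride, depthwise=True)
        self.bn_dw = BatchNorm2d(in_ch)
        self.pw = Conv2d(in_ch, out_ch, 1, rng)
        self.bn_pw = BatchNorm2d(out_ch)

    def forward(self, x):
        x = self.bn_dw(self.dw(x)).relu()
        return self.bn_pw(self.pw(x)).relu()


class DecoderBlock(Module):
    """Decoder stage built from an ordered BlockSpec sequence."""

    def __init__(self, specs, in_ch, out_ch, rng, se_reduction=16):
        super().__init__()
        specs = _specs_from_dicts(specs)
        if not specs:
            raise ValueError("decoder spec must contain at least one sub-block")
        self.stages = []
        ch = in_ch
        for spec in specs:
            if spec.conv_kind == "dilated":
                self.stages.append(
                    _ConvBNReLU(ch, out_ch, spec.kernel, spec.stride, spec.dilation, rng)
                )
            else:
                self.stages.append(
                    _DepthwiseSeparable(ch, ch, spec.kernel, spec.stride, rng)
                    if ch == out_ch
                    else _PointwiseThenDW(ch, out_ch, spec.kernel, spec.stride, rng)
                )
            ch = out_ch
            if spec.tail == "se_attention":
                self.stages.append(SEBlock(out_ch, rng, reduction=se_reduction))
            elif spec.tail == "maxpool3_s1":
                self.stages.append(MaxPool2d(3, 1, pad=1))

    def forward(self, x):
        for stage in self.stages:
            x = stage(x)
        return x


class _ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, kernel, stride, dilation, rng):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, stride=stride, dilation=dilation)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class _PointwiseThenDW(Module):
    """Channel-mapping variant of the depthwise-separable sub-block: the
    depthwise stage needs in_ch == out_ch, so map channels pointwise first."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        super().__init__()
        self.pw_in = Conv2d(in_ch, out_ch, 1, rng)
        self.bn_in = BatchNorm2d(out_ch)
        self.body = _DepthwiseSeparable(out_ch, out_ch, kernel, stride, rng)

    def forward(self, x):
        return self.body(self.bn_in(self.pw_in(x)).relu())


class FusionGate(Module):
    """Dual-task fusion: sigmoid(1x1 conv(boundary feature)) gates the mask
    feature as a single-channel multiplicative map."""

    def __init__(self, boundary_ch, rng):
        super().__init__()
        self.conv = Conv2d(boundary_ch, 1, 1, rng)
        self.force_gate = None  # test hook: None | float

    def gate(self, boundary_feat):
        if self.force_gate is not None:
            shape = (boundary_feat.shape[0], 1) + boundary_feat.shape[2:]
            return Tensor(np.full(shape, self.force_gate, dtype=np.float32))
        return self.conv(boundary_feat).sigmoid()

    def forward(self, mask_feat, boundary_feat):
        if mask_feat.shape[2:] != boundary_feat.shape[2:]:
            raise ValueError(
                f"spatial mismatch: mask {mask_feat.shape} vs boundary {boundary_feat.shape}"
            )
        return mask_feat * self.gate(boundary_feat)


def build_encoder_block(in_ch, out_ch, rng=None, se_reduction=16):
    """Encoder stage factory (see :class:`EncoderBlock`)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return EncoderBlock(in_ch, out_ch, rng, se_reduction)


def build_decoder_block(spec, in_ch, out_ch, role="mask", rng=None, se_reduction=16):
    """Decoder stage factory from a BlockSpec sequence; ``role`` is
    informational ('mask' or 'boundary')."""
    if role not in ("mask", "boundary"):
        raise ValueError(f"role must be 'mask' or 'boundary', got {role!r}")
    rng = rng if rng is not None else np.random.default_rng(0)
    return DecoderBlock(spec, in_ch, out_ch, rng, se_reduction)


class DualTaskNet(Module):
    """The full dual-task segmentation network."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or ModelConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        cfg = self.config
        chs = [cfg.base_channels * (2**i) for i in range(cfg.depth)]

        self.encoders = []
        in_ch = cfg.input_channels
        for ch in chs:
            self.encoders.append(EncoderBlock(in_ch, ch, rng, cfg.se_reduction))
            in_ch = ch

        # decoder stage channel plan: stage 0 keeps the bottleneck width,
        # stages 1..depth-1 halve it and concatenate the matching skip
        self.mask_ups, self.mask_blocks = [], []
        self.boundary_ups, self.boundary_blocks = [], []
        self.gates = []
        for branch, blocks, ups in (
            ("mask", self.mask_blocks, self.mask_ups),
            ("boundary", self.boundary_blocks, self.boundary_ups),
        ):
            spec = cfg.mask_decoder_spec if branch == "mask" else cfg.boundary_decoder_spec
            ch = chs[-1]
            for stage in range(cfg.depth):
                if stage == 0:
                    ups.append(ConvTranspose2x2(ch, ch, rng))
                    blocks.append(DecoderBlock(spec, ch, ch, rng, cfg.se_reduction))
                else:
                    skip_ch = chs[-1 - stage]
                    ups.append(ConvTranspose2x2(ch, skip_ch, rng))
                    blocks.append(
                        DecoderBlock(spec, 2 * skip_ch, skip_ch, rng, cfg.se_reduction)
                    )
                    ch = skip_ch
        out_ch = chs[-1]
        for stage in range(cfg.depth):
            gate_ch = chs[-1] if stage == 0 else chs[-1 - stage]
            self.gates.append(FusionGate(gate_ch, rng))
        self.mask_head = Conv2d(chs[0], 1, 1, rng)
        self.boundary_head = Conv2d(chs[0], 1, 1, rng)
        _ = out_ch

    # -- core batched pass -------------------------------------------------
    def forward_batch(self, x: Tensor):
        """(N,C,H,W) -> (mask_prob, boundary_prob) tensors, H/W divisible
        by 2^depth."""
        skips = []
        cur = x
        for enc in self.encoders:
            pre, cur = enc(cur)
            skips.append(pre)
        m = b = cur
        for stage in range(self.config.depth):
            m = self.mask_ups[stage](m)
            b = self.boundary_ups[stage](b)
            if stage > 0:
                skip = skips[-1 - stage]
                m = concat([m, skip], axis=1)
                b = concat([b, skip], axis=1)
            m = self.mask_blocks[stage](m)
            b = self.boundary_blocks[stage](b)
            m = self.gates[stage](m, b)
        mask_prob = self.mask_head(m).sigmoid()
        boundary_prob = self.boundary_head(b).sigmoid()
        return mask_prob, boundary_prob

    # -- single-image convenience ------------------------------------------
    def forward(self, image) -> DualTaskOutput:
        """2-D (H,W) or (H,W,3) image -> same-shape probability maps.

        Sides not divisible by 2^depth are reflect-padded and cropped back.
        """
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 2:
            img = img[None, None]
        elif img.ndim == 3 and img.shape[2] in (1, 3):
            img = img.transpose(2, 0, 1)[None]
        else:
            raise ValueError(
                f"expected a 2-D image or (H,W,1|3) array, got shape {np.shape(image)}"
            )
        if img.shape[1] != self.config.input_channels:
            raise ValueError(
                f"model expects {self.config.input_channels} channel(s), got {img.shape[1]}"
            )
        h, w = img.shape[2:]
        mult = 2**self.config.depth
        ph = (-h) % mult
        pw = (-w) % mult
        x = Tensor(img)
        if ph or pw:
            x = x.pad2d(0, ph, 0, pw, mode="reflect")
        mask_t, bnd_t = self.forward_batch(x)
        mask = mask_t.data[0, 0, :h, :w].copy()
        bnd = bnd_t.data[0, 0, :h, :w].copy()
        mask_t.release()
        bnd_t.release()
        return DualTaskOutput(mask_prob=mask, boundary_prob=bnd)

    # -- summaries and checkpoints -------------------------------------------
    def summary(self):
        counts = {
            "encoder": [e.parameter_count() for e in self.encoders],
            "mask_decoder": [b.parameter_count() for b in self.mask_blocks],
            "boundary_decoder": [b.parameter_count() for b in self.boundary_blocks],
            "mask_upsample": [u.parameter_count() for u in self.mask_ups],
            "boundary_upsample": [u.parameter_count() for u in self.boundary_ups],
            "fusion_gates": [g.parameter_count() for g in self.gates],
            "heads": self.mask_head.parameter_count()
            + self.boundary_head.parameter_count(),
        }
        counts["total"] = self.parameter_count()
        return counts

    def save(self, path):
        state = self.state_dict()
        meta = json.dumps({"config": self.config.to_dict(), "seed": self.seed})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path):
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            model = cls(ModelConfig.from_dict(meta["config"]), seed=meta["seed"])
            state = {k: data[k] for k in data.files if k != "__meta__"}
        model.load_state_dict(state)
        return model

    def make_optimizer(self, lr=1e-4):
        return Adam(self.parameters(), lr=lr)
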
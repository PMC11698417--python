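"""Dual-branch encoder-decoder for joint layer segmentation and TSDF
boundary regression.

One residual channel-attention encoder is shared by two decoders: a
segmentation decoder (channel-softmax head over K classes) and a boundary
regression decoder (tanh head predicting the K normalized TSDF maps).  At
every decoder level a spatial-attention fusion block couples the encoder
skip features F_i with the features of both branches (S_i, B_i) through
four attention gates (two per branch), so each branch can pull what it
needs from the other.

Channel attention doubles as the importance signal for structured pruning:
every 3x3 convolution carries a squeeze-excitation style gate whose
per-channel weights alpha are recorded at forward time.  All convolutions
are registered with named output "channel groups"; the pruning module
shrinks groups by index and every consumer slices its input channels
accordingly.  Residual connections always use a 1x1 projection (+BN) so
that each convolution remains an independently prunable group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Tensor, Module, ModuleList, Conv2d, BatchNorm2d, Linear,
                 concat, maxpool2x2, upsample2x, relu, sigmoid, tanh, softmax)

__all__ = ["ModelSpec", "DualBranchNet", "ChannelAttention", "ResAttBlock",
           "AttentionGate", "FusionLevel", "build_model", "count_parameters",
           "DEFAULT_CHANNELS"]

DEFAULT_CHANNELS = (32, 64, 128, 128, 128)
_BRANCHES = ("seg", "bou")


def _nominal_groups(channels) -> dict:
    groups = {}
    for i in range(5):
        groups[f"enc{i + 1}.mid"] = channels[i]
        groups[f"enc{i + 1}.out"] = channels[i]
    for br in _BRANCHES:
        for i in range(1, 5):
            c = channels[i - 1]
            groups[f"{br}{i}.fuse"] = c
            groups[f"{br}{i}.mid"] = c
            groups[f"{br}{i}.out"] = c
    return groups


@dataclass
class ModelSpec:
    """Single source of truth for network construction and pruning surgery.

    channels     : widths of the 4 encoder levels + bottleneck
    n_classes    : K, classes including background
    ca_reduction : squeeze ratio r of the channel-attention MLP
    kept         : per-group sorted original channel indices that survive
                   pruning; ``None`` means the full nominal plan.
    """

    n_classes: int
    channels: tuple = DEFAULT_CHANNELS
    ca_reduction: int = 4
    kernel_size: int = 3
    kept: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = tuple(int(c) for c in self.channels)
        if len(self.channels) != 5 or min(self.channels) < 1:
            raise ValueError("channels must be 5 positive widths")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        nominal = _nominal_groups(self.channels)
        for g, idx in self.kept.items():
            idx = list(idx)
            if g not in nominal:
                raise ValueError(f"unknown channel group {g!r}")
            if not idx or sorted(set(idx)) != idx or idx[-1] >= nominal[g]:
                raise ValueError(f"invalid kept indices for group {g!r}")

    @property
    def groups(self) -> dict:
        return _nominal_groups(self.channels)

    def kept_indices(self, group: str) -> list:
        if group in self.kept:
            return list(self.kept[group])
        return list(range(self.groups[group]))

    def width(self, group) -> int:
        if isinstance(group, int):
            return group
        return len(self.kept_indices(group))

    def hidden(self, group: str) -> int:
        """Hidden width of the attention MLP: fixed at construction value
        (nominal // r) so weights transfer through pruning."""
        return max(1, self.groups[group] // self.ca_reduction)

    def with_kept(self, kept: dict) -> "ModelSpec":
        return ModelSpec(n_classes=self.n_classes, channels=self.channels,
                         ca_reduction=self.ca_reduction,
                         kernel_size=self.kernel_size, kept=dict(kept))


class ChannelAttention(Module):
    """Squeeze-excitation gate: z_c = max_hw + mean_hw of channel c,
    alpha = sigmoid(W2 relu(W1 z)); features are reweighted by alpha.

    The per-channel alphas of the last forward pass are kept (detached) in
    ``last_alpha`` for the pruning importance accumulator.
    """

    def __init__(self, ch: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(ch, hidden, rng)
        self.fc2 = Linear(hidden, ch, rng)
        # damp the MLP at init: raw conv activations can be large, and a
        # saturated sigmoid gate (alpha near 0/1) stalls early training
        self.fc1.weight.data *= 0.2
        self.fc2.weight.data *= 0.2
        self.last_alpha = None

    def forward(self, x: Tensor):
        z = x.amax(axis=(2, 3)) + x.mean(axis=(2, 3))      # (N, C)
        alpha = sigmoid(self.fc2(relu(self.fc1(z))))       # (N, C)
        self.last_alpha = alpha.data.copy()
        n, c = alpha.shape
        return x * alpha.reshape(n, c, 1, 1), alpha


def channel_attention(features: Tensor, ca: ChannelAttention):
    """Functional form: returns (alpha, reweighted features)."""
    out, alpha = ca(features)
    return alpha, out


class ConvUnit(Module):
    """A registered convolution: conv [+ BN] [+ channel attention].

    ``in_groups`` and ``out_group`` are channel-group names (or plain ints
    for fixed, never-pruned widths); they drive pruning surgery.  Convs
    followed by BN carry no bias (BN absorbs it).

    Order is conv -> channel attention -> BN: the attention pools the raw
    convolution outputs, whose per-channel scale carries the importance
    signal used for pruning (after BN every channel is standardized and
    that signal is gone).
    """

    def __init__(self, name: str, in_groups, out_group, kernel: int,
                 spec: ModelSpec, rng, bn: bool = True, ca: bool = False):
        super().__init__()
        self.name = name
        self.in_groups = list(in_groups)
        self.out_group = out_group
        in_w = sum(spec.width(g) for g in self.in_groups)
        out_w = spec.width(out_group)
        self.conv = Conv2d(in_w, out_w, kernel, rng, bias=not bn)
        self.bn = BatchNorm2d(out_w) if bn else None
        self.ca = (ChannelAttention(out_w, spec.hidden(out_group), rng)
                   if ca else None)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.ca is not None:
            y, _ = self.ca(y)
        if self.bn is not None:
            y = self.bn(y)
        return y


class ResAttBlock(Module):
    """conv3x3-BN-CA-relu -> conv3x3-BN-CA, plus a 1x1 projection (+BN)
    residual, then relu.  Spatial size is preserved."""

    def __init__(self, prefix: str, in_group, mid_group: str, out_group: str,
                 spec: ModelSpec, rng):
        super().__init__()
        k = spec.kernel_size
        self.unit1 = ConvUnit(f"{prefix}.conv1", [in_group], mid_group, k,
                              spec, rng, bn=True, ca=True)
        self.unit2 = ConvUnit(f"{prefix}.conv2", [mid_group], out_group, k,
                              spec, rng, bn=True, ca=True)
        self.proj = ConvUnit(f"{prefix}.proj", [in_group], out_group, 1,
                             spec, rng, bn=True, ca=False)

    def forward(self, x: Tensor) -> Tensor:
        h = relu(self.unit1(x))
        return relu(self.unit2(h) + self.proj(x))


class AttentionGate(Module):
    """Spatial attention gate: map = sigmoid(w3 relu(w1 q + w2 g)),
    output = map * g.  w1, w2, w3 are 1x1 convolutions; the intermediate
    width is half the level width.  Query and gated inputs may have
    different channel counts (the 1x1 convs align them)."""

    def __init__(self, prefix: str, q_group, g_group, mid: int,
                 spec: ModelSpec, rng):
        super().__init__()
        self.w1 = ConvUnit(f"{prefix}.w1", [q_group], mid, 1, spec, rng,
                           bn=False)
        self.w2 = ConvUnit(f"{prefix}.w2", [g_group], mid, 1, spec, rng,
                           bn=False)
        self.w3 = ConvUnit(f"{prefix}.w3", [mid], 1, 1, spec, rng, bn=False)

    def forward(self, q: Tensor, g: Tensor):
        m = sigmoid(self.w3(relu(self.w1(q) + self.w2(g))))  # (N,1,H,W)
        return m * g, m


def attention_gate(query: Tensor, gated: Tensor, gate: AttentionGate):
    """Functional form: returns (gated output, attention map)."""
    return gate(query, gated)


class FusionLevel(Module):
    """One decoder level of one branch: two attention gates (over the
    encoder skip F and the other branch's features), concatenation with
    the branch's own upsampled features, a 3x3 fusion conv (BN+CA+relu)
    back to the level width, then a residual attention block."""

    def __init__(self, br: str, level: int, q_group, f_group, o_group,
                 spec: ModelSpec, rng):
        super().__init__()
        p = f"{br}{level}"
        mid = max(1, spec.groups[f"{p}.fuse"] // 2)
        self.gate_f = AttentionGate(f"{p}.gf", q_group, f_group, mid, spec, rng)
        self.gate_o = AttentionGate(f"{p}.gb", q_group, o_group, mid, spec, rng)
        self.fuse = ConvUnit(f"{p}.fuse", [q_group, f_group, o_group],
                             f"{p}.fuse", spec.kernel_size, spec, rng,
                             bn=True, ca=True)
        self.block = ResAttBlock(p, f"{p}.fuse", f"{p}.mid", f"{p}.out",
                                 spec, rng)

    def forward(self, q_up: Tensor, f_skip: Tensor, other_up: Tensor) -> Tensor:
        gf, _ = self.gate_f(q_up, f_skip)
        go, _ = self.gate_o(q_up, other_up)
        fused = relu(self.fuse(concat([q_up, gf, go], axis=1)))
        return self.block(fused)


def sadbifb(level: FusionLevel, f_i: Tensor, s_i: Tensor, b_i: Tensor,
            branch: str) -> Tensor:
    """Spatial-attention dual-branch fusion for one branch at one level.

    For the segmentation branch the query is S_i and the gated inputs are
    F_i and B_i; symmetric for the boundary branch.
    """
    if branch == "seg":
        return level(s_i, f_i, b_i)
    if branch == "bou":
        return level(b_i, f_i, s_i)
    raise ValueError(f"unknown branch {branch!r}")


class DualBranchNet(Module):
    """The full dual-branch model.  Forward returns (seg_probs, tsdf_pred),
    both (N, K, H, W); seg_probs is channel-softmaxed, tsdf_pred tanh-ed.

    Inputs whose H or W are not divisible by 16 are reflect-padded and the
    outputs cropped back.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        enc = []
        in_g = 1
        for i in range(1, 6):
            enc.append(ResAttBlock(f"enc{i}", in_g, f"enc{i}.mid",
                                   f"enc{i}.out", spec, rng))
            in_g = f"enc{i}.out"
        self.enc = ModuleList(enc)
        dec_seg, dec_bou = [], []
        for i in range(4, 0, -1):
            if i == 4:
                s_src = b_src = "enc5.out"
            else:
                s_src, b_src = f"seg{i + 1}.out", f"bou{i + 1}.out"
            f_src = f"enc{i}.out"
            dec_seg.append(FusionLevel("seg", i, s_src, f_src, b_src, spec, rng))
            dec_bou.append(FusionLevel("bou", i, b_src, f_src, s_src, spec, rng))
        self.dec_seg = ModuleList(dec_seg)
        self.dec_bou = ModuleList(dec_bou)
        self.seg_head = ConvUnit("seg_head", ["seg1.out"], spec.n_classes, 1,
                                 spec, rng, bn=False)
        self.bou_head = ConvUnit("bou_head", ["bou1.out"], spec.n_classes, 1,
                                 spec, rng, bn=False)

    # -- channel bookkeeping ----------------------------------------------
    @property
    def registry(self) -> dict:
        """name -> ConvUnit, for every convolution in the model."""
        return {m.name: m for m in self.modules() if isinstance(m, ConvUnit)}

    @property
    def attention_units(self) -> dict:
        """prunable group name -> ConvUnit carrying its channel attention."""
        return {u.out_group: u for u in self.registry.values()
                if u.ca is not None}

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        n, _, h, w = x.shape
        ph = (-h) % 16
        pw = (-w) % 16
        if ph or pw:
            x = Tensor(np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)),
                              mode="reflect"))
        skips = []
        e = x
        for i, block in enumerate(self.enc):
            e = block(e)
            if i < 4:
                skips.append(e)
                e = maxpool2x2(e)
        s = b = e
        for lvl in range(4):
            s_up, b_up = upsample2x(s), upsample2x(b)
            f_skip = skips[3 - lvl]
            s_new = self.dec_seg[lvl](s_up, f_skip, b_up)
            b_new = self.dec_bou[lvl](b_up, f_skip, s_up)
            s, b = s_new, b_new
        seg = softmax(self.seg_head(s), axis=1)
        tsdf = tanh(self.bou_head(b))
        if ph or pw:
            seg = seg[:, :, :h, :w]
            tsdf = tsdf[:, :, :h, :w]
        return seg, tsdf


    def predict(self, image: np.ndarray):
        """Segment a single (H,W) image in inference mode.

        Returns ``(mask, tsdf)``: the argmax label map (uint8) and the
        predicted (K,H,W) TSDF stack.
        """
        was_training = self.training
        self.eval()
        seg, tsd = self(np.asarray(image, dtype=np.float32)[None])
        if was_training:
            self.train()
        return seg.data[0].argmax(axis=0).astype(np.uint8), tsd.data[0]


def build_model(spec: ModelSpec, seed: int = 0) -> DualBranchNet:
    """Construct the dual-branch model from a spec; deterministic in seed."""
    return DualBranchNet(spec, seed=seed)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))
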
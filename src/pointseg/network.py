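"""Shared-encoder multi-decoder network with point-guided attention.

One residual encoder feeds ``k + 1`` structurally identical U-style
decoders: a segmentation decoder (2-class softmax head) and ``k``
Gaussian decoders (sigmoid heads) regressing the multi-scale
center-point targets. At every decoder level the segmentation feature
passes through point-guided attention — Query/Key projected from the
mean of the k Gaussian branch features, Value from the segmentation
feature — before being concatenated with the same-level encoder skip
and upsampled. Gaussian decoders run self-attention strictly within
their own branch so their predictions stay independent of each other.

Attention operates on a patch grid: the feature map is reflect-padded
to a multiple of ``patch_grid`` and split into ``grid x grid`` patches;
each patch is mean-pooled into a channel-dimension token, single-head
scaled-dot-product attention (d_k = channels) mixes the tokens, and the
token update is broadcast back onto the patch it came from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Module, Tensor
from .core import ModelOutput

_BACKBONES = {
    # name -> (blocks per stage, base channels); stage i halves resolution
    "resnet34": ((3, 4, 6, 3), 64),
    "resnet18": ((2, 2, 2, 2), 64),
    "tiny": ((1, 1), 8),
}


@dataclass(frozen=True)
class ModelConfig:
    n_gauss_branches: int = 4
    backbone: str = "resnet34"
    patch_grid: int = 7
    base_channels: int | None = None  # None -> backbone default
    use_attention: bool = True
    ffn_expansion: int = 2
    pretrained: bool = False  # no offline weight source; must stay False
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in _BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.n_gauss_branches < 0:
            raise ValueError("n_gauss_branches must be >= 0")
        if self.patch_grid < 1:
            raise ValueError("patch_grid must be >= 1")
        if self.pretrained:
            raise ValueError(
                "pretrained initialisation is not available; use random init"
            )

    @property
    def stage_blocks(self) -> tuple[int, ...]:
        return _BACKBONES[self.backbone][0]

    @property
    def channels(self) -> int:
        return self.base_channels or _BACKBONES[self.backbone][1]


# ------------------------------------------------------------------ patches
def patchify(feature_map: np.ndarray, grid: int = 7):
    """Split (C, H, W) into grid*grid patches of (C, ph, pw).

    Sides not divisible by the grid are reflect-padded first. Returns
    ``(patches, (H, W))`` where patches has shape (grid*grid, C, ph, pw).
    """
    fm = np.asarray(feature_map)
    squeeze = fm.ndim == 2
    if squeeze:
        fm = fm[None]
    c, h, w = fm.shape
    ph, pw = -(-h // grid), -(-w // grid)
    pad_h, pad_w = ph * grid - h, pw * grid - w
    if pad_h or pad_w:
        fm = np.pad(fm, ((0, 0), (0, pad_h), (0, pad_w)), mode="reflect")
    patches = (
        fm.reshape(c, grid, ph, grid, pw).transpose(1, 3, 0, 2, 4).reshape(-1, c, ph, pw)
    )
    return patches, (h, w)


def unpatchify(patches: np.ndarray, original_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`patchify`, cropped back to the unpadded region."""
    t, c, ph, pw = patches.shape
    grid = int(round(np.sqrt(t)))
    if grid * grid != t:
        raise ValueError(f"{t} patches do not form a square grid")
    fm = (
        patches.reshape(grid, grid, c, ph, pw)
        .transpose(2, 0, 3, 1, 4)
        .reshape(c, grid * ph, grid * pw)
    )
    h, w = original_shape
    return fm[:, :h, :w]


# ---------------------------------------------------------------- attention
def attention_core(seg_tokens, qk_tokens, lq, lk, lv, d_k: int):
    """Eqs. Q/K from the guiding tokens, V from the segmentation tokens;
    single-head scaled dot-product attention. Token shape (N, T, C)."""
    q = lq(qk_tokens)
    k = lk(qk_tokens)
    v = lv(seg_tokens)
    scores = ag.matmul(q, ag.transpose(k, (0, 2, 1))) * (1.0 / np.sqrt(d_k))
    return ag.matmul(ag.softmax(scores, axis=-1), v)


class _AttentionBlock(Module):
    """Norm -> Attn -> FFN token pipeline shared by the point-guided and
    self-attention variants; only the source of Q/K differs."""

    def __init__(self, channels: int, grid: int, ffn_expansion: int, rng):
        self.channels, self.grid = channels, grid
        self.norm_qk = ag.LayerNorm(channels)
        self.norm_v = ag.LayerNorm(channels)
        self.lq = ag.Linear(channels, channels, rng)
        self.lk = ag.Linear(channels, channels, rng)
        self.lv = ag.Linear(channels, channels, rng)
        self.norm_ffn = ag.LayerNorm(channels)
        self.ffn_in = ag.Linear(channels, ffn_expansion * channels, rng)
        self.ffn_out = ag.Linear(ffn_expansion * channels, channels, rng)

    # -- token helpers -----------------------------------------------------
    def _pad(self, fm):
        n, c, h, w = fm.shape
        g = self.grid
        ph, pw = -(-h // g), -(-w // g)
        fm_p = ag.pad2d_reflect(fm, (0, ph * g - h), (0, pw * g - w))
        return fm_p, (ph, pw)

    def tokens(self, fm_padded, patch_shape):
        n, c, hp, wp = fm_padded.shape
        g, (ph, pw) = self.grid, patch_shape
        x = ag.reshape(fm_padded, (n, c, g, ph, g, pw))
        x = ag.tmean(x, axis=(3, 5))            # (n, c, g, g)
        x = ag.reshape(x, (n, c, g * g))
        return ag.transpose(x, (0, 2, 1))        # (n, T, c)

    def _inject(self, fm, fm_padded, delta_tokens, patch_shape):
        n, c, h, w = fm.shape
        g, (ph, pw) = self.grid, patch_shape
        d = ag.transpose(delta_tokens, (0, 2, 1))
        d = ag.reshape(d, (n, c, g, g))
        d = ag.upsample_nearest(d, (ph, pw))
        return ag.crop2d(fm_padded + d, h, w)

    def _run(self, seg_fm, qk_token_source):
        fm_padded, patch_shape = self._pad(seg_fm)
        t0 = self.tokens(fm_padded, patch_shape)
        attn = attention_core(
            self.norm_v(t0), self.norm_qk(qk_token_source),
            self.lq, self.lk, self.lv, self.channels,
        )
        h = t0 + attn
        h = h + self.ffn_out(ag.relu(self.ffn_in(self.norm_ffn(h))))
        return self._inject(seg_fm, fm_padded, h - t0, patch_shape)


class PointGuidedAttention(_AttentionBlock):
    """Fuse segmentation features with the mean of the k Gaussian features."""

    def __call__(self, seg_fm, gauss_fms):
        if not gauss_fms:
            raise ValueError("point-guided attention needs >= 1 Gaussian feature map")
        shapes = {tuple(f.shape) for f in gauss_fms} | {tuple(seg_fm.shape)}
        if len(shapes) != 1:
            raise ValueError(f"mismatched feature shapes {shapes}")
        token_stacks = []
        for fm in gauss_fms:
            fm_p, ps = self._pad(fm)
            token_stacks.append(self.tokens(fm_p, ps))
        mean_tokens = token_stacks[0]
        for t in token_stacks[1:]:
            mean_tokens = mean_tokens + t
        mean_tokens = mean_tokens * (1.0 / len(token_stacks))
        return self._run(seg_fm, mean_tokens)


class SelfAttention(_AttentionBlock):
    """Within-branch attention: Q, K and V all from the branch's own map."""

    def __call__(self, fm):
        fm_p, ps = self._pad(fm)
        return self._run(fm, self.tokens(fm_p, ps))


# ----------------------------------------------------------------- backbone
class ResidualBlock(Module):
    def __init__(self, c_in, c_out, rng, stride=1):
        self.conv1 = ag.Conv2d(c_in, c_out, 3, rng, stride=stride)
        self.norm1 = ag.GroupNorm(c_out)
        self.conv2 = ag.Conv2d(c_out, c_out, 3, rng)
        self.norm2 = ag.GroupNorm(c_out)
        self.proj = (
            ag.Conv2d(c_in, c_out, 1, rng, stride=stride, padding=0)
            if (stride != 1 or c_in != c_out)
            else None
        )

    def __call__(self, x):
        h = ag.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        skip = self.proj(x) if self.proj is not None else x
        return ag.relu(h + skip)


class Encoder(Module):
    """Residual encoder; returns one feature map per resolution level."""

    def __init__(self, config: ModelConfig, rng):
        c = config.channels
        self.stem = ag.Conv2d(3, c, 3, rng)
        self.stem_norm = ag.GroupNorm(c)
        self.stages = []
        c_in = c
        for i, n_blocks in enumerate(config.stage_blocks):
            c_out = c * (2 ** i)
            blocks = [ResidualBlock(c_in, c_out, rng, stride=2)]
            blocks += [ResidualBlock(c_out, c_out, rng) for _ in range(n_blocks - 1)]
            self.stages.append(blocks)
            c_in = c_out
        self.stage_channels = [c] + [c * (2 ** i) for i in range(len(config.stage_blocks))]

    def __call__(self, x):
        feats = [ag.relu(self.stem_norm(self.stem(x)))]
        h = feats[0]
        for blocks in self.stages:
            for block in blocks:
                h = block(h)
            feats.append(h)
        return feats  # [full res, 1/2, 1/4, ...]


class DecoderLevel(Module):
    """Upsample, concatenate the encoder skip, and convolve."""

    def __init__(self, c_in, c_skip, c_out, rng):
        self.conv = ag.Conv2d(c_in + c_skip, c_out, 3, rng)
        self.norm = ag.GroupNorm(c_out)

    def __call__(self, x, skip):
        x = ag.upsample_nearest(x, 2)
        x = ag.concat([x, skip], axis=1)
        return ag.relu(self.norm(self.conv(x)))


class Decoder(Module):
    def __init__(self, stage_channels, rng, head_channels: int):
        # stage_channels: [stem, s1, ..., sL]; decode from sL back to stem res
        self.levels = []
        c_in = stage_channels[-1]
        for c_skip in reversed(stage_channels[:-1]):
            level = DecoderLevel(c_in, c_skip, c_skip, rng)
            self.levels.append(level)
            c_in = c_skip
        self.head = ag.Conv2d(c_in, head_channels, 1, rng, padding=0)


class SegmentationModel(Module):
    """The complete k+1 decoder model.

    ``forward`` maps a (N, 3, H, W) tensor (values in [0, 1]) to
    2-class softmax segmentation probabilities (N, 2, H, W) and k
    sigmoid Gaussian maps (N, k, H, W). ``predict`` wraps a uint8 RGB
    image into a :class:`~pointseg.core.ModelOutput`.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = Encoder(config, rng)
        ch = self.encoder.stage_channels
        k = config.n_gauss_branches
        self.seg_decoder = Decoder(ch, rng, head_channels=2)
        self.gauss_decoders = [Decoder(ch, rng, head_channels=1) for _ in range(k)]
        self.seg_attention = []
        self.gauss_attention = []
        if config.use_attention and k > 0:
            grid = config.patch_grid
            # one attention block per decoder level; feature channels at the
            # level's *input* (pre-upsample) resolution
            level_channels = [ch[-1]] + list(reversed(ch[1:-1]))
            self.seg_attention = [
                PointGuidedAttention(c, grid, config.ffn_expansion, rng)
                for c in level_channels
            ]
            self.gauss_attention = [
                [SelfAttention(c, grid, config.ffn_expansion, rng) for c in level_channels]
                for _ in range(k)
            ]

    # ------------------------------------------------------------------ fwd
    @property
    def n_gauss_branches(self) -> int:
        return self.config.n_gauss_branches

    def forward(self, x: Tensor):
        feats = self.encoder(x)
        skips = feats[:-1]
        k = self.n_gauss_branches
        attend = bool(self.seg_attention)
        xs_seg = feats[-1]
        xs_gauss = [feats[-1] for _ in range(k)]
        n_levels = len(self.seg_decoder.levels)
        for lvl in range(n_levels):
            skip = skips[n_levels - 1 - lvl]
            if attend:
                g_att = [
                    self.gauss_attention[j][lvl](xs_gauss[j]) for j in range(k)
                ]
                s_att = self.seg_attention[lvl](xs_seg, g_att)
            else:
                g_att, s_att = xs_gauss, xs_seg
            xs_seg = self.seg_decoder.levels[lvl](s_att, skip)
            xs_gauss = [
                self.gauss_decoders[j].levels[lvl](g_att[j], skip) for j in range(k)
            ]
        seg_logits = self.seg_decoder.head(xs_seg)
        seg_probs = ag.softmax(seg_logits, axis=1)
        gauss = None
        if k:
            gauss = ag.concat(
                [ag.sigmoid(self.gauss_decoders[j].head(xs_gauss[j])) for j in range(k)],
                axis=1,
            )
        return seg_probs, gauss

    # ------------------------------------------------------------- inference
    def predict(self, image: np.ndarray) -> ModelOutput:
        """Deterministic full-image prediction for a (H, W, 3) uint8 tile."""
        image = np.asarray(image)
        h, w = image.shape[:2]
        stride = 2 ** len(self.config.stage_blocks)
        pad_h = (-h) % stride
        pad_w = (-w) % stride
        x = image.astype(np.float64) / 255.0
        x = np.pad(x, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
        xt = Tensor(x.transpose(2, 0, 1)[None])
        seg_probs, gauss = self.forward(xt)
        seg_prob = seg_probs.data[0, 1, :h, :w]
        gauss_maps = (
            gauss.data[0, :, :h, :w] if gauss is not None else np.empty((0, h, w))
        )
        return ModelOutput(seg_prob=seg_prob, gauss_maps=gauss_maps)

    # ----------------------------------------------------------- checkpoints
    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))


def build_model(config: ModelConfig) -> SegmentationModel:
    """Construct the trainable model described by ``config``."""
    return SegmentationModel(config)
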
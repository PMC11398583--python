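"""2.5D U-Net with a vision-transformer bottleneck and dual heads.

The network takes a (2N+1, H, W) stack of z-slices as input channels (the
"2.5D" convention: the z dimension is treated like spectral channels, only
the two spatial dimensions are convolved).  A ResNet-style convolutional
encoder downsamples by 2 per level; at the deepest level the feature grid is
flattened into a token sequence, combined with learnable positional
encodings and processed by a small pre-norm transformer.  The tokens are
routed to two heads: an attention-pooled classifier that labels the channel
occupancy (full / partial / empty worm), and a convolutional decoder with
skip connections that produces a per-pixel soft segmentation (worm vs
background).  Long-range context matters here because a worm body spans
thousands of pixels along the channel axis.

Everything is built on :mod:`wormseg.nn` (numpy autograd) and runs on CPU;
full-resolution (5056 x 384) training is possible but slow — the intended
CPU use is small-grid configurations (``NetworkConfig.tiny``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .preprocess import InputTensor

__all__ = ["NetworkConfig", "ModelOutput", "ResidualBlock", "WormSegNet",
           "CLASS_INDEX"]

CLASS_INDEX = {"full": 0, "partial": 1, "empty": 2}


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``n_encoder_layers`` sets the downsampling factor ``s = 2**layers``; the
    padded input height and width must both be divisible by ``s``.
    ``bottleneck_dim`` is the token dimension ``c`` of the transformer
    (default 256), ``ffn_expansion`` the standard 4x feed-forward widening.
    ``max_input_hw`` bounds the learnable positional-encoding tables; any
    input whose bottleneck grid fits inside it is accepted.
    """

    n_encoder_layers: int = 4
    base_features: int = 16
    bottleneck_dim: int = 256
    vit_depth: int = 4
    n_heads: int = 8
    ffn_expansion: int = 4
    n_seg_classes: int = 2
    n_channel_classes: int = 3
    input_planes: int = 3
    dropout: float = 0.0
    norm: str = "group"          # "group" | "none"
    max_input_hw: tuple[int, int] = (5056, 384)

    def __post_init__(self):
        if self.bottleneck_dim % self.n_heads:
            raise ValueError(
                f"bottleneck_dim {self.bottleneck_dim} not divisible by "
                f"n_heads {self.n_heads}"
            )

    @property
    def downsampling(self) -> int:
        return 2**self.n_encoder_layers

    @classmethod
    def tiny(cls, **overrides) -> "NetworkConfig":
        """Small configuration for CPU tests (2 levels, 32-dim tokens)."""
        kw = dict(
            n_encoder_layers=2, base_features=8, bottleneck_dim=32,
            vit_depth=2, n_heads=4, max_input_hw=(512, 64),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class ModelOutput:
    """Per-pixel soft segmentation + per-channel class probabilities.

    ``soft_segmentation``: (B, n_seg_classes, H, W), softmax over classes at
    every pixel.  ``class_probs``: (B, 3) over (full, partial, empty).  The
    pre-softmax tensors are kept for loss computation.
    """

    soft_segmentation: np.ndarray
    class_probs: np.ndarray
    seg_logits: Tensor | None = None
    class_logits: Tensor | None = None


def _norm(cfg: NetworkConfig, channels: int) -> nn.Module:
    if cfg.norm == "group":
        groups = min(8, channels)
        while channels % groups:
            groups -= 1
        return nn.GroupNorm(groups, channels)
    return nn.Identity()


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions with normalization/ReLU and an additive skip.

    The skip is the identity when input and output channel counts match and
    a learned 1x1 projection otherwise; spatial dimensions are preserved.
    """

    def __init__(self, c_in: int, c_out: int, cfg: NetworkConfig,
                 rng: np.random.Generator):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, padding=1)
        self.norm1 = _norm(cfg, c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, padding=1)
        self.norm2 = _norm(cfg, c_out)
        self.proj = (
            nn.Conv2d(c_in, c_out, 1, rng, bias=False) if c_in != c_out
            else nn.Identity()
        )

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return (h + self.proj(x)).relu()


class _ViTBlock(nn.Module):
    """Pre-norm transformer block: LN -> MHSA -> +res, LN -> FFN -> +res."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        c = cfg.bottleneck_dim
        self.ln1 = nn.LayerNorm(c)
        self.attn = nn.MultiHeadSelfAttention(c, cfg.n_heads, rng)
        self.ln2 = nn.LayerNorm(c)
        self.ffn1 = nn.Linear(c, cfg.ffn_expansion * c, rng)
        self.ffn2 = nn.Linear(cfg.ffn_expansion * c, c, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ffn2(self.ffn1(self.ln2(x)).gelu())


class WormSegNet(nn.Module):
    """The full encoder / ViT bottleneck / classifier / decoder network."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        L, base, c = cfg.n_encoder_layers, cfg.base_features, cfg.bottleneck_dim
        self.stem = ResidualBlock(cfg.input_planes, base, cfg, rng)
        self.enc_blocks: list[nn.Module] = []
        self.downs: list[nn.Module] = []
        ch = base
        for _ in range(L):
            self.downs.append(nn.Conv2d(ch, 2 * ch, 2, rng, stride=2))
            self.enc_blocks.append(ResidualBlock(2 * ch, 2 * ch, cfg, rng))
            ch *= 2
        self.to_tokens = nn.Conv2d(ch, c, 1, rng)
        gh = cfg.max_input_hw[0] // cfg.downsampling
        gw = cfg.max_input_hw[1] // cfg.downsampling
        self.pos_rows = nn.Parameter(rng.normal(0, 0.02, size=(gh, c)))
        self.pos_cols = nn.Parameter(rng.normal(0, 0.02, size=(gw, c)))
        self.vit_blocks = [_ViTBlock(cfg, rng) for _ in range(cfg.vit_depth)]
        self.pool = nn.AttentionPool(c, cfg.n_heads, rng)
        self.cls_head1 = nn.Linear(c, c, rng)
        self.cls_head2 = nn.Linear(c, cfg.n_channel_classes, rng)
        self.from_tokens = nn.Conv2d(c, ch, 1, rng)
        self.ups: list[nn.Module] = []
        self.dec_blocks: list[nn.Module] = []
        for _ in range(L):
            self.ups.append(nn.ConvTranspose2d(ch, ch // 2, 2, rng, stride=2))
            # after concatenating the skip the block sees ch channels again
            self.dec_blocks.append(ResidualBlock(ch, ch // 2, cfg, rng))
            ch //= 2
        self.seg_head1 = nn.Conv2d(base, base, 1, rng)
        self.seg_head2 = nn.Conv2d(base, cfg.n_seg_classes, 1, rng)
        self._grid: tuple[int, int] | None = None  # set by encode()

    # -- pieces ---------------------------------------------------------------
    def encode(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Run the convolutional encoder; returns bottleneck + skip features.

        Skip ℓ has spatial dims (H/2^ℓ, W/2^ℓ) for ℓ = 0..L-1.
        """
        s = self.cfg.downsampling
        _, _, h, w = x.shape
        if h % s or w % s:
            raise ValueError(
                f"input {h}x{w} not divisible by the downsampling factor {s}; "
                f"pad to multiples of {s}"
            )
        skips = []
        f = self.stem(x)
        for down, block in zip(self.downs, self.enc_blocks):
            skips.append(f)
            f = block(down(f))
        self._grid = (f.shape[2], f.shape[3])
        return self.to_tokens(f), skips

    def tokenize(self, feat: Tensor) -> Tensor:
        """Flatten the (B, c, h, w) bottleneck grid to (B, h*w, c) tokens.

        Row-major order (y outer); learnable factorized positional encodings
        (row table + column table, cropped to the grid) are added.
        """
        b, c, h, w = feat.shape
        if h > self.pos_rows.shape[0] or w > self.pos_cols.shape[0]:
            raise ValueError(
                f"bottleneck grid {h}x{w} exceeds positional-encoding tables "
                f"{self.pos_rows.shape[0]}x{self.pos_cols.shape[0]}; "
                "increase max_input_hw"
            )
        tokens = feat.reshape(b, c, h * w).transpose(0, 2, 1)
        pos = (
            self.pos_rows[:h].reshape(h, 1, c)
            + self.pos_cols[:w].reshape(1, w, c)
        ).reshape(1, h * w, c)
        return tokens + pos

    def detokenize(self, tokens: Tensor, grid: tuple[int, int]) -> Tensor:
        h, w = grid
        b = tokens.shape[0]
        return tokens.transpose(0, 2, 1).reshape(
            b, self.cfg.bottleneck_dim, h, w
        )

    def vit_forward(self, tokens: Tensor) -> Tensor:
        """Run the transformer blocks; sequence length and dim preserved."""
        for blk in self.vit_blocks:
            tokens = blk(tokens)
        return tokens

    def classify(self, tokens: Tensor) -> Tensor:
        """Attention-pool the tokens with one seed vector -> 3 class logits."""
        pooled = self.pool(tokens)
        return self.cls_head2(self.cls_head1(pooled).relu())

    def decode(self, tokens: Tensor, skips: list[Tensor],
               grid: tuple[int, int] | None = None) -> Tensor:
        """Mirror of the encoder with skip concatenation -> seg logits."""
        grid = grid or self._grid
        f = self.from_tokens(self.detokenize(tokens, grid))
        for up, block, skip in zip(self.ups, self.dec_blocks,
                                   reversed(skips)):
            f = up(f)
            if f.shape != skip.shape:
                raise ValueError(
                    f"decoder feature {f.shape} does not match skip "
                    f"{skip.shape}"
                )
            f = block(nn.concatenate([f, skip], axis=1))
        return self.seg_head2(self.seg_head1(f).relu())

    # -- composition ----------------------------------------------------------
    def forward(self, x) -> ModelOutput:
        """Full forward pass on a batch.

        ``x`` may be a numpy array of shape (B, 2N+1, H, W), a single
        :class:`~wormseg.preprocess.InputTensor`, or a list of them.
        """
        x = self._as_batch(x)
        feat, skips = self.encode(x)
        tokens = self.vit_forward(self.tokenize(feat))
        class_logits = self.classify(tokens)
        seg_logits = self.decode(tokens, skips)
        return ModelOutput(
            soft_segmentation=seg_logits.softmax(axis=1).data,
            class_probs=class_logits.softmax(axis=-1).data,
            seg_logits=seg_logits,
            class_logits=class_logits,
        )

    @staticmethod
    def _as_batch(x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        if isinstance(x, InputTensor):
            return Tensor(x.planes[None])
        if isinstance(x, (list, tuple)):
            return Tensor(np.stack([t.planes for t in x]))
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        return Tensor(x)
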
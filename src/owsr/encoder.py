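"""Latent feature-grid encoder: a baseline EDSR-style residual CNN.

The encoder maps an H x W x 3 image in [0, 1] to an H x W x D feature grid:
a 3x3 head convolution, ``n_resblocks`` residual blocks (conv-ReLU-conv with
an identity skip and no batch normalization), a 3x3 tail convolution, and a
global skip from the head output.  There is no upsampling head — the grid
stays at input resolution and all upscaling happens in the continuous
decoder.

Defaults (16 blocks, depth 64) are the standard baseline; a reduced
configuration (4 blocks, depth 16) is first-class for CPU-scale work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["EncoderConfig", "EncoderParams", "init_encoder", "encode", "encode_batch"]


@dataclass
class EncoderConfig:
    n_resblocks: int = 16
    n_feats: int = 64
    kernel_size: int = 3
    res_scale: float = 1.0
    mean_shift: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self):
        if self.n_resblocks < 1 or self.n_feats < 1:
            raise ValueError("encoder needs >=1 residual block and >=1 feature")
        if self.kernel_size != 3:
            raise ValueError("only 3x3 kernels are supported")


@dataclass
class EncoderParams:
    head_w: Tensor
    head_b: Tensor
    blocks: list  # [(w1, b1, w2, b2), ...]
    tail_w: Tensor
    tail_b: Tensor
    config: EncoderConfig = field(default_factory=EncoderConfig)

    def parameters(self) -> list[Tensor]:
        out = [self.head_w, self.head_b]
        for w1, b1, w2, b2 in self.blocks:
            out += [w1, b1, w2, b2]
        out += [self.tail_w, self.tail_b]
        return out


def _he_conv(rng: np.random.Generator, f_out: int, f_in: int) -> Tensor:
    std = np.sqrt(2.0 / (f_in * 9))
    return Tensor(rng.normal(0.0, std, size=(f_out, f_in, 3, 3)), requires_grad=True)


def init_encoder(cfg: EncoderConfig, rng: np.random.Generator) -> EncoderParams:
    d = cfg.n_feats
    blocks = []
    for _ in range(cfg.n_resblocks):
        blocks.append((_he_conv(rng, d, d), Tensor(np.zeros(d), requires_grad=True),
                       _he_conv(rng, d, d), Tensor(np.zeros(d), requires_grad=True)))
    return EncoderParams(
        head_w=_he_conv(rng, d, 3),
        head_b=Tensor(np.zeros(d), requires_grad=True),
        blocks=blocks,
        tail_w=_he_conv(rng, d, d),
        tail_b=Tensor(np.zeros(d), requires_grad=True),
        config=cfg,
    )


def encode_batch(imgs, params: EncoderParams) -> Tensor:
    """Encode a (B, H, W, 3) batch to a (B, H, W, D) feature-grid tensor."""
    cfg = params.config
    x = imgs if isinstance(imgs, Tensor) else Tensor(np.asarray(imgs, dtype=np.float64))
    if x.data.ndim != 4 or x.data.shape[-1] != 3:
        raise ValueError("encoder input must be (B, H, W, 3); replicate "
                         "grayscale to 3 channels upstream")
    shift = Tensor(np.asarray(cfg.mean_shift, dtype=np.float64))
    x = (x - shift).transpose(0, 3, 1, 2)          # NCHW
    head = ad.conv3x3(x, params.head_w, params.head_b)
    y = head
    for w1, b1, w2, b2 in params.blocks:
        r = ad.conv3x3(ad.relu(ad.conv3x3(y, w1, b1)), w2, b2)
        y = y + cfg.res_scale * r
    y = ad.conv3x3(y, params.tail_w, params.tail_b) + head
    return y.transpose(0, 2, 3, 1)                 # (B, H, W, D)


def encode(img, params: EncoderParams) -> Tensor:
    """Encode a single (H, W, 3) image to an (H, W, D) feature-grid tensor."""
    arr = img.data if isinstance(img, Tensor) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected an (H, W, 3) image")
    return encode_batch(arr[None], params)[0]
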
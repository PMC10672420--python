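"""End-to-end model: encode once, decode anywhere.

A :class:`ModelBundle` holds the encoder parameters, the overlapping-window
parameters and the region size M.  ``upscale`` encodes the low-resolution
image once and evaluates the continuous decoder at every pixel center of the
target raster, in chunks; because each query is decoded independently and
the dense layers use einsum, the result is bitwise identical for any chunk
size.  One bundle serves every scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import grid, owindow
from .autodiff import Tensor, take_rows
from .encoder import EncoderConfig, EncoderParams, encode
from .owindow import OWParams

__all__ = ["ModelBundle", "init_model", "predict_point", "predict_points",
           "upscale", "round_half_away"]

FORMAT_VERSION = "owsr-checkpoint-1"


@dataclass
class ModelBundle:
    encoder: EncoderParams
    ow: OWParams
    m: int
    version: str = FORMAT_VERSION

    def __post_init__(self):
        if self.m != self.ow.m:
            raise ValueError(f"bundle M={self.m} inconsistent with "
                             f"window parameters (M={self.ow.m})")
        if self.encoder.config.n_feats != self.ow.depth:
            raise ValueError("encoder depth and window-parameter depth differ")

    def parameters(self):
        return self.encoder.parameters() + self.ow.parameters()


def init_model(enc_cfg: EncoderConfig | None = None, m: int = 6,
               mlp_hidden=(256, 256, 256, 256),
               rng: np.random.Generator | None = None) -> ModelBundle:
    """Freshly initialized model (average-init windows, He-init convs/MLP)."""
    from .encoder import init_encoder
    from .owindow import init_ow_params

    rng = np.random.default_rng(0) if rng is None else rng
    enc_cfg = enc_cfg or EncoderConfig()
    enc = init_encoder(enc_cfg, rng)
    ow = owindow.init_ow_params(m, enc_cfg.n_feats, mlp_hidden=mlp_hidden, rng=rng)
    return ModelBundle(encoder=enc, ow=ow, m=m)


def decode_queries(psi_flat: Tensor, grid_shape: tuple[int, int],
                   coords: np.ndarray, model: ModelBundle,
                   row_offset: int = 0) -> Tensor:
    """Decode a batch of queries against a flattened (rows x D) feature grid.

    ``row_offset`` shifts the gather rows, letting several images share one
    stacked row tensor during training.
    """
    rows, offsets = grid.semi_local_indices(coords, grid_shape, model.m)
    region = take_rows(psi_flat, rows + row_offset)          # (N, M, M, D)
    t = owindow.ow_reduce(region, model.ow)                  # (N, M/2, M/2, D)
    win = owindow.select_center_window(t, offsets)           # (N, 2, 2, D)
    return owindow.decode_rgb(win, offsets, model.ow.mlp)    # (N, 3)


def predict_points(psi: Tensor, coords: np.ndarray, model: ModelBundle) -> Tensor:
    """RGB predictions at ``coords`` ((N, 2) normalized) from an (H, W, D) grid."""
    h, w, d = psi.data.shape
    return decode_queries(psi.reshape((h * w, d)), (h, w),
                          np.asarray(coords, dtype=np.float64), model)


def predict_point(psi: Tensor, coord: tuple[float, float],
                  model: ModelBundle) -> np.ndarray:
    """Raw (unclamped) RGB at a single normalized coordinate."""
    return predict_points(psi, np.asarray([coord]), model).data[0]


def round_half_away(x: float) -> int:
    """Round positive reals half-away-from-zero (58 for 57.5)."""
    return int(np.floor(x + 0.5))


def target_size(hr_shape: tuple[int, int], scale: float | None,
                size: tuple[int, int] | None) -> tuple[int, int]:
    if size is not None:
        x, y = int(size[0]), int(size[1])
        if x < 1 or y < 1:
            raise ValueError("target size must be at least 1x1")
        return x, y
    if scale is None or scale <= 0:
        raise ValueError("need a positive scale factor or an explicit size")
    return round_half_away(scale * hr_shape[0]), round_half_away(scale * hr_shape[1])


def upscale(img_lr: np.ndarray, model: ModelBundle, scale: float | None = None,
            size: tuple[int, int] | None = None, chunk: int = 4096) -> np.ndarray:
    """Upscale an (H, W, 3) image in [0, 1] to any real factor or target size.

    Encodes once, then decodes every target pixel center in chunks of
    ``chunk`` queries; output clamped to [0, 1].
    """
    img_lr = np.asarray(img_lr, dtype=np.float64)
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    x, y = target_size(img_lr.shape[:2], scale, size)
    psi = encode(img_lr, model.encoder)
    h, w, d = psi.data.shape
    psi_flat = psi.reshape((h * w, d))
    rr, cc = np.meshgrid(np.arange(x), np.arange(y), indexing="ij")
    coords = np.stack([(rr.ravel() + 0.5) / x, (cc.ravel() + 0.5) / y], axis=1)
    out = np.empty((x * y, 3))
    for start in range(0, coords.shape[0], chunk):
        part = coords[start:start + chunk]
        out[start:start + part.shape[0]] = decode_queries(
            psi_flat, (h, w), part, model).data
    return np.clip(out.reshape(x, y, 3), 0.0, 1.0)
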
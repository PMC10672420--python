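"""Overlapping-window reduction of a semi-local region and the MLP decoder.

Given the M x M x D semi-local block S around a query point, four windows of
side m-1 sit at the four corners of the current m x m block; each corner
crop is weighted elementwise by a learnable tensor and the four weighted
crops are summed, shrinking the block by one cell per iteration.  The
cascade runs window sizes M-1, M-2, ..., M/2 (M/2 iterations), so for M = 6
the sizes are 5, 4, 3 and the result is 3 x 3 x D.  A final 2 x 2 window is
then chosen *centered on the query* (steered by the query's sub-cell
offset), flattened, concatenated with that offset, and decoded to RGB by a
small MLP.

Weights are distinct per corner and per iteration.  With the default
initialization (all corner weights 1/4) the cascade is a local averaging
operator: a constant region passes through unchanged.

All operations are differentiable and batched over queries; elementwise
arithmetic and einsum-based dense layers keep results bitwise independent of
the batch partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "OWParams",
    "init_ow_params",
    "window_sizes",
    "ow_step",
    "ow_reduce",
    "select_center_window",
    "decode_rgb",
]

# corner order everywhere: top-left, top-right, bottom-left, bottom-right
N_CORNERS = 4


def window_sizes(m: int) -> list[int]:
    """Window sizes of the cascade for region size ``m``: m-1 down to m//2."""
    if m < 4 or m % 2:
        raise ValueError(f"region size M must be an even integer >= 4, got {m}")
    return list(range(m - 1, m // 2 - 1, -1))


@dataclass
class OWParams:
    """Per-iteration corner weights plus the MLP decoder parameters.

    ``window_weights[i]`` has shape (4, s_i, s_i, D) with s_i the i-th entry
    of :func:`window_sizes`; ``mlp`` is a list of (W, b) pairs, input width
    4*D + 2 (flattened 2x2 window plus the query offset), output width 3.
    """

    m: int
    depth: int
    window_weights: list = field(default_factory=list)
    mlp: list = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        out = list(self.window_weights)
        for w, b in self.mlp:
            out += [w, b]
        return out

    @property
    def mlp_hidden(self) -> tuple[int, ...]:
        return tuple(w.shape[1] for w, _ in self.mlp[:-1])


def init_ow_params(m: int, depth: int, mlp_hidden=(256, 256, 256, 256),
                   rng: np.random.Generator | None = None) -> OWParams:
    """Average-preserving init: corner weights 1/4, He-initialized MLP."""
    rng = np.random.default_rng(0) if rng is None else rng
    weights = [Tensor(np.full((N_CORNERS, s, s, depth), 0.25), requires_grad=True)
               for s in window_sizes(m)]
    sizes = [4 * depth + 2, *mlp_hidden, 3]
    mlp = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        std = np.sqrt(2.0 / fan_in)
        mlp.append((Tensor(rng.normal(0.0, std, size=(fan_in, fan_out)),
                           requires_grad=True),
                    Tensor(np.zeros(fan_out), requires_grad=True)))
    return OWParams(m=m, depth=depth, window_weights=weights, mlp=mlp)


def _batched(t) -> tuple[Tensor, bool]:
    t = ad.as_tensor(t)
    if t.data.ndim == 3:
        return t.reshape((1,) + t.data.shape), False
    if t.data.ndim == 4:
        return t, True
    raise ValueError("expected (m, m, D) or (N, m, m, D)")


def ow_step(t, corner_weights) -> Tensor:
    """One cascade iteration: four weighted corner crops of side m-1, summed.

    ``t``: (m, m, D) or (N, m, m, D); ``corner_weights``: (4, m-1, m-1, D).
    """
    t, batched = _batched(t)
    w = ad.as_tensor(corner_weights)
    m = t.data.shape[1]
    if m < 3:
        raise ValueError("ow_step needs window size >= 3")
    s = m - 1
    if w.data.shape != (N_CORNERS, s, s, t.data.shape[3]):
        raise ValueError(f"corner weights must be (4, {s}, {s}, {t.data.shape[3]}), "
                         f"got {w.data.shape}")
    out = (t[:, :s, :s, :] * w[0] + t[:, :s, 1:, :] * w[1]
           + t[:, 1:, :s, :] * w[2] + t[:, 1:, 1:, :] * w[3])
    return out if batched else out[0]


def ow_reduce(region, params: OWParams) -> Tensor:
    """Full cascade: sizes M-1 ... M/2; output side M/2.

    ``region``: (M, M, D) or (N, M, M, D) (a SemiLocalRegion's ``values``).
    """
    values = getattr(region, "values", region)
    t, batched = _batched(values)
    m = t.data.shape[1]
    expected = window_sizes(params.m)
    if m != params.m or t.data.shape[3] != params.depth:
        raise ValueError(f"region {t.data.shape[1:]} does not match parameters "
                         f"(M={params.m}, D={params.depth})")
    for s, w in zip(expected, params.window_weights, strict=True):
        t = ow_step(t, w)
    return t if batched else t[0]


def _center_origin(m: int, offset_component: np.ndarray) -> np.ndarray:
    c = (m - 1) // 2
    return np.clip(c - 1 + (offset_component > 0), 0, m - 2)


def select_center_window(t, offset) -> Tensor:
    """The 2 x 2 window centered on the query inside an m x m block.

    The window's top-left index along each axis is c - 1 + [offset > 0] with
    c = floor((m-1)/2), clamped to [0, m-2]; for m = 2 this is the identity.
    Accepts a single block with a single (du, dv) offset, or a batch of
    blocks with per-query offsets.
    """
    t, batched = _batched(t)
    m = t.data.shape[1]
    if m < 2:
        raise ValueError("center window needs a block of side >= 2")
    off = np.atleast_2d(np.asarray(offset, dtype=np.float64))
    n, d = t.data.shape[0], t.data.shape[3]
    i0 = _center_origin(m, off[:, 0])
    j0 = _center_origin(m, off[:, 1])
    flat = t.reshape((n * m * m, d))
    base = np.arange(n, dtype=np.intp) * m * m
    di = np.array([0, 0, 1, 1], dtype=np.intp)
    dj = np.array([0, 1, 0, 1], dtype=np.intp)
    rows = (base[:, None] + (i0[:, None] + di) * m + (j0[:, None] + dj))
    win = ad.take_rows(flat, rows).reshape((n, 2, 2, d))
    return win if batched else win[0]


def decode_rgb(win, offset, mlp) -> Tensor:
    """Flatten the 2 x 2 x D window, append the query offset, run the MLP.

    Hidden layers are ReLU, the head is linear; outputs are raw (training
    clips nothing — clamping to [0, 1] happens at inference).
    """
    win, batched = _batched(win)
    n, d = win.data.shape[0], win.data.shape[3]
    if not np.all(np.isfinite(win.data)):
        raise ValueError("non-finite decoder input")
    off = np.atleast_2d(np.asarray(offset, dtype=np.float64))
    x = ad.concat([win.reshape((n, 4 * d)), Tensor(off)], axis=1)
    for i, (w, b) in enumerate(mlp):
        x = ad.linear(x, w, b)
        if i < len(mlp) - 1:
            x = ad.relu(x)
    return x if batched else x[0]
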
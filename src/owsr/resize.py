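"""Separable bicubic resampling (Keys kernel, a = -0.5) with antialiasing.

Used both to synthesize the low-resolution training inputs (bicubic
degradation) and as the classical upscaling baseline at evaluation.

Output pixel centers are aligned with source pixel centers
(u = (i + 0.5) * n_in / n_out - 0.5).  When downscaling with antialiasing
the kernel support is widened by the scale ratio.  Per-row weights are
normalized to sum to one, and the boundary is treated as periodic by
default, which keeps the operator exactly mean-preserving (a "replicate"
boundary is available as an option).  Dialects of bicubic resampling differ
between libraries; this one is pinned down so its values are reproducible in
closed form.
"""

from __future__ import annotations

import numpy as np

__all__ = ["keys_kernel", "resample_matrix", "bicubic_resize"]


def keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel; support (-2, 2), k(0)=1, k(±1)=k(±2)=0."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    near = t <= 1
    far = (t > 1) & (t < 2)
    out[near] = (a + 2) * t[near] ** 3 - (a + 3) * t[near] ** 2 + 1
    out[far] = a * (t[far] ** 3 - 5 * t[far] ** 2 + 8 * t[far] - 4)
    return out


def resample_matrix(n_in: int, n_out: int, antialias: bool = True,
                    a: float = -0.5, edge: str = "wrap") -> np.ndarray:
    """Dense (n_out, n_in) row-stochastic resampling matrix for one axis."""
    if n_in < 1 or n_out < 1:
        raise ValueError("resample needs at least one sample on each axis")
    if edge not in ("wrap", "replicate"):
        raise ValueError(f"unknown edge mode {edge!r}")
    ratio = n_in / n_out
    ss = max(1.0, ratio) if antialias else 1.0
    half = int(np.ceil(2 * ss))
    u = (np.arange(n_out) + 0.5) * ratio - 0.5                # (n_out,)
    j = np.floor(u)[:, None] + np.arange(-half + 1, half + 1)  # (n_out, taps)
    w = keys_kernel((u[:, None] - j) / ss, a=a)
    w /= w.sum(axis=1, keepdims=True)
    ji = j.astype(np.intp)
    ji = np.mod(ji, n_in) if edge == "wrap" else np.clip(ji, 0, n_in - 1)
    mat = np.zeros((n_out, n_in))
    np.add.at(mat, (np.repeat(np.arange(n_out), ji.shape[1]), ji.ravel()), w.ravel())
    return mat


def bicubic_resize(img: np.ndarray, target: tuple[int, int],
                   antialias: bool = True, a: float = -0.5,
                   edge: str = "wrap") -> np.ndarray:
    """Resize an (H, W[, C]) image in [0, 1] to ``target`` = (X, Y); clipped."""
    img = np.asarray(img, dtype=np.float64)
    x, y = int(target[0]), int(target[1])
    if x < 1 or y < 1:
        raise ValueError(f"degenerate target size {target}")
    squeeze = img.ndim == 2
    if squeeze:
        img = img[:, :, None]
    h, w = img.shape[:2]
    mr = resample_matrix(h, x, antialias=antialias, a=a, edge=edge)
    mc = resample_matrix(w, y, antialias=antialias, a=a, edge=edge)
    out = np.tensordot(mr, img, axes=([1], [0]))              # (X, W, C)
    out = np.tensordot(out, mc, axes=([1], [1]))              # (X, C, Y)
    out = np.clip(out.transpose(0, 2, 1), 0.0, 1.0)
    return out[:, :, 0] if squeeze else out
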
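"""Continuous coordinate system and semi-local feature sampling.

The image and its latent feature grid both live on the unit square with
cell-centered pixels: cell (p, q) of a P x Q grid is centered at
((p + 0.5)/P, (q + 0.5)/Q), 0-based and row-major.  A query pixel of the
high-resolution target maps to the *same* normalized coordinate in the
feature grid, and the decoder reads an M x M block of latent vectors gathered
around that point by nearest-cell (Euclidean) lookup.

Conventions fixed here and relied on everywhere else:

* sample-grid offsets are the M half-integers {-(M-1)/2, ..., +(M-1)/2}
  times the cell size, so the grid is point-symmetric about the query and
  adjacent samples are exactly one cell apart;
* coordinates are clamped into [0, 1]^2 before lookup (replicate padding at
  the borders);
* at an exact tie between two cell centers the smaller index wins, which
  makes the query's offset from its nearest cell center lie in (-0.5, 0.5]
  cell units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureMap",
    "SemiLocalRegion",
    "hr_to_feature_coord",
    "build_sample_grid",
    "nearest_cell_lookup",
    "nearest_cells",
    "semi_local_indices",
    "extract_semi_local",
]


@dataclass
class FeatureMap:
    """A P x Q x D latent grid with derived cell sizes (1/P, 1/Q)."""

    values: np.ndarray  # (P, Q, D)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("feature map must be (P, Q, D)")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature map contains non-finite values")
        self.values = v

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[0], self.values.shape[1]

    @property
    def depth(self) -> int:
        return self.values.shape[2]

    @property
    def cell_size(self) -> tuple[float, float]:
        p, q = self.grid_shape
        return 1.0 / p, 1.0 / q


@dataclass
class SemiLocalRegion:
    """M x M x D feature block around a query plus its sub-cell offset."""

    values: np.ndarray          # (M, M, D)
    center: tuple[float, float]
    offset: tuple[float, float]  # cell units, each in (-0.5, 0.5]


def _check_m(m: int) -> None:
    if m < 4 or m % 2 != 0:
        raise ValueError(f"region size M must be an even integer >= 4, got {m}")


def hr_to_feature_coord(hr_index: tuple[int, int],
                        hr_shape: tuple[int, int]) -> tuple[float, float]:
    """Normalized coordinate of HR pixel center (r, c) in an X x Y image.

    Because image and feature grid share the unit square, this coordinate is
    directly the query point in the feature grid.
    """
    r, c = hr_index
    x, y = hr_shape
    if not (0 <= r < x and 0 <= c < y):
        raise ValueError(f"pixel index {hr_index} outside image of shape {hr_shape}")
    return (r + 0.5) / x, (c + 0.5) / y


def grid_offsets(m: int) -> np.ndarray:
    """The M symmetric half-integer offsets, in cell units."""
    return np.arange(m, dtype=np.float64) - (m - 1) / 2.0


def build_sample_grid(center: tuple[float, float], m: int,
                      cell_size: tuple[float, float]) -> np.ndarray:
    """M x M x 2 array of sample coordinates, symmetric about ``center``."""
    _check_m(m)
    offs = grid_offsets(m)
    u = center[0] + offs * cell_size[0]
    v = center[1] + offs * cell_size[1]
    coords = np.empty((m, m, 2))
    coords[:, :, 0] = u[:, None]
    coords[:, :, 1] = v[None, :]
    return coords


def nearest_cells(coords: np.ndarray,
                  grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-cell lookup; ``coords[..., 0]`` = u, ``[..., 1]`` = v.

    Coordinates are clamped to [0, 1]^2 first; exact ties go to the smaller
    index (ceil(u*P) - 1 rather than floor(u*P), identical off the cell
    boundaries).
    """
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite query coordinate")
    p_n, q_n = grid_shape
    u = np.clip(coords[..., 0], 0.0, 1.0)
    v = np.clip(coords[..., 1], 0.0, 1.0)
    p = np.clip(np.ceil(u * p_n).astype(np.intp) - 1, 0, p_n - 1)
    q = np.clip(np.ceil(v * q_n).astype(np.intp) - 1, 0, q_n - 1)
    return p, q


def nearest_cell_lookup(coord: tuple[float, float],
                        grid_shape: tuple[int, int]) -> tuple[int, int]:
    """Cell whose center is Euclidean-closest to ``coord`` (after clamping)."""
    p, q = nearest_cells(np.asarray(coord, dtype=np.float64), grid_shape)
    return int(p), int(q)


def center_offsets(coords: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Signed displacement of each query from its nearest cell center, in
    cell units; components lie in (-0.5, 0.5]."""
    coords = np.asarray(coords, dtype=np.float64)
    p_n, q_n = grid_shape
    p, q = nearest_cells(coords, grid_shape)
    du = np.clip(coords[..., 0], 0.0, 1.0) * p_n - (p + 0.5)
    dv = np.clip(coords[..., 1], 0.0, 1.0) * q_n - (q + 0.5)
    return np.stack([du, dv], axis=-1)


def semi_local_indices(coords: np.ndarray, grid_shape: tuple[int, int],
                       m: int) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of the M x M gather for a batch of queries.

    Parameters
    ----------
    coords : (N, 2) normalized query coordinates.
    grid_shape : (P, Q) of the feature grid.
    m : region side length (even, >= 4).

    Returns
    -------
    rows : (N, M, M) intp — flat indices into the row-major (P*Q, D) grid.
    offsets : (N, 2) — sub-cell offset of each query, in cell units.
    """
    _check_m(m)
    coords = np.asarray(coords, dtype=np.float64)
    p_n, q_n = grid_shape
    offs = grid_offsets(m)
    u = coords[:, 0:1] + offs[None, :] / p_n          # (N, M)
    v = coords[:, 1:2] + offs[None, :] / q_n
    pu = np.clip(np.ceil(np.clip(u, 0.0, 1.0) * p_n).astype(np.intp) - 1, 0, p_n - 1)
    qv = np.clip(np.ceil(np.clip(v, 0.0, 1.0) * q_n).astype(np.intp) - 1, 0, q_n - 1)
    rows = pu[:, :, None] * q_n + qv[:, None, :]      # (N, M, M)
    return rows, center_offsets(coords, grid_shape)


def extract_semi_local(psi: FeatureMap, center: tuple[float, float],
                       m: int) -> SemiLocalRegion:
    """Gather the M x M x D semi-local feature block around ``center``."""
    rows, offsets = semi_local_indices(
        np.asarray([center], dtype=np.float64), psi.grid_shape, m)
    flat = psi.values.reshape(-1, psi.depth)
    return SemiLocalRegion(values=flat[rows[0]],
                           center=(float(center[0]), float(center[1])),
                           offset=(float(offsets[0, 0]), float(offsets[0, 1])))
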
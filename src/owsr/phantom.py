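"""Synthetic OCT-angiography-like fixtures and analytic test images.

Real OCT-A en-face angiograms show bright, branching, curvilinear vessels
(capillaries about 1-4 px wide at typical sampling) over a dark background
with low-frequency perfusion texture, corrupted by multiplicative speckle.
The phantom generator emulates exactly those features so that training,
inference and every test run without any external dataset:

* background: a base level plus Gaussian-smoothed low-frequency texture;
* vessels: random branching trees of smoothly curving polylines, rendered
  with Gaussian cross-sections whose width tapers down the tree;
* speckle: unit-mean multiplicative gamma noise (variance 1/shape), the
  standard surrogate for coherent-imaging speckle.

The generator also returns the clean (noise-free) render and the centerline
mask, which oracle-style tests use; it makes no claim of physical realism
(no flow dynamics, projection artifacts or motion lines).

Analytic images (constant / gradient / sinusoid) provide closed-form
fixtures for deterministic numerical tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "PhantomRender", "gen_vessel_phantom",
           "render_vessel_phantom", "gen_analytic_image", "make_fixture_dataset"]


@dataclass
class PhantomSpec:
    size: tuple[int, int] = (96, 96)
    n_trees: int = 3
    branch_prob: float = 0.35          # per growth segment
    width_range: tuple[float, float] = (1.0, 4.0)   # px, root width
    vessel_gain: float = 0.7
    background_level: float = 0.10
    background_texture: float = 0.08   # amplitude of the low-frequency texture
    background_sigma: float = 8.0      # px, smoothing of the texture
    speckle_shape: float = 40.0        # gamma shape; var = 1/shape
    seed: int = 0

    def __post_init__(self):
        if min(self.size) < 8:
            raise ValueError("phantom must be at least 8x8")
        if self.width_range[0] <= 0 or self.width_range[1] < self.width_range[0]:
            raise ValueError("width_range must be positive and ordered")
        if self.speckle_shape <= 0 or self.background_sigma <= 0:
            raise ValueError("speckle_shape and background_sigma must be positive")


@dataclass
class PhantomRender:
    image: np.ndarray   # (H, W, 3) in [0, 1], speckled
    clean: np.ndarray   # (H, W, 3) in [0, 1], noise-free
    mask: np.ndarray    # (H, W) bool, vessel centerlines


def _grow_tree(rng: np.random.Generator, h: int, w: int,
               width0: float, branch_prob: float,
               canvas: np.ndarray, mask: np.ndarray, depth: int = 0) -> None:
    """Grow one (sub)tree of curving segments, stamping Gaussian profiles."""
    # start on a border (roots) or wherever the caller placed us (branches)
    side = rng.integers(4)
    if side == 0:
        pos = np.array([0.0, rng.uniform(0, w)])
    elif side == 1:
        pos = np.array([h - 1.0, rng.uniform(0, w)])
    elif side == 2:
        pos = np.array([rng.uniform(0, h), 0.0])
    else:
        pos = np.array([rng.uniform(0, h), w - 1.0])
    heading = np.arctan2(h / 2 - pos[0], w / 2 - pos[1])
    _grow_branch(rng, h, w, pos, heading, width0, branch_prob, canvas, mask, depth)


def _grow_branch(rng, h, w, pos, heading, width, branch_prob,
                 canvas, mask, depth) -> None:
    n_steps = int(rng.integers(max(h, w) // 2, int(1.5 * max(h, w))))
    step = 1.0
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.15)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if not (0 <= pos[0] < h and 0 <= pos[1] < w):
            return
        _stamp(canvas, mask, pos, width)
        if depth < 3 and rng.random() < branch_prob * 0.1:
            child_heading = heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.1)
            _grow_branch(rng, h, w, pos.copy(), child_heading,
                         max(0.6, width * rng.uniform(0.5, 0.8)),
                         branch_prob, canvas, mask, depth + 1)
        width = max(0.6, width * 0.999)  # gentle taper along the vessel


def _stamp(canvas: np.ndarray, mask: np.ndarray, pos: np.ndarray,
           width: float) -> None:
    h, w = canvas.shape
    sigma = width / 2.0
    rad = max(1, int(np.ceil(3 * sigma)))
    r0 = min(h - 1, max(0, int(round(pos[0]))))
    c0 = min(w - 1, max(0, int(round(pos[1]))))
    rs = slice(max(0, r0 - rad), min(h, r0 + rad + 1))
    cs = slice(max(0, c0 - rad), min(w, c0 + rad + 1))
    rr, cc = np.mgrid[rs, cs]
    d2 = (rr - pos[0]) ** 2 + (cc - pos[1]) ** 2
    np.maximum(canvas[rs, cs], np.exp(-d2 / (2 * sigma ** 2)), out=canvas[rs, cs])
    mask[r0, c0] = True


def render_vessel_phantom(spec: PhantomSpec) -> PhantomRender:
    """Render a phantom plus its clean version and centerline mask."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    texture = rng.standard_normal((h, w))
    texture = gaussian_filter(texture, sigma=spec.background_sigma, mode="wrap")
    span = np.ptp(texture)
    if span > 0:
        texture = (texture - texture.min()) / span
    background = spec.background_level + spec.background_texture * texture

    vessels = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_trees):
        width0 = rng.uniform(*spec.width_range)
        _grow_tree(rng, h, w, width0, spec.branch_prob, vessels, mask)

    clean = np.clip(background + spec.vessel_gain * vessels, 0.0, 1.0)
    speckle = rng.gamma(shape=spec.speckle_shape,
                        scale=1.0 / spec.speckle_shape, size=(h, w))
    image = np.clip(clean * speckle, 0.0, 1.0)
    to3 = lambda x: np.repeat(x[:, :, None], 3, axis=2)
    return PhantomRender(image=to3(image), clean=to3(clean), mask=mask)


def gen_vessel_phantom(spec: PhantomSpec) -> np.ndarray:
    """The speckled (H, W, 3) phantom image in [0, 1]."""
    return render_vessel_phantom(spec).image


def gen_analytic_image(kind: str, size: tuple[int, int], *, value: float = 0.5,
                       fx: float = 0.0, fy: float = 0.0) -> np.ndarray:
    """Closed-form (H, W, 3) images: 'constant', 'gradient' or 'sinusoid'.

    The sinusoid is 0.5 + 0.5*sin(2*pi*(fx*u + fy*v)) sampled at pixel
    centers of the unit square; the gradient ramps along the width.
    """
    h, w = size
    u = (np.arange(h) + 0.5) / h
    v = (np.arange(w) + 0.5) / w
    if kind == "constant":
        img = np.full((h, w), float(value))
    elif kind == "gradient":
        img = np.broadcast_to(v, (h, w)).copy()
    elif kind == "sinusoid":
        img = 0.5 + 0.5 * np.sin(2 * np.pi * (fx * u[:, None] + fy * v[None, :]))
    else:
        raise ValueError(f"unknown analytic image kind {kind!r}")
    return np.repeat(np.clip(img, 0.0, 1.0)[:, :, None], 3, axis=2)


def make_fixture_dataset(n: int, size: tuple[int, int], seed: int,
                         out_dir) -> dict:
    """Write ``n`` phantom PNGs plus a JSON manifest; returns the manifest.

    Deterministic for a fixed seed: rerunning produces identical bytes.
    """
    from .io import write_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n):
        spec = PhantomSpec(size=tuple(size), seed=seed + i)
        img = gen_vessel_phantom(spec)
        name = f"phantom_{i:03d}.png"
        write_image(out_dir / name, img)
        entry = asdict(spec)
        entry["file"] = name
        entries.append(entry)
    manifest = {"n": n, "size": list(size), "seed": seed, "images": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
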
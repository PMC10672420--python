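"""Image and checkpoint I/O.

Images are 8-bit PNG (or any raster imageio reads): values map to [0, 1]
reals by /255 on read and round-half-away(v*255) on write; grayscale is
replicated to three channels and alpha is dropped.

Checkpoints are ``.npz`` containers written at run time (never shipped with
the package): named parameter arrays under ``encoder.*``, ``ow.*`` and
``mlp.*`` plus a JSON config echo and a format-version tag.  Loading is
bit-exact and refuses mismatched versions or an inconsistent region size.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .autodiff import Tensor
from .encoder import EncoderConfig, EncoderParams
from .owindow import OWParams, window_sizes
from .pipeline import FORMAT_VERSION, ModelBundle

__all__ = ["read_image", "write_image", "save_checkpoint", "load_checkpoint",
           "CheckpointError"]


class CheckpointError(RuntimeError):
    pass


def read_image(path) -> np.ndarray:
    """Read a raster image as an (H, W, 3) float64 array in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        img = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        img = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        img = np.asarray(arr, dtype=np.float64)
    else:
        raise ValueError(f"unsupported image dtype {arr.dtype} in {path}")
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    elif img.ndim == 3:
        if img.shape[2] == 4:
            img = img[:, :, :3]
        elif img.shape[2] == 1:
            img = np.repeat(img, 3, axis=2)
        elif img.shape[2] != 3:
            raise ValueError(f"unsupported channel count {img.shape[2]} in {path}")
    else:
        raise ValueError(f"unsupported image rank {img.ndim} in {path}")
    return np.clip(img, 0.0, 1.0)


def write_image(path, img: np.ndarray) -> None:
    """Write an (H, W[, 3]) array in [0, 1] as an 8-bit PNG."""
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    data = np.floor(img * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(Path(path), data)


def _bundle_config(bundle: ModelBundle) -> dict:
    cfg = bundle.encoder.config
    return {
        "m": bundle.m,
        "n_resblocks": cfg.n_resblocks,
        "n_feats": cfg.n_feats,
        "res_scale": cfg.res_scale,
        "mean_shift": list(cfg.mean_shift),
        "mlp_hidden": list(bundle.ow.mlp_hidden),
    }


def save_checkpoint(bundle: ModelBundle, path) -> None:
    arrays: dict[str, np.ndarray] = {
        "__format__": np.asarray(FORMAT_VERSION),
        "__config__": np.asarray(json.dumps(_bundle_config(bundle))),
    }
    enc = bundle.encoder
    arrays["encoder.head.w"] = enc.head_w.data
    arrays["encoder.head.b"] = enc.head_b.data
    for i, (w1, b1, w2, b2) in enumerate(enc.blocks):
        arrays[f"encoder.block{i}.w1"] = w1.data
        arrays[f"encoder.block{i}.b1"] = b1.data
        arrays[f"encoder.block{i}.w2"] = w2.data
        arrays[f"encoder.block{i}.b2"] = b2.data
    arrays["encoder.tail.w"] = enc.tail_w.data
    arrays["encoder.tail.b"] = enc.tail_b.data
    for i, w in enumerate(bundle.ow.window_weights):
        arrays[f"ow.iter{i}"] = w.data
    for i, (w, b) in enumerate(bundle.ow.mlp):
        arrays[f"mlp.layer{i}.w"] = w.data
        arrays[f"mlp.layer{i}.b"] = b.data
    with open(Path(path), "wb") as fh:  # keep the exact filename (no .npz suffixing)
        np.savez(fh, **arrays)


def load_checkpoint(path, expect_m: int | None = None) -> ModelBundle:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such checkpoint: {path}")
    try:
        with np.load(path, allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
    except Exception as exc:  # zipfile/format errors -> corrupt container
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    version = str(arrays.get("__format__", ""))
    if version != FORMAT_VERSION:
        raise CheckpointError(f"checkpoint format {version!r} does not match "
                              f"{FORMAT_VERSION!r}")
    cfg = json.loads(str(arrays["__config__"]))
    if expect_m is not None and expect_m != cfg["m"]:
        raise CheckpointError(f"checkpoint was trained with M={cfg['m']}, "
                              f"requested M={expect_m}")
    enc_cfg = EncoderConfig(n_resblocks=cfg["n_resblocks"], n_feats=cfg["n_feats"],
                            res_scale=cfg["res_scale"],
                            mean_shift=tuple(cfg["mean_shift"]))

    def t(key):
        if key not in arrays:
            raise CheckpointError(f"checkpoint is missing array {key!r}")
        return Tensor(arrays[key], requires_grad=True)

    blocks = [(t(f"encoder.block{i}.w1"), t(f"encoder.block{i}.b1"),
               t(f"encoder.block{i}.w2"), t(f"encoder.block{i}.b2"))
              for i in range(enc_cfg.n_resblocks)]
    enc = EncoderParams(head_w=t("encoder.head.w"), head_b=t("encoder.head.b"),
                        blocks=blocks, tail_w=t("encoder.tail.w"),
                        tail_b=t("encoder.tail.b"), config=enc_cfg)
    n_iters = len(window_sizes(cfg["m"]))
    ow = OWParams(m=cfg["m"], depth=cfg["n_feats"],
                  window_weights=[t(f"ow.iter{i}") for i in range(n_iters)],
                  mlp=[(t(f"mlp.layer{i}.w"), t(f"mlp.layer{i}.b"))
                       for i in range(len(cfg["mlp_hidden"]) + 1)])
    return ModelBundle(encoder=enc, ow=ow, m=cfg["m"])
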
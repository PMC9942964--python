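"""Serialization helpers: HDF5 latent/boundary/kernel containers, CSV
tables, JSON manifests and PNG image export."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import h5py
import numpy as np
from PIL import Image

from tagprobe.feature_discovery import KernelBank
from tagprobe.latent_probe import BoundaryModel
from tagprobe.multiscale_generator import LatentCode


def save_latents(
    path,
    codes: Sequence[LatentCode],
    labels: Optional[Sequence[str]] = None,
    factors: Optional[np.ndarray] = None,
) -> None:
    arr = np.stack([c.layers for c in codes]).astype(np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("latents", data=arr)
        if labels is not None:
            f.create_dataset(
                "labels", data=np.array([str(x) for x in labels], dtype="S16")
            )
        if factors is not None:
            f.create_dataset("factors", data=np.asarray(factors, dtype=np.float32))


def load_latents(path):
    with h5py.File(path, "r") as f:
        arr = f["latents"][...]
        labels = (
            [s.decode() for s in f["labels"][...]] if "labels" in f else None
        )
        factors = f["factors"][...] if "factors" in f else None
    return [LatentCode(a) for a in arr], labels, factors


def save_boundaries(path, boundaries: Sequence[BoundaryModel]) -> None:
    with h5py.File(path, "w") as f:
        for bm in boundaries:
            g = f.create_group(f"layer_{bm.layer_index:02d}")
            g.create_dataset("weights", data=bm.weights)
            g.attrs["bias"] = bm.bias
            g.attrs["C_selected"] = bm.C_selected
            g.attrs["cv_accuracy"] = bm.cv_accuracy
            if bm.norm_bounds is not None:
                g.create_dataset("norm_bounds", data=np.array(bm.norm_bounds))


def load_boundaries(path) -> List[BoundaryModel]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(
                BoundaryModel(
                    layer_index=int(name.split("_")[1]),
                    weights=g["weights"][...],
                    bias=float(g.attrs["bias"]),
                    C_selected=float(g.attrs["C_selected"]),
                    cv_accuracy=float(g.attrs["cv_accuracy"]),
                    norm_bounds=(
                        tuple(g["norm_bounds"][...]) if "norm_bounds" in g else None
                    ),
                )
            )
    return out


def save_kernels(path, bank: KernelBank) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kernels", data=bank.kernels.astype(np.float32))
        f.create_dataset("nongaussianity", data=bank.nongaussianity)
        if bank.chromaticity is not None:
            f.create_dataset(
                "chromaticity",
                data=np.array(bank.chromaticity, dtype="S16"),
            )
            f.create_dataset(
                "orientation",
                data=np.array(
                    [np.nan if a is None else a for a in bank.orientation]
                ),
            )


def write_png(path, pixels: np.ndarray) -> None:
    arr = np.clip(np.asarray(pixels) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def write_filmstrip(path, images, pad: int = 2) -> None:
    """Horizontal PNG filmstrip of equally sized frames."""
    frames = [np.asarray(im.pixels if hasattr(im, "pixels") else im) for im in images]
    h = frames[0].shape[0]
    strip = np.ones((h, 0, 3))
    spacer = np.ones((h, pad, 3))
    for fr in frames:
        strip = np.concatenate([strip, fr, spacer], axis=1)
    write_png(path, strip)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


__all__ = [
    "save_latents",
    "load_latents",
    "save_boundaries",
    "load_boundaries",
    "save_kernels",
    "write_png",
    "write_filmstrip",
    "write_json",
]
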
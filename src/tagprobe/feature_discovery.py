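"""ICA discovery of translucency-diagnostic chromatic kernels.

The pipeline: build a "high translucency" image set by swapping the
middle-layer latent rows of diverse source codes with those of top-rated
targets and keeping the material-scale (64 px) intermediate render of
every ordered source-target pair; resize, sample random patches; learn a
bank of unit-norm ICA basis functions; annotate each kernel as
chromatic/achromatic and oriented/orientation-free; and contrast kernel
responses between translucent and opaque stimuli inside an object-mask
edge band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as sk_resize
from sklearn.decomposition import FastICA

from tagprobe.latent_morphing import morph
from tagprobe.multiscale_generator import (
    GeneratorConfig,
    LatentCode,
    material_render,
)
from tagprobe.scene_synth import StimulusImage

DEFAULT_K = 64
DEFAULT_PATCH = 24
DEFAULT_RESIZE = 512
DEFAULT_PATCHES_PER_IMAGE = 10


@dataclass
class KernelBank:
    """K learned p x p x 3 basis functions with per-kernel annotations."""

    kernels: np.ndarray  # (K, p, p, 3), each unit-norm
    nongaussianity: np.ndarray  # |excess kurtosis| of each source, desc order
    chromaticity: Optional[List[str]] = None  # "chromatic" / "achromatic"
    orientation: Optional[List[Optional[float]]] = None  # angle or None

    @property
    def K(self) -> int:
        return self.kernels.shape[0]

    @property
    def patch(self) -> int:
        return self.kernels.shape[1]

    def annotations(self) -> pd.DataFrame:
        if self.chromaticity is None or self.orientation is None:
            raise ValueError("kernels not yet classified")
        return pd.DataFrame(
            {
                "kernel": np.arange(self.K),
                "chromaticity": self.chromaticity,
                "oriented": [a is not None for a in self.orientation],
                "angle": [np.nan if a is None else a for a in self.orientation],
                "nongaussianity": self.nongaussianity,
            }
        )


def build_high_translucency_set(
    codes: Sequence[LatentCode],
    translucency_ratings: Sequence[float],
    n_targets: int,
    n_extra_sources: int,
    cfg: GeneratorConfig,
    middle_layers: Optional[Sequence[int]] = None,
    resolution: int = 64,
) -> List[StimulusImage]:
    """Middle-layer latent swap over every ordered source-target pair.

    Targets are the ``n_targets`` top-rated codes; sources are the targets
    plus the next ``n_extra_sources`` rated codes.  Self-pairs (source is
    the target) are excluded, so the returned count is
    ``(n_targets + n_extra_sources) * n_targets - n_targets``.
    Each returned image is the material-scale intermediate render of the
    swapped code.
    """
    ratings = np.asarray(translucency_ratings, dtype=float)
    if len(codes) != len(ratings):
        raise ValueError("codes and ratings must align")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if n_targets + n_extra_sources > len(codes):
        raise ValueError(
            f"need {n_targets + n_extra_sources} rated codes, have {len(codes)}"
        )
    order = np.argsort(-ratings, kind="stable")
    target_idx = list(order[:n_targets])
    source_idx = target_idx + list(order[n_targets : n_targets + n_extra_sources])
    mid = tuple(middle_layers) if middle_layers is not None else cfg.groups.middle
    images = []
    for si in source_idx:
        for ti in target_idx:
            if si == ti:
                continue
            swapped = morph(codes[si], codes[ti], mid, 1.0)
            images.append(material_render(swapped, cfg, resolution=resolution))
    return images


def sample_patches(
    images: Sequence,
    resize_to: int,
    patch: int,
    per_image: int,
    seed: int,
) -> np.ndarray:
    """Random patch matrix ``(n_images * per_image, patch, patch, 3)``.

    Each image is bilinearly resized to ``resize_to`` per side before
    patches are cut at uniform random offsets.
    """
    if patch > resize_to:
        raise ValueError("patch size cannot exceed the resize target")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x1CA)))
    out = np.empty((len(images) * per_image, patch, patch, 3))
    k = 0
    for im in images:
        px = np.asarray(im.pixels if hasattr(im, "pixels") else im, dtype=float)
        if px.shape[0] != resize_to:
            px = sk_resize(
                px, (resize_to, resize_to, 3), order=1, anti_aliasing=False
            )
        offs = rng.integers(0, resize_to - patch + 1, size=(per_image, 2))
        for r, c in offs:
            out[k] = px[r : r + patch, c : c + patch]
            k += 1
    return out


def learn_ica_kernels(patches: np.ndarray, K: int, seed: int) -> KernelBank:
    """Fixed-point ICA basis (mixing) functions from a patch matrix.

    Patches are mean-subtracted and whitened inside FastICA; the returned
    kernels are the unit-normalized mixing columns, ordered by descending
    non-Gaussianity (absolute excess kurtosis of the source activations)
    with the sign fixed so each kernel's maximum-magnitude coefficient is
    positive.
    """
    patches = np.asarray(patches, dtype=float)
    n = patches.shape[0]
    p = patches.shape[1]
    X = patches.reshape(n, -1)
    if n < 10 * K:
        raise ValueError(f"need at least {10 * K} patches for K={K}, have {n}")
    Xc = X - X.mean(axis=0)
    # rank check before whitening: K principal directions must carry variance
    sv = np.linalg.svd(Xc, compute_uv=False)
    rank = int((sv > sv[0] * 1e-10).sum())
    if K > rank:
        raise ValueError(f"patch matrix rank {rank} is below K={K}")
    ica = FastICA(
        n_components=K,
        whiten="unit-variance",
        random_state=np.random.default_rng(seed).integers(2**31),
        max_iter=1000,
        tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sources = ica.fit_transform(X)
    mixing = ica.mixing_.T  # (K, features)
    kurt = np.abs(stats_kurtosis(sources))
    order = np.argsort(-kurt, kind="stable")
    mixing, kurt = mixing[order], kurt[order]
    kernels = np.empty((K, p, p, 3))
    for i in range(K):
        k = mixing[i] / np.linalg.norm(mixing[i])
        if k[np.argmax(np.abs(k))] < 0:
            k = -k
        kernels[i] = k.reshape(p, p, 3)
    return KernelBank(kernels=kernels, nongaussianity=kurt)


def stats_kurtosis(sources: np.ndarray) -> np.ndarray:
    """Excess kurtosis per column (the non-Gaussianity ranking score)."""
    z = sources - sources.mean(axis=0)
    v = (z**2).mean(axis=0)
    return (z**4).mean(axis=0) / np.maximum(v**2, 1e-300) - 3.0


def classify_kernels(
    bank: KernelBank,
    chroma_threshold: float = 0.2,
    anisotropy_threshold: float = 0.4,
) -> KernelBank:
    """Annotate each kernel's chromaticity and orientation (in place).

    Chromatic iff the energy in between-channel differences exceeds
    ``chroma_threshold`` of the total; oriented iff the luminance
    structure tensor's anisotropy exceeds ``anisotropy_threshold``, with
    the reported angle the dominant gradient direction in ``[0, pi)``.
    """
    chroma, orient = [], []
    for k in bank.kernels:
        mean_ch = k.mean(axis=2, keepdims=True)
        total = float((k**2).sum())
        diff = float(((k - mean_ch) ** 2).sum())
        chroma.append(
            "chromatic" if diff / max(total, 1e-300) > chroma_threshold
            else "achromatic"
        )
        # channel-summed structure tensor, so purely chromatic (zero
        # luminance) patterns still expose their spatial orientation
        jxx = jyy = jxy = 0.0
        for c in range(3):
            gy, gx = np.gradient(k[:, :, c])
            jxx += (gx**2).sum()
            jyy += (gy**2).sum()
            jxy += (gx * gy).sum()
        denom = jxx + jyy
        aniso = np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2) / max(denom, 1e-300)
        if denom > 0 and aniso > anisotropy_threshold:
            angle = 0.5 * np.arctan2(2 * jxy, jxx - jyy)
            orient.append(float(angle % np.pi))
        else:
            orient.append(None)
    bank.chromaticity = chroma
    bank.orientation = orient
    return bank


def filter_image(image, kernel: np.ndarray) -> np.ndarray:
    """Channel-summed cross-correlation (no kernel flip), reflect-padded.

    Returns a 2-D response map the same spatial size as the image.
    """
    from scipy.signal import fftconvolve

    px = np.asarray(image.pixels if hasattr(image, "pixels") else image, float)
    kernel = np.asarray(kernel, dtype=float)
    if px.shape[0] < kernel.shape[0] or px.shape[1] < kernel.shape[1]:
        raise ValueError("image is smaller than the kernel")
    kh, kw = kernel.shape[:2]
    pt, pb = (kh - 1) // 2, kh // 2
    pl, pr = (kw - 1) // 2, kw // 2
    padded = np.pad(px, ((pt, pb), (pl, pr), (0, 0)), mode="symmetric")
    out = np.zeros(px.shape[:2])
    for c in range(3):
        # cross-correlation = convolution with the flipped kernel
        out += fftconvolve(padded[:, :, c], kernel[::-1, ::-1, c], mode="valid")
    return out


def _edge_band(mask: np.ndarray, band_frac: float = 0.2) -> np.ndarray:
    edt = ndimage.distance_transform_edt(mask)
    width = max(2.0, band_frac * mask.shape[0])
    return (edt >= 1.0) & (edt <= width)


def translucency_response_contrast(
    images_translucent: Sequence,
    images_opaque: Sequence,
    bank: KernelBank,
    masks_translucent: Sequence[np.ndarray],
    masks_opaque: Sequence[np.ndarray],
) -> np.ndarray:
    """Standardized per-kernel edge-band response contrast.

    For each kernel: mean absolute response inside the object edge band,
    averaged per image, then (translucent - opaque) divided by the
    standard error of the difference.  Zero when the two samples are
    identical; antisymmetric under swapping the sets.
    """
    if not len(images_translucent) or not len(images_opaque):
        raise ValueError("both image sets must be nonempty")

    def _means(images, masks):
        per_img = np.empty((len(images), bank.K))
        for j, (im, m) in enumerate(zip(images, masks)):
            band = _edge_band(np.asarray(m, bool))
            if not band.any():
                raise ValueError(f"empty mask edge band for image {j}")
            for i in range(bank.K):
                per_img[j, i] = np.abs(filter_image(im, bank.kernels[i]))[band].mean()
        return per_img

    t = _means(images_translucent, masks_translucent)
    o = _means(images_opaque, masks_opaque)
    diff = t.mean(axis=0) - o.mean(axis=0)
    var = t.var(axis=0, ddof=1) / len(t) if len(t) > 1 else np.zeros(bank.K)
    var = var + (o.var(axis=0, ddof=1) / len(o) if len(o) > 1 else 0.0)
    se = np.sqrt(var)
    out = np.zeros(bank.K)
    nz = se > 0
    out[nz] = diff[nz] / se[nz]
    # zero spread with a real difference: report the raw difference sign
    out[~nz] = np.sign(diff[~nz]) * np.inf * (diff[~nz] != 0)
    return np.nan_to_num(out, nan=0.0, posinf=np.inf, neginf=-np.inf)


__all__ = [
    "KernelBank",
    "DEFAULT_K",
    "DEFAULT_PATCH",
    "DEFAULT_RESIZE",
    "DEFAULT_PATCHES_PER_IMAGE",
    "build_high_translucency_set",
    "sample_patches",
    "learn_ica_kernels",
    "classify_kernels",
    "filter_image",
    "translucency_response_contrast",
]
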
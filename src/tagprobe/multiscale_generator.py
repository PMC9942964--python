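"""Analytic layer-wise generator and linear image encoder.

An ``L x d`` latent code (default 18 x 16) plays the role of an extended,
per-synthesis-layer latent space.  Configured layer groups own disjoint
factor subsets through per-group affine readout maps:

* early group (layers 1-6): contour shape, orientation, light azimuth;
* middle group (layers 7-9): translucency ``tau``, backlight strength;
* late group (layers 10-18): body color and fine texture.

``decode`` reads the factors back through the affine maps (with hard,
saturating clamps — decoding never fails on extreme codes), renders the
stimulus with :mod:`tagprobe.scene_synth`, and exposes coarse-to-fine
intermediate renders: a 16 px shape-only render, a 64 px material render
with neutralized body color, and the full-resolution output.

``encode_factors`` is the exact affine inverse on the factor-relevant
subspace; nuisance latent directions (the null space of each readout map)
are filled with seeded Gaussian noise so downstream probes must learn to
ignore irrelevant directions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from tagprobe.scene_synth import (
    AMP_MAX,
    N_HARMONICS,
    SceneFactors,
    StimulusImage,
    render_scene,
)

_PI = np.pi

#: per-group factor layout: name -> (dimension, (low, high) clamp per dim).
#: Angular factors live in Cartesian coordinates (harmonic cos/sin pairs,
#: light direction vector, texture cos/sin) so that the pixel -> factor
#: relationship stays close to linear; :class:`SceneFactors` keeps the
#: amplitude/phase convention and the conversion is exact both ways.
GROUP_FACTORS = {
    "early": (
        ("contour_cos", N_HARMONICS, [(-cap, cap) for cap in AMP_MAX]),
        ("contour_sin", N_HARMONICS, [(-cap, cap) for cap in AMP_MAX]),
        ("orientation", 1, [(-_PI / 12, _PI / 12)]),
        ("light_dir", 2, [(-1.0, 1.0)] * 2),
    ),
    "middle": (
        ("tau", 1, [(0.0, 1.0)]),
        ("backlight_strength", 1, [(0.0, 1.0)]),
    ),
    "late": (
        ("body_color", 3, [(0.02, 1.0)] * 3),
        ("texture_cos", 1, [(-0.04, 0.04)]),
        ("texture_sin", 1, [(-0.04, 0.04)]),
    ),
}

GROUP_NAMES = ("early", "middle", "late")

#: relative latent footprint per factor dimension: the share of latent
#: magnitude a factor's full range occupies, mirroring how visually salient
#: it is (a tiny orientation tilt or a sub-pixel high harmonic should not
#: claim as much latent variance as the light direction or tau)
FACTOR_SALIENCE = {
    "contour_cos": np.array([1.0, 0.45, 0.28, 0.2]),
    "contour_sin": np.array([1.0, 0.45, 0.28, 0.2]),
    "orientation": np.array([0.1]),
    "light_dir": np.array([1.4, 1.4]),
    "tau": np.array([1.0]),
    "backlight_strength": np.array([1.0]),
    "body_color": np.array([1.0, 1.0, 1.0]),
    "texture_cos": np.array([1.0]),
    "texture_sin": np.array([1.0]),
}


@dataclass(frozen=True)
class LayerGroups:
    """Disjoint early/middle/late layer index sets (1-based, union = 1..L)."""

    early: Tuple[int, ...] = tuple(range(1, 7))
    middle: Tuple[int, ...] = (7, 8, 9)
    late: Tuple[int, ...] = tuple(range(10, 19))

    def __post_init__(self):
        sets = [set(self.early), set(self.middle), set(self.late)]
        if any(not s for s in sets):
            raise ValueError("every layer group must be nonempty")
        union = sets[0] | sets[1] | sets[2]
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("layer groups must be disjoint")
        if union != set(range(1, max(union) + 1)):
            raise ValueError("layer groups must partition 1..L")

    @property
    def L(self) -> int:
        return len(self.early) + len(self.middle) + len(self.late)

    def __getitem__(self, name: str) -> Tuple[int, ...]:
        return getattr(self, name)


@dataclass
class LatentCode:
    """L x d layer-wise latent matrix (row i-1 holds layer i's vector)."""

    layers: np.ndarray

    def __post_init__(self):
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 2:
            raise ValueError("layers must be an L x d matrix")
        if not np.all(np.isfinite(self.layers)):
            raise ValueError("latent entries must be finite")

    @property
    def L(self) -> int:
        return self.layers.shape[0]

    @property
    def d(self) -> int:
        return self.layers.shape[1]

    def copy(self) -> "LatentCode":
        return LatentCode(self.layers.copy())


@dataclass
class IntermediateRenders:
    """Coarse-to-fine renders; the last entry is the full decode output."""

    renders: List[Tuple[int, StimulusImage]]

    def __post_init__(self):
        res = [r for r, _ in self.renders]
        if any(b <= a for a, b in zip(res, res[1:])):
            raise ValueError("resolutions must be strictly increasing")

    def __iter__(self):
        return iter(self.renders)

    def __len__(self):
        return len(self.renders)

    def at(self, resolution: int) -> StimulusImage:
        for r, img in self.renders:
            if r == resolution:
                return img
        raise KeyError(f"no intermediate render at resolution {resolution}")


class GeneratorConfig:
    """Deterministic construction of the per-group affine factor maps.

    Each group's map ``(A_g, b_g)`` sends the group's concatenated latent
    rows to the factor sub-vector it controls; ``A_g`` has full row rank so
    factors are exactly recoverable on the row space.
    """

    def __init__(
        self,
        L: int = 18,
        d: int = 16,
        groups: Optional[LayerGroups] = None,
        seed: int = 0,
        nuisance_sd: float = 0.4,
        resolution: int = 128,
        factor_gain: float = 6.0,
    ):
        groups = groups if groups is not None else LayerGroups()
        if groups.L != L:
            raise ValueError("layer groups do not cover 1..L")
        self.L, self.d = L, d
        self.groups = groups
        self.seed = seed
        self.nuisance_sd = nuisance_sd
        self.resolution = resolution
        if factor_gain <= 0:
            raise ValueError("factor_gain must be positive")
        self.factor_gain = factor_gain

        self.factor_names: Dict[str, list] = {}
        self.clamps: Dict[str, np.ndarray] = {}
        self.A: Dict[str, np.ndarray] = {}
        self.b: Dict[str, np.ndarray] = {}
        self._pinv: Dict[str, np.ndarray] = {}
        self._null: Dict[str, np.ndarray] = {}

        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11)))
        for g in GROUP_NAMES:
            names, bounds = [], []
            for name, dim, bnds in GROUP_FACTORS[g]:
                names.append((name, dim))
                bounds.extend(bnds)
            f_dim = sum(dim for _, dim in names)
            m = len(groups[g]) * d
            if m < f_dim:
                raise ValueError(
                    f"group {g!r} has too few latent dims ({m}) for its "
                    f"{f_dim} factors"
                )
            # gain > 1 spreads factor variation over a larger latent range,
            # keeping class signal visible against the nuisance noise; each
            # row is scaled by the factor's half-range so heterogeneous
            # factor units occupy comparable latent magnitudes
            half_range = np.array([(hi - lo) / 2.0 for lo, hi in bounds])
            salience = np.concatenate(
                [FACTOR_SALIENCE[name] for name, _dim, _b in GROUP_FACTORS[g]]
            )
            A = (
                rng.normal(size=(f_dim, m))
                / (np.sqrt(m) * factor_gain)
                * (half_range / salience)[:, None]
            )
            self.factor_names[g] = names
            self.clamps[g] = np.array(bounds)
            self.A[g] = A
            self.b[g] = np.array([(lo + hi) / 2.0 for lo, hi in bounds])
            self._pinv[g] = np.linalg.pinv(A)
            _, _, vt = np.linalg.svd(A, full_matrices=True)
            self._null[g] = vt[f_dim:].T  # orthonormal nuisance directions
            if np.linalg.matrix_rank(A) != f_dim:
                raise ValueError(f"factor map for group {g!r} is rank deficient")

    # -- factor <-> vector plumbing ----------------------------------------

    def group_rows(self, g: str) -> np.ndarray:
        return np.array([i - 1 for i in self.groups[g]])

    def factors_to_vector(self, g: str, factors: SceneFactors) -> np.ndarray:
        amps = factors.contour_coeffs[:N_HARMONICS]
        phases = factors.contour_coeffs[N_HARMONICS:]
        parts = []
        for name, _dim in self.factor_names[g]:
            if name == "contour_cos":
                parts.append(amps * np.cos(phases))
            elif name == "contour_sin":
                parts.append(-amps * np.sin(phases))
            elif name == "light_dir":
                az = factors.light_azimuth
                parts.append(np.array([np.cos(az), np.sin(az)]))
            elif name == "texture_cos":
                parts.append(
                    np.atleast_1d(factors.texture_amp * np.cos(factors.texture_phase))
                )
            elif name == "texture_sin":
                parts.append(
                    np.atleast_1d(factors.texture_amp * np.sin(factors.texture_phase))
                )
            else:
                parts.append(np.atleast_1d(np.asarray(getattr(factors, name), float)))
        return np.concatenate(parts)

    def vector_to_factor_dict(self, g: str, vec: np.ndarray) -> dict:
        out, k = {}, 0
        for name, dim in self.factor_names[g]:
            v = vec[k : k + dim]
            out[name] = v if dim > 1 else float(v[0])
            k += dim
        return out

    def clamp_vector(self, g: str, vec: np.ndarray) -> np.ndarray:
        c = self.clamps[g]
        return np.clip(vec, c[:, 0], c[:, 1])

    def validate_in_range(self, g: str, vec: np.ndarray) -> None:
        c = self.clamps[g]
        bad = (vec < c[:, 0] - 1e-12) | (vec > c[:, 1] + 1e-12)
        if bad.any():
            labels = []
            for name, dim in self.factor_names[g]:
                labels.extend([name] * dim)
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"factor out of clamp range: {labels[i]!r} (value {vec[i]:.4g})"
            )

    def readout(self, g: str, code: LatentCode) -> np.ndarray:
        """Clamped factor sub-vector read from the group's latent rows."""
        w = code.layers[self.group_rows(g)].ravel()
        return self.clamp_vector(g, self.A[g] @ w + self.b[g])


# ---------------------------------------------------------------------------
# encode / decode


def encode_factors(
    factors: SceneFactors, cfg: GeneratorConfig, rng_seed
) -> LatentCode:
    """Invert the factor maps analytically; fill nuisance dims with noise."""
    rng = np.random.default_rng(rng_seed)
    W = np.zeros((cfg.L, cfg.d))
    for g in GROUP_NAMES:
        f = cfg.factors_to_vector(g, factors)
        cfg.validate_in_range(g, f)
        w = cfg._pinv[g] @ (f - cfg.b[g])
        null = cfg._null[g]
        if null.shape[1] > 0:
            w = w + null @ rng.normal(scale=cfg.nuisance_sd, size=null.shape[1])
        W[cfg.group_rows(g)] = w.reshape(len(cfg.groups[g]), cfg.d)
    return LatentCode(W)


def decode_factors(code: LatentCode, cfg: GeneratorConfig) -> SceneFactors:
    """Read (clamped) scene factors from a latent code without rendering."""
    if code.layers.shape != (cfg.L, cfg.d):
        raise ValueError(
            f"latent code shape {code.layers.shape} does not match "
            f"config ({cfg.L}, {cfg.d})"
        )
    vals = {}
    for g in GROUP_NAMES:
        vals.update(cfg.vector_to_factor_dict(g, cfg.readout(g, code)))
    tau = vals["tau"]
    cc, ss = np.asarray(vals["contour_cos"]), np.asarray(vals["contour_sin"])
    amps = np.hypot(cc, ss)
    phases = np.where(amps > 0, np.arctan2(-ss, cc), 0.0)
    lx, ly = vals["light_dir"]
    azimuth = float(np.arctan2(ly, lx)) if np.hypot(lx, ly) > 1e-9 else 0.0
    tc, ts = vals["texture_cos"], vals["texture_sin"]
    return SceneFactors(
        contour_coeffs=np.concatenate([amps, phases]),
        orientation=vals["orientation"],
        tau=tau,
        body_color=np.asarray(vals["body_color"]),
        light_azimuth=azimuth,
        backlight_strength=vals["backlight_strength"],
        material_class="glycerin" if tau >= 0.5 else "milky",
        texture_amp=float(np.hypot(tc, ts)),
        texture_phase=float(np.arctan2(ts, tc)),
    )


_NEUTRAL = np.array([0.5, 0.5, 0.5])

SHAPE_RENDER_RES = 16
MATERIAL_RENDER_RES = 64


def material_render(
    code: LatentCode, cfg: GeneratorConfig, resolution: int = MATERIAL_RENDER_RES
) -> StimulusImage:
    """Material-scale intermediate render: shape + material, neutral color.

    Reflects the early and middle factor groups but none of the late-group
    factors (body color and texture are fixed to neutral defaults).
    """
    f = decode_factors(code, cfg)
    f_mat = replace(f, body_color=_NEUTRAL.copy(), texture_amp=0.0, texture_phase=0.0)
    return render_scene(f_mat, resolution)


def decode(
    code: LatentCode, cfg: GeneratorConfig
) -> Tuple[StimulusImage, IntermediateRenders]:
    """Decode a latent code to the full render plus intermediate renders."""
    f = decode_factors(code, cfg)
    f_shape = replace(
        f,
        tau=0.0,
        backlight_strength=0.0,
        body_color=_NEUTRAL.copy(),
        texture_amp=0.0,
        texture_phase=0.0,
    )
    shape_img = render_scene(f_shape, SHAPE_RENDER_RES)
    full = render_scene(f, cfg.resolution)
    renders = [(SHAPE_RENDER_RES, shape_img)]
    # the material-scale entry is dropped when the output resolution is not
    # above it, keeping the coarse-to-fine ladder strictly increasing
    if cfg.resolution > MATERIAL_RENDER_RES:
        renders.append((MATERIAL_RENDER_RES, material_render(code, cfg)))
    renders.append((cfg.resolution, full))
    return full, IntermediateRenders(renders)


def sample_codes(
    n: int,
    cfg: GeneratorConfig,
    seed: int,
    material_class: Optional[str] = None,
    scene_config=None,
):
    """Sample ``n`` scenes and encode them; returns (codes, factors)."""
    from tagprobe import scene_synth

    sc = scene_config if scene_config is not None else scene_synth.DEFAULT_SCENE_CONFIG
    children = np.random.SeedSequence((seed, 0x5C)).spawn(2 * n)
    codes, factors = [], []
    for i in range(n):
        f = scene_synth.sample_scene(
            children[2 * i], material_class=material_class, config=sc
        )
        codes.append(encode_factors(f, cfg, children[2 * i + 1]))
        factors.append(f)
    return codes, factors


# ---------------------------------------------------------------------------
# linear image encoder (stand-in for a trained image-to-latent encoder)


@dataclass
class ImageEncoder:
    """Affine ridge map from flattened pixels to an L x d latent matrix."""

    coef: np.ndarray  # (n_features, L*d)
    intercept: np.ndarray  # (L*d,)
    resolution: int
    L: int
    d: int
    ridge_strength: float
    n_train: int
    train_rmse: float

    def __call__(self, image: StimulusImage) -> LatentCode:
        return embed_image(image, self)


def _flatten_images(images: Sequence[StimulusImage]) -> np.ndarray:
    res = images[0].resolution
    for im in images:
        if im.resolution != res:
            raise ValueError("all training images must share one resolution")
    return np.stack([im.pixels.ravel() for im in images])


def fit_image_encoder(
    pairs: Sequence[Tuple[StimulusImage, LatentCode]], ridge_strength: float
) -> ImageEncoder:
    """Ridge regression from pixels to latent codes.

    The penalty applies to the *average* squared loss, so duplicating the
    training set leaves the fit unchanged; ``ridge_strength -> inf``
    shrinks coefficients to zero and predictions to the training mean.
    """
    if not pairs:
        raise ValueError("no training pairs")
    images = [p[0] for p in pairs]
    X = _flatten_images(images)
    L, d = pairs[0][1].L, pairs[0][1].d
    Y = np.stack([p[1].layers.ravel() for p in pairs])
    n, f = X.shape
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    lam = max(float(ridge_strength), 0.0)
    if f <= n:
        G = Xc.T @ Xc / n + lam * np.eye(f)
        coef = np.linalg.solve(G, Xc.T @ Yc / n)
    else:  # dual form when features outnumber samples
        K = Xc @ Xc.T / n + lam * np.eye(n)
        coef = Xc.T @ np.linalg.solve(K, Yc) / n
    intercept = ym - xm @ coef
    rmse = float(np.sqrt(np.mean((Xc @ coef - Yc) ** 2)))
    return ImageEncoder(
        coef=coef,
        intercept=intercept,
        resolution=images[0].resolution,
        L=L,
        d=d,
        ridge_strength=ridge_strength,
        n_train=n,
        train_rmse=rmse,
    )


def embed_image(image: StimulusImage, enc: ImageEncoder) -> LatentCode:
    """Deterministic affine embedding of an image into the latent space."""
    if image.resolution != enc.resolution:
        raise ValueError(
            f"image resolution {image.resolution} does not match encoder "
            f"training resolution {enc.resolution}"
        )
    flat = image.pixels.ravel() @ enc.coef + enc.intercept
    return LatentCode(flat.reshape(enc.L, enc.d))


__all__ = [
    "LayerGroups",
    "LatentCode",
    "IntermediateRenders",
    "GeneratorConfig",
    "GROUP_NAMES",
    "SHAPE_RENDER_RES",
    "MATERIAL_RENDER_RES",
    "encode_factors",
    "decode_factors",
    "decode",
    "material_render",
    "sample_codes",
    "fit_image_encoder",
    "embed_image",
    "ImageEncoder",
]
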
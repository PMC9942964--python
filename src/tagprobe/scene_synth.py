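"""Procedural renderer for translucent/opaque soap-like stimuli.

Every stimulus is generated from a small set of ground-truth factors
(:class:`SceneFactors`): a low-order Fourier contour, an orientation, a
scalar translucency level ``tau``, a body color, and a lighting
configuration.  The renderer composes an opaque component (diffuse shading
of an implied relief plus a hard cast shadow) with a translucent component
(edge glow, a low-frequency interior hue gradient, a softened shadow and a
chromatic caustic opposite the light); the two are blended with a weight
that grows monotonically with ``tau`` and backlight strength.

Design constraints the rest of the pipeline relies on:

* the binary object mask is a function of the contour and orientation
  only — ``tau``, body color and texture never move a mask pixel;
* at ``tau == 0`` the object interior has spatially constant chromaticity,
  so :func:`glow_statistic` is exactly zero;
* (seed, config) fully determine every output byte.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

MATERIAL_CLASSES = ("milky", "glycerin")
LIGHTING_CATEGORIES = ("backlight", "partial_front", "side", "diffuse")

#: approximate illumination-direction mix of the emulated photo dataset
DEFAULT_LIGHTING_PROBS = {
    "backlight": 0.44,
    "partial_front": 0.08,
    "side": 0.40,
    "diffuse": 0.08,
}

N_HARMONICS = 4
#: per-harmonic amplitude cap; sum(sqrt(2) * cap) < 1 keeps the radius
#: strictly positive even at the corners of the Cartesian clamp box
AMP_MAX = tuple(0.2 / (k + 1) for k in range(N_HARMONICS))
BASE_RADIUS = 0.55

_WARM_TINT = np.array([1.00, 0.30, 0.05])
_COOL_TINT = np.array([0.05, 0.30, 1.00])


def wrap_angle(a: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    a = float(a)
    w = (a + np.pi) % (2.0 * np.pi) - np.pi
    if w == -np.pi:
        w = np.pi
    return w


@dataclass(frozen=True)
class SceneConfig:
    """Class-conditional factor distributions for scene sampling."""

    tau_threshold: float = 0.5
    tau_overlap: float = 0.0
    tau_milky_mean: float = 0.18
    tau_glycerin_mean: float = 0.82
    tau_sd: float = 0.15
    lighting_probs: dict = field(default_factory=lambda: dict(DEFAULT_LIGHTING_PROBS))

    def tau_support(self, material_class: str) -> tuple:
        half = self.tau_overlap / 2.0
        if material_class == "milky":
            return (0.0, min(1.0, self.tau_threshold + half))
        return (max(0.0, self.tau_threshold - half), 1.0)


DEFAULT_SCENE_CONFIG = SceneConfig()


@dataclass
class SceneFactors:
    """Ground-truth generative factors of one stimulus."""

    contour_coeffs: np.ndarray  # [a_1..a_H, phi_1..phi_H]
    orientation: float
    tau: float
    body_color: np.ndarray
    light_azimuth: float
    backlight_strength: float
    material_class: str
    lighting_category: Optional[str] = None
    texture_amp: float = 0.0
    texture_phase: float = 0.0

    def __post_init__(self):
        self.contour_coeffs = np.asarray(self.contour_coeffs, dtype=float)
        self.body_color = np.asarray(self.body_color, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.material_class not in MATERIAL_CLASSES:
            raise ValueError(f"unknown material class: {self.material_class!r}")
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if self.body_color.shape != (3,):
            raise ValueError("body_color must be an RGB triple")
        if np.any(self.body_color < 0) or np.any(self.body_color > 1):
            raise ValueError("body_color channels must lie in [0, 1]")
        if not (0.0 <= self.backlight_strength <= 1.0):
            raise ValueError("backlight_strength must lie in [0, 1]")
        if self.contour_coeffs.shape != (2 * N_HARMONICS,):
            raise ValueError(
                f"contour_coeffs must have length {2 * N_HARMONICS}"
            )


@dataclass
class StimulusImage:
    """Square RGB raster with values clipped to [0, 1] (sRGB convention)."""

    pixels: np.ndarray
    resolution: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (self.resolution, self.resolution, 3):
            raise ValueError("pixels must be resolution x resolution x 3")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")


# ---------------------------------------------------------------------------
# sampling


def _sample_truncnorm(rng, mean, sd, lo, hi) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_scene(
    rng_seed: int,
    material_class: Optional[str] = None,
    config: SceneConfig = DEFAULT_SCENE_CONFIG,
) -> SceneFactors:
    """Draw one set of scene factors from the class-conditional distributions.

    ``glycerin`` draws ``tau`` from a high-translucency truncated normal,
    ``milky`` from a low one; with ``config.tau_overlap == 0`` the two
    supports meet only at the class threshold and the classes are linearly
    separable in ``tau``.
    """
    rng = np.random.default_rng(rng_seed)
    if material_class is None:
        material_class = MATERIAL_CLASSES[int(rng.integers(2))]
    elif material_class not in MATERIAL_CLASSES:
        raise ValueError(f"unknown material class: {material_class!r}")

    lo, hi = config.tau_support(material_class)
    mean = (
        config.tau_milky_mean
        if material_class == "milky"
        else config.tau_glycerin_mean
    )
    tau = _sample_truncnorm(rng, mean, config.tau_sd, lo, hi)

    amps = np.array([rng.uniform(0.0, cap) for cap in AMP_MAX])
    phases = rng.uniform(-np.pi, np.pi, N_HARMONICS)
    # full rotational diversity comes from the harmonic phases; orientation
    # is a small residual tilt on top
    orientation = float(rng.uniform(-np.pi / 12, np.pi / 12))

    cats = list(config.lighting_probs)
    probs = np.array([config.lighting_probs[c] for c in cats], dtype=float)
    category = cats[int(rng.choice(len(cats), p=probs / probs.sum()))]
    if category == "backlight":
        backlight = float(rng.uniform(0.6, 1.0))
        azimuth = wrap_angle(np.pi + rng.normal(0.0, 0.4))
    elif category == "partial_front":
        backlight = float(rng.uniform(0.0, 0.3))
        azimuth = wrap_angle(rng.normal(0.0, 0.4))
    elif category == "side":
        backlight = float(rng.uniform(0.1, 0.5))
        side = 1.0 if rng.random() < 0.5 else -1.0
        azimuth = wrap_angle(side * np.pi / 2 + rng.normal(0.0, 0.3))
    else:  # diffuse
        backlight = float(rng.uniform(0.0, 0.2))
        azimuth = float(rng.uniform(-np.pi, np.pi))

    # body color via HSV so saturated dye colors are common
    import colorsys

    h, s, v = rng.uniform(0, 1), rng.uniform(0.2, 0.8), rng.uniform(0.45, 0.95)
    body = np.clip(np.array(colorsys.hsv_to_rgb(h, s, v)), 0.05, 1.0)

    return SceneFactors(
        contour_coeffs=np.concatenate([amps, phases]),
        orientation=orientation,
        tau=tau,
        body_color=body,
        light_azimuth=azimuth,
        backlight_strength=backlight,
        material_class=material_class,
        lighting_category=category,
        texture_amp=float(rng.uniform(0.0, 0.035)),
        texture_phase=float(rng.uniform(-np.pi, np.pi)),
    )


# ---------------------------------------------------------------------------
# rendering


@functools.lru_cache(maxsize=16)
def _pixel_grid(resolution: int):
    c = (np.arange(resolution) + 0.5) / resolution * 2.0 - 1.0
    x, y = np.meshgrid(c, c[::-1])  # x increases rightward, y upward
    rad = np.hypot(x, y)
    ang = np.arctan2(y, x)
    return x, y, rad, ang


def contour_radius(factors: SceneFactors, theta: np.ndarray) -> np.ndarray:
    """Radius of the closed contour at polar angle(s) ``theta``."""
    amps = factors.contour_coeffs[:N_HARMONICS]
    phases = factors.contour_coeffs[N_HARMONICS:]
    t = np.asarray(theta, dtype=float) - factors.orientation
    r = np.ones_like(t)
    for k in range(N_HARMONICS):
        r = r + amps[k] * np.cos((k + 2) * t + phases[k])
    return BASE_RADIUS * r


def contour_points(factors: SceneFactors, n: int = 256) -> np.ndarray:
    """Sampled closed contour; the first and last point are identical."""
    theta = np.linspace(0.0, 2.0 * np.pi, n + 1)
    r = contour_radius(factors, theta)
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def object_mask(factors: SceneFactors, resolution: int) -> np.ndarray:
    """Binary object mask; depends on the contour and orientation only."""
    _, _, rad, ang = _pixel_grid(resolution)
    return rad <= contour_radius(factors, ang)


def _blend_weights(tau: float, backlight: float) -> tuple:
    # object blend is nearly linear in tau (weak backlight coupling keeps
    # tau linearly readable); the background blend leans on the backlight
    # so caustic strength and shadow softening track the lighting
    w_obj = tau * (0.9 + 0.1 * backlight)
    w_bg = tau * (0.75 + 0.25 * backlight)
    return w_obj, w_bg


def render_scene(factors: SceneFactors, resolution: int) -> StimulusImage:
    """Deterministically render one stimulus at ``resolution`` pixels/side."""
    if resolution < 16:
        raise ValueError(f"resolution must be >= 16, got {resolution}")
    x, y, rad, ang = _pixel_grid(resolution)
    mask = object_mask(factors, resolution)

    edt = ndimage.distance_transform_edt(mask)
    edt_max = max(edt.max(), 1.0)
    height = np.sqrt(np.clip(edt / edt_max, 0.0, 1.0))

    gy, gx = np.gradient(height)  # row (=-y) and column (=+x) derivatives
    scale = resolution / 24.0
    nx, ny, nz = -gx * scale, gy * scale, np.ones_like(height)
    norm = np.sqrt(nx**2 + ny**2 + nz**2)
    az, elev = factors.light_azimuth, np.pi / 4
    lx = np.cos(az) * np.cos(elev)
    ly = np.sin(az) * np.cos(elev)
    lz = np.sin(elev)
    shading = np.clip((nx * lx + ny * ly + nz * lz) / norm, 0.0, 1.0)

    body = factors.body_color
    # opaque object: diffuse shading of a gray-floored body color; the
    # floor shares the shading profile so interior chromaticity stays
    # spatially constant, and it keeps the darkest channel clear of the
    # negative swings of the opponent translucency cues below
    base_color = 0.30 + 0.40 * body
    opaque_obj = base_color[None, None, :] * (0.45 + 0.55 * shading)[:, :, None]

    # translucent object: the same diffuse base plus additive cues (linear
    # in the blend weight, no body x tau cross-term): an edge glow with a
    # luminance part and a warm opponent (luminance-balanced) chromatic
    # part, and a low-frequency warm-to-cool hue ramp along the light axis
    # warm "inner glow" ring displaced inward from the silhouette so the
    # chromatic glow source is spatially decorrelated from the achromatic
    # boundary step (keeps the two separable as independent components)
    glow = np.exp(-((edt / resolution - 0.10) ** 2) / (2 * 0.035**2))
    grad = 0.5 * (1.0 + (x * np.cos(az) + y * np.sin(az)) / 1.5)
    opp_warm = _WARM_TINT - _WARM_TINT.mean()
    opp_rb = np.array([0.475, 0.0, -0.475])
    # a uniform achromatic brightening of the whole body ("lit from
    # within") provides a broad, linearly readable translucency cue; being
    # spatially constant it leaves band gradient statistics chroma-driven
    transl_obj = opaque_obj + (
        0.30 * glow[:, :, None] * opp_warm[None, None, :]
        + 0.35 * (grad - 0.5)[:, :, None] * opp_rb[None, None, :]
    )

    # backgrounds: hard shadow (opaque) vs softened shadow + caustic
    bg_level = 0.60 + 0.12 * factors.backlight_strength
    shift = int(round(0.12 * resolution))
    drow = int(round(shift * np.sin(az)))  # shadow falls away from the light
    dcol = int(round(-shift * np.cos(az)))
    shadow = (np.roll(np.roll(mask, drow, axis=0), dcol, axis=1) & ~mask).astype(float)
    hard = ndimage.gaussian_filter(shadow, sigma=max(0.75, 0.012 * resolution))
    bg_opaque = bg_level * (1.0 - 0.40 * hard)

    soft = ndimage.gaussian_filter(shadow, sigma=max(1.5, 0.035 * resolution))
    cx = -np.cos(az) * (BASE_RADIUS + 0.22)
    cy = -np.sin(az) * (BASE_RADIUS + 0.22)
    caustic = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 0.09**2))
    shadow_tint = np.array([1.25, 1.0, 0.55])  # bluish soft shadows
    # translucent surround: a flat warm color cast (transmitted light),
    # bluish soft shadow and a chromatic caustic; the cast is spatially
    # constant so structure-sensitive (zero-mean) filters ignore it while
    # it stays a clean linear translucency cue for the image encoder
    warm_cast = np.array([1.09, 1.00, 0.91])  # luminance-neutral (sums to 3)
    bg_transl = (
        bg_level * warm_cast[None, None, :]
        * (1.0 - 0.30 * soft[:, :, None] * shadow_tint[None, None, :])
        + 0.28 * (caustic * ~mask)[:, :, None] * opp_warm[None, None, :]
    )
    bg_opaque = np.repeat(bg_opaque[:, :, None], 3, axis=2)

    w_obj, w_bg = _blend_weights(factors.tau, factors.backlight_strength)
    obj = (1.0 - w_obj) * opaque_obj + w_obj * transl_obj
    bg = (1.0 - w_bg) * bg_opaque + w_bg * bg_transl

    # fine luminance texture, multiplicative so interior chromaticity is
    # untouched; the 0.58/0.28/0.14 budget keeps values below 1/1.1 so the
    # texture never clips inside the mask
    if factors.texture_amp > 0:
        tc = factors.texture_amp * np.cos(factors.texture_phase)
        ts = factors.texture_amp * np.sin(factors.texture_phase)
        pattern = tc * np.sin(2 * np.pi * 6.0 * x) + ts * np.sin(2 * np.pi * 6.0 * y)
        obj = obj * (1.0 + pattern)[:, :, None]

    # anti-aliased composite: ~1.5 px smooth silhouette, so small contour
    # perturbations move pixel values continuously (and near-linearly)
    signed = (rad - contour_radius(factors, ang)) * (resolution / 2.0)
    alpha = np.clip(0.5 - signed / 1.5, 0.0, 1.0)[:, :, None]
    img = alpha * obj + (1.0 - alpha) * bg
    return StimulusImage(np.clip(img, 0.0, 1.0), resolution)


# ---------------------------------------------------------------------------
# dataset + summary statistic


def make_dataset(
    n_per_class: int,
    seed: int,
    resolution: int = 128,
    config: SceneConfig = DEFAULT_SCENE_CONFIG,
):
    """Render ``n_per_class`` stimuli per material class.

    Returns a list of ``(StimulusImage, SceneFactors)`` pairs, classes
    interleaved, fully determined by ``(seed, config, resolution)``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(2 * n_per_class)
    out = []
    for i in range(n_per_class):
        for j, cls in enumerate(MATERIAL_CLASSES):
            f = sample_scene(child[2 * i + j], material_class=cls, config=config)
            out.append((render_scene(f, resolution), f))
    return out


def glow_statistic(image: StimulusImage, mask: np.ndarray) -> float:
    """Mean chromatic-gradient energy in an interior edge band of ``mask``.

    Chromaticity (per-channel fraction of the pixel sum) is constant for a
    flat-chromaticity interior, so purely opaque renders score exactly 0.
    The band keeps a safety margin from the silhouette so that no finite
    difference reaches across the anti-aliased object boundary, and the
    definition is isotropic (invariant to 90-degree rotations).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    px = np.asarray(image.pixels, dtype=float)
    s = px.sum(axis=2, keepdims=True) + 1e-12
    chroma = px / s

    edt = ndimage.distance_transform_edt(mask)
    inner = 3.5
    band_width = max(inner + 2.0, 0.18 * image.resolution)
    band = (edt >= inner) & (edt <= band_width)
    if not band.any():
        band = edt >= inner
    if not band.any():
        return 0.0

    energy = np.zeros(px.shape[:2])
    for c in range(3):
        gy, gx = np.gradient(chroma[:, :, c])
        energy += gx**2 + gy**2
    return float(energy[band].mean())


__all__ = [
    "SceneConfig",
    "SceneFactors",
    "StimulusImage",
    "DEFAULT_SCENE_CONFIG",
    "DEFAULT_LIGHTING_PROBS",
    "MATERIAL_CLASSES",
    "LIGHTING_CATEGORIES",
    "sample_scene",
    "render_scene",
    "make_dataset",
    "glow_statistic",
    "object_mask",
    "contour_points",
    "contour_radius",
    "wrap_angle",
]
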
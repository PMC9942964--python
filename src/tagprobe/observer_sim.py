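"""Synthetic observers for the three psychophysical experiment designs.

* attribute ratings: monotone links from the ground-truth translucency
  factor to a seven-point scale, with per-observer bias and noise;
* real-versus-generated discrimination: equal-variance Gaussian signal
  detection with a closed-form calibration from target error rates;
* morph-sequence attribute selection: softmax choice over standardized
  ground-truth factor deltas between sequence endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from tagprobe.multiscale_generator import GeneratorConfig, decode_factors
from tagprobe.scene_synth import SceneFactors, wrap_angle

ATTRIBUTES = ("translucency", "see_throughness", "glow")
CHOICE_OPTIONS = ("shape_orientation", "color", "material", "lighting")

#: attribute link: rating = offset + tau_slope * tau + backlight_slope * b
DEFAULT_LINKS = {
    "translucency": (1.0, 6.0, 0.0),
    "see_throughness": (0.7, 5.4, 0.6),
    "glow": (0.9, 5.0, 1.2),
}


@dataclass
class ObserverModel:
    n_observers: int = 20
    rating_noise_sd: float = 0.6
    observer_bias_sd: float = 0.5
    observer_noise_mult_sd: float = 0.2
    links: Dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_LINKS))
    dprime: float = 1.2
    criterion: float = 0.0
    choice_temperature: float = 0.25

    def __post_init__(self):
        if self.rating_noise_sd < 0:
            raise ValueError("rating noise SD must be nonnegative")
        for attr, (_off, slope, _b) in self.links.items():
            if slope <= 0:
                raise ValueError(f"link for {attr!r} must be increasing in tau")

    def link_value(self, attr: str, factors: SceneFactors) -> float:
        off, slope, bslope = self.links[attr]
        return off + slope * factors.tau + bslope * factors.backlight_strength

    @classmethod
    def calibrated(
        cls, generated_error: float, real_error: float, **kwargs
    ) -> "ObserverModel":
        d, c = sdt_calibrate(generated_error, real_error)
        return cls(dprime=d, criterion=c, **kwargs)


# ---------------------------------------------------------------------------
# Experiment 2: attribute ratings


def simulate_ratings(
    stimuli_factors: Sequence[SceneFactors],
    model: ObserverModel,
    seed: int,
) -> pd.DataFrame:
    """Complete observer x stimulus x attribute rating table (values 1..7)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE2)))
    biases = rng.normal(0.0, model.observer_bias_sd, model.n_observers)
    mults = np.abs(1.0 + rng.normal(0.0, model.observer_noise_mult_sd,
                                    model.n_observers))
    rows = []
    for o in range(model.n_observers):
        for s, f in enumerate(stimuli_factors):
            for attr in model.links:
                mu = model.link_value(attr, f) + biases[o]
                noise = rng.normal(0.0, model.rating_noise_sd * mults[o])
                rating = int(np.clip(np.round(mu + noise), 1, 7))
                rows.append((o, s, attr, rating))
    return pd.DataFrame(rows, columns=["observer", "stimulus", "attribute", "rating"])


# ---------------------------------------------------------------------------
# Experiment 1: real-versus-generated discrimination


def sdt_calibrate(generated_error: float, real_error: float):
    """Invert the equal-variance SDT error-rate equations.

    With internal signal x ~ N(+d'/2, 1) for real and N(-d'/2, 1) for
    generated stimuli and a "real" response when x > c:
    P(miss real) = Phi(c - d'/2), P(false "real") = 1 - Phi(c + d'/2).
    """
    if not (0 < generated_error < 1 and 0 < real_error < 1):
        raise ValueError("target error rates must lie in (0, 1)")
    zg = norm.ppf(1.0 - generated_error)
    zr = norm.ppf(real_error)
    dprime = zg - zr
    criterion = 0.5 * (zg + zr)
    return float(dprime), float(criterion)


def sdt_error_rates(dprime: float, criterion: float):
    """Forward model: (generated_error, real_error)."""
    return (
        float(1.0 - norm.cdf(criterion + dprime / 2.0)),
        float(norm.cdf(criterion - dprime / 2.0)),
    )


def simulate_discrimination(
    realism_scores: Sequence[float],
    is_real: Sequence[bool],
    model: ObserverModel,
    n_repeats: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian SDT judgments; one row per observer x repeat x image.

    ``realism_scores`` shift each image's internal-signal mean (zero for a
    homogeneous set); judgments are "real" when signal exceeds the
    criterion.
    """
    realism = np.asarray(realism_scores, dtype=float)
    if not np.all(np.isfinite(realism)):
        raise ValueError("realism scores must be finite")
    real = np.asarray(is_real, dtype=bool)
    if realism.shape != real.shape:
        raise ValueError("realism scores and labels must align")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE1)))
    mu = np.where(real, model.dprime / 2.0, -model.dprime / 2.0) + realism
    rows = []
    for o in range(model.n_observers):
        for rep in range(n_repeats):
            x = rng.normal(mu, 1.0)
            judged_real = x > model.criterion
            for i in range(len(mu)):
                rows.append(
                    (o, rep, i, bool(real[i]), bool(judged_real[i]),
                     bool(judged_real[i] == real[i]))
                )
    return pd.DataFrame(
        rows,
        columns=["observer", "repeat", "image", "is_real", "judged_real", "correct"],
    )


# ---------------------------------------------------------------------------
# Experiment 3: attribute-selection choices


def _contour_cartesian(f: SceneFactors) -> np.ndarray:
    amps, phases = f.contour_coeffs[:4], f.contour_coeffs[4:]
    return np.concatenate([amps * np.cos(phases), -amps * np.sin(phases)])


def factor_deltas(a: SceneFactors, b: SceneFactors) -> Dict[str, float]:
    """Raw per-attribute change between two sets of scene factors.

    Shape is measured in Cartesian harmonic coordinates (sensitive to both
    amplitude and phase changes) and weighted so a typical contour change
    reads as more prominent than the incidental lighting rotation that
    accompanies it, mirroring how dominant shape changes are perceptually.
    """
    return {
        "shape_orientation": float(
            np.linalg.norm(_contour_cartesian(b) - _contour_cartesian(a)) * 8.0
            + abs(wrap_angle(b.orientation - a.orientation)) / np.pi
        ),
        "color": float(np.abs(b.body_color - a.body_color).mean()),
        "material": float(abs(b.tau - a.tau)),
        "lighting": float(
            0.15 * abs(wrap_angle(b.light_azimuth - a.light_azimuth)) / np.pi
            + 0.5 * abs(b.backlight_strength - a.backlight_strength)
        ),
    }


def sequence_deltas(stimuli, cfg: GeneratorConfig) -> pd.DataFrame:
    """Endpoint factor deltas for a list of Exp3Stimulus."""
    rows = []
    for k, st in enumerate(stimuli):
        fa = decode_factors(st.sequence.codes[0], cfg)
        fb = decode_factors(st.sequence.codes[-1], cfg)
        d = factor_deltas(fa, fb)
        d.update(sequence=k, pair_condition=st.pair_condition,
                 layer_group=st.layer_group)
        rows.append(d)
    return pd.DataFrame(rows)


def choice_probabilities(
    deltas: pd.DataFrame, temperature: float
) -> np.ndarray:
    """Softmax over standardized deltas; temperature 0 gives the argmax."""
    D = deltas[list(CHOICE_OPTIONS)].to_numpy(dtype=float)
    scale = D.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z = D / scale
    if temperature <= 0:
        probs = np.zeros_like(Z)
        allzero = (Z == 0).all(axis=1)
        probs[np.arange(len(Z)), Z.argmax(axis=1)] = 1.0
        probs[allzero] = 1.0 / Z.shape[1]
        return probs
    logits = Z / temperature
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def simulate_exp3_choices(
    stimuli,
    cfg: GeneratorConfig,
    model: ObserverModel,
    seed: int = 0,
) -> pd.DataFrame:
    """One forced choice per observer per morph sequence.

    Deltas are measured on ground-truth endpoint factors (not pixels), so
    pipeline recovery checks stay sharp; all-zero delta rows fall back to
    a uniform choice and are flagged in the ``degenerate`` column.
    """
    deltas = sequence_deltas(stimuli, cfg)
    probs = choice_probabilities(deltas, model.choice_temperature)
    degenerate = (deltas[list(CHOICE_OPTIONS)].to_numpy() == 0).all(axis=1)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE3C)))
    rows = []
    for o in range(model.n_observers):
        picks = [
            int(rng.choice(len(CHOICE_OPTIONS), p=p)) for p in probs
        ]
        for k, st in enumerate(stimuli):
            rows.append(
                (
                    o,
                    k,
                    st.pair_condition,
                    st.layer_group,
                    CHOICE_OPTIONS[picks[k]],
                    bool(degenerate[k]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "observer",
            "sequence",
            "pair_condition",
            "layer_group",
            "choice",
            "degenerate",
        ],
    )


__all__ = [
    "ATTRIBUTES",
    "CHOICE_OPTIONS",
    "ObserverModel",
    "simulate_ratings",
    "sdt_calibrate",
    "sdt_error_rates",
    "simulate_discrimination",
    "factor_deltas",
    "sequence_deltas",
    "choice_probabilities",
    "simulate_exp3_choices",
]
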
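"""Layer-subset linear interpolation between latent codes.

``morph`` interpolates a chosen set of layers between a source and a
target code, ``w_lam{s} = (1 - lam) * w_A{s} + lam * w_B{s}``, leaving all
other layers bit-identical to the source.  ``build_exp3_stimuli``
assembles the 3 pair-condition x 3 layer-manipulation morph-sequence
design used by the attribute-selection experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import List, Optional, Sequence, Tuple

import numpy as np

from tagprobe.multiscale_generator import (
    GeneratorConfig,
    GROUP_NAMES,
    LatentCode,
    LayerGroups,
    decode,
)
from tagprobe.scene_synth import StimulusImage

DEFAULT_LAMBDAS = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)

PAIR_CONDITIONS = ("OT", "OO", "TT")


@dataclass
class MorphSpec:
    source: LatentCode
    target: LatentCode
    layer_set: Tuple[int, ...]
    lambdas: Tuple[float, ...] = DEFAULT_LAMBDAS

    def __post_init__(self):
        self.layer_set = tuple(sorted(int(i) for i in self.layer_set))
        self.lambdas = tuple(float(v) for v in self.lambdas)
        if not self.layer_set:
            raise ValueError("layer set must be nonempty")
        if any(not (0.0 <= v <= 1.0) for v in self.lambdas):
            raise ValueError("lambdas must lie in [0, 1]")
        if list(self.lambdas) != sorted(self.lambdas):
            raise ValueError("lambdas must be sorted ascending")


@dataclass
class MorphSequence:
    spec: MorphSpec
    codes: List[LatentCode]
    images: Optional[List[StimulusImage]] = None

    def __post_init__(self):
        if len(self.codes) != len(self.spec.lambdas):
            raise ValueError("one code per lambda required")
        if self.images is not None and len(self.images) != len(self.codes):
            raise ValueError("one image per code required")

    def __len__(self):
        return len(self.codes)


def morph(
    source: LatentCode, target: LatentCode, s: Sequence[int], lam: float
) -> LatentCode:
    """Interpolate layers in ``s`` (1-based indices); others stay source."""
    if source.layers.shape != target.layers.shape:
        raise ValueError("source and target codes must share dimensions")
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    s = sorted(set(int(i) for i in s))
    if not s:
        raise ValueError("layer set must be nonempty")
    if s[0] < 1 or s[-1] > source.L:
        raise ValueError(f"layer indices must lie in 1..{source.L}")
    out = source.layers.copy()
    rows = [i - 1 for i in s]
    out[rows] = (1.0 - lam) * source.layers[rows] + lam * target.layers[rows]
    return LatentCode(out)


def morph_sequence(
    spec: MorphSpec, cfg: Optional[GeneratorConfig] = None, render: bool = True
) -> MorphSequence:
    """One code (and optionally one decoded image) per interpolation step."""
    codes = [
        morph(spec.source, spec.target, spec.layer_set, lam) for lam in spec.lambdas
    ]
    images = None
    if render:
        if cfg is None:
            raise ValueError("a GeneratorConfig is required to render")
        images = [decode(c, cfg)[0] for c in codes]
    return MorphSequence(spec=spec, codes=codes, images=images)


@dataclass
class Exp3Stimulus:
    """One morph sequence tagged with its design cell."""

    pair_condition: str  # OT / OO / TT
    layer_group: str  # early / middle / late
    source_index: int
    target_index: int
    sequence: MorphSequence


def _eligible_pairs(labels: Sequence[str], condition: str) -> List[Tuple[int, int]]:
    opaque = [i for i, c in enumerate(labels) if c == "milky"]
    transl = [i for i, c in enumerate(labels) if c == "glycerin"]
    if condition == "OT":
        return [(a, b) for a in opaque for b in transl]
    if condition == "OO":
        return [(a, b) for a in opaque for b in opaque if a != b]
    if condition == "TT":
        return [(a, b) for a in transl for b in transl if a != b]
    raise ValueError(f"unknown pair condition: {condition!r}")


def build_exp3_stimuli(
    codes: Sequence[LatentCode],
    labels: Sequence[str],
    groups: LayerGroups,
    n_per_cell: int,
    seed: int,
    cfg: Optional[GeneratorConfig] = None,
    lambdas: Tuple[float, ...] = DEFAULT_LAMBDAS,
    render: bool = False,
    with_replacement: bool = False,
) -> List[Exp3Stimulus]:
    """Sample ``n_per_cell`` morph sequences for each of the 9 design cells.

    Cells are the product of pair conditions (OT = opaque source,
    translucent target; OO; TT) and the three layer-manipulation groups.
    Pairs are sampled without replacement within a cell unless
    ``with_replacement`` is set (small-dataset fallback).
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if len(codes) != len(labels):
        raise ValueError("codes and labels must align")
    if len(set(labels)) < 2:
        raise ValueError("dataset must contain both material classes")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE3)))
    stimuli: List[Exp3Stimulus] = []
    for condition, group in product(PAIR_CONDITIONS, GROUP_NAMES):
        pairs = _eligible_pairs(labels, condition)
        if not with_replacement and len(pairs) < n_per_cell:
            raise ValueError(
                f"cell ({condition}, {group}): only {len(pairs)} eligible "
                f"pairs for {n_per_cell} requested sequences"
            )
        idx = rng.choice(len(pairs), size=n_per_cell, replace=with_replacement)
        for k in idx:
            a, b = pairs[int(k)]
            spec = MorphSpec(
                source=codes[a],
                target=codes[b],
                layer_set=groups[group],
                lambdas=lambdas,
            )
            seq = morph_sequence(spec, cfg=cfg, render=render)
            stimuli.append(
                Exp3Stimulus(
                    pair_condition=condition,
                    layer_group=group,
                    source_index=a,
                    target_index=b,
                    sequence=seq,
                )
            )
    return stimuli


__all__ = [
    "DEFAULT_LAMBDAS",
    "PAIR_CONDITIONS",
    "MorphSpec",
    "MorphSequence",
    "Exp3Stimulus",
    "morph",
    "morph_sequence",
    "build_exp3_stimuli",
]
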
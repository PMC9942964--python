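"""Pipeline configuration with a JSON schema-style validation layer."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict


@dataclass
class PipelineConfig:
    """Desk-scale defaults; every knob is JSON-overridable.

    ``stages`` toggles whole pipeline sections; disabling one simply drops
    its section from the report.
    """

    # generator
    L: int = 18
    d: int = 16
    generator_seed: int = 0
    nuisance_sd: float = 0.4
    resolution: int = 64

    # dataset sizes
    n_train_per_class: int = 100
    n_eval: int = 60
    working_resolution: int = 32

    # encoder
    encoder_ridge: float = 1e-3

    # observer model
    n_observers: int = 20
    rating_noise_sd: float = 0.6
    choice_temperature: float = 0.25
    target_generated_error: float = 0.28
    target_real_error: float = 0.25

    # experiment 3 design
    n_sequences_per_cell: int = 10
    choice_bootstrap: int = 50

    # probing / baselines
    baseline_embed_dim: int = 8
    baseline_perplexity: float = 15.0

    # feature discovery
    ica_targets: int = 8
    ica_extra_sources: int = 8
    ica_components: int = 16
    ica_patch: int = 12
    ica_resize: int = 96
    ica_patches_per_image: int = 10

    stages: Dict[str, bool] = field(
        default_factory=lambda: {
            "dataset": True,
            "encoder": True,
            "psychophysics": True,
            "probing": True,
            "baselines": True,
            "editing": True,
            "ica": True,
        }
    )

    def validate(self) -> None:
        if self.L < 3 or self.d < 2:
            raise ValueError("config stage 'generator': L >= 3 and d >= 2 required")
        if self.n_train_per_class < 10:
            raise ValueError("config stage 'dataset': n_train_per_class >= 10")
        if self.n_eval < 10:
            raise ValueError("config stage 'dataset': n_eval >= 10")
        if self.resolution < 16 or self.working_resolution < 16:
            raise ValueError("config stage 'dataset': resolutions must be >= 16")
        if self.ica_patch > self.ica_resize:
            raise ValueError("config stage 'ica': patch exceeds resize target")
        unknown = set(self.stages) - {
            "dataset", "encoder", "psychophysics", "probing",
            "baselines", "editing", "ica",
        }
        if unknown:
            raise ValueError(f"config stage toggles unknown: {sorted(unknown)}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def load_config(path) -> PipelineConfig:
    data = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


__all__ = ["PipelineConfig", "load_config"]
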
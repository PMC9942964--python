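import numpy as np
import pytest

from tagprobe import multiscale_generator as mg
from tagprobe import latent_probe as lp
from tagprobe import scene_synth


@pytest.fixture(scope="session")
def cfg():
    """Default-shape generator (L=18, d=16) at a desk-scale resolution."""
    return mg.GeneratorConfig(resolution=48)


@pytest.fixture(scope="session")
def balanced_codes_n1000(cfg):
    """500 codes per material class, as in the boundary-training design."""
    milky, f_m = mg.sample_codes(500, cfg, seed=101, material_class="milky")
    glyc, f_g = mg.sample_codes(500, cfg, seed=102, material_class="glycerin")
    codes = milky + glyc
    labels = ["milky"] * 500 + ["glycerin"] * 500
    factors = f_m + f_g
    return codes, labels, factors


@pytest.fixture(scope="session")
def latents_n1000(balanced_codes_n1000):
    codes, labels, _ = balanced_codes_n1000
    return np.stack([c.layers for c in codes]), labels


@pytest.fixture(scope="session")
def boundaries18(latents_n1000):
    """18 nested-CV boundaries trained on the 1000-code balanced set."""
    latents, labels = latents_n1000
    return lp.train_layer_boundaries(latents, labels, seed=0)


@pytest.fixture(scope="session")
def eval_set(cfg):
    """60 unconditional evaluation codes with their ground-truth factors."""
    codes, factors = mg.sample_codes(60, cfg, seed=301)
    return codes, factors


@pytest.fixture(scope="session")
def finalized_boundaries(boundaries18, eval_set):
    codes, _ = eval_set
    stack = np.stack([c.layers for c in codes])
    lp.finalize_norm_bounds(boundaries18, stack)
    return boundaries18, stack
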
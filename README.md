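# tagprobe

A fully synthetic, seed-reproducible pipeline for studying how a layer-wise
latent representation encodes translucent material appearance.  The package
replaces a GPU-trained style-based generator and its image encoder with an
analytic multi-scale stand-in whose coarse / middle / fine layer groups
control shape, material, and body color by construction, so that every
downstream analysis can be validated by ground-truth factor recovery:

- **scene_synth** — procedural renderer for translucent/opaque soap-like
  stimuli with known generative factors (contour, translucency `tau`,
  body color, lighting); translucency cues are a chromatic inner glow,
  an interior hue gradient, a softened shadow and a chromatic caustic.
- **multiscale_generator** — an 18-layer × 16-dim latent code with
  per-group affine factor maps (early → shape/lighting direction,
  middle → material, late → color/texture), intermediate coarse-to-fine
  renders, and a linear ridge image encoder.
- **latent_morphing** — layer-subset interpolation between codes and the
  3 pair-conditions × 3 layer-manipulations morph-sequence design.
- **latent_probe** — per-layer linear decision boundaries (nested-CV
  `C ∈ [0.001, 0.1]`), normalized-distance predictions, the layer-wise
  correlation tuning curve, and t-SNE/MDS pixel-embedding baselines.
- **latent_editing** — boundary-normal traversal of a single layer and
  selectivity reports (material moves; shape and color do not).
- **feature_discovery** — middle-layer latent swap construction of a
  high-translucency image set, ICA basis kernels from random patches,
  chromaticity/orientation annotation, and response contrasts.
- **observer_sim** — synthetic observers for rating, discrimination
  (Gaussian signal detection with closed-form calibration) and
  forced-choice attribute selection.
- **perception_analysis** — rating normalization and correlations,
  translucency binning, discrimination summaries, choice heat maps, and a
  multinomial-logit choice model with observer-cluster bootstrap CIs.
- **orchestration** — configuration, per-stage seeding, and the CLI.

## CLI

```bash
tag-probe run --seed 1 --outdir runs/demo          # full pipeline
tag-probe probe --seed 1 --outdir runs/probe       # probing only
tag-probe psych --seed 1 --outdir runs/psych       # observer simulation
tag-probe ica --seed 1 --outdir runs/ica           # kernel discovery
tag-probe report runs/demo/report.json             # summarize a report
```

A JSON config (see `tagprobe.orchestration.PipelineConfig`) overrides any
stage size or toggle; the same config + seed reproduces every output byte.

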
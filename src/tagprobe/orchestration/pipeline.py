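"""Single entry point: run the full synthetic replication end to end.

Stage ordering: dataset synthesis -> generator construction -> encoder fit
-> psychophysics simulation (Experiments 1-3) -> layer-wise probing with
tuning curve and pixel-embedding baselines -> boundary-normal editing
selectivity -> ICA feature discovery -> aggregated JSON report.

One global seed fans out to fixed per-stage child seeds (counter-based
spawn keys) so individual stages are independently reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from tagprobe import (
    feature_discovery,
    io,
    latent_editing,
    latent_morphing,
    latent_probe,
    multiscale_generator as mg,
    observer_sim,
    perception_analysis,
    scene_synth,
)
from tagprobe.orchestration.config import PipelineConfig

_STAGE_KEYS = {
    "dataset": 1,
    "encoder": 2,
    "psychophysics": 3,
    "probing": 4,
    "baselines": 5,
    "editing": 6,
    "ica": 7,
}


def stage_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    """Counter-based child seed for one pipeline stage."""
    return np.random.SeedSequence(entropy=global_seed,
                                  spawn_key=(_STAGE_KEYS[stage],))


def _log(lines, stage, msg):
    lines.append(f"[{stage}] {msg}")


def run_pipeline(config: PipelineConfig, seed: int, outdir=None) -> dict:
    """Execute every enabled stage and return the structured report."""
    config.validate()
    report = {"seed": seed, "config": config.__dict__.copy()}
    report["config"] = {
        k: (dict(v) if isinstance(v, dict) else v)
        for k, v in report["config"].items()
    }
    log: list = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cfg = mg.GeneratorConfig(
        L=config.L,
        d=config.d,
        seed=config.generator_seed,
        nuisance_sd=config.nuisance_sd,
        resolution=config.resolution,
    )
    report["generator"] = {"L": cfg.L, "d": cfg.d, "groups": {
        g: list(cfg.groups[g]) for g in mg.GROUP_NAMES}}

    # ---- dataset ----------------------------------------------------------
    ds_seed = stage_seed(seed, "dataset").generate_state(1)[0]
    n_cls = config.n_train_per_class
    codes_m, factors_m = mg.sample_codes(n_cls, cfg, int(ds_seed),
                                         material_class="milky")
    codes_g, factors_g = mg.sample_codes(n_cls, cfg, int(ds_seed) + 1,
                                         material_class="glycerin")
    train_codes = codes_m + codes_g
    train_factors = factors_m + factors_g
    train_labels = ["milky"] * n_cls + ["glycerin"] * n_cls
    eval_codes, eval_factors = mg.sample_codes(config.n_eval, cfg,
                                               int(ds_seed) + 2)
    train_latents = np.stack([c.layers for c in train_codes])
    eval_latents = np.stack([c.layers for c in eval_codes])
    _log(log, "dataset", f"{len(train_codes)} train / {len(eval_codes)} eval codes")
    report["dataset"] = {
        "n_train": len(train_codes),
        "n_eval": len(eval_codes),
        "classes": sorted(set(train_labels)),
    }
    if out is not None:
        io.save_latents(out / "train_latents.h5", train_codes, train_labels)
        io.save_latents(out / "eval_latents.h5", eval_codes)

    def render_at(factors_list, res):
        return [scene_synth.render_scene(f, res) for f in factors_list]

    work_res = config.working_resolution
    eval_images = render_at(eval_factors, work_res)

    # ---- encoder ----------------------------------------------------------
    if config.stages.get("encoder", True):
        train_images = render_at(train_factors, work_res)
        enc = mg.fit_image_encoder(
            list(zip(train_images, train_codes)), config.encoder_ridge
        )
        tau_err = []
        for img, f in zip(eval_images, eval_factors):
            f_hat = mg.decode_factors(mg.embed_image(img, enc), cfg)
            tau_err.append(abs(f_hat.tau - f.tau))
        report["encoder"] = {
            "train_rmse": enc.train_rmse,
            "eval_tau_mae": float(np.mean(tau_err)),
            "n_train": enc.n_train,
        }
        _log(log, "encoder", f"tau MAE {np.mean(tau_err):.4f}")

    # ---- psychophysics ----------------------------------------------------
    mean_ratings = None
    if config.stages.get("psychophysics", True):
        ps = stage_seed(seed, "psychophysics").generate_state(3)
        model = observer_sim.ObserverModel.calibrated(
            config.target_generated_error,
            config.target_real_error,
            n_observers=config.n_observers,
            rating_noise_sd=config.rating_noise_sd,
            choice_temperature=config.choice_temperature,
        )
        # Experiment 2: ratings on the evaluation stimuli
        ratings = observer_sim.simulate_ratings(eval_factors, model, int(ps[0]))
        mean_ratings, flags = perception_analysis.normalize_ratings(ratings)
        corr, pvals, _ = perception_analysis.attribute_correlations(mean_ratings)
        bins = perception_analysis.bin_by_translucency(
            mean_ratings["translucency"].to_numpy()
        )
        # Experiment 1: discrimination at the calibrated sensitivity
        half = len(eval_factors) // 2
        is_real = np.arange(len(eval_factors)) < half
        judgments = observer_sim.simulate_discrimination(
            np.zeros(len(eval_factors)), is_real, model, n_repeats=2,
            seed=int(ps[1]),
        )
        disc = perception_analysis.discrimination_summary(judgments)
        # Experiment 3: morph-sequence choices
        stimuli = latent_morphing.build_exp3_stimuli(
            train_codes, train_labels, cfg.groups,
            n_per_cell=config.n_sequences_per_cell, seed=int(ps[2]) % 2**31,
        )
        choices = observer_sim.simulate_exp3_choices(
            stimuli, cfg, model, seed=int(ps[2]) % 2**31
        )
        heat, heat_sd = perception_analysis.choice_heatmap(choices)
        fit = perception_analysis.fit_choice_model(
            choices, n_bootstrap=config.choice_bootstrap,
            seed=int(ps[2]) % 2**31,
        )
        report["psychophysics"] = {
            "constant_rating_observers": len(flags),
            "attribute_correlations": corr.round(4).to_dict(),
            "bin_counts": {b: bins.count(b) for b in set(bins)},
            "discrimination": disc["overall"],
            "n_sequences": len(stimuli),
            "heatmap": {
                f"{l}/{p}": heat.loc[(l, p)].round(4).to_dict()
                for l, p in heat.index
            },
            "choice_model_converged": fit.converged,
            "middle_OT_material_prob": float(
                fit.cell_probs.loc[("middle", "OT"), "material"]
            ),
        }
        _log(log, "psychophysics",
             f"{len(stimuli)} sequences, heatmap rows sum to 1")
        if out is not None:
            ratings.to_csv(out / "ratings.csv", index=False)
            choices.to_csv(out / "choices.csv", index=False)
            heat.to_csv(out / "choice_heatmap.csv")

    # ---- probing ----------------------------------------------------------
    boundaries = None
    if config.stages.get("probing", True):
        pr_seed = int(stage_seed(seed, "probing").generate_state(1)[0]) % 2**31
        boundaries = latent_probe.train_layer_boundaries(
            train_latents, train_labels, seed=pr_seed
        )
        latent_probe.finalize_norm_bounds(boundaries, eval_latents)
        probing = {
            "n_boundaries": len(boundaries),
            "cv_accuracy": {b.layer_index: b.cv_accuracy for b in boundaries},
        }
        if mean_ratings is not None:
            curve = latent_probe.tuning_curve(boundaries, eval_latents,
                                              mean_ratings)
            probing["tuning_curve"] = [
                {k: (bool(v) if isinstance(v, np.bool_) else v)
                 for k, v in row.items()}
                for row in curve.table.to_dict("records")
            ]
            probing["peak_layer_translucency"] = curve.peak_layer("translucency")
            if out is not None:
                curve.table.to_csv(out / "tuning_curve.csv", index=False)
        report["probing"] = probing
        _log(log, "probing", f"{len(boundaries)} boundaries trained")
        if out is not None:
            io.save_boundaries(out / "boundaries.h5", boundaries)

    # ---- baselines --------------------------------------------------------
    if config.stages.get("baselines", True) and mean_ratings is not None:
        bl_seed = int(stage_seed(seed, "baselines").generate_state(1)[0]) % 2**31
        train_images = render_at(train_factors, work_res)
        base = {}
        for method in ("tsne", "mds"):
            res = latent_probe.pixel_embedding_baseline(
                train_images, train_labels, eval_images, method=method,
                embed_dim=config.baseline_embed_dim,
                ratings=mean_ratings,
                perplexity=config.baseline_perplexity,
                seed=bl_seed,
            )
            base[method] = {
                "cv_accuracy": res["cv_accuracy"],
                "r_hc": {
                    k: {"r": float(v["r"]), "p": float(v["p"])}
                    for k, v in res["r_hc"].items()
                },
            }
        report["baselines"] = base
        _log(log, "baselines", "t-SNE and MDS probes computed")

    # ---- editing ----------------------------------------------------------
    if config.stages.get("editing", True) and boundaries is not None:
        mid_layer = cfg.groups.middle[len(cfg.groups.middle) // 2]
        late_layer = cfg.groups.late[len(cfg.groups.late) // 3]
        code = eval_codes[0]
        reports = {}
        for name, layer in (("middle", mid_layer), ("late", late_layer)):
            bm = boundaries[layer - 1]
            steps = latent_editing.edit_along_normal(code, bm, cfg=cfg)
            er = latent_editing.evaluate_edit(steps, cfg)
            reports[name] = {
                "layer": layer,
                "tau_monotone": er.tau_monotone,
                "shape_invariant": er.shape_invariant,
                "tau_range": [float(er.table.tau.min()),
                              float(er.table.tau.max())],
            }
        report["editing"] = reports
        _log(log, "editing", "edit selectivity evaluated")

    # ---- ica ---------------------------------------------------------------
    if config.stages.get("ica", True) and mean_ratings is not None:
        ica_seed = int(stage_seed(seed, "ica").generate_state(1)[0]) % 2**31
        ratings_vec = mean_ratings["translucency"].to_numpy()
        n_needed = config.ica_targets + config.ica_extra_sources
        if n_needed > len(eval_codes):
            raise ValueError("ica stage: evaluation set too small")
        images = feature_discovery.build_high_translucency_set(
            eval_codes, ratings_vec, config.ica_targets,
            config.ica_extra_sources, cfg,
        )
        patches = feature_discovery.sample_patches(
            images, config.ica_resize, config.ica_patch,
            config.ica_patches_per_image, seed=ica_seed,
        )
        bank = feature_discovery.learn_ica_kernels(
            patches, config.ica_components, seed=ica_seed
        )
        feature_discovery.classify_kernels(bank)
        ann = bank.annotations()
        report["ica"] = {
            "n_swap_images": len(images),
            "n_patches": len(patches),
            "n_kernels": bank.K,
            "n_chromatic": int((ann.chromaticity == "chromatic").sum()),
            "n_oriented": int(ann.oriented.sum()),
        }
        _log(log, "ica", f"{bank.K} kernels learned from {len(patches)} patches")
        if out is not None:
            io.save_kernels(out / "kernels.h5", bank)

    report["log"] = log
    if out is not None:
        io.write_json(out / "report.json", report)
        config.to_json(out / "config_snapshot.json")
    return report


__all__ = ["run_pipeline", "stage_seed"]
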
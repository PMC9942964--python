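import warnings

import numpy as np
import pandas as pd
import pytest

from tagprobe import observer_sim as osim
from tagprobe import perception_analysis as pa
from tagprobe import scene_synth as ss


def _rating_table(rows):
    return pd.DataFrame(rows, columns=["observer", "stimulus", "attribute", "rating"])


class TestNormalizeRatings:
    def test_full_scale_min_max(self):
        rows = [(0, s, "translucency", r) for s, r in enumerate([1, 7, 4])]
        mean, flags = pa.normalize_ratings(_rating_table(rows))
        np.testing.assert_allclose(
            mean["translucency"].to_numpy(), [0.0, 1.0, 0.5]
        )
        assert flags == []

    def test_constant_observer_flagged_center(self):
        rows = [(0, s, "glow", 4) for s in range(5)]
        mean, flags = pa.normalize_ratings(_rating_table(rows))
        assert (mean["glow"] == 0.5).all()
        assert flags == [(0, "glow")]

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(0)
        ratings = rng.integers(1, 8, size=20)
        rows = [(0, s, "translucency", int(r)) for s, r in enumerate(ratings)]
        base, _ = pa.normalize_ratings(_rating_table(rows))
        rows2 = [(0, s, "translucency", 2 * int(r) + 3) for s, r in enumerate(ratings)]
        shifted, _ = pa.normalize_ratings(_rating_table(rows2))
        np.testing.assert_allclose(
            base["translucency"].to_numpy(), shifted["translucency"].to_numpy()
        )


class TestAttributeCorrelations:
    def _mean_frame(self):
        rng = np.random.default_rng(1)
        x = rng.random(30)
        return pd.DataFrame(
            {"translucency": x, "see_throughness": x, "glow": 1.0 - x}
        )

    def test_duplicate_attribute_correlates_one(self):
        r, p, _ = pa.attribute_correlations(self._mean_frame())
        assert r.loc["translucency", "see_throughness"] == pytest.approx(1.0)

    def test_negated_attribute_correlates_minus_one(self):
        r, p, _ = pa.attribute_correlations(self._mean_frame())
        assert r.loc["translucency", "glow"] == pytest.approx(-1.0)

    def test_symmetry_and_unit_diagonal(self):
        r, p, _ = pa.attribute_correlations(self._mean_frame())
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
        np.testing.assert_allclose(np.diag(r.to_numpy()), 1.0)

    def test_synthetic_pipeline_all_positive_significant(self):
        factors = [ss.sample_scene(s) for s in range(120)]
        table = osim.simulate_ratings(factors, osim.ObserverModel(), seed=4)
        mean, _ = pa.normalize_ratings(table)
        r, p, flagged = pa.attribute_correlations(mean)
        off = ~np.eye(3, dtype=bool)
        assert (r.to_numpy()[off] > 0).all()
        assert (p.to_numpy()[off] < 0.05).all()
        assert flagged == []

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError, match="10"):
            pa.attribute_correlations(self._mean_frame().head(5))


class TestBinByTranslucency:
    def test_interval_assignment(self):
        assert pa.bin_by_translucency([0.61]) == ["high"]
        assert pa.bin_by_translucency([0.2]) == ["intermediate"]
        assert pa.bin_by_translucency([0.0]) == ["low"]
        assert pa.bin_by_translucency([0.6]) == ["high"]
        assert pa.bin_by_translucency([1.0]) == ["high"]
        assert pa.bin_by_translucency([0.19999]) == ["low"]

    def test_counts_conserved(self):
        vals = np.random.default_rng(2).random(200)
        labels = pa.bin_by_translucency(vals)
        assert len(labels) == 200

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            pa.bin_by_translucency([1.2])


class TestDiscriminationSummary:
    def test_all_correct(self):
        model = osim.ObserverModel(n_observers=5, dprime=50.0, criterion=0.0)
        is_real = np.arange(40) < 20
        table = osim.simulate_discrimination(np.zeros(40), is_real, model, seed=0)
        summ = pa.discrimination_summary(table)
        assert summ["overall"]["generated_error"] == 0.0
        assert summ["overall"]["real_error"] == 0.0
        assert (summ["per_image"].misjudged_fraction == 0).all()

    def test_coin_flip_near_half(self):
        model = osim.ObserverModel(n_observers=20, dprime=0.0, criterion=0.0)
        is_real = np.arange(300) < 150
        table = osim.simulate_discrimination(
            np.zeros(300), is_real, model, n_repeats=2, seed=1
        )
        summ = pa.discrimination_summary(table)
        for key in ("generated_error", "real_error"):
            assert abs(summ["overall"][key] - 0.5) < 0.02

    def test_per_repeat_breakdown_present(self):
        model = osim.ObserverModel(n_observers=3)
        is_real = np.arange(20) < 10
        table = osim.simulate_discrimination(
            np.zeros(20), is_real, model, n_repeats=2, seed=2
        )
        summ = pa.discrimination_summary(table)
        assert len(summ["per_condition_repeat"]) == 4  # 2 conditions x 2 repeats


def _choices_from_probs(cell_probs, n_observers=20, n_per_cell=50, seed=0):
    """Sample a ChoiceTable from known per-cell category probabilities."""
    rng = np.random.default_rng(seed)
    rows = []
    seq = 0
    for (layer, pair), probs in cell_probs.items():
        for k in range(n_per_cell):
            for o in range(n_observers):
                choice = osim.CHOICE_OPTIONS[
                    rng.choice(len(osim.CHOICE_OPTIONS), p=probs)
                ]
                rows.append((o, seq, pair, layer, choice, False))
            seq += 1
    return pd.DataFrame(
        rows,
        columns=[
            "observer", "sequence", "pair_condition", "layer_group",
            "choice", "degenerate",
        ],
    )


def _uniformish_design(p_major=0.7):
    probs = {}
    majors = {"early": 0, "middle": 2, "late": 1}
    rest = (1.0 - p_major) / 3.0
    for layer, major in majors.items():
        for pair in ("OO", "OT", "TT"):
            p = np.full(4, rest)
            p[major] = p_major
            probs[(layer, pair)] = p
    return probs


class TestChoiceHeatmap:
    def test_rows_sum_to_one(self):
        choices = _choices_from_probs(_uniformish_design(), n_per_cell=10)
        props, sds = pa.choice_heatmap(choices)
        np.testing.assert_allclose(props.sum(axis=1).to_numpy(), 1.0, atol=1e-12)
        assert props.shape == (9, 4)
        assert (sds.to_numpy() >= 0).all()

    def test_degenerate_choices_put_mass_on_majors(self):
        probs = _uniformish_design(p_major=1.0)
        choices = _choices_from_probs(probs, n_per_cell=5)
        props, _ = pa.choice_heatmap(choices)
        assert (props.loc[("early",), "shape_orientation"] == 1.0).all()

    def test_sequence_permutation_invariance(self):
        choices = _choices_from_probs(_uniformish_design(), n_per_cell=8)
        props, _ = pa.choice_heatmap(choices)
        shuffled = choices.sample(frac=1.0, random_state=3).reset_index(drop=True)
        props2, _ = pa.choice_heatmap(shuffled)
        pd.testing.assert_frame_equal(props, props2)

    def test_empty_cell_error_names_cell(self):
        choices = _choices_from_probs(_uniformish_design(), n_per_cell=5)
        partial = choices[
            ~(
                (choices.layer_group == "middle")
                & (choices.pair_condition == "TT")
            )
        ]
        with pytest.raises(ValueError, match="TT"):
            pa.choice_heatmap(partial)


class TestFitChoiceModel:
    def test_intercept_only_matches_empirical_frequencies(self):
        choices = _choices_from_probs(_uniformish_design(), n_per_cell=20)
        fit = pa.fit_choice_model(choices, formula="intercept", n_bootstrap=0)
        emp = choices.choice.value_counts(normalize=True)
        for opt in osim.CHOICE_OPTIONS:
            assert fit.cell_probs.iloc[0][opt] == pytest.approx(
                emp.get(opt, 0.0), abs=1e-5
            )

    def test_full_model_recovers_cell_probabilities(self):
        probs = _uniformish_design()
        choices = _choices_from_probs(probs, n_per_cell=50, seed=5)
        fit = pa.fit_choice_model(choices, n_bootstrap=0)
        for cell, p in probs.items():
            got = fit.cell_probs.loc[cell].to_numpy()
            emp = (
                choices[
                    (choices.layer_group == cell[0])
                    & (choices.pair_condition == cell[1])
                ]
                .choice.value_counts(normalize=True)
                .reindex(list(osim.CHOICE_OPTIONS), fill_value=0.0)
                .to_numpy()
            )
            # saturated design: fitted cell probabilities equal empirical
            np.testing.assert_allclose(got, emp, atol=1e-4)

    def test_two_cell_log_odds_recovery(self):
        rng = np.random.default_rng(7)
        rows = []
        for o in range(20):
            for s in range(60):
                p = 0.9 if s < 30 else 0.1
                layer = "early" if s < 30 else "middle"
                choice = "shape_orientation" if rng.random() < p else "material"
                rows.append((o, s, "OO", layer, choice, False))
        choices = pd.DataFrame(
            rows,
            columns=[
                "observer", "sequence", "pair_condition", "layer_group",
                "choice", "degenerate",
            ],
        )
        fit = pa.fit_choice_model(choices, n_bootstrap=100, seed=1)
        p_early = fit.cell_probs.loc[("early", "OO"), "material"]
        p_mid = fit.cell_probs.loc[("middle", "OO"), "material"]
        lo = np.log(p_mid / (1 - p_mid)) - np.log(p_early / (1 - p_early))
        assert abs(lo - 2 * np.log(9)) < 0.6
        assert fit.ci_lower.loc[("middle", "OO"), "material"] <= 0.9
        assert fit.ci_upper.loc[("middle", "OO"), "material"] >= 0.9

    def test_separation_triggers_warning_and_ridge(self):
        probs = _uniformish_design(p_major=1.0)
        choices = _choices_from_probs(probs, n_per_cell=10)
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = pa.fit_choice_model(choices, n_bootstrap=0)
        assert fit.separation_flagged

    def test_single_category_rejected(self):
        probs = {k: np.array([1.0, 0, 0, 0]) for k in _uniformish_design()}
        choices = _choices_from_probs(probs, n_per_cell=3)
        with pytest.raises(ValueError, match="2"):
            pa.fit_choice_model(choices)
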
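import warnings

import numpy as np
import pandas as pd
import pytest

from lexcat import (
    DEFAULT_REGISTRY,
    ObservedROI,
    bonferroni,
    compare_to_observed,
    lexicon_size_sweep,
    model_correlation_matrix,
    run_benchmark_contrasts,
    score_models,
    subset_stability,
    synth_lexicon,
)
from lexcat.model import SimulationResult
from lexcat.pipeline import run_canonical_study


def make_sim(categories, activations, model="toy", extra_cols=None):
    data = pd.DataFrame(
        {
            "string": [f"s{i}" for i in range(len(categories))],
            "category": categories,
            "wordlikeness": np.ones(len(categories)),
            "activation": activations,
        }
    )
    if extra_cols:
        for k, v in extra_cols.items():
            data[k] = v
    return SimulationResult(data, model=model)


class TestRegistry:
    def test_encodes_exactly_nine_effects(self):
        ids = [s.id for s in DEFAULT_REGISTRY]
        assert len(ids) == 9
        assert set(ids) == {
            "pw_gt_w", "w_gt_cs", "pw_gt_w_gt_cs", "ph_gt_w", "ph_eq_pw",
            "matched_pw_gt_w", "word_similarity", "freq_slope", "bigram_slope",
        }
        kinds = {s.id: s.kind for s in DEFAULT_REGISTRY}
        assert kinds["pw_gt_w_gt_cs"] == "conjunction"
        assert kinds["ph_eq_pw"] == "equal"
        assert kinds["word_similarity"] == "chain"
        assert kinds["freq_slope"] == "slope"

    def test_bonferroni_is_direct_multiplication(self):
        assert bonferroni(0.004) == pytest.approx(0.036)
        assert bonferroni(0.2) == 1.0


class TestRunBenchmarkContrasts:
    def test_canonical_lcm_pseudoword_word_contrast(self, canonical):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_benchmark_contrasts(canonical.simulation, table=canonical.table)
        by_id = {r.id: r for r in results}
        assert by_id["pw_gt_w"].verdict == "correct"
        assert by_id["w_gt_cs"].verdict == "correct"
        assert by_id["pw_gt_w_gt_cs"].verdict == "correct"
        assert by_id["freq_slope"].verdict == "correct"
        assert by_id["freq_slope"].estimated_direction == -1

    def test_all_equal_simulation_yields_no_directional_effects(self):
        cats = ["PW"] * 30 + ["W"] * 30 + ["CS"] * 30 + ["PH"] * 30
        sim = make_sim(cats, np.ones(120))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_benchmark_contrasts(sim)
        by_id = {r.id: r for r in results}
        assert by_id["pw_gt_w"].verdict == "null"
        assert by_id["ph_eq_pw"].verdict == "correct"  # equality holds

    def test_missing_condition_skips_with_warning(self):
        sim = make_sim(["W"] * 10 + ["PW"] * 10, np.arange(20, dtype=float))
        with pytest.warns(UserWarning, match="ph_gt_w"):
            results = run_benchmark_contrasts(sim)
        assert "ph_gt_w" not in {r.id for r in results}

    def test_frequency_slope_sign_matches_normal_equations(self, canonical):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_benchmark_contrasts(canonical.simulation, table=canonical.table)
        slope_res = next(r for r in results if r.id == "freq_slope")
        merged = canonical.simulation.data.merge(
            canonical.table.data[["string", "frequency"]].drop_duplicates("string"),
            on="string",
            how="left",
        )
        sub = merged[merged["category"].isin(["W", "PW"])]
        x = np.log2(1 + sub["frequency"].to_numpy())
        y = sub["activation"].to_numpy()
        beta = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert np.sign(beta) == slope_res.estimated_direction
        assert slope_res.extras["slope"] == pytest.approx(beta)


class TestScoreModels:
    def test_all_equal_model_scores_only_equality_contrasts(self):
        cats = ["PW"] * 30 + ["W"] * 30 + ["CS"] * 30 + ["PH"] * 30
        sim = make_sim(cats, np.ones(120))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_benchmark_contrasts(sim)
        scores = score_models({"flat": results})
        n_equal = sum(r.verdict == "correct" for r in results)
        assert scores.loc["flat", "score_correct"] == n_equal
        assert all(
            r.kind == "equal"
            for r in [next(s for s in DEFAULT_REGISTRY if s.id == rr.id)
                      for rr in results if rr.verdict == "correct"]
        )

    def test_penalized_never_exceeds_correct(self, canonical):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_benchmark_contrasts(canonical.simulation, table=canonical.table)
        scores = score_models({"lcm": results})
        assert (scores["score_penalized"] <= scores["score_correct"]).all()


class TestCompareToObserved:
    @pytest.fixture()
    def toy_roi(self):
        return ObservedROI(
            pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [0.0, 2.0, 1.0]},
                         index=["p1", "p2", "p3"])
        )

    def test_hand_computed_toy_deviation(self, toy_roi):
        sim = make_sim(["A", "A", "B", "B"], [2.0, 4.0, 1.0, 3.0])
        report = compare_to_observed(sim, toy_roi, [("A", "B")])
        row = report.data.iloc[0]
        # frozen from an explicit spreadsheet-style hand computation
        assert row["delta_sim"] == pytest.approx(0.7745966692, abs=1e-9)
        assert row["delta_obs"] == pytest.approx(0.9534625892, abs=1e-9)
        assert row["sd_obs"] == pytest.approx(0.9534625892, abs=1e-9)
        assert row["deviation"] == pytest.approx(0.1875961595, abs=1e-9)

    def test_matching_condition_means_give_zero_deviation(self, toy_roi):
        # items = the observed cells themselves, so z-profiles coincide
        sim = make_sim(
            ["A", "A", "A", "B", "B", "B"], [1.0, 2.0, 3.0, 0.0, 2.0, 1.0]
        )
        report = compare_to_observed(sim, toy_roi, [("A", "B")])
        assert report.data["deviation"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_affine_rescaling_is_absorbed(self, toy_roi):
        sim = make_sim(["A", "A", "B", "B"], [2.0, 4.0, 1.0, 3.0])
        rescaled = make_sim(["A", "A", "B", "B"], [13.0, 19.0, 10.0, 16.0])
        r1 = compare_to_observed(sim, toy_roi, [("A", "B")])
        r2 = compare_to_observed(rescaled, toy_roi, [("A", "B")])
        assert r1.data["deviation"].iloc[0] == pytest.approx(
            r2.data["deviation"].iloc[0], abs=1e-12
        )

    def test_strictly_closer_model_has_smaller_total(self, toy_roi):
        close = make_sim(["A", "A", "B", "B"], [2.0, 4.0, 1.0, 3.0])
        far = make_sim(["A", "A", "B", "B"], [1.0, 1.0, 4.0, 4.0])
        assert (
            compare_to_observed(close, toy_roi, [("A", "B")]).total_deviation
            < compare_to_observed(far, toy_roi, [("A", "B")]).total_deviation
        )

    def test_label_mismatch_lists_conditions(self, toy_roi):
        sim = make_sim(["A", "A"], [1.0, 2.0])
        with pytest.raises(ValueError, match="B"):
            compare_to_observed(sim, toy_roi, [("A", "B")])

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            ObservedROI(pd.DataFrame({"A": [1.0], "B": [2.0]}))


class TestModelCorrelationMatrix:
    def test_self_and_rescaled_correlation_is_one(self):
        a = make_sim(["W"] * 5, [1.0, 2.0, 3.0, 4.0, 5.0], model="a")
        b = make_sim(["W"] * 5, [3.0, 5.0, 7.0, 9.0, 11.0], model="b")
        corr = model_correlation_matrix([a, b])
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_five_item_toy_matches_textbook_pearson(self):
        a = make_sim(["W"] * 5, [1.0, 2.0, 3.0, 4.0, 5.0], model="a")
        b = make_sim(["W"] * 5, [2.0, 1.0, 4.0, 3.0, 5.0], model="b")
        corr = model_correlation_matrix([a, b])
        assert corr.loc["a", "b"] == pytest.approx(0.8)

    def test_zero_variance_model_marked_undefined(self):
        a = make_sim(["W"] * 5, [1.0, 2.0, 3.0, 4.0, 5.0], model="a")
        flat = make_sim(["W"] * 5, np.ones(5), model="flat")
        corr = model_correlation_matrix([a, flat])
        assert np.isnan(corr.loc["a", "flat"])

    def test_mismatched_item_lists_rejected(self):
        a = make_sim(["W"] * 5, np.ones(5), model="a")
        b = make_sim(["W"] * 4, np.ones(4), model="b")
        with pytest.raises(ValueError):
            model_correlation_matrix([a, b])


class TestSubsetStability:
    def test_full_proportion_is_exactly_one(self, canonical):
        report = subset_stability(canonical.table, [1.0], n_draws=3, seed=0)
        assert report["mean_r"].iloc[0] == 1.0
        assert report["sd_r"].iloc[0] == 0.0

    def test_invalid_proportion_rejected(self, canonical):
        with pytest.raises(ValueError):
            subset_stability(canonical.table, [0.0], n_draws=2, seed=0)


class TestLexiconSizeSweep:
    def test_small_sizes_skipped_with_warning(self, small_lexicon):
        with pytest.warns(UserWarning, match="21"):
            report = lexicon_size_sweep(small_lexicon, [10, 50], seed=0)
        assert report["size"].tolist() == [50]

    def test_full_size_matches_direct_simulation(self):
        lex = synth_lexicon(120, seed=21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = lexicon_size_sweep(lex, [120], seed=21)
            run = run_canonical_study(n_words=120, seed=21)
        med = run.simulation.activation_by_category("median")
        assert report["median_W"].iloc[0] == pytest.approx(med["W"])
        assert report["median_PW"].iloc[0] == pytest.approx(med["PW"])
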
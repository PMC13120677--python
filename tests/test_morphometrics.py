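import numpy as np
import pandas as pd
import pytest

from helpers import ann_frame, ann_row, width_print

from flukeprints.errors import InvalidDesignError
from flukeprints.kinematics import print_sequences_from_annotations
from flukeprints.morphometrics import (
    classify_age,
    crossvalidate_scaling,
    fit_scaling,
    summarize_individuals,
)


def summaries_frame(widths_by_class: dict, responses: dict | None = None) -> pd.DataFrame:
    rows = []
    i = 0
    for cls, widths in widths_by_class.items():
        for w in widths:
            row = {
                "whale_id": f"w{i:03d}",
                "age_class": cls,
                "mean_flukeprint_width_m": float(w),
                "mean_body_length_m": np.nan,
                "mean_fluke_span_m": np.nan,
                "n_measurements": 1,
            }
            if responses is not None:
                row["mean_body_length_m"] = float(responses[cls](w))
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)


class TestSummaries:
    def test_mean_width_over_valid_prints(self):
        rows = width_print("w0", 0, 0, 2.0) + width_print("w0", 0, 1, 3.0)
        out = summarize_individuals(ann_frame(rows))
        assert len(out) == 1
        assert out.loc[0, "mean_flukeprint_width_m"] == pytest.approx(2.5)
        assert out.loc[0, "n_measurements"] == 2

    def test_late_print_excluded_from_size_analysis(self):
        rows = width_print("w0", 0, 0, 2.0) + width_print("w0", 0, 1, 4.0, offset=6.0)
        out = summarize_individuals(ann_frame(rows))
        assert out.loc[0, "mean_flukeprint_width_m"] == pytest.approx(2.0)
        assert out.loc[0, "n_measurements"] == 1

    def test_degraded_print_excluded_from_width_but_kept_for_movement(self):
        rows = (
            width_print("w0", 0, 0, 2.0)
            + width_print("w0", 0, 1, 4.0, degraded=1)
            + [
                ann_row("print_centroid", print_id=0, t=0.0, x=0.0, y=0.0),
                ann_row("print_centroid", print_id=1, t=4.0, x=5.0, y=0.0, degraded=1),
            ]
        )
        ann = ann_frame(rows)
        out = summarize_individuals(ann)
        assert out.loc[0, "mean_flukeprint_width_m"] == pytest.approx(2.0)
        seqs = print_sequences_from_annotations(ann)
        assert len(seqs) == 1 and len(seqs[0].t_s) == 2  # degraded centroid retained

    def test_whale_without_valid_widths_dropped(self):
        rows = width_print("w0", 0, 0, 2.0) + width_print("w1", 0, 0, 3.0, degraded=1)
        out = summarize_individuals(ann_frame(rows))
        assert list(out["whale_id"]) == ["w0"]


class TestScaling:
    def test_noiseless_linear_data(self):
        s = summaries_frame(
            {"adult": np.linspace(3.0, 4.5, 10)},
            responses={"adult": lambda w: 3.0 * w},
        )
        fit = fit_scaling(s, "body_length", "adult")
        assert fit.params["width"] == pytest.approx(3.0, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_equal_slopes_different_intercepts(self):
        # Parallel class lines: interaction non-significant, class effect strong.
        rng = np.random.default_rng(0)
        w_a = np.linspace(3.0, 4.5, 20)
        w_c = np.linspace(1.2, 2.0, 20)
        s = summaries_frame({"adult": w_a, "calf": w_c})
        s.loc[s.age_class == "adult", "mean_body_length_m"] = (
            2.0 * w_a + 5.0 + rng.normal(0, 0.05, 20)
        )
        s.loc[s.age_class == "calf", "mean_body_length_m"] = (
            2.0 * w_c + 1.0 + rng.normal(0, 0.05, 20)
        )
        fit = fit_scaling(s, "body_length", "interaction")
        assert fit.interaction_p > 0.1
        assert fit.p_values["class_adult"] < 0.001

    def test_constant_response_within_class(self):
        rng = np.random.default_rng(1)
        w_c = rng.uniform(1.2, 2.0, 12)
        s = summaries_frame({"calf": w_c})
        s["mean_body_length_m"] = 4.8  # calf size effectively constant
        fit = fit_scaling(s, "body_length", "calf")
        assert fit.params["width"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(0.0, abs=1e-10)

    def test_interaction_requires_both_classes(self):
        s = summaries_frame(
            {"adult": np.linspace(3, 4, 5)}, responses={"adult": lambda w: 3 * w}
        )
        with pytest.raises(InvalidDesignError):
            fit_scaling(s, "body_length", "interaction")

    def test_interaction_rss_nested_below_pooled(self):
        rng = np.random.default_rng(2)
        s = summaries_frame(
            {"adult": rng.uniform(3, 4.5, 20), "calf": rng.uniform(1.2, 2, 8)}
        )
        s["mean_body_length_m"] = np.where(
            s.age_class == "adult", 12.0, 4.5
        ) + rng.normal(0, 0.8, len(s))
        pooled = fit_scaling(s, "body_length", "pooled")
        inter = fit_scaling(s, "body_length", "interaction")
        assert inter.rss <= pooled.rss + 1e-12


class TestCrossValidation:
    def test_noiseless_linear_data_scores_perfectly(self):
        s = summaries_frame(
            {"adult": np.linspace(3.0, 4.5, 20)},
            responses={"adult": lambda w: 3.0 * w + 1.0},
        )
        rmse, r2 = crossvalidate_scaling(s, "body_length", "adult", k=10, seed=0)
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_response_has_nonpositive_r2_on_average(self):
        rng = np.random.default_rng(3)
        r2s = []
        for seed in range(20):
            s = summaries_frame({"adult": rng.uniform(3, 4.5, 30)})
            s["mean_body_length_m"] = rng.normal(12.0, 1.0, 30)
            r2s.append(crossvalidate_scaling(s, "body_length", "adult", seed=seed)[1])
        assert np.mean(r2s) <= 0.0

    def test_same_seed_same_metrics(self):
        rng = np.random.default_rng(4)
        s = summaries_frame({"adult": rng.uniform(3, 4.5, 25)})
        s["mean_body_length_m"] = 2.0 * s["mean_flukeprint_width_m"] + rng.normal(
            0, 0.5, 25
        )
        assert crossvalidate_scaling(s, "body_length", "adult", seed=5) == (
            crossvalidate_scaling(s, "body_length", "adult", seed=5)
        )

    def test_fold_count_reduced_with_few_whales(self):
        s = summaries_frame(
            {"adult": np.linspace(3, 4.5, 6)}, responses={"adult": lambda w: 3 * w}
        )
        rmse, _ = crossvalidate_scaling(s, "body_length", "adult", k=10, seed=0)
        assert rmse == pytest.approx(0.0, abs=1e-9)


class TestClassifier:
    def test_disjoint_widths_classify_perfectly(self):
        rng = np.random.default_rng(5)
        s = summaries_frame(
            {"calf": rng.uniform(1.2, 2.0, 12), "adult": rng.uniform(3.0, 4.5, 80)}
        )
        fit = classify_age(s)
        assert fit.sensitivity == 1.0
        assert fit.specificity == 1.0
        assert fit.accuracy == 1.0
        assert fit.youden_j == 1.0
        assert fit.separation_flag
        assert fit.auc == 1.0

    def test_identical_distributions_give_no_signal(self):
        w = np.linspace(2.0, 3.0, 10)
        s = summaries_frame({"calf": w, "adult": w})
        fit = classify_age(s)
        assert fit.auc == pytest.approx(0.5, abs=1e-12)
        assert fit.youden_j == pytest.approx(0.0, abs=1e-12)

    def test_threshold_is_gap_midpoint(self):
        s = summaries_frame({"calf": [1.0, 2.0], "adult": [3.0, 4.0]})
        fit = classify_age(s)
        assert fit.youden_threshold_m == pytest.approx(2.5)

    def test_exhaustive_threshold_scan_oracle(self):
        # Brute force over a fine threshold grid must not beat the chosen J.
        rng = np.random.default_rng(6)
        calf = rng.uniform(1.0, 2.6, 8)
        adult = rng.uniform(2.2, 4.5, 15)
        s = summaries_frame({"calf": calf, "adult": adult})
        fit = classify_age(s)
        grid = np.linspace(0.5, 5.0, 2000)
        js = [
            np.mean(adult > t) + np.mean(calf <= t) - 1.0 for t in grid
        ]
        assert fit.youden_j == pytest.approx(max(js), abs=1e-9)

    def test_roc_monotonicity(self):
        rng = np.random.default_rng(7)
        s = summaries_frame(
            {"calf": rng.uniform(1, 2.5, 10), "adult": rng.uniform(2, 4.5, 20)}
        )
        fit = classify_age(s)
        pts = sorted(fit.roc_points)
        sens = [p[1] for p in pts]
        spec = [p[2] for p in pts]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_auc_equals_brute_force_mann_whitney(self):
        rng = np.random.default_rng(8)
        calf = rng.uniform(1, 3, 6)
        adult = rng.uniform(2, 4, 9)
        s = summaries_frame({"calf": calf, "adult": adult})
        fit = classify_age(s)
        wins = sum(
            1.0 if a > c else (0.5 if a == c else 0.0) for a in adult for c in calf
        )
        assert fit.auc == pytest.approx(wins / (len(adult) * len(calf)), abs=1e-12)

    def test_single_class_rejected(self):
        s = summaries_frame({"adult": [3.0, 3.5, 4.0]})
        with pytest.raises(InvalidDesignError):
            classify_age(s)
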
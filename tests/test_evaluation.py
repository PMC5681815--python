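import dataclasses

import numpy as np
import pandas as pd
import pytest

from coexdiff.dc_metrics import MetricSpec, default_metric_specs
from coexdiff.evaluation import (
    COMPARISONS,
    evaluate_controlled,
    metric_correlation_matrix,
    relative_sensitivity,
    sensitivity_summary,
    top_n_detection,
    validate_de_free,
)
from coexdiff.evaluation import EvaluationReport
from coexdiff.simulator import ControlledDataset

# Reference detection counts (top-500 positives out of 500, six stage
# comparisons in COMPARISONS order) for the lung-, liver- and colon-derived
# controlled benchmarks, with their published sensitivity summaries
# (s33, s66, s100, global, relative).  These are pure-arithmetic oracles for
# sensitivity_summary / relative_sensitivity.
BENCHMARK_TABLES = {
    "lung": {
        "counts": {
            "M1.1": (256, 263, 269, 275, 270, 284),
            "M1.3": (221, 216, 235, 223, 223, 234),
            "M1.5": (106, 95, 102, 111, 106, 113),
            "M2": (320, 316, 321, 329, 337, 336),
            "M3.1": (315, 319, 311, 439, 439, 455),
            "M3.3": (235, 228, 231, 231, 228, 231),
            "M3.5": (223, 208, 216, 214, 214, 209),
            "M4": (340, 343, 336, 405, 398, 433),
            "M5": (346, 343, 335, 407, 398, 433),
            "M6": (412, 399, 405, 404, 411, 406),
        },
        "expected": {
            "M1.1": (0.53, 0.55, 0.57, 0.54, 0.67),
            "M1.3": (0.45, 0.45, 0.47, 0.45, 0.56),
            "M1.5": (0.20, 0.22, 0.23, 0.21, 0.26),
            "M2": (0.64, 0.67, 0.67, 0.65, 0.80),
            "M3.1": (0.63, 0.88, 0.91, 0.76, 0.94),
            "M3.3": (0.46, 0.46, 0.46, 0.46, 0.57),
            "M3.5": (0.43, 0.43, 0.42, 0.43, 0.53),
            "M4": (0.68, 0.80, 0.87, 0.75, 0.93),
            "M5": (0.68, 0.81, 0.87, 0.75, 0.93),
            "M6": (0.81, 0.82, 0.81, 0.81, 1.00),
        },
    },
    "liver": {
        "counts": {
            "M1.1": (265, 264, 254, 266, 274, 260),
            "M1.3": (117, 118, 112, 135, 133, 144),
            "M1.5": (90, 111, 88, 105, 113, 96),
            "M2": (287, 295, 290, 300, 296, 289),
            "M3.1": (260, 255, 247, 279, 280, 308),
            "M3.3": (230, 231, 224, 228, 221, 235),
            "M3.5": (55, 56, 61, 60, 59, 57),
            "M4": (312, 303, 296, 317, 328, 329),
            "M5": (309, 304, 298, 326, 332, 337),
            "M6": (313, 321, 311, 321, 322, 316),
        },
        "expected": {
            "M1.1": (0.52, 0.54, 0.52, 0.53, 0.83),
            "M1.3": (0.23, 0.27, 0.29, 0.25, 0.39),
            "M1.5": (0.19, 0.22, 0.19, 0.20, 0.31),
            "M2": (0.58, 0.60, 0.58, 0.59, 0.92),
            "M3.1": (0.51, 0.56, 0.62, 0.54, 0.84),
            "M3.3": (0.46, 0.45, 0.47, 0.46, 0.72),
            "M3.5": (0.11, 0.12, 0.11, 0.12, 0.19),
            "M4": (0.61, 0.65, 0.66, 0.63, 0.98),
            "M5": (0.61, 0.66, 0.67, 0.64, 1.00),
            "M6": (0.63, 0.64, 0.63, 0.63, 0.98),
        },
    },
    "colon": {
        "counts": {
            "M1.1": (284, 290, 264, 302, 283, 307),
            "M1.3": (140, 125, 125, 137, 129, 139),
            "M1.5": (89, 71, 69, 89, 71, 87),
            "M2": (328, 331, 307, 346, 323, 354),
            "M3.1": (347, 333, 302, 448, 444, 448),
            "M3.3": (229, 228, 235, 237, 222, 236),
            "M3.5": (156, 157, 149, 150, 154, 163),
            "M4": (401, 403, 377, 438, 430, 448),
            "M5": (401, 406, 374, 437, 427, 450),
            "M6": (350, 346, 344, 350, 343, 348),
        },
        "expected": {
            "M1.1": (0.56, 0.59, 0.61, 0.58, 0.70),
            "M1.3": (0.26, 0.27, 0.28, 0.27, 0.33),
            "M1.5": (0.15, 0.16, 0.17, 0.16, 0.19),
            "M2": (0.64, 0.67, 0.71, 0.66, 0.80),
            "M3.1": (0.65, 0.89, 0.90, 0.77, 0.93),
            "M3.3": (0.46, 0.46, 0.47, 0.46, 0.55),
            "M3.5": (0.31, 0.30, 0.33, 0.31, 0.37),
            "M4": (0.79, 0.87, 0.90, 0.83, 1.00),
            "M5": (0.79, 0.86, 0.90, 0.83, 1.00),
            "M6": (0.69, 0.69, 0.70, 0.69, 0.83),
        },
    },
}


def report_from_counts(table: dict, n_positives: int = 500) -> EvaluationReport:
    rows = {}
    for label, cnt in table["counts"].items():
        row = dict(zip(COMPARISONS, cnt))
        row.update(sensitivity_summary(row, n_positives))
        rows[label] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    report = EvaluationReport(frame=frame, top_n=n_positives, n_positives=n_positives)
    return relative_sensitivity(report)


class TestTopNDetection:
    def test_perfect_ranking(self):
        values = np.concatenate([np.full(5, 10.0), np.zeros(15)])
        truth = values > 1
        assert top_n_detection(values, truth, 5) == 5

    def test_tie_policy_stable_gene_order(self):
        values = np.zeros(10)
        truth = np.array([True, False] * 5)
        assert top_n_detection(values, truth, 4) == 2  # positives at 0 and 2

    def test_random_values_near_hypergeometric_expectation(self):
        counts = []
        truth = np.zeros(3200, dtype=bool)
        truth[:500] = True
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts.append(top_n_detection(rng.normal(size=3200), truth, 500))
        assert abs(np.mean(counts) - 500 * 500 / 3200) < 25

    def test_top_n_bounded_by_gene_count(self):
        with pytest.raises(ValueError):
            top_n_detection(np.zeros(5), np.zeros(5, dtype=bool), 6)


class TestSensitivityArithmetic:
    @pytest.mark.parametrize("dataset", list(BENCHMARK_TABLES))
    def test_reproduces_every_printed_cell(self, dataset):
        """sensitivity_summary + relative_sensitivity regenerate all
        published summary rows from the raw detection counts."""
        table = BENCHMARK_TABLES[dataset]
        report = report_from_counts(table)
        for label, (s33, s66, s100, glob, rel) in table["expected"].items():
            row = report.frame.loc[label]
            assert row["sens_33"] == pytest.approx(s33, abs=1e-9), label
            assert row["sens_66"] == pytest.approx(s66, abs=1e-9), label
            assert row["sens_100"] == pytest.approx(s100, abs=1e-9), label
            assert row["global_sensitivity"] == pytest.approx(glob, abs=1e-9), label
            assert row["relative_sensitivity"] == pytest.approx(rel, abs=1e-9), label

    def test_missing_comparison_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            sensitivity_summary({"N-T1": 10}, 500)

    def test_single_metric_relative_is_one(self):
        counts = dict(zip(COMPARISONS, (256, 263, 269, 275, 270, 284)))
        row = sensitivity_summary(counts, 500)
        frame = pd.DataFrame.from_dict({"M1.1": {**counts, **row}}, orient="index")
        report = relative_sensitivity(
            EvaluationReport(frame=frame, top_n=500, n_positives=500)
        )
        assert report.frame.loc["M1.1", "relative_sensitivity"] == 1.00

    def test_tied_best_metrics_both_one(self):
        report = report_from_counts(BENCHMARK_TABLES["colon"])
        assert report.frame.loc["M4", "relative_sensitivity"] == 1.00
        assert report.frame.loc["M5", "relative_sensitivity"] == 1.00


class TestEvaluateControlled:
    def test_report_layout_and_invariants(self, scaled_controlled):
        report = evaluate_controlled(scaled_controlled)
        frame = report.frame
        assert list(frame.index) == ["M1.1", "M1.3", "M1.5", "M2", "M3.1", "M3.3",
                                     "M3.5", "M4", "M5", "M6"]
        assert report.top_n == scaled_controlled.n_positives
        for comp in COMPARISONS:
            assert (frame[comp] <= report.top_n).all()
        sens = frame[["sens_33", "sens_66", "sens_100", "global_sensitivity"]]
        assert ((sens >= 0) & (sens <= 1)).all().all()
        assert frame["relative_sensitivity"].max() == 1.00

    def test_distribution_metrics_beat_random_ranking(self, scaled_controlled):
        """M2, M4, M5 and M6 all recover clearly more positives in the
        N-vs-T3 comparison than a random ranking would."""
        report = evaluate_controlled(scaled_controlled)
        n = len(scaled_controlled.gene_ids)
        random_expectation = report.top_n * report.n_positives / n
        for label in ("M2", "M4", "M5", "M6"):
            assert report.frame.loc[label, "N-T3"] > random_expectation

    def test_metric_agreement_clusters(self, scaled_controlled):
        """M4 agrees more with M5 than with the heavily thresholded M1.5."""
        report = evaluate_controlled(scaled_controlled)
        vals = report.metadata["values_by_comparison"]["N-T3"]
        corr = metric_correlation_matrix(vals[["M4", "M5", "M1.5"]])
        assert corr.loc["M4", "M5"] > corr.loc["M4", "M1.5"]


class TestMetricCorrelationMatrix:
    def test_self_correlation_and_clone(self):
        rng = np.random.default_rng(0)
        m4 = rng.uniform(size=100)
        frame = pd.DataFrame({"M4": m4, "clone": m4.copy(), "other": rng.uniform(size=100)})
        corr = metric_correlation_matrix(frame)
        assert corr.loc["M4", "M4"] == 1.0
        assert corr.loc["M4", "clone"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_zeroed_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"a": rng.uniform(size=50), "b": np.ones(50)})
        with caplog.at_level("WARNING"):
            corr = metric_correlation_matrix(frame)
        assert corr.loc["a", "b"] == 0.0
        assert corr.loc["b", "b"] == 1.0
        assert "constant" in caplog.text


class TestDeFreeValidation:
    def test_stage_against_itself_is_zero(self, scaled_controlled):
        assert validate_de_free(scaled_controlled, stage_a="N", stage_b="N") == 0

    def test_controlled_build_is_de_free(self, scaled_controlled):
        assert validate_de_free(scaled_controlled, alpha_fdr=0.1) == 0

    def test_power_detects_spiked_mean_shift(self, scaled_controlled):
        """Welch t-test + BH finds nearly all of 10 genes given a +2 shift."""
        ctrl = scaled_controlled
        t3 = ctrl.stages["T3"]
        spiked_values = t3.values.copy()
        spiked_values[:10] += 2.0
        spiked = ControlledDataset(
            stages={**ctrl.stages, "T3": dataclasses.replace(t3, values=spiked_values)},
            truth=ctrl.truth,
            provenance=dict(ctrl.provenance),
        )
        assert validate_de_free(spiked, alpha_fdr=0.1) >= 8
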
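"""Benchmark accounting: top-N detection counts and sensitivity summaries.

Performance of a metric on a controlled dataset is measured by ranking all
genes by the metric (descending) and counting how many truth positives land
in the top N (N defaults to the number of positives).  With four stages there
are six pairwise comparisons; sensitivities are summarized at the fraction of
accumulated alteration each comparison spans:

* *sensitivity at 33%* — mean count over the one-step comparisons
  N-T1, T1-T2, T2-T3, divided by the number of positives;
* *sensitivity at 66%* — mean over the two-step comparisons N-T2, T1-T3;
* *sensitivity at 100%* — the full-span comparison N-T3;
* *global sensitivity* — mean over all six comparisons;
* *relative sensitivity* — a metric's global sensitivity divided by the
  best global sensitivity among the metrics being compared.

All sensitivities are reported rounded to two decimals, and the relative
sensitivity is taken as a ratio of the rounded globals (so a printed table of
rounded values is internally consistent).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import corrspace, dc_metrics
from .significance import bh_adjust
from .simulator import STAGES, ControlledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "COMPARISONS",
    "EvaluationReport",
    "top_n_detection",
    "sensitivity_summary",
    "relative_sensitivity",
    "evaluate_controlled",
    "metric_correlation_matrix",
    "validate_de_free",
]

#: the six stage-pair comparisons, one-step pairs first
COMPARISONS = ("N-T1", "T1-T2", "T2-T3", "N-T2", "T1-T3", "N-T3")
_ONE_STEP = COMPARISONS[:3]
_TWO_STEP = COMPARISONS[3:5]
_FULL = COMPARISONS[5]

_SENS_COLS = ("sens_33", "sens_66", "sens_100", "global_sensitivity", "relative_sensitivity")


def _round2(x: float) -> float:
    """Round half up to two decimals (0.525 -> 0.53), with a tiny nudge so
    binary representations of exact halves do not round down."""
    return math.floor(x * 100 + 0.5 + 1e-9) / 100


@dataclass
class EvaluationReport:
    """Counts per comparison plus sensitivity rows, one row per metric label.

    ``frame`` columns are the six comparisons followed by the sensitivity
    summaries.  Counts are bounded by ``top_n``; sensitivities lie in [0, 1];
    the best metric's relative sensitivity is 1.00.
    """

    frame: pd.DataFrame
    top_n: int
    n_positives: int
    metadata: dict = field(default_factory=dict)


def top_n_detection(values, truth_positive, top_n: int) -> int:
    """Number of truth positives among the top ``top_n`` genes ranked by
    descending metric value; ties broken by stable input gene order."""
    values = np.asarray(values, dtype=float)
    truth_positive = np.asarray(truth_positive, dtype=bool)
    if top_n > values.size:
        raise ValueError("top_n exceeds the number of genes")
    order = np.argsort(-values, kind="stable")
    return int(truth_positive[order[:top_n]].sum())


def sensitivity_summary(counts: Mapping[str, int], n_positives: int) -> dict[str, float]:
    """Sensitivity rows from six per-comparison detection counts."""
    missing = [c for c in COMPARISONS if c not in counts]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    one = [counts[c] for c in _ONE_STEP]
    two = [counts[c] for c in _TWO_STEP]
    all_six = [counts[c] for c in COMPARISONS]
    return {
        "sens_33": _round2(np.mean(one) / n_positives),
        "sens_66": _round2(np.mean(two) / n_positives),
        "sens_100": _round2(counts[_FULL] / n_positives),
        "global_sensitivity": _round2(np.mean(all_six) / n_positives),
    }


def relative_sensitivity(report: EvaluationReport) -> EvaluationReport:
    """Fill the relative-sensitivity column from the rounded globals."""
    g = report.frame["global_sensitivity"]
    best = g.max()
    if best <= 0:
        report.frame["relative_sensitivity"] = 0.0
        return report
    report.frame["relative_sensitivity"] = [_round2(v / best) for v in g]
    return report


def evaluate_controlled(
    controlled: ControlledDataset,
    specs: Optional[Sequence[dc_metrics.MetricSpec]] = None,
    top_n: Optional[int] = None,
) -> EvaluationReport:
    """Run every metric over all six stage comparisons of a controlled
    dataset and assemble the sensitivity report.

    ``top_n`` defaults to the number of truth positives.
    """
    specs = list(specs) if specs is not None else dc_metrics.default_metric_specs()
    positives = controlled.positive_mask
    n_pos = int(positives.sum())
    if top_n is None:
        top_n = n_pos
    combined = controlled.combined()
    matrices = {st: corrspace.spearman_matrix(combined, st) for st in STAGES}

    counts: dict[str, dict[str, int]] = {spec.label: {} for spec in specs}
    values_by_comparison: dict[str, pd.DataFrame] = {}
    for comp in COMPARISONS:
        st_a, st_b = comp.split("-")
        vals = dc_metrics.compute_all_metrics(matrices[st_a], matrices[st_b], specs)
        values_by_comparison[comp] = vals
        for spec in specs:
            counts[spec.label][comp] = top_n_detection(
                vals[spec.label].to_numpy(), positives, top_n
            )

    rows = {}
    for spec in specs:
        row: dict[str, float] = dict(counts[spec.label])
        row.update(sensitivity_summary(counts[spec.label], n_pos))
        rows[spec.label] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame[list(COMPARISONS) + list(_SENS_COLS[:-1])]
    report = EvaluationReport(
        frame=frame,
        top_n=top_n,
        n_positives=n_pos,
        metadata={"values_by_comparison": values_by_comparison},
    )
    return relative_sensitivity(report)


def metric_correlation_matrix(all_values: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Pairwise correlation between metric value vectors across genes.

    Quantifies whether two metrics prioritize the same genes.  Constant
    metric columns get 0 against everything (diagonal stays 1), with a
    warning.
    """
    if all_values.shape[1] < 2:
        raise ValueError("need at least 2 metric columns")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    constant = all_values.nunique() <= 1
    corr = all_values.corr(method=method)
    if constant.any():
        logger.warning(
            "constant metric column(s) %s; correlations set to 0",
            list(all_values.columns[constant]),
        )
        corr.loc[constant, :] = 0.0
        corr.loc[:, constant] = 0.0
    np.fill_diagonal(corr.values, 1.0)
    return corr


def validate_de_free(
    controlled: ControlledDataset,
    alpha_fdr: float = 0.1,
    stage_a: str = "N",
    stage_b: str = "T3",
) -> int:
    """Count genes differentially expressed between two stages.

    Per-gene Welch two-sample t-test followed by Benjamini–Hochberg; a
    correctly built controlled dataset returns 0 at the default FDR of 0.1,
    because stage noise perturbs correlations without shifting means.
    """
    va = controlled.stages[stage_a].values
    vb = controlled.stages[stage_b].values
    if stage_a == stage_b:
        return 0
    res = stats.ttest_ind(va, vb, axis=1, equal_var=False)
    q = bh_adjust(res.pvalue)
    return int((q < alpha_fdr).sum())
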
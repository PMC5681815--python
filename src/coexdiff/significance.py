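"""Permutation significance for differential co-expression metrics.

The null hypothesis for a gene is that its correlation profile is the same in
both conditions.  The null distribution of a metric is estimated by permuting
condition labels among the pooled samples (preserving group sizes),
recomputing correlation matrices and metric values, and comparing the
observed metric to the permuted ones.  By default permuted values are pooled
across genes, which yields p-value resolution of roughly
``1/(n_genes * n_permutations)`` from a handful of permutations; a strictly
per-gene null is available.  With more than two conditions, pairwise p-values
are combined per gene with Fisher's method and corrected across genes by
Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import corrspace, dc_metrics
from .expr_io import AnalysisConfig, ExpressionDataset

__all__ = [
    "PermutationNull",
    "SignificanceTable",
    "permute_labels",
    "permutation_pvalues",
    "fisher_combine",
    "bh_adjust",
    "run_significance",
]


@dataclass(frozen=True)
class PermutationNull:
    """Permuted metric values for one metric label and condition pair.

    In pooled mode ``null_values`` concatenates the permuted values of every
    gene (length ``n_permutations * n_genes``); in per-gene mode it is a
    (n_genes, n_permutations) matrix.
    """

    metric_label: str
    comparison: tuple[str, str]
    null_values: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.null_values, dtype=float)
        object.__setattr__(self, "null_values", vals)
        if not np.all(np.isfinite(vals)):
            raise ValueError("null distribution contains non-finite values")


@dataclass
class SignificanceTable:
    """Per-gene metric values, p-values, combined p and q per metric label.

    ``frame`` is indexed by gene id with flat columns
    ``"<label>|<A>-<B>|stat"``, ``"<label>|<A>-<B>|p"``,
    ``"<label>|combined_p"``, ``"<label>|q"``.  ``metadata`` records seeds,
    permutation count and pooling mode for provenance.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def column(self, label: str, kind: str, comparison: Optional[tuple[str, str]] = None):
        if kind in ("stat", "p"):
            key = f"{label}|{comparison[0]}-{comparison[1]}|{kind}"
        else:
            key = f"{label}|{kind}"
        return self.frame[key]


def permute_labels(
    dataset: ExpressionDataset,
    cond_a: str,
    cond_b: str,
    seed: int,
) -> ExpressionDataset:
    """Randomly reassign the two conditions' labels among their pooled samples.

    Group sizes are preserved and expression values are untouched; the result
    is reproducible for a given seed.
    """
    idx_a = dataset.sample_indices(cond_a)
    idx_b = dataset.sample_indices(cond_b)
    pooled = np.concatenate([idx_a, idx_b])
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(pooled)
    new_labels = dict(dataset.condition_of)
    for i in shuffled[: idx_a.size]:
        new_labels[dataset.sample_ids[i]] = cond_a
    for i in shuffled[idx_a.size :]:
        new_labels[dataset.sample_ids[i]] = cond_b
    return dataset.with_labels(new_labels)


def permutation_pvalues(
    observed: np.ndarray,
    null: PermutationNull,
    mode: str = "pooled",
    smoothed: bool = True,
) -> np.ndarray:
    """Upper-tail permutation p-values for observed metric values.

    With add-one smoothing (default), ``p = (1 + #{null >= obs}) / (1 + N)``,
    so p lies in (0, 1] and Benjamini–Hochberg remains valid.  Without
    smoothing the raw proportion of permuted values larger than the observed
    one is returned and can be 0.
    """
    observed = np.asarray(observed, dtype=float)
    nv = null.null_values
    if mode == "pooled":
        if nv.ndim != 1:
            raise ValueError("pooled mode expects a 1-D null vector")
        if nv.size == 0:
            raise ValueError("empty null distribution")
        sorted_null = np.sort(nv)
        # #{null >= obs} via position of obs in the sorted null
        n_ge = nv.size - np.searchsorted(sorted_null, observed, side="left")
    elif mode == "per_gene":
        if nv.ndim != 2 or nv.shape[0] != observed.size:
            raise ValueError("per-gene mode expects a (n_genes, n_permutations) null")
        n_ge = (nv >= observed[:, None]).sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_null = null.null_values.size if mode == "pooled" else null.null_values.shape[1]
    if smoothed:
        return (1.0 + n_ge) / (1.0 + n_null)
    return n_ge / n_null


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's combined probability: X^2 = -2 sum(ln p) on chi2 with 2K df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x2, df=2 * p.size))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _pair_seed(master_seed: int, pair_index: int, perm_index: int) -> int:
    # deterministic per (comparison, permutation) stream below 2**31
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(pair_index, perm_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_significance(
    dataset: ExpressionDataset,
    specs: Sequence[dc_metrics.MetricSpec],
    cfg: AnalysisConfig,
    conditions: Optional[Sequence[str]] = None,
) -> SignificanceTable:
    """Full pipeline: per-pair metrics and permutation p-values, Fisher
    combination across pairs, BH correction across genes.

    Every unordered pair of condition labels (in first-appearance order) is
    analyzed; each condition needs at least 3 samples.  Correlation matrices
    are recomputed from scratch in every permutation.
    """
    conds = list(conditions) if conditions is not None else list(dataset.conditions)
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    for c in conds:
        if dataset.sample_indices(c).size < 3:
            raise ValueError(f"condition {c!r} has fewer than 3 samples")

    pairs = list(combinations(conds, 2))
    gene_ids = list(dataset.gene_ids)
    columns: dict[str, np.ndarray] = {}
    pvals_by_label: dict[str, list[np.ndarray]] = {s.label: [] for s in specs}
    pair_seeds: dict[str, list[int]] = {}

    for pair_index, (ca_label, cb_label) in enumerate(pairs):
        mat_a = corrspace.spearman_matrix(dataset, ca_label)
        mat_b = corrspace.spearman_matrix(dataset, cb_label)
        observed = dc_metrics.compute_all_metrics(mat_a, mat_b, specs)

        null_frames = []
        seeds_used = []
        for perm_index in range(cfg.n_permutations):
            seed = _pair_seed(cfg.seed, pair_index, perm_index)
            seeds_used.append(seed)
            permuted = permute_labels(dataset, ca_label, cb_label, seed)
            pa = corrspace.spearman_matrix(permuted, ca_label)
            pb = corrspace.spearman_matrix(permuted, cb_label)
            null_frames.append(dc_metrics.compute_all_metrics(pa, pb, specs))
        pair_seeds[f"{ca_label}-{cb_label}"] = seeds_used

        for spec in specs:
            obs = observed[spec.label].to_numpy()
            if cfg.pooling == "pooled":
                nv = np.concatenate([nf[spec.label].to_numpy() for nf in null_frames])
            else:
                nv = np.column_stack([nf[spec.label].to_numpy() for nf in null_frames])
            null = PermutationNull(
                metric_label=spec.label,
                comparison=(ca_label, cb_label),
                null_values=nv,
                n_permutations=cfg.n_permutations,
                seed=cfg.seed,
            )
            p = permutation_pvalues(obs, null, mode=cfg.pooling)
            columns[f"{spec.label}|{ca_label}-{cb_label}|stat"] = obs
            columns[f"{spec.label}|{ca_label}-{cb_label}|p"] = p
            pvals_by_label[spec.label].append(p)

    for spec in specs:
        stacked = np.column_stack(pvals_by_label[spec.label])
        combined = np.array([fisher_combine(row) for row in stacked])
        columns[f"{spec.label}|combined_p"] = combined
        columns[f"{spec.label}|q"] = bh_adjust(combined)

    frame = pd.DataFrame(columns, index=gene_ids)
    metadata = {
        "master_seed": cfg.seed,
        "n_permutations": cfg.n_permutations,
        "pooling": cfg.pooling,
        "comparisons": [f"{a}-{b}" for a, b in pairs],
        "permutation_seeds": pair_seeds,
        "metric_labels": [s.label for s in specs],
    }
    return SignificanceTable(frame=frame, metadata=metadata)
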
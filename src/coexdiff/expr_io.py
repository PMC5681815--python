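"""Expression-matrix data model and delimited-text I/O.

The central container is :class:`ExpressionDataset`: a genes x samples real
matrix with unique gene and sample identifiers and a condition label per
sample.  Expression values are on whatever normalized scale the user supplies;
the pipeline only assumes that within-condition ranks are meaningful, since
co-expression is measured with Spearman correlation downstream.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "AnalysisConfig",
    "read_expression_table",
    "standardize_genes",
    "write_results_table",
]


class FormatError(ValueError):
    """Malformed input table (header, duplicates, non-numeric cells)."""


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples expression matrix with per-sample condition labels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``.
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    condition_of
        Mapping from sample id to condition label.  Every sample must be
        annotated.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    condition_of: Mapping[str, str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "condition_of", dict(self.condition_of))
        if values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n_genes, n_samples = values.shape
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"row count {n_genes} != number of gene ids {len(self.gene_ids)}"
            )
        if n_samples != len(self.sample_ids):
            raise FormatError(
                f"column count {n_samples} != number of sample ids {len(self.sample_ids)}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise FormatError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise FormatError(f"duplicate sample ids: {dupes}")
        missing = [s for s in self.sample_ids if s not in self.condition_of]
        if missing:
            raise FormatError(f"samples missing from annotation: {missing}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> tuple[str, ...]:
        """Condition labels in first-appearance (sample) order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of[s], None)
        return tuple(seen)

    def sample_indices(self, condition: str) -> np.ndarray:
        """Column indices of the samples belonging to ``condition``."""
        idx = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.condition_of[s] == condition],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"no samples with condition {condition!r}")
        return idx

    def condition_values(self, condition: str) -> np.ndarray:
        return self.values[:, self.sample_indices(condition)]

    def subset_genes(self, gene_index: np.ndarray) -> "ExpressionDataset":
        gene_index = np.asarray(gene_index, dtype=int)
        return ExpressionDataset(
            values=self.values[gene_index],
            gene_ids=tuple(self.gene_ids[i] for i in gene_index),
            sample_ids=self.sample_ids,
            condition_of=self.condition_of,
        )

    def with_labels(self, condition_of: Mapping[str, str]) -> "ExpressionDataset":
        return dataclasses.replace(self, condition_of=dict(condition_of))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


@dataclass
class AnalysisConfig:
    """Run-wide knobs for the significance pipeline.

    ``pooling='pooled'`` concatenates permuted metric values across genes when
    estimating the null, giving p-value resolution of about
    ``1 / (n_genes * n_permutations)`` from few permutations; ``'per_gene'``
    uses only a gene's own permuted values.
    """

    metric_specs: Sequence = field(default_factory=list)
    n_permutations: int = 10
    seed: int = 0
    pooling: str = "pooled"
    top_n: int = 500
    missing_policy: str = "reject"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("permutation count must be >= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.pooling not in ("pooled", "per_gene"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")
        if self.missing_policy not in ("reject", "pairwise_complete"):
            raise ValueError(f"unknown missing-data policy {self.missing_policy!r}")


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for it in items:
        if it in seen and it not in dupes:
            dupes.append(it)
        seen.add(it)
    return dupes


def read_expression_table(
    path,
    annotation_path,
    delimiter: str = "\t",
    missing_policy: str = "reject",
) -> ExpressionDataset:
    """Read an expression matrix plus a sample annotation table.

    The matrix file has a header row of sample identifiers with ``gene_id`` as
    its first column; the annotation file has two columns ``sample_id`` and
    ``condition`` (header required).  Samples present in the matrix but absent
    from the annotation are an error.
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    if missing_policy == "reject" and np.isnan(values).any():
        bad = [frame.index[i] for i in np.unique(np.where(np.isnan(values))[0])[:10]]
        raise FormatError(f"{path}: missing values under policy 'reject', e.g. genes {bad}")

    ann = pd.read_csv(annotation_path, sep=delimiter)
    if ann.shape[1] < 2:
        raise FormatError(f"{annotation_path}: annotation needs (sample_id, condition) columns")
    sample_col, cond_col = ann.columns[0], ann.columns[1]
    condition_of = dict(zip(ann[sample_col].astype(str), ann[cond_col].astype(str)))
    unannotated = [s for s in frame.columns.astype(str) if s not in condition_of]
    if unannotated:
        raise FormatError(f"samples missing from annotation {annotation_path}: {unannotated}")
    return ExpressionDataset(
        values=values,
        gene_ids=tuple(frame.index.astype(str)),
        sample_ids=tuple(frame.columns.astype(str)),
        condition_of=condition_of,
    )


def write_expression_table(dataset: ExpressionDataset, path, delimiter: str = "\t") -> None:
    """Write a dataset's matrix in the same layout ``read_expression_table`` expects."""
    frame = dataset.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=delimiter, float_format="%.10g")


def write_annotation_table(dataset: ExpressionDataset, path, delimiter: str = "\t") -> None:
    rows = pd.DataFrame(
        {"sample_id": list(dataset.sample_ids),
         "condition": [dataset.condition_of[s] for s in dataset.sample_ids]}
    )
    rows.to_csv(path, sep=delimiter, index=False)


def standardize_genes(dataset: ExpressionDataset, per_condition: bool = False) -> ExpressionDataset:
    """Scale every gene row to mean 0 and sample standard deviation 1.

    With ``per_condition=True`` each condition's sample group is standardized
    separately, mirroring the per-subset standardization used when conditions
    come from different cohorts.  Standardization is affine per gene, so it
    leaves Spearman correlations untouched.

    Uses the n-1 (sample) standard deviation.  Genes with zero variance in any
    standardized group are rejected.
    """
    values = dataset.values.copy()
    groups: list[np.ndarray]
    if per_condition:
        groups = [dataset.sample_indices(c) for c in dataset.conditions]
    else:
        groups = [np.arange(dataset.n_samples)]
    bad: list[str] = []
    for idx in groups:
        block = values[:, idx]
        sd = block.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            bad.extend(dataset.gene_ids[i] for i in np.where(zero)[0])
            continue
        values[:, idx] = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
    if bad:
        raise ValueError(f"zero-variance genes cannot be standardized: {sorted(set(bad))}")
    return dataclasses.replace(dataset, values=values)


def write_results_table(table, path, delimiter: str = "\t") -> None:
    """Serialize a significance table as TSV.

    One row per gene: ``gene_id``, then per pairwise comparison the metric
    value and permutation p-value, then the Fisher-combined p and the BH
    q-value, repeated per metric label.  Values carry >= 6 significant digits
    so a read-back reproduces them within 1e-6.
    """
    frame = getattr(table, "frame", table)
    if frame is None or len(frame) == 0:
        raise ValueError("refusing to write an empty results table")
    out = frame.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=delimiter, float_format="%.8g")
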
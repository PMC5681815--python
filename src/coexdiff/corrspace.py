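"""Spearman correlation matrices and per-gene correlation profiles.

Co-expression between two genes is quantified by the Spearman rank
correlation of their expression values across the samples of one condition.
A gene's *correlation profile* in a condition is the vector of its
correlations to every other gene; differential co-expression metrics compare
the two profiles a gene has under two conditions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expr_io import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "GeneCorrelationProfilePair",
    "spearman_corr",
    "spearman_matrix",
    "profile_pair",
    "correlation_distribution",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric genes x genes Spearman correlation matrix for one condition."""

    corr: np.ndarray
    gene_ids: tuple[str, ...]
    n_samples: int

    def __post_init__(self) -> None:
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "corr", corr)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if corr.shape[0] != corr.shape[1] or corr.shape[0] != len(self.gene_ids):
            raise ValueError("correlation matrix shape does not match gene ids")

    def index_of(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None


@dataclass(frozen=True)
class GeneCorrelationProfilePair:
    """One gene's correlation profiles under conditions A and B.

    ``a[k]`` and ``b[k]`` are the gene's Spearman correlations to
    ``partner_ids[k]`` in the two conditions; the self-correlation is
    excluded, so the profiles have length (total genes - 1).
    """

    gene_id: str
    a: np.ndarray
    b: np.ndarray
    partner_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "partner_ids", tuple(self.partner_ids))
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("profile vectors a and b must be 1-D with equal length")

    @property
    def n(self) -> int:
        return self.a.size


def _rank_rows(values: np.ndarray) -> np.ndarray:
    # midranks along samples; ties get the average rank
    return stats.rankdata(values, axis=1, method="average")


def spearman_corr(values: np.ndarray) -> np.ndarray:
    """All-pairs Spearman correlation of the rows of a genes x samples array.

    Rows that are constant get 0 against everything (diagonal 1); the result
    is exactly symmetric with a unit diagonal, entries clipped to [-1, 1].
    """
    values = np.asarray(values, dtype=float)
    ranks = _rank_rows(values)
    constant = ranks.std(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(ranks)
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    if constant.any():
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return (corr + corr.T) / 2.0


def spearman_matrix(dataset: ExpressionDataset, condition: str) -> CorrelationMatrix:
    """All-pairs Spearman correlation of genes within one condition.

    Computed as the Pearson correlation of midranked rows.  A gene that is
    constant within the condition has an undefined correlation; its row and
    column are set to 0 (diagonal stays 1) with a warning, so the matrix
    remains total.

    Requires at least 3 samples in the condition.
    """
    block = dataset.condition_values(condition)
    if block.shape[1] < 3:
        raise ValueError(
            f"condition {condition!r} has {block.shape[1]} samples; >= 3 required"
        )
    constant = _rank_rows(block).std(axis=1) == 0
    if constant.any():
        names = [dataset.gene_ids[i] for i in np.where(constant)[0][:10]]
        logger.warning(
            "%d constant gene(s) in condition %r (e.g. %s); correlations set to 0",
            int(constant.sum()), condition, names,
        )
    corr = spearman_corr(block)
    return CorrelationMatrix(corr=corr, gene_ids=dataset.gene_ids, n_samples=block.shape[1])


def profile_pair(
    ca: CorrelationMatrix, cb: CorrelationMatrix, gene_id: str
) -> GeneCorrelationProfilePair:
    """Extract one gene's (a, b) profile pair from two aligned matrices."""
    if ca.gene_ids != cb.gene_ids:
        raise ValueError("correlation matrices are not aligned on gene ids")
    i = ca.index_of(gene_id)
    keep = np.ones(len(ca.gene_ids), dtype=bool)
    keep[i] = False
    partners = tuple(g for j, g in enumerate(ca.gene_ids) if j != i)
    return GeneCorrelationProfilePair(
        gene_id=gene_id, a=ca.corr[i, keep], b=cb.corr[i, keep], partner_ids=partners
    )


def correlation_distribution(
    c: CorrelationMatrix, max_pairs: int = 50_000, seed: int = 0
) -> np.ndarray:
    """Upper-triangle correlations, subsampled without replacement.

    When the number of gene pairs exceeds ``max_pairs`` a reproducible random
    subsample is drawn; otherwise all pairs are returned.  This is the
    empirical distribution of pairwise co-expression used when matching a
    noise level to a target dataset.
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    iu = np.triu_indices(len(c.gene_ids), k=1)
    vals = c.corr[iu]
    if vals.size > max_pairs:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=max_pairs, replace=False)
    return vals
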
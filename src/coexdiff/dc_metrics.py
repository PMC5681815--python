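"""Gene-level differential co-expression metrics.

Each metric condenses the change between a gene's two correlation profiles
``a`` and ``b`` (its Spearman correlations to all other genes under
conditions A and B) into a single nonnegative score:

* **M1** — absolute difference in the number of correlations exceeding a
  threshold ``th1`` (co-expression-count difference).
* **M2** — two-sample Kolmogorov–Smirnov statistic between the two profile
  distributions.
* **M3** — number of per-partner correlation differences exceeding ``th3``.
* **M4** — Euclidean distance between profiles scaled by 1/n.
* **M5** — symmetrized Kullback–Leibler divergence between histogram
  estimates of the two profile distributions.
* **M6** — sum of soft-thresholded adjacency differences
  ``(sqrt(|sign(a)a^2 - sign(b)b^2| / 2))**beta``, the per-gene score of the
  adjacency-difference approach used for differential-network clustering.

All six are symmetric in A and B.  User-defined metrics plug in through
:class:`MetricSpec` with ``metric_id='user'`` and a callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .corrspace import CorrelationMatrix, GeneCorrelationProfilePair

__all__ = [
    "MetricSpec",
    "default_metric_specs",
    "adaptive_bins",
    "metric_m1",
    "metric_m2",
    "metric_m3",
    "metric_m4",
    "metric_m5",
    "metric_m6",
    "compute_all_metrics",
]

_KNOWN_IDS = ("M1", "M2", "M3", "M4", "M5", "M6", "user")


@dataclass(frozen=True)
class MetricSpec:
    """Which metric to compute and with what parameters.

    ``label`` follows the convention of appending the threshold to the metric
    name for the thresholded metrics: threshold 0.1 on M1 is labelled
    ``"M1.1"``.  For ``metric_id='user'`` supply ``func(a, b, spec) -> float``
    and an explicit label.
    """

    metric_id: str
    threshold: Optional[float] = None
    beta: float = 2.5
    bins: Optional[int] = 100
    use_absolute_correlation: bool = True
    pseudocount: bool = False
    func: Optional[Callable] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.metric_id not in _KNOWN_IDS:
            raise ValueError(f"unknown metric id {self.metric_id!r}")
        if self.metric_id in ("M1", "M3") and self.threshold is None:
            raise ValueError(f"{self.metric_id} requires a threshold")
        if self.metric_id == "user":
            if self.func is None:
                raise ValueError("user metric requires a callable")
            if not self.label:
                raise ValueError("user metric requires a label")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.bins is not None and self.bins < 2:
            raise ValueError("bins must be >= 2")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.metric_id in ("M1", "M3"):
            th = format(float(self.threshold), "g")
            suffix = th[2:] if th.startswith("0.") else th
            return f"{self.metric_id}.{suffix}"
        return self.metric_id


def default_metric_specs(
    thresholds: Sequence[float] = (0.1, 0.3, 0.5),
) -> list[MetricSpec]:
    """The ten standard metric configurations: M1 and M3 at each threshold
    plus the four threshold-free metrics.

    M5 is configured with occupancy-matched bins (see :func:`adaptive_bins`)
    and pseudocount regularization: with hard zero-bin skipping the score of a
    gene whose correlation changes are confined to sparsely populated tail
    bins collapses to the background level, which blinds M5 to small injected
    networks on short profiles.  The strict skip-rule form remains available
    via ``MetricSpec('M5', pseudocount=False, bins=...)``.
    """
    specs = [MetricSpec("M1", threshold=t) for t in thresholds]
    specs.append(MetricSpec("M2"))
    specs.extend(MetricSpec("M3", threshold=t) for t in thresholds)
    specs.extend(
        [MetricSpec("M4"), MetricSpec("M5", bins=None, pseudocount=True), MetricSpec("M6")]
    )
    return specs


def adaptive_bins(n: int) -> int:
    """Histogram bin count matched to profile length.

    Targets ~24 values per bin, capped at 100 bins (the count used on
    profiles of several thousand genes) and floored at 10.
    """
    return max(10, min(100, n // 24))


# -- scalar metric kernels (1-D profile vectors) ------------------------------


def _m1(a: np.ndarray, b: np.ndarray, th1: float, use_absolute: bool) -> float:
    if not 0 <= th1 < 1:
        raise ValueError("th1 must lie in [0, 1)")
    xa, xb = (np.abs(a), np.abs(b)) if use_absolute else (a, b)
    return float(abs(np.count_nonzero(xa > th1) - np.count_nonzero(xb > th1)))


def _m2(a: np.ndarray, b: np.ndarray) -> float:
    # two-sample KS statistic: sup over pooled points of |ECDF_a - ECDF_b|
    sa, sb = np.sort(a), np.sort(b)
    pooled = np.concatenate([sa, sb])
    cdf_a = np.searchsorted(sa, pooled, side="right") / sa.size
    cdf_b = np.searchsorted(sb, pooled, side="right") / sb.size
    return float(np.abs(cdf_a - cdf_b).max())


def _m3(a: np.ndarray, b: np.ndarray, th3: float) -> float:
    if not 0 <= th3 <= 2:
        raise ValueError("th3 must lie in [0, 2]")
    return float(np.count_nonzero(np.abs(a - b) > th3))


def _m4(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.sum((a - b) ** 2)) / a.size)


def _histogram_probs(x: np.ndarray, bins: int, pseudocount: bool) -> np.ndarray:
    counts, _ = np.histogram(x, bins=bins, range=(-1.0, 1.0))
    counts = counts.astype(float)
    if pseudocount:
        counts += 1.0 / (2.0 * x.size)
    total = counts.sum()
    return counts / total if total > 0 else counts


def _m5(a: np.ndarray, b: np.ndarray, bins: int, pseudocount: bool) -> float:
    pa = _histogram_probs(a, bins, pseudocount)
    pb = _histogram_probs(b, bins, pseudocount)
    mask = (pa > 0) & (pb > 0)
    if not mask.any():
        return 0.0
    pa, pb = pa[mask], pb[mask]
    return float(np.sum(pa * np.log(pa / pb)) + np.sum(pb * np.log(pb / pa)))


def _signed_square(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * x * x


def _m6(a: np.ndarray, b: np.ndarray, beta: float) -> float:
    terms = np.sqrt(0.5 * np.abs(_signed_square(a) - _signed_square(b)))
    return float(np.sum(terms**beta))


# -- public per-profile API ----------------------------------------------------


def metric_m1(
    p: GeneCorrelationProfilePair, th1: float, use_absolute: bool = True
) -> float:
    """|#a - #b|: difference in the number of correlations above ``th1``."""
    return _m1(p.a, p.b, th1, use_absolute)


def metric_m2(p: GeneCorrelationProfilePair) -> float:
    """Kolmogorov–Smirnov distance between the two profile distributions."""
    return _m2(p.a, p.b)


def metric_m3(p: GeneCorrelationProfilePair, th3: float) -> float:
    """Number of per-partner correlation differences exceeding ``th3``."""
    return _m3(p.a, p.b, th3)


def metric_m4(p: GeneCorrelationProfilePair) -> float:
    """Scaled Euclidean distance (1/n) * sqrt(sum (a-b)^2); at most 2/sqrt(n)."""
    return _m4(p.a, p.b)


def metric_m5(
    p: GeneCorrelationProfilePair, bins: int = 100, pseudocount: bool = False
) -> float:
    """Symmetrized KL divergence between profile histograms on [-1, 1].

    Natural logarithm; bins where either probability is zero are skipped, so
    two profiles with fully disjoint histograms score 0 — enable
    ``pseudocount`` to regularize that degenerate case.
    """
    return _m5(p.a, p.b, bins, pseudocount)


def metric_m6(p: GeneCorrelationProfilePair, beta: float = 2.5) -> float:
    """Adjacency-difference score; ``beta`` up-weights large differences."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return _m6(p.a, p.b, beta)


def metric_value(p: GeneCorrelationProfilePair, spec: MetricSpec) -> float:
    """Evaluate one metric spec on one profile pair."""
    if spec.metric_id == "M1":
        return _m1(p.a, p.b, spec.threshold, spec.use_absolute_correlation)
    if spec.metric_id == "M2":
        return _m2(p.a, p.b)
    if spec.metric_id == "M3":
        return _m3(p.a, p.b, spec.threshold)
    if spec.metric_id == "M4":
        return _m4(p.a, p.b)
    if spec.metric_id == "M5":
        bins = spec.bins if spec.bins is not None else adaptive_bins(p.n)
        return _m5(p.a, p.b, bins, spec.pseudocount)
    if spec.metric_id == "M6":
        return _m6(p.a, p.b, spec.beta)
    value = float(spec.func(p.a, p.b, spec))
    _validate_user_value(value, spec)
    return value


def _validate_user_value(value: float, spec: MetricSpec) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(
            f"user metric {spec.label!r} returned {value!r}; "
            "metric values must be finite and nonnegative"
        )


# -- whole-matrix computation ---------------------------------------------------


def _offdiag_rows(m: np.ndarray):
    """Yield (i, row-without-diagonal) for each gene."""
    g = m.shape[0]
    mask = ~np.eye(g, dtype=bool)
    for i in range(g):
        yield i, m[i, mask[i]]


def compute_all_metrics(
    ca: CorrelationMatrix, cb: CorrelationMatrix, specs: Sequence[MetricSpec]
) -> pd.DataFrame:
    """Compute every metric spec for every gene from two aligned matrices.

    Returns a DataFrame indexed by gene id with one column per metric label,
    in gene order.  The self-correlation is excluded from every profile, so
    the effective profile length is (genes - 1).  Counting and distance
    metrics are evaluated with vectorized row operations; the
    distribution-based metrics (M2, M5) and user metrics are evaluated per
    gene.
    """
    if ca.gene_ids != cb.gene_ids:
        raise ValueError("correlation matrices are not aligned on gene ids")
    a, b = ca.corr, cb.corr
    g = a.shape[0]
    n = g - 1
    if n < 1:
        raise ValueError("need at least 2 genes")
    out: dict[str, np.ndarray] = {}
    labels_seen: set[str] = set()
    for spec in specs:
        if spec.label in labels_seen:
            raise ValueError(f"duplicate metric label {spec.label!r}")
        labels_seen.add(spec.label)
        if spec.metric_id == "M1":
            xa = np.abs(a) if spec.use_absolute_correlation else a
            xb = np.abs(b) if spec.use_absolute_correlation else b
            # diagonal is exactly 1 and counts in both conditions, so it
            # cancels inside |#a - #b|; subtract it anyway for clarity
            ca_cnt = (xa > spec.threshold).sum(axis=1) - 1
            cb_cnt = (xb > spec.threshold).sum(axis=1) - 1
            vals = np.abs(ca_cnt - cb_cnt).astype(float)
        elif spec.metric_id == "M3":
            diff = np.abs(a - b)
            np.fill_diagonal(diff, 0.0)  # strict >, so a zeroed diagonal never counts
            vals = (diff > spec.threshold).sum(axis=1).astype(float)
        elif spec.metric_id == "M4":
            sq = (a - b) ** 2
            np.fill_diagonal(sq, 0.0)
            vals = np.sqrt(sq.sum(axis=1)) / n
        elif spec.metric_id == "M6":
            t = np.sqrt(0.5 * np.abs(_signed_square(a) - _signed_square(b)))
            np.fill_diagonal(t, 0.0)
            vals = (t**spec.beta).sum(axis=1)
        elif spec.metric_id == "M2":
            vals = np.empty(g)
            rows_b = b[~np.eye(g, dtype=bool)].reshape(g, n)
            for i, row_a in _offdiag_rows(a):
                vals[i] = _m2(row_a, rows_b[i])
        elif spec.metric_id == "M5":
            bins = spec.bins if spec.bins is not None else adaptive_bins(n)
            vals = np.empty(g)
            rows_b = b[~np.eye(g, dtype=bool)].reshape(g, n)
            for i, row_a in _offdiag_rows(a):
                vals[i] = _m5(row_a, rows_b[i], bins, spec.pseudocount)
        else:  # user metric
            vals = np.empty(g)
            rows_b = b[~np.eye(g, dtype=bool)].reshape(g, n)
            for i, row_a in _offdiag_rows(a):
                vals[i] = float(spec.func(row_a, rows_b[i], spec))
                if i == 0:
                    _validate_user_value(vals[0], spec)
            _validate_user_value(float(np.min(vals)), spec)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"metric {spec.label!r} produced non-finite values")
        out[spec.label] = vals
    return pd.DataFrame(out, index=list(ca.gene_ids))
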
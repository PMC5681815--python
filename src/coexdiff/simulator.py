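"""Controlled-dataset construction with known differential-correlation genes.

A controlled benchmark emulates tumor progression from normal tissue through
three artificial stages (T1, T2, T3) so that the genes whose co-expression
changes — the *positives* — are known by construction while no gene is
differentially expressed:

1. sample background genes from a normal dataset and standardize each gene;
2. estimate the Gaussian noise level ``s`` whose addition makes the normal
   correlation distribution resemble the tumor one;
3. degrade a subset of genes (*noised positives*) with cumulative per-stage
   noise of sd ``s/3``;
4. give the remaining genes (*negatives*) cumulative noise of sd ``s/10``,
   preserving variability without erasing their correlations;
5. append fully connected *network blocks*: groups of genes drawn from an
   equicorrelated multivariate normal whose common correlation ``v`` is
   shifted by +/-0.05, 0.10, 0.15 across the stages (half the blocks gain,
   half lose correlation).

At the default scale the result has 3200 genes: 2700 negatives, 300 noised
positives and 200 network genes (20 blocks of 10); the 500 noised + network
genes are the truth positives.  Builds at smaller counts in the same
proportions are first-class for fast experimentation.

Because adding independent noise changes correlations but not expected
means, the stages contain no differential expression by design.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from . import corrspace
from .expr_io import ExpressionDataset, standardize_genes

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkBlockSpec",
    "NoiseEstimate",
    "ControlledDataset",
    "STAGES",
    "LOSS_SCHEDULE",
    "GAIN_SCHEDULE",
    "generate_synthetic_base",
    "estimate_noise_level",
    "add_stage_noise",
    "inject_network_blocks",
    "default_block_specs",
    "build_controlled_dataset",
]

STAGES = ("N", "T1", "T2", "T3")

#: base correlations v for blocks losing correlation, stepped by -0.05/-0.10/-0.15
LOSS_SCHEDULE = (0.9, 0.75, 0.6, 0.45, 0.3)
#: base correlations v for blocks gaining correlation, stepped by +0.05/+0.10/+0.15
GAIN_SCHEDULE = (0.15, 0.30, 0.45, 0.60, 0.75)

_STAGE_STEP = (0.05, 0.10, 0.15)


@dataclass(frozen=True)
class NetworkBlockSpec:
    """One injected equicorrelated network block.

    ``stage_offsets`` are the signed T1/T2/T3 deltas added to the base
    correlation ``v`` (negative for loss blocks).
    """

    direction: str
    v: float
    stage_offsets: tuple[float, float, float]
    size: int = 10

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if not 0 < self.v < 1:
            raise ValueError("base correlation v must lie in (0, 1)")
        if self.size < 2:
            raise ValueError("block size must be >= 2")
        for corr in self.stage_correlations():
            if not -1 < corr < 1:
                raise ValueError(f"stage correlation {corr} out of (-1, 1)")

    @classmethod
    def loss(cls, v: float, size: int = 10) -> "NetworkBlockSpec":
        return cls("loss", v, tuple(-d for d in _STAGE_STEP), size)

    @classmethod
    def gain(cls, v: float, size: int = 10) -> "NetworkBlockSpec":
        return cls("gain", v, _STAGE_STEP, size)

    def stage_correlations(self) -> tuple[float, float, float, float]:
        """Target equicorrelation at (Normal, T1, T2, T3)."""
        return (self.v,) + tuple(self.v + d for d in self.stage_offsets)


@dataclass(frozen=True)
class NoiseEstimate:
    """Grid search result for the matched noise level ``s``."""

    s: float
    grid: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))
        if self.grid[int(np.argmin(self.distances))] != self.s:
            raise ValueError("s is not the grid argmin of the distances")


@dataclass(frozen=True)
class ControlledDataset:
    """Four stage matrices over identical genes plus per-gene truth labels."""

    stages: Mapping[str, ExpressionDataset]
    truth: Mapping[str, str]
    provenance: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", dict(self.stages))
        object.__setattr__(self, "truth", dict(self.truth))
        gene_sets = {st: ds.gene_ids for st, ds in self.stages.items()}
        ref = next(iter(gene_sets.values()))
        for st, ids in gene_sets.items():
            if ids != ref:
                raise ValueError(f"stage {st} gene ids differ from the others")
        if set(self.truth) != set(ref):
            raise ValueError("truth labels do not cover exactly the dataset's genes")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.stages[STAGES[0]].gene_ids

    @property
    def positive_mask(self) -> np.ndarray:
        pos = {"noised_positive", "network_gain", "network_loss"}
        return np.array([self.truth[g] in pos for g in self.gene_ids])

    @property
    def n_positives(self) -> int:
        return int(self.positive_mask.sum())

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.truth.values():
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def combined(self) -> ExpressionDataset:
        """All stages side by side as one dataset with stage condition labels."""
        values = np.hstack([self.stages[st].values for st in STAGES])
        sample_ids: list[str] = []
        condition_of: dict[str, str] = {}
        for st in STAGES:
            for s in self.stages[st].sample_ids:
                sample_ids.append(s)
                condition_of[s] = st
        return ExpressionDataset(
            values=values,
            gene_ids=self.gene_ids,
            sample_ids=tuple(sample_ids),
            condition_of=condition_of,
        )


# -- base data ----------------------------------------------------------------


def _equicorrelated_sample(
    rng: np.random.Generator, size: int, v: float, n_samples: int
) -> np.ndarray:
    """Draw size x n_samples from a multivariate normal with equicorrelation v."""
    if v <= -1.0 / (size - 1):
        raise ValueError(f"equicorrelation v={v} is not positive semidefinite for size {size}")
    m = np.full((size, size), v)
    np.fill_diagonal(m, 1.0)
    chol = np.linalg.cholesky(m)
    z = rng.standard_normal((size, n_samples))
    return chol @ z


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1, ddof=1, keepdims=True)
    return (values - values.mean(axis=1, keepdims=True)) / sd


def generate_synthetic_base(
    n_genes: int,
    n_samples: int,
    block_structure: Optional[Sequence[tuple[int, float]]] = None,
    seed: int = 0,
    condition: str = "N",
    n_factors: int = 0,
    factor_loading_sd: float = 0.5,
) -> ExpressionDataset:
    """Standardized Gaussian base data with optional co-expression structure.

    ``block_structure`` is a list of ``(size, correlation)`` pairs assigned to
    consecutive genes from the top of the matrix; genes outside any block are
    independent of each other.  ``n_factors > 0`` additionally superimposes
    shared latent expression programs: every gene loads on each factor with a
    N(0, ``factor_loading_sd``) coefficient, which gives all genes broad,
    heavy-tailed correlation profiles like those of real tissue — the
    structure that cumulative noise later degrades.  With 10 factors and the
    default loading sd the pairwise Spearman distribution has an sd of
    roughly 0.25.
    """
    if n_genes < 2 or n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    if n_factors > 0:
        loadings = rng.normal(0.0, factor_loading_sd, (n_genes, n_factors))
        factors = rng.standard_normal((n_factors, n_samples))
        values += loadings @ factors
    offset = 0
    for size, corr in block_structure or []:
        if offset + size > n_genes:
            raise ValueError("block structure exceeds the number of genes")
        values[offset : offset + size] = _equicorrelated_sample(rng, size, corr, n_samples)
        offset += size
    values = _standardize_rows(values)
    gene_ids = tuple(f"G{i + 1:05d}" for i in range(n_genes))
    sample_ids = tuple(f"S{j + 1:04d}" for j in range(n_samples))
    return ExpressionDataset(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        condition_of={s: condition for s in sample_ids},
    )


# -- noise level --------------------------------------------------------------


def estimate_noise_level(
    normal: ExpressionDataset,
    tumor: ExpressionDataset,
    grid: Sequence[float] = tuple(np.round(np.arange(0.0, 3.01, 0.1), 2)),
    pairs: int = 20_000,
    seed: int = 0,
) -> NoiseEstimate:
    """Find the Gaussian noise sd ``s`` that makes normal correlations look
    like tumor ones.

    For each candidate ``s`` on the grid, independent N(0, s) noise is added
    to the normal matrix, the Spearman pair-correlation distribution is
    sampled (``pairs`` gene pairs), and its two-sample Kolmogorov–Smirnov
    distance to the tumor correlation distribution is measured.  The argmin
    ``s`` is returned with the full distance profile; ties break to the
    smaller ``s``.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be nondecreasing")
    if grid.size == 1:
        logger.warning("degenerate single-point grid; s estimation is a no-op")

    tumor_corr = corrspace.spearman_corr(tumor.values)
    tumor_dist = _sample_upper_triangle(tumor_corr, pairs, seed)

    distances = np.empty(grid.size)
    for k, s in enumerate(grid):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, k)))
        noised = normal.values + (rng.standard_normal(normal.values.shape) * s if s > 0 else 0.0)
        corr = corrspace.spearman_corr(noised)
        cand = _sample_upper_triangle(corr, pairs, seed)
        distances[k] = stats.ks_2samp(cand, tumor_dist).statistic
    best = int(np.argmin(distances))  # first minimum -> smaller s on ties
    return NoiseEstimate(s=float(grid[best]), grid=grid, distances=distances)


def _sample_upper_triangle(corr: np.ndarray, pairs: int, seed: int) -> np.ndarray:
    vals = corr[np.triu_indices(corr.shape[0], k=1)]
    if vals.size > pairs:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
        vals = rng.choice(vals, size=pairs, replace=False)
    return vals


# -- stage noise --------------------------------------------------------------


def add_stage_noise(
    base: ExpressionDataset, s: float, divisor: float, seed: int = 0
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Cumulative per-stage Gaussian noise: T1 = base + N(0, s/divisor),
    T2 = T1 + N(0, s/divisor), T3 = T2 + N(0, s/divisor).

    The three noise draws are independent, so Var(T3 - base) = 3 (s/divisor)^2.
    """
    if s < 0:
        raise ValueError("noise level s must be nonnegative")
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    sd = s / divisor
    rng = np.random.default_rng(seed)
    stages = []
    current = base.values
    for _ in range(3):
        current = current + (rng.standard_normal(current.shape) * sd if sd > 0 else 0.0)
        stages.append(dataclasses.replace(base, values=current))
    return tuple(stages)


# -- network blocks -----------------------------------------------------------


def inject_network_blocks(
    spec: NetworkBlockSpec,
    n_samples_per_stage: Sequence[int],
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Draw one block's four stage matrices at its stage-specific
    equicorrelations, each standardized per gene.

    Stages are drawn independently: the recipe fixes target correlations per
    stage, not a joint process across stages.
    """
    if len(n_samples_per_stage) != len(STAGES):
        raise ValueError("need one sample count per stage")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for stage, corr, n_samp in zip(STAGES, spec.stage_correlations(), n_samples_per_stage):
        block = _equicorrelated_sample(rng, spec.size, corr, n_samp)
        out[stage] = _standardize_rows(block)
    return out


def default_block_specs(n_blocks: int = 20, block_size: int = 10) -> list[NetworkBlockSpec]:
    """Half loss, half gain, cycling through the base-correlation schedules
    (at the default 20 blocks: two blocks per schedule value)."""
    if n_blocks % 2 != 0:
        raise ValueError("number of network blocks must be even (half gain, half loss)")
    half = n_blocks // 2
    specs = [
        NetworkBlockSpec.loss(LOSS_SCHEDULE[i % len(LOSS_SCHEDULE)], block_size)
        for i in range(half)
    ]
    specs += [
        NetworkBlockSpec.gain(GAIN_SCHEDULE[i % len(GAIN_SCHEDULE)], block_size)
        for i in range(half)
    ]
    return specs


# -- full build ---------------------------------------------------------------


def build_controlled_dataset(
    normal: ExpressionDataset,
    tumor: Optional[ExpressionDataset] = None,
    s: Optional[float] = None,
    counts: tuple[int, int, int, int] = (3000, 300, 20, 10),
    seed: int = 0,
    grid: Optional[Sequence[float]] = None,
    noise_pairs: int = 20_000,
) -> ControlledDataset:
    """Execute the five-step controlled-dataset recipe.

    ``counts`` is ``(n_background, n_noised_positive, n_blocks, block_size)``;
    the default reproduces the 3200-gene scale (2700 negatives, 300 noised
    positives, 20 networks of 10).  ``s`` may be given directly; otherwise it
    is estimated from ``tumor``.  All randomness derives from ``seed``.
    """
    n_background, n_noised, n_blocks, block_size = counts
    if n_noised > n_background:
        raise ValueError("more noised positives than background genes")
    if normal.n_genes < n_background:
        raise ValueError(
            f"normal dataset has {normal.n_genes} genes; {n_background} required"
        )
    if s is None and tumor is None:
        raise ValueError("supply either a tumor dataset or an explicit noise level s")

    root = np.random.SeedSequence(entropy=seed)
    ss_pick, ss_noise_est, ss_pos, ss_neg, ss_blocks = root.spawn(5)

    # step 1: sample background genes and standardize per gene
    rng_pick = np.random.default_rng(ss_pick)
    gene_idx = np.sort(rng_pick.choice(normal.n_genes, size=n_background, replace=False))
    base = standardize_genes(normal.subset_genes(gene_idx))

    # step 2: matched noise level
    estimate = None
    if s is None:
        kwargs = {} if grid is None else {"grid": grid}
        estimate = estimate_noise_level(
            base, tumor, pairs=noise_pairs,
            seed=int(ss_noise_est.generate_state(1)[0] % 2**31), **kwargs
        )
        s = estimate.s

    # steps 3-4: cumulative noise, sd s/3 for the positives, s/10 for the rest
    pos_idx = np.sort(rng_pick.choice(n_background, size=n_noised, replace=False))
    neg_idx = np.setdiff1d(np.arange(n_background), pos_idx)
    pos_stages = add_stage_noise(
        base.subset_genes(pos_idx), s, divisor=3.0,
        seed=int(ss_pos.generate_state(1)[0]),
    )
    neg_stages = add_stage_noise(
        base.subset_genes(neg_idx), s, divisor=10.0,
        seed=int(ss_neg.generate_state(1)[0]),
    )

    n_samples = base.n_samples
    stage_values: dict[str, np.ndarray] = {"N": base.values.copy()}
    for stage, pos_ds, neg_ds in zip(STAGES[1:], pos_stages, neg_stages):
        vals = np.empty_like(base.values)
        vals[pos_idx] = pos_ds.values
        vals[neg_idx] = neg_ds.values
        stage_values[stage] = vals

    # step 5: append network blocks as new genes
    block_specs = default_block_specs(n_blocks, block_size)
    block_seeds = ss_blocks.spawn(len(block_specs))
    block_values: dict[str, list[np.ndarray]] = {st: [] for st in STAGES}
    net_gene_ids: list[str] = []
    truth: dict[str, str] = {}
    for g, lab in zip(base.gene_ids, _background_labels(base.gene_ids, pos_idx)):
        truth[g] = lab
    for b, (bspec, bseed) in enumerate(zip(block_specs, block_seeds)):
        blocks = inject_network_blocks(
            bspec, [n_samples] * len(STAGES), seed=int(bseed.generate_state(1)[0])
        )
        for st in STAGES:
            block_values[st].append(blocks[st])
        for j in range(bspec.size):
            gid = f"NET{b + 1:02d}_{j + 1:02d}"
            net_gene_ids.append(gid)
            truth[gid] = f"network_{bspec.direction}"

    gene_ids = base.gene_ids + tuple(net_gene_ids)
    stages: dict[str, ExpressionDataset] = {}
    for st in STAGES:
        vals = np.vstack([stage_values[st]] + block_values[st])
        sample_ids = tuple(f"{st}_{j + 1:04d}" for j in range(n_samples))
        stages[st] = ExpressionDataset(
            values=vals,
            gene_ids=gene_ids,
            sample_ids=sample_ids,
            condition_of={samp: st for samp in sample_ids},
        )

    provenance = {
        "s": float(s),
        "seed": int(seed),
        "counts": tuple(int(c) for c in counts),
        "n_samples_per_stage": int(n_samples),
        "block_specs": [
            {"direction": bs.direction, "v": bs.v, "size": bs.size,
             "stage_offsets": list(bs.stage_offsets)}
            for bs in block_specs
        ],
        "noise_estimate": None
        if estimate is None
        else {"grid": estimate.grid.tolist(), "distances": estimate.distances.tolist()},
    }
    return ControlledDataset(stages=stages, truth=truth, provenance=provenance)


def _background_labels(gene_ids: Sequence[str], pos_idx: np.ndarray) -> list[str]:
    labels = ["negative"] * len(gene_ids)
    for i in pos_idx:
        labels[i] = "noised_positive"
    return labels
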
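import numpy as np
import pytest

from coexdiff import build_controlled_dataset, generate_synthetic_base
from coexdiff.corrspace import GeneCorrelationProfilePair
from coexdiff.expr_io import ExpressionDataset


def make_pair(a, b, gene_id="g0"):
    """Profile pair from raw correlation vectors, partners named by index."""
    a = np.asarray(a, dtype=float)
    return GeneCorrelationProfilePair(
        gene_id=gene_id, a=a, b=np.asarray(b, dtype=float),
        partner_ids=tuple(f"p{i}" for i in range(a.size)),
    )


def make_dataset(values, conditions, gene_prefix="g", sample_prefix="s"):
    """ExpressionDataset from an array and one condition label per column."""
    values = np.asarray(values, dtype=float)
    gene_ids = tuple(f"{gene_prefix}{i}" for i in range(values.shape[0]))
    sample_ids = tuple(f"{sample_prefix}{j}" for j in range(values.shape[1]))
    return ExpressionDataset(
        values=values, gene_ids=gene_ids, sample_ids=sample_ids,
        condition_of=dict(zip(sample_ids, conditions)),
    )


def random_profile_pairs(n_pairs, n_min=3, n_max=50, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        n = int(rng.integers(n_min, n_max + 1))
        out.append(make_pair(rng.uniform(-1, 1, n), rng.uniform(-1, 1, n)))
    return out


@pytest.fixture(scope="session")
def scaled_controlled():
    """Desk-scale controlled dataset: 600 background genes (10 latent
    factors), 60 noised positives, 8 network blocks of 10, s = 1.5."""
    base = generate_synthetic_base(600, 60, n_factors=10, seed=11)
    return build_controlled_dataset(base, s=1.5, counts=(600, 60, 8, 10), seed=11)


@pytest.fixture(scope="session")
def paper_scale_controlled():
    """Full-scale controlled dataset: 3200 genes over 60 samples per stage."""
    base = generate_synthetic_base(3000, 60, n_factors=10, seed=2026)
    return build_controlled_dataset(base, s=1.5, seed=2026)
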
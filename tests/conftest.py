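import numpy as np
import pytest

from refstab.data_io import CqTable
from refstab.quantification import RelativeQuantityMatrix


def make_table(cq, genes=None, samples=None, groups=None, **kwargs) -> CqTable:
    cq = np.asarray(cq, dtype=float)
    genes = genes or [f"G{i}" for i in range(cq.shape[0])]
    samples = samples or [f"s{j}" for j in range(cq.shape[1])]
    group_of = None
    if groups is not None:
        group_of = dict(zip(samples, groups))
    return CqTable(genes=list(genes), samples=list(samples), cq=cq,
                   group_of=group_of, **kwargs)


def make_q(q, genes=None, samples=None, groups=None) -> RelativeQuantityMatrix:
    q = np.asarray(q, dtype=float)
    genes = genes or [f"G{i}" for i in range(q.shape[0])]
    samples = samples or [f"s{j}" for j in range(q.shape[1])]
    group_of = dict(zip(samples, groups)) if groups is not None else None
    return RelativeQuantityMatrix(
        genes=list(genes), samples=list(samples), q=q,
        base_of={g: 2.0 for g in genes}, group_of=group_of,
    )


def q_from_cq(cq, base=2.0, **kwargs) -> RelativeQuantityMatrix:
    """Comparative-Cq quantities straight from a Cq array (complete data)."""
    cq = np.asarray(cq, dtype=float)
    q = base ** (cq.min(axis=1, keepdims=True) - cq)
    return make_q(q, **kwargs)


def random_table(rng, n_genes=5, n_samples=8, missing_frac=0.0, groups=None):
    cq = rng.uniform(15.0, 32.0, size=(n_genes, n_samples))
    if missing_frac:
        mask = rng.random(cq.shape) < missing_frac
        cq[mask] = np.nan
    return make_table(cq, groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
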
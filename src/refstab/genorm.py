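"""geNorm gene-stability values, iterative exclusion ranking, and the
V(n/n+1) pairwise-variation series for normalization-panel sizing.

All logarithms are base 2 and all standard deviations use the n-1
denominator; any fixed choice rescales M and V by a constant and leaves
every ranking unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from refstab.errors import InputError
from refstab.quantification import RelativeQuantityMatrix

logger = logging.getLogger(__name__)


@dataclass
class GenormResult:
    """Outcome of the iterative geNorm ranking.

    Attributes
    ----------
    m_final : dict
        Gene -> M value at the step the gene was excluded; the final tied
        pair shares its common pairwise M.
    exclusion_order : list
        Genes in removal order, least stable first.
    ranking : dict
        Gene -> rank; the final two genes share rank 1.
    m_trajectory : list of (remaining genes, average M)
        One entry per elimination step.
    v_series : dict
        n -> V(n/n+1), for n = 2 .. k-1.
    stability_order : list
        Genes from most to least stable (tied top pair first, input order).
    """

    m_final: dict[str, float]
    exclusion_order: list[str]
    ranking: dict[str, int]
    m_trajectory: list[tuple[list[str], float]]
    v_series: dict[int, float] = field(default_factory=dict)
    stability_order: list[str] = field(default_factory=list)


def _log_ratios(q: RelativeQuantityMatrix, j: int, k: int) -> np.ndarray:
    return np.log2(q.q[j] / q.q[k])


def pairwise_variation(q: RelativeQuantityMatrix, gene_j: str, gene_k: str) -> float:
    """V_jk: sample SD over samples of log2(q_j / q_k). Symmetric in (j, k)."""
    if gene_j == gene_k:
        raise InputError("pairwise variation needs two distinct genes")
    if q.n_samples < 3:
        raise InputError("pairwise variation needs at least 3 samples")
    j, k = q.gene_index(gene_j), q.gene_index(gene_k)
    return float(np.std(_log_ratios(q, j, k), ddof=1))


def _pairwise_sd_matrix(logq: np.ndarray) -> np.ndarray:
    """SD of log-ratio for every gene pair; diagonal zero."""
    k = logq.shape[0]
    out = np.zeros((k, k))
    for a in range(k):
        diff = logq[a] - logq[a + 1:]
        if diff.size:
            sds = np.std(diff, axis=1, ddof=1)
            out[a, a + 1:] = sds
            out[a + 1:, a] = sds
    return out


def m_values(q: RelativeQuantityMatrix, genes: list[str] | None = None) -> dict[str, float]:
    """M_j: arithmetic mean of V_jk over all other genes in the active set."""
    active = list(genes) if genes is not None else list(q.genes)
    if len(active) < 2:
        raise InputError("M values need at least 2 active genes")
    idx = [q.gene_index(g) for g in active]
    logq = np.log2(q.q[idx])
    vmat = _pairwise_sd_matrix(logq)
    k = len(active)
    return {g: float(vmat[i].sum() / (k - 1)) for i, g in enumerate(active)}


def genorm_rank(q: RelativeQuantityMatrix) -> GenormResult:
    """Iterative geNorm exclusion ranking plus the V(n/n+1) series.

    At each step the gene with the highest average M is removed (ties:
    the later gene in input order, logged); its M at removal is recorded.
    The surviving pair shares rank 1 and its common pairwise M.
    """
    if q.n_genes < 3:
        raise InputError("geNorm ranking needs at least 3 genes")
    if q.n_samples < 3:
        raise InputError("geNorm ranking needs at least 3 samples")

    active = list(q.genes)
    m_final: dict[str, float] = {}
    exclusion_order: list[str] = []
    trajectory: list[tuple[list[str], float]] = []

    while len(active) > 2:
        mvals = m_values(q, active)
        trajectory.append((list(active), float(np.mean(list(mvals.values())))))
        worst_m = max(mvals.values())
        candidates = [g for g in active if mvals[g] == worst_m]
        if len(candidates) > 1:
            logger.info("M-value tie at %.6f between %s; removing the later "
                        "gene in input order", worst_m, candidates)
        victim = candidates[-1]  # later in input order (active preserves it)
        m_final[victim] = float(mvals[victim])
        exclusion_order.append(victim)
        active.remove(victim)

    final_m = m_values(q, active)
    trajectory.append((list(active), float(np.mean(list(final_m.values())))))
    for g in active:
        m_final[g] = float(final_m[g])

    ranking: dict[str, int] = {active[0]: 1, active[1]: 1}
    for r, gene in enumerate(reversed(exclusion_order), start=2):
        ranking[gene] = r

    # tied top pair first, then ascending M at exclusion (stable on the
    # reversed exclusion order for exact ties)
    rest = sorted(reversed(exclusion_order), key=lambda g: m_final[g])
    stability_order = list(active) + rest

    result = GenormResult(
        m_final=m_final,
        exclusion_order=exclusion_order,
        ranking=ranking,
        m_trajectory=trajectory,
        stability_order=stability_order,
    )
    result.v_series = nf_pairwise_variation(q, result)
    return result


def nf_pairwise_variation(q: RelativeQuantityMatrix, ranking: GenormResult) -> dict[int, float]:
    """V(n/n+1) series over normalization factors of growing panels.

    NF_n(s) is the geometric mean of q over the n most stable genes (tied
    top pair first, then ascending M at exclusion); V(n/n+1) is the sample
    SD over samples of log2(NF_n / NF_{n+1}), for n = 2 .. k-1.
    """
    order = ranking.stability_order
    k = len(order)
    if k < 3:
        raise InputError("V series needs at least 3 genes")
    logq = np.log2(q.q[[q.gene_index(g) for g in order]])
    # log2 NF_n per sample = mean of the first n rows
    cum = np.cumsum(logq, axis=0)
    v_series: dict[int, float] = {}
    for n in range(2, k):
        log_nf_n = cum[n - 1] / n
        log_nf_n1 = cum[n] / (n + 1)
        v_series[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    return v_series
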
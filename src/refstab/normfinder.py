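"""Model-based stability scoring via intra/inter-group variance decomposition.

Log2 relative quantities are centered per sample (removing shared loading),
then each gene's technical variance is estimated within every group with a
moment correction for the dependence that centering introduces, and each
gene's group-level deviations are shrunken toward zero in proportion to the
evidence for a real group effect. The per-gene stability score combines the
absolute shrunken deviation with the standard error of the within-group
component; lower is more stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from refstab.errors import InputError
from refstab.quantification import RelativeQuantityMatrix

logger = logging.getLogger(__name__)

#: Lower bound on estimated variances; keeps the shrinkage ratio defined.
VARIANCE_FLOOR = 1e-8


@dataclass
class NormfinderResult:
    """Per-gene stability scores with grouped diagnostics.

    Attributes
    ----------
    stability : dict
        Gene -> rho (log2 units, >= 0); lower = more stable.
    rank : dict
        Gene -> rank, 1 = most stable; ties share the smaller rank.
    intra_var : dict
        (gene, group) -> estimated within-group variance (log2^2 units).
    inter_dev : dict
        (gene, group) -> shrunken group deviation (log2 units).
    groups : list
        Group labels in first-seen order ([""] in ungrouped mode).
    """

    stability: dict[str, float]
    rank: dict[str, int]
    intra_var: dict[tuple[str, str], float]
    inter_dev: dict[tuple[str, str], float]
    groups: list[str]


def sample_center(y: np.ndarray) -> np.ndarray:
    """Subtract each sample's across-gene mean: z_gs = y_gs - mean_g(y_gs).

    Removes any per-sample loading effect; every column of z sums to zero.
    Requires at least 3 genes (the variance correction downstream is
    undefined at k <= 2).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[0] < 3:
        raise InputError("sample centering needs a matrix with >= 3 genes")
    if np.isnan(y).any():
        raise InputError("sample centering needs a complete matrix")
    return y - y.mean(axis=0, keepdims=True)


def variance_decomposition(
    z: np.ndarray, group_cols: dict[str, list[int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate within-group variances and raw group deviations per gene.

    Parameters
    ----------
    z : ndarray, genes x samples
        Sample-centered log2 quantities.
    group_cols : dict
        Group label -> column indices; every group needs >= 2 samples.

    Returns
    -------
    sigma2 : ndarray, genes x groups
        Moment-corrected within-group variance estimates, floored at
        ``VARIANCE_FLOOR``. Centering across k genes makes the naive sample
        variance biased: E[s2_ig] = sigma2_ig (1 - 2/k) + S_g / k^2 with
        S_g the group's summed true variance, estimated from
        sum_i s2_ig = S_g (k-1)/k.
    d : ndarray, genes x groups
        Raw deviations of each gene's group mean from that gene's average
        group mean; rows sum to zero over groups, columns over genes.
    """
    z = np.asarray(z, dtype=float)
    k = z.shape[0]
    if k < 3:
        raise InputError("variance decomposition needs >= 3 genes")
    for g, cols in group_cols.items():
        if len(cols) < 2:
            raise InputError(f"group {g!r} has {len(cols)} sample(s); need >= 2")

    groups = list(group_cols)
    n_groups = len(groups)
    s2 = np.empty((k, n_groups))
    zbar = np.empty((k, n_groups))
    for gi, g in enumerate(groups):
        block = z[:, group_cols[g]]
        s2[:, gi] = np.var(block, axis=1, ddof=1)
        zbar[:, gi] = block.mean(axis=1)

    s_hat = (k / (k - 1)) * s2.sum(axis=0)  # per group: estimate of sum_i sigma2_ig
    sigma2 = (s2 - s_hat[None, :] / k**2) / (1.0 - 2.0 / k)
    sigma2 = np.maximum(sigma2, VARIANCE_FLOOR)

    d = zbar - zbar.mean(axis=1, keepdims=True)
    return sigma2, d


def normfinder_stability(
    q: RelativeQuantityMatrix, grouped: bool = True
) -> NormfinderResult:
    """Rank genes by the combined intra/inter-group stability score.

    Grouped mode (requires group labels on `q`): per gene i,

    * gamma2_i = max(0, var_g(d_ig) - mean_g(sigma2_ig / n_g)) estimates the
      real between-group variance of the gene;
    * deviations shrink as d~_ig = d_ig * gamma2_i / (gamma2_i + sigma2_ig/n_g);
    * rho_i = mean_g(|d~_ig| + sqrt(sigma2_ig / n_g)).

    Ungrouped mode treats all samples as one group with zero deviations, so
    rho_i = sqrt(sigma2_i).
    """
    y = q.log2()
    if q.n_genes < 3:
        raise InputError("stability scoring needs >= 3 genes")
    z = sample_center(y)

    if grouped:
        if q.group_of is None:
            raise InputError("grouped stability scoring needs group labels")
        missing = [s for s in q.samples if s not in q.group_of]
        if missing:
            raise InputError(f"samples without group labels: {missing}")
        groups: list[str] = []
        group_cols: dict[str, list[int]] = {}
        for j, s in enumerate(q.samples):
            g = q.group_of[s]
            if g not in group_cols:
                group_cols[g] = []
                groups.append(g)
            group_cols[g].append(j)
        if len(groups) < 2:
            logger.info("only one group present; falling back to ungrouped mode")
            return normfinder_stability(q, grouped=False)

        sigma2, d = variance_decomposition(z, group_cols)
        n_g = np.array([len(group_cols[g]) for g in groups], dtype=float)
        se2 = sigma2 / n_g[None, :]  # squared SE of each group mean

        n_groups = len(groups)
        gamma2 = (d**2).sum(axis=1) / (n_groups - 1) - se2.mean(axis=1)
        gamma2 = np.maximum(gamma2, 0.0)

        shrink = gamma2[:, None] / (gamma2[:, None] + se2)
        d_tilde = d * shrink
        rho = (np.abs(d_tilde) + np.sqrt(se2)).mean(axis=1)

        intra_var = {
            (gene, grp): float(sigma2[i, gi])
            for i, gene in enumerate(q.genes)
            for gi, grp in enumerate(groups)
        }
        inter_dev = {
            (gene, grp): float(d_tilde[i, gi])
            for i, gene in enumerate(q.genes)
            for gi, grp in enumerate(groups)
        }
    else:
        groups = [""]
        var = np.var(z, axis=1, ddof=1)
        k = q.n_genes
        s_hat = (k / (k - 1)) * var.sum()
        sigma2_1d = np.maximum((var - s_hat / k**2) / (1.0 - 2.0 / k),
                               VARIANCE_FLOOR)
        rho = np.sqrt(sigma2_1d)
        intra_var = {(gene, ""): float(sigma2_1d[i]) for i, gene in enumerate(q.genes)}
        inter_dev = {(gene, ""): 0.0 for gene in q.genes}

    stability = {gene: float(rho[i]) for i, gene in enumerate(q.genes)}
    rank = _competition_rank(stability)
    return NormfinderResult(
        stability=stability,
        rank=rank,
        intra_var=intra_var,
        inter_dev=inter_dev,
        groups=groups,
    )


def _competition_rank(scores: dict[str, float]) -> dict[str, int]:
    """Ascending competition ranking ('1224'); ties share the smaller rank."""
    ordered = sorted(scores, key=lambda g: scores[g])
    ranks: dict[str, int] = {}
    for pos, gene in enumerate(ordered, start=1):
        prev = ordered[pos - 2] if pos > 1 else None
        if prev is not None and scores[gene] == scores[prev]:
            ranks[gene] = ranks[prev]
        else:
            ranks[gene] = pos
    return ranks
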
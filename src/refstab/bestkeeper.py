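"""BestKeeper-style descriptives on raw Cq, x-fold coefficients, the
per-sample index (geometric mean Cq) and Pearson correlations with p-values.

Sign convention for x-fold coefficients: the fold at the minimum Cq
(highest expression) is negative, the fold at the maximum Cq positive;
``sd_xfold = base ** sd_cq``. Genes with Cq SD >= 1 cycle are flagged
"inconsistent" but still ranked.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from refstab.data_io import CqTable, complete_case_subset
from refstab.errors import ConfigError, InputError

logger = logging.getLogger(__name__)

#: Cq SD at or above this is flagged as inconsistent (not excluded).
SD_CONSISTENCY_LIMIT = 1.0


def min_xfold(geo_mean_cq: float, min_cq: float, base: float = 2.0) -> float:
    """Signed fold coefficient at the minimum Cq (highest expression):
    -(base ** (geo_mean_cq - min_cq))."""
    if base <= 1.0:
        raise ConfigError(f"x-fold base must be > 1, got {base}")
    return -(base ** (geo_mean_cq - min_cq))


def max_xfold(geo_mean_cq: float, max_cq: float, base: float = 2.0) -> float:
    """Signed fold coefficient at the maximum Cq (lowest expression):
    +(base ** (max_cq - geo_mean_cq))."""
    if base <= 1.0:
        raise ConfigError(f"x-fold base must be > 1, got {base}")
    return base ** (max_cq - geo_mean_cq)


def sd_xfold(sd_cq: float, base: float = 2.0) -> float:
    """Cq standard deviation re-expressed as a fold change: base ** sd_cq."""
    if base <= 1.0:
        raise ConfigError(f"x-fold base must be > 1, got {base}")
    return base**sd_cq


@dataclass
class BestkeeperGeneStats:
    """Descriptive statistics for one gene's Cq values."""

    gene: str
    n: int
    geo_mean_cq: float
    ar_mean_cq: float
    min_cq: float
    max_cq: float
    sd_cq: float
    cv_pct: float
    min_xfold: float
    max_xfold: float
    sd_xfold: float
    consistent: bool = True


@dataclass
class BestkeeperResult:
    """Full BestKeeper analysis: descriptives, index, correlations, ranking."""

    stats: dict[str, BestkeeperGeneStats]
    index_cq: dict[str, float]
    gene_vs_index: dict[str, tuple[float, float]]
    pairwise_r: dict[tuple[str, str], tuple[float, float]]
    ranking: dict[str, int] = field(default_factory=dict)
    order: list[str] = field(default_factory=list)


def descriptive_stats(
    table: CqTable, gene: str, base: float = 2.0, sd_method: str = "sample_sd"
) -> BestkeeperGeneStats:
    """Descriptives for one gene over its non-missing Cq values.

    sd_method "sample_sd" is the n-1 standard deviation; "mad" is the mean
    absolute deviation from the arithmetic mean (the convention attributed
    to the original tool). The x-fold fields re-express the Cq spread as
    fold changes in base `base`.
    """
    if base <= 1.0:
        raise ConfigError(f"x-fold base must be > 1, got {base}")
    if sd_method not in ("sample_sd", "mad"):
        raise ConfigError(f"sd_method must be 'sample_sd' or 'mad', got {sd_method!r}")
    i = table.gene_index(gene)
    vals = table.cq[i]
    vals = vals[~np.isnan(vals)]
    if vals.size < 3:
        raise InputError(f"gene {gene!r} has {vals.size} non-missing Cq; need >= 3")
    if (vals <= 0).any():
        raise InputError(f"gene {gene!r} has non-positive Cq; geometric mean undefined")

    mn0, mx0 = float(vals.min()), float(vals.max())
    # clamp away exp/log round-off: the geometric mean lies in [min, max]
    geo = float(min(max(np.exp(np.mean(np.log(vals))), mn0), mx0))
    ar = float(np.mean(vals))
    if sd_method == "sample_sd":
        sd = float(np.std(vals, ddof=1))
    else:
        sd = float(np.mean(np.abs(vals - ar)))
    mn, mx = mn0, mx0
    return BestkeeperGeneStats(
        gene=gene,
        n=int(vals.size),
        geo_mean_cq=geo,
        ar_mean_cq=ar,
        min_cq=mn,
        max_cq=mx,
        sd_cq=sd,
        cv_pct=100.0 * sd / ar,
        min_xfold=min_xfold(geo, mn, base),
        max_xfold=max_xfold(geo, mx, base),
        sd_xfold=sd_xfold(sd, base),
        consistent=sd < SD_CONSISTENCY_LIMIT,
    )


def bestkeeper_index(table: CqTable, genes: list[str] | None = None) -> dict[str, float]:
    """Per-sample geometric mean Cq over the selected genes (complete cases)."""
    gene_list = list(genes) if genes is not None else list(table.genes)
    if len(gene_list) < 2:
        raise InputError("BestKeeper index needs at least 2 genes")
    sub = complete_case_subset(table, gene_list)
    log_cq = np.log(sub.cq)
    idx = np.exp(log_cq.mean(axis=0))
    return {s: float(v) for s, v in zip(sub.samples, idx)}


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t distribution.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom. Perfect
    correlation returns p at the numeric floor rather than exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InputError("pearson_with_p needs two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("pearson_with_p needs non-zero variance in both vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    n = x.size
    if 1.0 - r * r <= 0:
        p = float(np.finfo(float).tiny)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        p = min(1.0, max(p, float(np.finfo(float).tiny)))
    return r, p


def bestkeeper_rank(
    stats: dict[str, BestkeeperGeneStats]
) -> tuple[dict[str, int], list[str]]:
    """Rank genes by ascending Cq SD; ties by ascending sd_xfold, then by
    input order (stable sort). Inconsistent genes (SD >= 1) stay ranked.

    Ties after both keys share the smaller rank.
    """
    if len(stats) < 2:
        raise InputError("ranking needs stats for at least 2 genes")
    order = sorted(stats, key=lambda g: (stats[g].sd_cq, stats[g].sd_xfold))
    ranks: dict[str, int] = {}
    for pos, gene in enumerate(order, start=1):
        prev = order[pos - 2] if pos > 1 else None
        if (
            prev is not None
            and stats[gene].sd_cq == stats[prev].sd_cq
            and stats[gene].sd_xfold == stats[prev].sd_xfold
        ):
            ranks[gene] = ranks[prev]
        else:
            ranks[gene] = pos
    for g, st in stats.items():
        if not st.consistent:
            logger.info("gene %s flagged inconsistent (Cq SD %.2f >= %.0f)",
                        g, st.sd_cq, SD_CONSISTENCY_LIMIT)
    return ranks, order


def bestkeeper_analysis(
    table: CqTable,
    base: float = 2.0,
    sd_method: str = "sample_sd",
    bases_by_gene: dict[str, float] | None = None,
) -> BestkeeperResult:
    """Full BestKeeper pass: per-gene descriptives on all non-missing Cq,
    index and correlations on the complete-case subset, and the SD ranking.

    The correlation table is advisory; only (sd_cq, sd_xfold) drives the
    ranking.
    """
    stats = {
        g: descriptive_stats(
            table, g,
            base=(bases_by_gene or {}).get(g, base),
            sd_method=sd_method,
        )
        for g in table.genes
    }
    sub = complete_case_subset(table)
    index = bestkeeper_index(sub)
    idx_vec = np.array([index[s] for s in sub.samples])
    gene_vs_index: dict[str, tuple[float, float]] = {}
    for i, g in enumerate(sub.genes):
        try:
            gene_vs_index[g] = pearson_with_p(sub.cq[i], idx_vec)
        except InputError:
            logger.warning("gene %s has zero Cq variance; no index correlation", g)
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in itertools.combinations(sub.genes, 2):
        ia, ib = sub.gene_index(a), sub.gene_index(b)
        try:
            pairwise[(a, b)] = pearson_with_p(sub.cq[ia], sub.cq[ib])
        except InputError:
            continue
    ranks, order = bestkeeper_rank(stats)
    return BestkeeperResult(
        stats=stats,
        index_cq=index,
        gene_vs_index=gene_vs_index,
        pairwise_r=pairwise,
        ranking=ranks,
        order=order,
    )
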
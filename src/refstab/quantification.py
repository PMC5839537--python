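"""Standard-curve fitting, amplification efficiency, comparative-Cq quantities.

Efficiency is derived from the standard-curve slope as ``E = 10**(-1/slope)``
(slope in Cq per log10 dilution; a slope of -3.3219 gives E = 2, i.e. perfect
doubling). Relative quantities are computed on the comparative-Cq scale,
referenced to each gene's minimum Cq so that ``max_s q_gs == 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from refstab.data_io import CqTable, EfficiencySet
from refstab.errors import ConfigError, InputError

logger = logging.getLogger(__name__)


@dataclass
class StandardCurve:
    """OLS fit of Cq against log10 relative input for one gene."""

    gene: str
    slope: float
    intercept: float
    r2: float
    efficiency: float

    @property
    def efficiency_fraction(self) -> float:
        """Percent efficiency, (E - 1) * 100."""
        return (self.efficiency - 1.0) * 100.0


@dataclass
class RelativeQuantityMatrix:
    """Per-gene, per-sample relative quantities on the comparative-Cq scale.

    Every q lies in (0, 1] and each gene's maximum over samples is exactly 1.
    """

    genes: list[str]
    samples: list[str]
    q: np.ndarray
    base_of: dict[str, float]
    group_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.genes), len(self.samples)):
            raise InputError("q matrix shape does not match genes x samples")
        if not np.isfinite(self.q).all() or (self.q <= 0).any():
            raise InputError("relative quantities must be finite and > 0")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise InputError(f"unknown gene {gene!r}") from None

    def log2(self) -> np.ndarray:
        """log2 of q — the scale on which variance decompositions operate."""
        return np.log2(self.q)


def efficiency_from_slope(slope: float) -> float:
    """Amplification base E = 10**(-1/slope) from a standard-curve slope.

    Percent efficiency is (E - 1) * 100; a slope of -3.3219 yields E = 2.
    """
    if not np.isfinite(slope) or slope >= 0:
        raise InputError(f"standard-curve slope must be negative, got {slope}")
    return float(10.0 ** (-1.0 / slope))


def slope_from_efficiency(efficiency: float) -> float:
    """Inverse of :func:`efficiency_from_slope`."""
    if not np.isfinite(efficiency) or efficiency <= 1.0:
        raise InputError(f"efficiency must be > 1, got {efficiency}")
    return float(-1.0 / np.log10(efficiency))


def fit_standard_curve(
    dilution_points: Sequence[tuple[float, float]], gene: str = ""
) -> StandardCurve:
    """Fit Cq = slope * log10(input) + intercept by ordinary least squares.

    Parameters
    ----------
    dilution_points : sequence of (log10 relative input, mean Cq)
        At least 3 points with at least 2 distinct x values.
    """
    pts = np.asarray(dilution_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InputError("need at least 3 (log10_input, cq) dilution points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise InputError("all dilution points share one x value; slope undefined")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if slope >= 0:
        raise InputError(
            f"fitted standard-curve slope {slope:.4f} is non-negative; "
            "check dilution orientation"
        )
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        efficiency=efficiency_from_slope(slope),
    )


def fit_standard_curves(
    points_by_gene: Mapping[str, Sequence[tuple[float, float]]]
) -> EfficiencySet:
    """Fit one curve per gene and bundle the results as an EfficiencySet.

    Replicate Cq at the same dilution are averaged before fitting.
    """
    eff: dict[str, float] = {}
    slopes: dict[str, float] = {}
    r2s: dict[str, float] = {}
    for gene, pts in points_by_gene.items():
        averaged: dict[float, list[float]] = {}
        for x, yv in pts:
            averaged.setdefault(float(x), []).append(float(yv))
        mean_pts = [(x, float(np.mean(ys))) for x, ys in averaged.items()]
        curve = fit_standard_curve(mean_pts, gene=gene)
        eff[gene] = curve.efficiency
        slopes[gene] = curve.slope
        r2s[gene] = curve.r2
    return EfficiencySet(efficiency_of=eff, slope_of=slopes, r2_of=r2s)


def relative_quantities(
    table: CqTable,
    efficiencies: EfficiencySet | float | None = None,
) -> RelativeQuantityMatrix:
    """Transform Cq into relative quantities q = E**(minCq - Cq) per gene.

    The per-gene minimum Cq is the reference point, so max q per gene is 1.
    Any common reference cancels in every downstream log-ratio, so this
    choice is presentation-only. The table must be complete (no missing Cq).

    `efficiencies` may be an :class:`EfficiencySet`, a uniform base, or None
    (base 2, i.e. 100% efficiency).
    """
    if np.isnan(table.cq).any():
        raise InputError(
            "relative_quantities requires a complete-case table; "
            "apply complete_case_subset first"
        )
    if efficiencies is None:
        base_of = {g: 2.0 for g in table.genes}
    elif isinstance(efficiencies, EfficiencySet):
        base_of = {g: efficiencies.get(g) for g in table.genes}
    else:
        base_of = {g: float(efficiencies) for g in table.genes}
    for g, e in base_of.items():
        if not np.isfinite(e) or e <= 1.0:
            raise ConfigError(f"amplification base for {g!r} must be > 1, got {e}")

    bases = np.array([base_of[g] for g in table.genes])[:, None]
    min_cq = table.cq.min(axis=1, keepdims=True)
    q = bases ** (min_cq - table.cq)
    # guard against floating fuzz at the reference point
    np.minimum(q, 1.0, out=q)
    return RelativeQuantityMatrix(
        genes=list(table.genes),
        samples=list(table.samples),
        q=q,
        base_of=base_of,
        group_of=dict(table.group_of) if table.group_of else None,
    )
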
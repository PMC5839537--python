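"""End-to-end orchestration: Cq table in, per-algorithm results and the
consensus recommendation out, as one JSON-able mapping consumed by
:func:`refstab.consensus.render_report`.
"""

from __future__ import annotations

import logging
from typing import Any

from refstab import __version__
from refstab.bestkeeper import bestkeeper_analysis
from refstab.consensus import (DEFAULT_V_THRESHOLD, aggregate_ranks,
                               finalize_consensus)
from refstab.data_io import CqTable, EfficiencySet, collapse_replicates, complete_case_subset
from refstab.errors import ConfigError, InputError
from refstab.genorm import genorm_rank
from refstab.normfinder import normfinder_stability
from refstab.quantification import relative_quantities

logger = logging.getLogger(__name__)

ALGORITHMS = ("genorm", "normfinder", "bestkeeper")


def run_pipeline(
    table: CqTable,
    efficiencies: EfficiencySet | float | None = None,
    algorithms: tuple[str, ...] = ALGORITHMS,
    per_group: bool = False,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    sd_method: str = "sample_sd",
    meta: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Run the requested stability algorithms and aggregate the rankings.

    Technical replicates are collapsed by mean first. geNorm and NormFinder
    run on the complete-case subset of relative quantities; BestKeeper
    descriptives use all non-missing Cq per gene. The consensus block is
    produced only when all three algorithms ran.
    """
    for a in algorithms:
        if a not in ALGORITHMS:
            raise ConfigError(f"unknown algorithm {a!r}; choose from {ALGORITHMS}")
    if not algorithms:
        raise ConfigError("no algorithms requested")

    if table.replicate_of:
        table = collapse_replicates(table)

    results: dict[str, Any] = {
        "meta": {
            "package_version": __version__,
            "n_genes": table.n_genes,
            "n_samples": table.n_samples,
            "algorithms": list(algorithms),
            "v_threshold": v_threshold,
            "sd_method": sd_method,
            **(meta or {}),
        }
    }

    needs_q = any(a in algorithms for a in ("genorm", "normfinder"))
    q = None
    if needs_q:
        complete = complete_case_subset(table)
        q = relative_quantities(complete, efficiencies)

    if "genorm" in algorithms:
        gr = genorm_rank(q)
        results["genorm"] = {
            "m_final": gr.m_final,
            "ranking": gr.ranking,
            "exclusion_order": gr.exclusion_order,
            "stability_order": gr.stability_order,
            "v_series": {str(n): v for n, v in gr.v_series.items()},
        }

    if "normfinder" in algorithms:
        grouped = table.group_of is not None
        nf = normfinder_stability(q, grouped=grouped)
        results["normfinder"] = {
            "stability": nf.stability,
            "rank": nf.rank,
            "grouped": grouped,
            "groups": nf.groups,
            "intra_sd": _nested(nf.intra_var, sqrt=True),
            "inter_dev": _nested(nf.inter_dev),
        }

    if "bestkeeper" in algorithms:
        bases = None
        if isinstance(efficiencies, EfficiencySet):
            bases = {g: efficiencies.get(g, 2.0) for g in table.genes}
        base = float(efficiencies) if isinstance(efficiencies, (int, float)) else 2.0
        bk = bestkeeper_analysis(table, base=base, sd_method=sd_method,
                                 bases_by_gene=bases)
        results["bestkeeper"] = {
            "sd_cq": {g: st.sd_cq for g, st in bk.stats.items()},
            "ranking": bk.ranking,
            "order": bk.order,
            "stats": {
                g: {
                    "n": st.n,
                    "geo_mean_cq": st.geo_mean_cq,
                    "ar_mean_cq": st.ar_mean_cq,
                    "min_cq": st.min_cq,
                    "max_cq": st.max_cq,
                    "sd_cq": st.sd_cq,
                    "cv_pct": st.cv_pct,
                    "min_xfold": st.min_xfold,
                    "max_xfold": st.max_xfold,
                    "sd_xfold": st.sd_xfold,
                    "consistent": st.consistent,
                }
                for g, st in bk.stats.items()
            },
            "gene_vs_index": {g: list(v) for g, v in bk.gene_vs_index.items()},
            "pairwise_r": {f"{a}|{b}": list(v) for (a, b), v in bk.pairwise_r.items()},
        }

    if set(ALGORITHMS) <= set(algorithms):
        cr = aggregate_ranks(
            results["genorm"]["ranking"],
            results["normfinder"]["rank"],
            results["bestkeeper"]["ranking"],
        )
        v_series = {int(n): v for n, v in results["genorm"]["v_series"].items()}
        cr = finalize_consensus(cr, v_series, threshold=v_threshold)
        results["consensus"] = {
            "per_algorithm_ranks": {g: list(r) for g, r in cr.per_algorithm_ranks.items()},
            "aggregate_score": cr.aggregate_score,
            "consensus_order": cr.consensus_order,
            "panel": cr.panel,
            "panel_size": cr.panel_size,
            "v_used": cr.v_used,
            "threshold_met": cr.threshold_met,
        }

    if per_group:
        results["per_group"] = _per_group_genorm(table, efficiencies)

    return results


def _per_group_genorm(table: CqTable, efficiencies) -> dict[str, Any]:
    """Rerun geNorm (M and V) within each group; NormFinder is skipped
    per-group since a single group has no inter-group term."""
    table.require_groups()
    out: dict[str, Any] = {}
    for grp in table.groups():
        cols = [s for s in table.samples if table.group_of.get(s) == grp]
        sub = CqTable(
            genes=list(table.genes),
            samples=cols,
            cq=table.cq[:, [table.samples.index(s) for s in cols]].copy(),
            group_of={s: grp for s in cols},
        )
        try:
            complete = complete_case_subset(sub)
            q = relative_quantities(complete, efficiencies)
            gr = genorm_rank(q)
        except InputError as exc:
            logger.warning("per-group geNorm skipped for %s: %s", grp, exc)
            out[grp] = {"skipped": str(exc)}
            continue
        out[grp] = {
            "genorm": {
                "m_final": gr.m_final,
                "ranking": gr.ranking,
                "v_series": {str(n): v for n, v in gr.v_series.items()},
            }
        }
    return out


def _nested(d: dict[tuple[str, str], float], sqrt: bool = False) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for (gene, grp), v in d.items():
        out.setdefault(gene, {})[grp] = float(v) ** 0.5 if sqrt else float(v)
    return out
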
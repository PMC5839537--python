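"""Rank aggregation across the three algorithms, panel-size selection via
the V-threshold rule, and deterministic report rendering.

The consensus order is the geometric mean of the three per-algorithm ranks —
an artifact convention giving a total order consistent with the usual
narrative intersection of the three lists; it is not itself one of the
published algorithms.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

from refstab.errors import ConfigError, InputError

logger = logging.getLogger(__name__)

#: Suggestive (not universal) V(n/n+1) cutoff for panel sizing.
DEFAULT_V_THRESHOLD = 0.15


@dataclass
class ConsensusResult:
    """Aggregated ranking and panel recommendation."""

    per_algorithm_ranks: dict[str, tuple[int, int, int]]
    aggregate_score: dict[str, float]
    consensus_order: list[str]
    panel: list[str] = field(default_factory=list)
    panel_size: int = 0
    v_used: float = float("nan")
    threshold_met: bool = False


def aggregate_ranks(
    genorm_rank: Mapping[str, int],
    normfinder_rank: Mapping[str, int],
    bestkeeper_rank: Mapping[str, int],
) -> ConsensusResult:
    """Order genes by the geometric mean of their three ranks.

    All three rankings must cover the same gene set; within-algorithm ties
    carry their shared (minimum) rank into the product. Aggregate ties break
    by the better geNorm rank, then input order (order of `genorm_rank`).
    """
    genes = list(genorm_rank)
    for name, other in (("normfinder", normfinder_rank), ("bestkeeper", bestkeeper_rank)):
        diff = set(genes) ^ set(other)
        if diff:
            raise InputError(f"gene sets differ between genorm and {name}: {sorted(diff)}")
    per = {
        g: (int(genorm_rank[g]), int(normfinder_rank[g]), int(bestkeeper_rank[g]))
        for g in genes
    }
    score = {g: (r[0] * r[1] * r[2]) ** (1.0 / 3.0) for g, r in per.items()}
    order = sorted(genes, key=lambda g: (score[g], per[g][0]))
    return ConsensusResult(
        per_algorithm_ranks=per,
        aggregate_score=score,
        consensus_order=order,
    )


def recommend_panel_size(
    v_series: Mapping[int, float], threshold: float = DEFAULT_V_THRESHOLD
) -> tuple[int, float, bool]:
    """Smallest n with V(n/n+1) <= threshold, else the argmin of the series.

    Returns (panel_size, v_used, threshold_met). When no V meets the
    threshold the smallest-V size is recommended anyway — the cutoff is
    suggestive, not universal — and an advisory is logged.
    """
    if not v_series:
        raise InputError("empty V series")
    if threshold <= 0:
        raise ConfigError(f"V threshold must be positive, got {threshold}")
    for n in sorted(v_series):
        if v_series[n] <= threshold:
            return n, float(v_series[n]), True
    best_n = min(sorted(v_series), key=lambda n: v_series[n])
    logger.info(
        "no V(n/n+1) at or below %.3f; recommending the minimum-V size %d "
        "(V=%.3f) — the cutoff is a suggestive criterion, not a universal one",
        threshold, best_n, v_series[best_n],
    )
    return best_n, float(v_series[best_n]), False


def finalize_consensus(
    result: ConsensusResult,
    v_series: Mapping[int, float] | None,
    threshold: float = DEFAULT_V_THRESHOLD,
) -> ConsensusResult:
    """Attach the recommended panel (top consensus genes at the chosen size)."""
    if v_series:
        size, v_used, met = recommend_panel_size(v_series, threshold)
    else:
        size, v_used, met = 2, float("nan"), False
    size = max(2, size)
    result.panel = result.consensus_order[:size]
    result.panel_size = size
    result.v_used = v_used
    result.threshold_met = met
    return result


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _round_floats(obj: Any, ndigits: int) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def input_digest(payload: bytes | str) -> str:
    """Stable sha256 digest of raw input bytes, for report provenance."""
    if isinstance(payload, str):
        payload = payload.encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


def render_report(results: Mapping[str, Any], fmt: str = "json") -> str:
    """Serialize a results mapping deterministically.

    Scores are fixed at 4 decimals, Cq-style descriptives at 2 decimals
    (the report builder pre-rounds those); key order is sorted; identical
    inputs produce byte-identical output.

    `results` is a plain mapping as built by the pipeline: keys among
    ``meta, genorm, normfinder, bestkeeper, consensus, per_group``.
    """
    if not results:
        raise InputError("no algorithm results to render")
    if fmt == "json":
        return json.dumps(_round_floats(results, 4), indent=2, sort_keys=True,
                          allow_nan=True) + "\n"
    if fmt == "tsv":
        return _render_tsv(results)
    if fmt == "markdown":
        return _render_markdown(results)
    raise ConfigError(f"unknown report format {fmt!r}")


def _ranking_rows(results: Mapping[str, Any]) -> dict[str, list[tuple]]:
    """Per-algorithm (gene, score, rank) rows in rank order."""
    out: dict[str, list[tuple]] = {}
    if "genorm" in results:
        gr = results["genorm"]
        rows = sorted(gr["m_final"], key=lambda g: (gr["ranking"][g], g))
        out["genorm"] = [(g, gr["m_final"][g], gr["ranking"][g]) for g in rows]
    if "normfinder" in results:
        nf = results["normfinder"]
        rows = sorted(nf["stability"], key=lambda g: (nf["rank"][g], g))
        out["normfinder"] = [(g, nf["stability"][g], nf["rank"][g]) for g in rows]
    if "bestkeeper" in results:
        bk = results["bestkeeper"]
        rows = sorted(bk["sd_cq"], key=lambda g: (bk["ranking"][g], g))
        out["bestkeeper"] = [(g, bk["sd_cq"][g], bk["ranking"][g]) for g in rows]
    if "consensus" in results:
        cr = results["consensus"]
        out["consensus"] = [
            (g, cr["aggregate_score"][g], i + 1)
            for i, g in enumerate(cr["consensus_order"])
        ]
    return out


def _render_tsv(results: Mapping[str, Any]) -> str:
    lines: list[str] = []
    for name, rows in _ranking_rows(results).items():
        lines.append(f"# {name}")
        lines.append("gene\tscore\trank")
        for g, score, rank in rows:
            lines.append(f"{g}\t{score:.4f}\t{rank}")
        lines.append("")
    if "genorm" in results and results["genorm"].get("v_series"):
        lines.append("# v_series")
        lines.append("n\tv")
        for n in sorted(results["genorm"]["v_series"], key=int):
            lines.append(f"{n}\t{results['genorm']['v_series'][n]:.4f}")
        lines.append("")
    return "\n".join(lines)


def _render_markdown(results: Mapping[str, Any]) -> str:
    score_name = {"genorm": "M", "normfinder": "stability",
                  "bestkeeper": "sd_cq", "consensus": "aggregate"}
    lines = ["# Reference-gene stability report", ""]
    meta = results.get("meta", {})
    if meta:
        for k in sorted(meta):
            lines.append(f"- {k}: {meta[k]}")
        lines.append("")
    for name, rows in _ranking_rows(results).items():
        lines.append(f"## {name}")
        lines.append("")
        lines.append(f"| gene | {score_name[name]} | rank |")
        lines.append("| --- | --- | --- |")
        for g, score, rank in rows:
            lines.append(f"| {g} | {score:.4f} | {rank} |")
        lines.append("")
    cr = results.get("consensus")
    if cr and cr.get("panel"):
        lines.append(
            f"Recommended panel (size {cr['panel_size']}, "
            f"V={cr['v_used']:.4f}, threshold_met={cr['threshold_met']}): "
            + ", ".join(cr["panel"])
        )
        lines.append("")
    return "\n".join(lines)
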
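"""Reading, validation and normalisation of Cq tables and efficiency files.

The single input currency of the pipeline is :class:`CqTable`: a rectangular
genes x samples matrix of quantification-cycle values with per-sample group
(tissue) labels and optional subject / technical-replicate annotations.
Missing Cq values are stored as NaN.

Two plain-text layouts are supported:

* **long** — one row per measurement with columns
  ``sample_id, group, subject_id (optional), replicate (optional), gene, cq``;
* **wide** — header ``gene,<sample1>,<sample2>,...`` with one row per gene;
  group labels come from a sidecar CSV (``sample_id, group``).

Comma is the default separator; tab is accepted. Decimal point only; UTF-8.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from refstab.errors import ConfigError, InputError

logger = logging.getLogger(__name__)

#: Cq values above this many cycles are implausible and trigger a warning.
CQ_PLAUSIBLE_MAX = 45.0

#: Technical-replicate spread (max - min) above this triggers a QC warning.
REPLICATE_SPREAD_WARN = 0.5

_LONG_COLUMNS = {"sample_id", "group", "subject_id", "replicate", "gene", "cq"}


@dataclass
class CqTable:
    """Rectangular Cq matrix with sample metadata.

    Parameters
    ----------
    genes : list of str
        Gene identifiers, first-seen order, unique.
    samples : list of str
        Column keys, first-seen order, unique. When technical replicates are
        present each (sample, replicate) well gets its own column keyed
        ``"<sample>::<replicate>"`` and `sample_of` maps it back.
    cq : ndarray, shape (n_genes, n_samples)
        Cq values in cycles; NaN marks missing.
    group_of : dict, optional
        Column key -> group (tissue) label.
    subject_of : dict, optional
        Column key -> biological-subject label.
    sample_of : dict, optional
        Column key -> underlying biological sample id (defaults to the key).
    replicate_of : dict, optional
        Column key -> technical-replicate label; None when collapsed.
    """

    genes: list[str]
    samples: list[str]
    cq: np.ndarray
    group_of: dict[str, str] | None = None
    subject_of: dict[str, str] | None = None
    sample_of: dict[str, str] | None = None
    replicate_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.cq = np.asarray(self.cq, dtype=float)
        if self.cq.shape != (len(self.genes), len(self.samples)):
            raise InputError(
                f"cq matrix shape {self.cq.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise InputError("gene identifiers are not unique")
        if len(set(self.samples)) != len(self.samples):
            raise InputError("sample identifiers are not unique")
        finite = self.cq[~np.isnan(self.cq)]
        if finite.size and (~np.isfinite(finite)).any():
            raise InputError("non-missing Cq values must be finite")
        if finite.size and (finite <= 0).any():
            raise InputError("non-missing Cq values must be > 0 cycles")
        n_implausible = int((finite > CQ_PLAUSIBLE_MAX).sum())
        if n_implausible:
            logger.warning(
                "%d Cq value(s) exceed %.0f cycles (implausible)",
                n_implausible, CQ_PLAUSIBLE_MAX,
            )

    # -- convenience accessors -------------------------------------------

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean genes x samples matrix, True where Cq is missing."""
        return np.isnan(self.cq)

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

    def groups(self) -> list[str]:
        """Group labels in first-seen column order."""
        if self.group_of is None:
            return []
        seen: list[str] = []
        for s in self.samples:
            g = self.group_of.get(s)
            if g is not None and g not in seen:
                seen.append(g)
        return seen

    def require_groups(self) -> None:
        if self.group_of is None or any(s not in self.group_of for s in self.samples):
            missing = [] if self.group_of is None else [
                s for s in self.samples if s not in self.group_of]
            raise InputError(
                "grouped analysis requested but group labels are missing"
                + (f" for samples {missing}" if missing else "")
            )

    def equals(self, other: "CqTable") -> bool:
        return (
            self.genes == other.genes
            and self.samples == other.samples
            and np.array_equal(self.cq, other.cq, equal_nan=True)
            and (self.group_of or {}) == (other.group_of or {})
            and (self.subject_of or {}) == (other.subject_of or {})
        )


@dataclass
class EfficiencySet:
    """Per-gene amplification efficiency E (base per cycle).

    When a standard-curve slope is recorded for a gene, E and slope must be
    consistent via E = 10**(-1/slope).
    """

    efficiency_of: dict[str, float]
    slope_of: dict[str, float] = field(default_factory=dict)
    r2_of: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, e in self.efficiency_of.items():
            if not np.isfinite(e) or e <= 1.0:
                raise InputError(f"efficiency for {gene!r} must be > 1, got {e}")
        for gene, slope in self.slope_of.items():
            e = self.efficiency_of.get(gene)
            if e is None:
                continue
            implied = 10.0 ** (-1.0 / slope)
            if abs(implied - e) > 1e-6:
                raise InputError(
                    f"gene {gene!r}: efficiency {e} inconsistent with slope "
                    f"{slope} (implies E={implied:.8f})"
                )

    def get(self, gene: str, default: float | None = None) -> float:
        e = self.efficiency_of.get(gene, default)
        if e is None:
            raise InputError(f"no efficiency for gene {gene!r}")
        return float(e)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def _read_rows(path: Path) -> tuple[list[str], list[list[str]]]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    delim = _sniff_delimiter(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = [row for row in reader if row and any(c.strip() for c in row)]
    if not rows:
        raise InputError(f"empty file: {path}")
    header = [c.strip() for c in rows[0]]
    return header, [[c.strip() for c in r] for r in rows[1:]]


def _parse_cq(raw: str, where: str) -> float:
    if raw == "" or raw.upper() in {"NA", "NAN", "NULL", "UNDETERMINED"}:
        return float("nan")
    try:
        return float(raw)
    except ValueError:
        logger.warning("unparseable Cq %r at %s treated as missing", raw, where)
        return float("nan")


def read_cq_table(
    path: str | Path,
    layout: str = "long",
    column_map: Mapping[str, str] | None = None,
    groups_path: str | Path | None = None,
) -> CqTable:
    """Read a Cq table from a long or wide CSV/TSV file.

    Parameters
    ----------
    path : path
        Input file.
    layout : {"long", "wide"}
    column_map : mapping, optional
        Maps canonical names (``sample_id``, ``group``, ``subject_id``,
        ``replicate``, ``gene``, ``cq``) to the file's column names.
    groups_path : path, optional
        Sidecar CSV ``sample_id, group`` (wide layout, or to override).

    Returns
    -------
    CqTable
        Validated; unparseable Cq cells become missing (logged); gene and
        sample order is first-seen order.
    """
    if layout not in ("long", "wide"):
        raise ConfigError(f"layout must be 'long' or 'wide', got {layout!r}")
    if layout == "long":
        table = _read_long(Path(path), column_map or {})
    else:
        table = _read_wide(Path(path), column_map or {})
    if groups_path is not None:
        table = replace(table, group_of=_read_group_sidecar(Path(groups_path), table.samples))
    return table


def _read_long(path: Path, column_map: Mapping[str, str]) -> CqTable:
    header, rows = _read_rows(path)
    name = {canon: column_map.get(canon, canon) for canon in _LONG_COLUMNS}
    # tolerate common aliases for the sample column
    if name["sample_id"] not in header:
        for alias in ("sample", "Sample", "sample_name"):
            if alias in header and "sample_id" not in column_map:
                name["sample_id"] = alias
                break
    idx: dict[str, int] = {}
    for canon in _LONG_COLUMNS:
        if name[canon] in header:
            idx[canon] = header.index(name[canon])
    for mandatory in ("sample_id", "gene", "cq"):
        if mandatory not in idx:
            raise InputError(
                f"long layout requires column {name[mandatory]!r}; "
                f"found {header}"
            )

    genes: list[str] = []
    columns: list[str] = []
    group_of: dict[str, str] = {}
    subject_of: dict[str, str] = {}
    sample_of: dict[str, str] = {}
    replicate_of: dict[str, str] = {}
    has_replicates = "replicate" in idx
    values: dict[tuple[str, str], float] = {}

    for lineno, row in enumerate(rows, start=2):
        sample = row[idx["sample_id"]]
        gene = row[idx["gene"]]
        rep = row[idx["replicate"]] if has_replicates and idx["replicate"] < len(row) else ""
        col = f"{sample}::{rep}" if rep else sample
        key = (gene, col)
        if key in values:
            raise InputError(
                f"duplicate (gene, sample, replicate) = "
                f"({gene!r}, {sample!r}, {rep or None!r}) at line {lineno}"
            )
        values[key] = _parse_cq(row[idx["cq"]], f"{path.name}:{lineno}")
        if gene not in genes:
            genes.append(gene)
        if col not in columns:
            columns.append(col)
            sample_of[col] = sample
            if rep:
                replicate_of[col] = rep
        if "group" in idx and idx["group"] < len(row) and row[idx["group"]]:
            group_of[col] = row[idx["group"]]
        if "subject_id" in idx and idx["subject_id"] < len(row) and row[idx["subject_id"]]:
            subject_of[col] = row[idx["subject_id"]]

    cq = np.full((len(genes), len(columns)), np.nan)
    for (gene, col), v in values.items():
        cq[genes.index(gene), columns.index(col)] = v
    return CqTable(
        genes=genes,
        samples=columns,
        cq=cq,
        group_of=group_of or None,
        subject_of=subject_of or None,
        sample_of=sample_of or None,
        replicate_of=replicate_of or None,
    )


def _read_wide(path: Path, column_map: Mapping[str, str]) -> CqTable:
    header, rows = _read_rows(path)
    if len(header) < 2:
        raise InputError("wide layout needs a gene column plus sample columns")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise InputError("duplicate sample columns in wide header")
    genes: list[str] = []
    cq_rows: list[list[float]] = []
    for lineno, row in enumerate(rows, start=2):
        gene = row[0]
        if gene in genes:
            raise InputError(f"duplicate gene row {gene!r} at line {lineno}")
        genes.append(gene)
        padded = row[1:] + [""] * (len(samples) - len(row) + 1)
        cq_rows.append([
            _parse_cq(c, f"{path.name}:{lineno}") for c in padded[: len(samples)]
        ])
    group_of = None
    if column_map:
        # column_map may carry sample -> group assignments directly
        candidate = {s: column_map[s] for s in samples if s in column_map}
        group_of = candidate or None
    return CqTable(genes=genes, samples=list(samples), cq=np.array(cq_rows),
                   group_of=group_of)


def _read_group_sidecar(path: Path, samples: Sequence[str]) -> dict[str, str]:
    header, rows = _read_rows(path)
    lower = [h.lower() for h in header]
    try:
        si = lower.index("sample_id")
    except ValueError:
        si = 0
    try:
        gi = lower.index("group")
    except ValueError:
        gi = 1
    mapping = {row[si]: row[gi] for row in rows if len(row) > max(si, gi)}
    unknown = [s for s in samples if s not in mapping and "::" not in s]
    if unknown:
        logger.warning("group sidecar missing %d sample(s): %s", len(unknown), unknown)
    # map replicate columns via their underlying sample id
    out: dict[str, str] = {}
    for s in samples:
        base = s.split("::", 1)[0]
        if base in mapping:
            out[s] = mapping[base]
    return out


def read_efficiencies(path: str | Path) -> EfficiencySet:
    """Read a per-gene efficiency CSV (columns ``gene, efficiency`` or
    ``gene, slope``; an optional ``r2`` column is carried as provenance)."""
    header, rows = _read_rows(Path(path))
    lower = [h.lower() for h in header]
    if "gene" not in lower:
        raise InputError("efficiency file needs a 'gene' column")
    gi = lower.index("gene")
    ei = lower.index("efficiency") if "efficiency" in lower else None
    si = lower.index("slope") if "slope" in lower else None
    ri = lower.index("r2") if "r2" in lower else None
    if ei is None and si is None:
        raise InputError("efficiency file needs an 'efficiency' or 'slope' column")
    eff: dict[str, float] = {}
    slopes: dict[str, float] = {}
    r2s: dict[str, float] = {}
    for row in rows:
        gene = row[gi]
        if si is not None and si < len(row) and row[si]:
            slope = float(row[si])
            if slope >= 0:
                raise InputError(f"slope for {gene!r} must be negative, got {slope}")
            slopes[gene] = slope
        if ei is not None and ei < len(row) and row[ei]:
            eff[gene] = float(row[ei])
        elif gene in slopes:
            eff[gene] = 10.0 ** (-1.0 / slopes[gene])
        if ri is not None and ri < len(row) and row[ri]:
            r2s[gene] = float(row[ri])
    return EfficiencySet(efficiency_of=eff, slope_of=slopes, r2_of=r2s)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return "" if np.isnan(v) else repr(float(v))


def write_cq_table(table: CqTable, path: str | Path, layout: str = "long",
                   groups_path: str | Path | None = None) -> None:
    """Write a CqTable back to CSV; inverse of :func:`read_cq_table`.

    Floats are written with ``repr`` so a round trip is bit-identical.
    For the wide layout group labels go to `groups_path` when given.
    """
    path = Path(path)
    if layout == "long":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            has_group = table.group_of is not None
            has_subject = table.subject_of is not None
            has_rep = table.replicate_of is not None
            header = ["sample_id"]
            if has_group:
                header.append("group")
            if has_subject:
                header.append("subject_id")
            if has_rep:
                header.append("replicate")
            header += ["gene", "cq"]
            w.writerow(header)
            for j, col in enumerate(table.samples):
                sample = (table.sample_of or {}).get(col, col)
                for i, gene in enumerate(table.genes):
                    row = [sample]
                    if has_group:
                        row.append(table.group_of.get(col, ""))
                    if has_subject:
                        row.append(table.subject_of.get(col, ""))
                    if has_rep:
                        row.append(table.replicate_of.get(col, ""))
                    row += [gene, _fmt(table.cq[i, j])]
                    w.writerow(row)
    elif layout == "wide":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["gene"] + list(table.samples))
            for i, gene in enumerate(table.genes):
                w.writerow([gene] + [_fmt(v) for v in table.cq[i]])
        if groups_path is not None and table.group_of is not None:
            with open(groups_path, "w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow(["sample_id", "group"])
                for s in table.samples:
                    if s in table.group_of:
                        w.writerow([s, table.group_of[s]])
    else:
        raise ConfigError(f"layout must be 'long' or 'wide', got {layout!r}")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def collapse_replicates(table: CqTable, method: str = "mean") -> CqTable:
    """Collapse technical replicates to one Cq per (gene, sample).

    Non-missing replicate Cq are combined by arithmetic mean (default) or
    median; all-missing cells stay missing. A replicate spread above
    0.5 cycles is logged as a QC warning. Collapsing a table without
    replicate labels is the identity.
    """
    if method not in ("mean", "median"):
        raise ConfigError(f"method must be 'mean' or 'median', got {method!r}")
    reducer = np.nanmean if method == "mean" else np.nanmedian

    sample_of = table.sample_of or {s: s for s in table.samples}
    out_samples: list[str] = []
    members: dict[str, list[int]] = {}
    for j, col in enumerate(table.samples):
        base = sample_of.get(col, col)
        if base not in members:
            members[base] = []
            out_samples.append(base)
        members[base].append(j)

    cq = np.full((table.n_genes, len(out_samples)), np.nan)
    for jj, base in enumerate(out_samples):
        cols = members[base]
        block = table.cq[:, cols]
        with np.errstate(invalid="ignore"):
            any_present = ~np.all(np.isnan(block), axis=1)
            if any_present.any():
                cq[any_present, jj] = reducer(block[any_present], axis=1)
            if len(cols) > 1:
                spread = np.nanmax(block[any_present], axis=1) - np.nanmin(block[any_present], axis=1)
                for gi, sp in zip(np.flatnonzero(any_present), spread):
                    if sp > REPLICATE_SPREAD_WARN:
                        logger.warning(
                            "replicate spread %.2f cycles for gene %s sample %s",
                            sp, table.genes[gi], base,
                        )

    def remap(m: dict[str, str] | None) -> dict[str, str] | None:
        if m is None:
            return None
        out: dict[str, str] = {}
        for col, v in m.items():
            base = sample_of.get(col, col)
            out.setdefault(base, v)
        return out

    return CqTable(
        genes=list(table.genes),
        samples=out_samples,
        cq=cq,
        group_of=remap(table.group_of),
        subject_of=remap(table.subject_of),
        sample_of=None,
        replicate_of=None,
    )


def complete_case_subset(table: CqTable, genes: Iterable[str] | None = None) -> CqTable:
    """Restrict to samples with no missing Cq in any of the requested genes.

    Dropped samples are logged by identity. Fewer than 3 surviving samples
    is a hard error (downstream standard deviations degenerate).
    """
    gene_list = list(genes) if genes is not None else list(table.genes)
    rows = [table.gene_index(g) for g in gene_list]
    sub = table.cq[rows, :]
    keep = ~np.isnan(sub).any(axis=0)
    dropped = [s for s, k in zip(table.samples, keep) if not k]
    if dropped:
        logger.info("complete-case subset drops %d sample(s): %s",
                    len(dropped), dropped)
    if int(keep.sum()) < 3:
        raise InputError(
            f"complete-case subset leaves {int(keep.sum())} samples (< 3); "
            f"dropped: {dropped}"
        )
    kept_samples = [s for s, k in zip(table.samples, keep) if k]

    def restrict(m: dict[str, str] | None) -> dict[str, str] | None:
        if m is None:
            return None
        return {s: m[s] for s in kept_samples if s in m}

    return CqTable(
        genes=gene_list,
        samples=kept_samples,
        cq=sub[:, keep].copy(),
        group_of=restrict(table.group_of),
        subject_of=restrict(table.subject_of),
        sample_of=restrict(table.sample_of),
        replicate_of=restrict(table.replicate_of),
    )
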
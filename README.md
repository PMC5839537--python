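# refstab

Reference-gene stability ranking for RT-qPCR quantification-cycle (Cq) data.

Given a genes × samples Cq table with tissue/group labels, `refstab` runs the
three standard candidate-reference-gene stability algorithms and aggregates
them into a consensus panel recommendation:

* **geNorm** — pairwise-variation M values, iterative exclusion ranking, and
  the V(n/n+1) series for choosing the normalization-panel size
  (suggestive cutoff V ≤ 0.15).
* **NormFinder-style variance decomposition** — log2 quantities are centered
  per sample, within-group (intra) variances are estimated with a moment
  correction, group deviations (inter) are shrunken toward zero, and both are
  combined into a per-gene stability score ρ (lower = more stable).
* **BestKeeper** — descriptive statistics on raw Cq (geometric/arithmetic
  mean, min/max, SD, CV), signed x-fold coefficients, the per-sample index
  (geometric mean Cq), and Pearson correlations with p-values. Genes are
  ranked by Cq SD; SD ≥ 1 cycle is flagged as inconsistent.

Also included: comparative-Cq relative quantification with per-gene
amplification efficiencies from standard-curve slopes (E = 10^(−1/slope)),
and a synthetic Cq generator with planted ground truth (shared per-sample
loading, gene-specific noise, group-specific regulation) for end-to-end
recovery testing.

## CLI

Simulate a study-scale dataset (10 genes × 12 tissues × 54 samples) and run
the full pipeline on it:

```bash
refstab simulate --preset paper-like --seed 42 --out sim/
refstab run --cq sim/cq_long.csv --layout long --out results/ --format json
```

`refstab run` options: `--groups` (sidecar CSV for wide layout),
`--efficiencies` (CSV `gene,efficiency` or `gene,slope`), `--base` (uniform
amplification base, default 2), `--algorithms genorm,normfinder,bestkeeper`,
`--per-group` (rerun geNorm within each tissue), `--v-threshold` (default
0.15), `--sd-method sample_sd|mad`, `--format json|tsv|markdown`.
Exit codes: 0 success, 1 input error, 2 configuration error.

Input layouts (CSV or TSV, UTF-8):

* long — columns `sample_id, group, subject_id?, replicate?, gene, cq`;
* wide — header `gene,<sample1>,...` plus a `sample_id,group` sidecar.

Technical replicates are collapsed by arithmetic mean (replicate spread
above 0.5 cycles is logged). geNorm and the variance decomposition run on
the complete-case subset; BestKeeper descriptives use all non-missing
values per gene.

## Python API

```python
import refstab

cfg = refstab.preset_paper_like(seed=42)
table, truth = refstab.simulate_cq(cfg)

q = refstab.relative_quantities(table)          # comparative-Cq quantities
gr = refstab.genorm_rank(q)                     # M values, V series
nf = refstab.normfinder_stability(q)            # intra/inter decomposition
bk = refstab.bestkeeper_analysis(table)         # Cq descriptives + index

consensus = refstab.aggregate_ranks(gr.ranking, nf.rank, bk.ranking)
```

The consensus order is the geometric mean of the three per-algorithm ranks
(ties broken by the geNorm rank) — a package convention providing a total
order, not one of the published algorithms.

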
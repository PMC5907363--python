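# airrprof

Immune receptor repertoire profiling for high-throughput TR beta-chain and
BcR IG heavy-chain sequencing data.

Adaptive immune receptor repertoire (AIRR) studies start from reads that
have already been annotated — typically by IMGT/HighV-QUEST or IgBLAST —
with the rearranged germline V, D and J genes and the CDR3 junction.
`airrprof` takes it from there: it is the *quantification and comparison*
layer for immunogeneticists who need clonotype diversity, gene usage and
cross-sample overlap out of annotated read tables, with every intermediate
result persisted as a plain tab-delimited file.

## What it computes

A **clonotype** is a unique tuple of receptor properties.  Five definitions
are supported, from most to least detailed:

| id        | key tuple                      |
|-----------|--------------------------------|
| `vdjcdr3` | (CDR3-AA, V-gene, D-gene, J-gene) — the IMGT clonotype (AA) with allele information discarded |
| `vjcdr3`  | (CDR3-AA, V-gene, J-gene) — robust to D-assignment ambiguity |
| `vcdr3`   | (CDR3-AA, V-gene)              |
| `jcdr3`   | (CDR3-AA, J-gene)              |
| `cdr3`    | (CDR3-AA,)                     |

CDR3-AA is the amino-acid junction *including* the conserved anchors
(cysteine at IMGT position 104, tryptophan/phenylalanine at 118).

On top of that sit five pipeline stages, each a pure table-in/table-out
operation:

1. **Filtering** — eleven independently switchable criteria: seven quality
   checks (conserved anchors, in-frame junction, productive rearrangement,
   functional V gene, V-region identity ≥ threshold, unambiguous V,
   present and unambiguous J) and four dataset queries (V/J whitelists,
   CDR3 length range, CDR3 motif).  Rejected reads are kept, with the full
   list of reasons.
2. **Clonotype diversity and expression** — reads grouped by the clonotype
   key; for each clonotype the read count *n_c* and relative frequency
   *f_c = 100·n_c / N* (percent of the *N* filtered-in reads), in
   decreasing order; plus the top-10 list and a summary (dominant
   clonotype, totals, expanded clonotypes with ≥ 2 reads, singletons).
3. **Gene usage** — for the V or J subgroup, the fraction of *distinct
   clonotypes* employing each germline gene (each clonotype counts once,
   however expanded).  D-gene usage is not offered: D assignments are too
   frequently ambiguous.
4. **Public / exclusive clonotypes** — across ≥ 2 repertoires (under the
   `cdr3`, `vcdr3` or `jcdr3` definition), the clonotypes present in at
   least two repertoires with their per-repertoire frequencies and
   repertoire count; or, for a pair, the clonotypes of the first absent
   from the second.
5. **Gene usage comparison** — V or J usages of ≥ 2 repertoires side by
   side with the arithmetic mean across all of them (zeros included for
   absent genes).

A seeded synthetic-data generator emits IMGT-dialect tables with known
clonal structure and planted quality failures, so the whole pipeline is
testable without external data.

## Worked example

```python
import io
from airrprof import (ClonotypeDefinition, FilterConfig, SimulationConfig,
                      apply_filters, compute_gene_usage, extract_clonotypes,
                      generate_repertoire, parse_reads, read_summary_report,
                      summarize_repertoire)

sim = generate_repertoire(SimulationConfig(n_reads=2000, n_clonotypes=150, seed=2))
reads = parse_reads(read_summary_report(io.StringIO(sim.table_text())))
passed = apply_filters(reads, FilterConfig.quality()).passed
rep = extract_clonotypes(passed, ClonotypeDefinition.VJ_CDR3)
s = summarize_repertoire(rep)
print(f"V+J+CDR3 repertoire over {rep.total_reads} reads:")
print(f"  dominant clonotype {s.dominant_key} at {s.dominant_freq_pct:.2f}%")
print(f"  expanded (>=2 reads): {s.expanded_clonotypes}, singletons: {s.singletons}")
```

prints (see `examples/02_clonotype_diversity.py`):

```
V+J+CDR3 repertoire over 1660 reads:
  dominant clonotype ('CDDNGLKYF', 'TRBV27', 'TRBJ2-4') at 4.64%
  expanded (>=2 reads): 95, singletons: 45
```

i.e. of the 2000 simulated reads, 1660 survived the quality criteria; the
most expanded clone — the triple of its CDR3 junction, V gene and J gene —
accounts for 4.64 % of them, and 45 of the 140 distinct clonotypes are
supported by a single read.  The `examples/` directory holds one short
script per capability (filtering, diversity, gene usage, repertoire
comparison, simulation).

The same pipeline is available from the shell:

```bash
airrprof simulate --config sim.yaml --out data/
airrprof filter --input data/repertoire_1.tsv --out-prefix run/s1
airrprof clonotypes --input run/s1_filtered_in.tsv --definition vjcdr3 --out-prefix run/s1
airrprof gene-usage --input run/s1_clonotypes.tsv --subgroup V --out-prefix run/s1
airrprof public --inputs run/s1_clonotypes.tsv --inputs run/s2_clonotypes.tsv --out run/public.tsv
```

All inputs and outputs are tab-delimited with a single header row; reading
other annotators' tables is a matter of passing a column map
(`--column-map`, or `column_map=` in `read_summary_report`).

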
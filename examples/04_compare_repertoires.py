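"""Compare repertoires: public clonotypes, exclusive clonotypes, gene usage.

Two repertoires are simulated with five clonotypes deliberately planted in
both.  After filtering and CDR3-clonotype extraction, the public-clonotype
join recovers exactly the planted overlap, the exclusive set is everything
else in the first repertoire, and gene usages are placed side by side with
their mean.
"""

import io

from airrprof import (
    ClonotypeDefinition,
    FilterConfig,
    PlantedClonotype,
    SimulationConfig,
    apply_filters,
    compare_gene_usage,
    compute_gene_usage,
    extract_clonotypes,
    find_exclusive_clonotypes,
    find_public_clonotypes,
    generate_cohort,
    parse_reads,
    read_summary_report,
)

planted = tuple(
    PlantedClonotype(cdr3_aa=f"CASSPUBL{i}QYF", v_gene="TRBV9",
                     j_gene="TRBJ2-3", repertoires=(0, 1),
                     reads_per_repertoire=2)
    for i in range(5)
)
cohort = generate_cohort(
    [SimulationConfig(n_reads=800, n_clonotypes=80, seed=10 + i)
     for i in range(2)],
    planted,
)

reps, usages = [], []
for i, sim in enumerate(cohort.repertoires):
    reads = parse_reads(read_summary_report(io.StringIO(sim.table_text())))
    passed = apply_filters(reads, FilterConfig.quality()).passed
    reps.append(extract_clonotypes(passed, ClonotypeDefinition.CDR3,
                                   label=f"donor{i + 1}"))
    vj = extract_clonotypes(passed, ClonotypeDefinition.VJ_CDR3,
                            label=f"donor{i + 1}")
    usages.append(compute_gene_usage(vj, "V"))

public = find_public_clonotypes(reps)
print(f"public clonotypes (present in both donors): {len(public.rows)}")
for row in public.rows:
    print(f"  {row.key[0]}  freqs {tuple(round(f, 3) for f in row.freq_pct)}% "
          f"in {row.repertoire_count} repertoires")

exclusive = find_exclusive_clonotypes(reps[0], reps[1])
print(f"\nclonotypes exclusive to donor1: {len(exclusive.rows)} "
      f"of {len(reps[0].records)}")

comparison = compare_gene_usage(usages)
print("\nV-gene usage side by side (top 5 by mean):")
for row in comparison.rows[:5]:
    cols = "  ".join(f"{p:6.2f}%" for p in row.usage_pct)
    print(f"  {row.gene:<10s} {cols}  mean {row.mean_usage_pct:6.2f}%")
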
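"""Compute V and J germline-gene usage over distinct clonotypes.

Usage is clonotype-weighted: a clonally expanded clonotype counts once, the
same as a singleton, so the percentages describe the diversity of gene
employment, not read abundance.  D-gene usage is not offered (D assignments
are too often ambiguous).
"""

import io

from airrprof import (
    ClonotypeDefinition,
    FilterConfig,
    SimulationConfig,
    UnsupportedSubgroupError,
    apply_filters,
    compute_gene_usage,
    extract_clonotypes,
    generate_repertoire,
    parse_reads,
    read_summary_report,
    top_genes,
)

sim = generate_repertoire(SimulationConfig(n_reads=1500, n_clonotypes=120, seed=3))
reads = parse_reads(read_summary_report(io.StringIO(sim.table_text())))
passed = apply_filters(reads, FilterConfig.quality()).passed
rep = extract_clonotypes(passed, ClonotypeDefinition.VJ_CDR3)

for subgroup in ("V", "J"):
    usage = compute_gene_usage(rep, subgroup)
    print(f"{subgroup} usage over {usage.total_clonotypes} clonotypes, top 5:")
    for record in top_genes(usage, 5):
        print(f"  {record.gene:<10s} {record.clonotype_count:3d} clonotypes "
              f"({record.usage_pct:.2f}%)")

try:
    compute_gene_usage(rep, "D")
except UnsupportedSubgroupError as exc:
    print(f"\nD usage request -> {exc}")
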
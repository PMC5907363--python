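"""Quantify clonotype diversity and expression under the five definitions.

A clonotype is a unique tuple of receptor properties; the definitions range
from (CDR3-AA, V, D, J) — the IMGT clonotype (AA) without alleles — down to
the CDR3 AA string alone.  Coarser definitions merge groups, so the
clonotype count shrinks monotonically.
"""

import io

from airrprof import (
    ClonotypeDefinition,
    FilterConfig,
    SimulationConfig,
    apply_filters,
    extract_clonotypes,
    generate_repertoire,
    parse_reads,
    read_summary_report,
    summarize_repertoire,
    top_clonotypes,
)

sim = generate_repertoire(SimulationConfig(n_reads=2000, n_clonotypes=150, seed=2))
reads = parse_reads(read_summary_report(io.StringIO(sim.table_text())))
passed = apply_filters(reads, FilterConfig.quality()).passed

for definition in ClonotypeDefinition:
    rep = extract_clonotypes(passed, definition)
    print(f"{definition.id:>8s}: {len(rep.records):4d} distinct clonotypes")

rep = extract_clonotypes(passed, ClonotypeDefinition.VJ_CDR3)
s = summarize_repertoire(rep)
print(f"\nV+J+CDR3 repertoire over {rep.total_reads} reads:")
print(f"  dominant clonotype {s.dominant_key} at {s.dominant_freq_pct:.2f}%")
print(f"  expanded (>=2 reads): {s.expanded_clonotypes}, "
      f"singletons: {s.singletons}")
print("\ntop 5 clonotypes (key, reads, % of repertoire):")
for record in top_clonotypes(rep, 5):
    print(f"  {record.key}  {record.read_count:3d}  {record.rel_freq_pct:.2f}%")
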
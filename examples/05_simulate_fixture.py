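"""Generate a synthetic IMGT-dialect table with ground truth.

The generator emits a tab-delimited Summary-Report-style table (clonal
expansions, IMGT-style gene strings, planted quality failures) together
with the exact clonotype composition and the identity of every corrupted
read — the fixture every other stage is tested against.
"""

from airrprof import SimulationConfig, generate_repertoire

sim = generate_repertoire(SimulationConfig(
    n_reads=50, n_clonotypes=10, seed=4,
    clone_size_distribution="explicit",
    explicit_sizes=(15, 10, 8, 6, 4, 3, 1, 1, 1, 1),
))

print("first rows of the emitted table:")
for line in sim.table_text().splitlines()[:6]:
    print(" ", line)

print("\nground-truth clonotypes (V+D+J+CDR3), planted read counts:")
for key, count in sorted(sim.truth.clonotype_counts["vdjcdr3"].items(),
                         key=lambda kv: -kv[1]):
    print(f"  {key}  x{count}")

print("\nplanted quality failures (read ids per corruption):")
for name, ids in sim.truth.corrupted_read_ids.items():
    if ids:
        print(f"  {name}: {sorted(ids, key=int)}")
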
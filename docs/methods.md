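# Methods

## Input model

The pipeline consumes tab-delimited tables with one row per annotated
receptor read and one header row, in the dialect of the IMGT/HighV-QUEST
Summary Report.  Six fields are used: the AA junction, the V gene and
allele, the V-region identity percentage, the J gene and allele, the D
gene and allele, and the Functionality label.  Any annotation source with
semantically equivalent columns is read through a role→header column map;
matching is exact on the header text after surrounding-whitespace strip,
and case-sensitive (IMGT headers are stable, and silent fuzzy matching
would hide schema drift).  Rows are never dropped at read time — a read
with no V assignment at all is retained and left to the filter stage,
where it fails every V-dependent criterion.  Read identifiers are taken
from an optional id column or synthesized as the 1-based row index.

Gene assignment strings are parsed by IMGT nomenclature structure: an
optional species prefix ("Homsap"), the gene name, an allele designator
from `*` onward, an optional trailing functionality letter (F, P or ORF,
possibly bracketed) and parenthetical notes such as "(see comment)".
Only the bare gene name survives; all candidates of an ambiguous
assignment ("..., or ...") are kept in their stated preference order,
duplicates (same gene, different alleles) collapsing to one.  Downstream
stages use the first-listed (primary) gene; a filter criterion can reject
ambiguous assignments outright.  Parsing is best-effort and never raises:
an unrecognized candidate degrades to its last non-letter token,
deterministically.

## Filtering

Eleven criteria, each independently switchable.  Quality criteria:

1. **anchors** — the junction starts with the conserved cysteine (position
   104) and ends with phenylalanine or tryptophan (position 118);
2. **in-frame** — the Functionality text does not contain an out-of-frame
   marker;
3. **functionality** — the leading whitespace/comma-delimited token of the
   Functionality field, compared case-insensitively, is in the allowed
   set (default `{"productive"}`; "No results" therefore fails);
4. **v-functional** — no candidate V gene carries a pseudogene (P) or ORF
   annotation letter;
5. **v-identity** — V-region identity ≥ threshold, *inclusive*; the
   default 97 % is the conventional clonality threshold and is
   configurable;
6. **ambiguous-v** — exactly one candidate V gene;
7. **missing-or-ambiguous-j** — exactly one candidate J gene.

Query criteria: 8. V-gene whitelist, 9. J-gene whitelist, 10. CDR3 AA
length within a range (anchors counted), 11. CDR3 contains an AA motif.

A read passes iff it satisfies every enabled criterion.  All enabled
criteria are evaluated for every read — no short-circuiting — so rejected
reads carry their complete reason list and the per-reason summary is an
exact tally (a read may appear under several reasons).  Data missing for
an enabled criterion fails that criterion: a blank identity cell fails
v-identity, a blank Functionality fails both frame and productivity
checks.  The reason codes are stable kebab-case identifiers, written
comma-joined in one column of the filtered-out file.

Library defaults leave every criterion off (explicit opt-in);
`FilterConfig.quality()` — and the CLI's defaults — enable the seven
quality criteria.

## Clonotypes, expression, gene usage

Reads are grouped by the key tuple of the chosen definition; the key
leads with the CDR3 (under V + J + CDR3 it is the triple
(CDR3-AA, V-gene, J-gene)).  CDR3 matching is exact, case-sensitive string
equality, anchors included — no Hamming/fuzzy clustering.  An empty D
assignment under the finest definition is a legitimate key value (reads
with no D group together), because IMGT frequently leaves D unassigned; an
empty V or J where the definition requires one is a contract error naming
the read, since such reads should have been filtered.

Records are ordered by decreasing read count with lexicographic key
tie-break, which makes every output file deterministic.  Relative
frequencies are `100·count/total`; percentages are exact internally and
rounded only at serialization (4 decimal places, round-half-even — enough
for an unambiguous round trip at realistic dataset sizes).  A singleton is
a clonotype with exactly one supporting read; expanded means ≥ 2.

Gene usage iterates over *distinct clonotypes*: each clonotype contributes
one count to its V (or J) gene regardless of expansion.  A read-weighted
variant is deliberately not offered.  The repertoire's definition must
contain the requested gene component (J usage from a `vcdr3` repertoire is
an error), and D usage is refused.

## Repertoire comparison

Public and exclusive detection require all inputs to share one of the
`cdr3`, `vcdr3`, `jcdr3` definitions.  Public clonotypes are the outer
join of the repertoires on the key, keeping rows present in ≥ 2 of them,
with each repertoire's frequency (0 when absent — 0 rather than blank, so
the table loads numerically everywhere) and the repertoire count; rows are
ordered by repertoire count, then key.  Exclusive clonotypes are the
anti-join of the first repertoire against the second's key set; since any
key present in a repertoire has count ≥ 1, key membership and a
non-zero-frequency test coincide.  Usage comparison outer-joins on the
gene and appends the arithmetic mean across *all* inputs, zeros included —
the alternative (mean over repertoires where the gene occurs) would not
reduce to the column means of a fully populated table.

All joins are dict-based hash joins, so each comparison is linear in the
total number of keys; the single-input stages are single passes and linear
in the number of rows.

## Synthetic data

The generator emulates the input contract, not the biology: clone
identities are (CDR3, V, D, J) tuples with genes drawn (optionally
weighted) from pools of 20 TRBV / 13 TRBJ / 2 TRBD plausible names, and
CDR3s are random AA strings of 9–20 residues starting with C and ending
with F or W.  The stop character `*` never appears in a junction; random
CDR3s are unique per clonotype (bounded rejection sampling), so planted
clone sizes are recoverable exactly under every definition.  Clone sizes
come from explicit counts, a uniform split, or a rank-geometric decay
(weight (1−p)^rank, default p = 0.05 — a moderately expanded repertoire),
apportioned to the requested read total by largest remainder with at least
one read per clone.

Quality failures are planted per criterion at configurable rates
(defaults: 2 % anchor loss, 5 % out-of-frame, 3 % unproductive, 2 % low
V identity, 3 % ambiguous V, 2 % missing J — a problematic-read fraction
typical of amplicon AIRR-seq after IMGT annotation).  Planted sets are
disjoint by construction, with one unavoidable semantic interaction: an
out-of-frame junction is annotated "unproductive (out-of-frame junction)",
as real annotations are, so those reads fail both the frame and the
productivity criteria.  The ground truth therefore records two things
separately: the planted set per corruption, and the exact read set failing
each criterion.  At generation time the clean-read clonotype map is
re-derived from the emitted table by direct string inspection and compared
against the recorded truth (a hard self-check).

For cohorts, the random clonotypes of different repertoires are kept
CDR3-disjoint via a shared avoid set, and the specified shared clonotypes
are appended uncorrupted to their target repertoires — so the expected
public and exclusive key sets are known exactly.

What passing tests on this generator do **not** show: robustness to
somatic hypermutation, sequencing error at the nucleotide level, UMI
structure, true V(D)J recombination statistics, or real IMGT formatting
quirks beyond the fields consumed.  The generator exercises the pipeline's
contracts, not the annotator's.

## Numerical and scale choices

Percentages are float64 throughout; the normalization invariants
(frequencies and usages summing to 100) hold to 1e-9.  Determinism:
a fixed seed gives byte-identical simulator output (one `random.Random`
stream, no set-iteration order dependence), and fixed inputs give
byte-identical pipeline outputs.

Test problem sizes: the property suite runs on 50 seeded repertoires of
1e2–1e4 reads; the linearity check times filtering, clonotype extraction
and gene usage on 1e4–8e4-row inputs and requires each doubling to stay
within 1.5× the linear extrapolation (best-of-repeats timing to suppress
scheduler noise); the acceptance script uses two 5000-read repertoires.
These sizes keep the full verification loop fast while being large enough
that super-linear behavior or bookkeeping errors would surface.

## Known limitations

- No diversity indices (Shannon, Gini), rarefaction, similarity indices or
  statistical testing of usage differences — out of scope by design.
- Single-chain analysis; no pairing, no nucleotide-level junctions.
- The embedded-tab/newline policy is rejection, not quoting: fields never
  legitimately contain them, and a quoting dialect would break naive
  downstream consumers.
- Annotation itself (CDR3 detection, germline assignment) is upstream of
  this package.
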
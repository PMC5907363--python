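"""Multi-repertoire comparison: public clonotypes, exclusive clonotypes,
and side-by-side gene usage.

A *public* clonotype is one present in at least two of the compared
repertoires; an *exclusive* clonotype of a pair is present in the first
and absent from the second.  Both operations are restricted to the CDR3,
V + CDR3 and J + CDR3 clonotype definitions, where cross-sample key
identity is biologically meaningful.  Joins are hash-based (dict lookups),
so each operation is linear in the total number of keys.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

from .clonotypes import ClonotypeDefinition, ClonotypeRepertoire
from .errors import ContractError, IncompatibleDefinitionError
from .gene_usage import GeneUsageRepertoire
from .imgt import write_table

#: Definitions under which repertoires may be compared.
ELIGIBLE_DEFINITIONS = frozenset(
    {ClonotypeDefinition.CDR3, ClonotypeDefinition.V_CDR3, ClonotypeDefinition.J_CDR3}
)


@dataclass(frozen=True)
class PublicClonotypeRow:
    key: tuple[str, ...]
    freq_pct: tuple[float, ...]  # one per repertoire, 0.0 when absent
    repertoire_count: int


@dataclass(frozen=True)
class PublicClonotypeTable:
    definition: ClonotypeDefinition
    labels: tuple[str, ...]
    rows: tuple[PublicClonotypeRow, ...]

    def keys(self) -> set[tuple[str, ...]]:
        return {r.key for r in self.rows}


@dataclass(frozen=True)
class ExclusiveClonotypeTable:
    definition: ClonotypeDefinition
    label_first: str
    label_second: str
    rows: tuple[tuple[tuple[str, ...], float], ...]  # (key, freq in first)

    def keys(self) -> set[tuple[str, ...]]:
        return {k for k, _ in self.rows}


@dataclass(frozen=True)
class GeneUsageComparisonRow:
    gene: str
    usage_pct: tuple[float, ...]  # one per repertoire, 0.0 when absent
    mean_usage_pct: float


@dataclass(frozen=True)
class GeneUsageComparisonTable:
    subgroup: str
    labels: tuple[str, ...]
    rows: tuple[GeneUsageComparisonRow, ...]


def _labels(
    reps: Sequence[ClonotypeRepertoire | GeneUsageRepertoire],
    labels: Sequence[str] | None,
) -> tuple[str, ...]:
    if labels is not None:
        if len(labels) != len(reps):
            raise ContractError("one label per repertoire is required")
        return tuple(labels)
    return tuple(r.label or f"repertoire-{i + 1}" for i, r in enumerate(reps))


def _check_definitions(reps: Sequence[ClonotypeRepertoire]) -> ClonotypeDefinition:
    definition = reps[0].definition
    if any(r.definition is not definition for r in reps):
        raise IncompatibleDefinitionError(
            "all compared repertoires must share one clonotype definition"
        )
    if definition not in ELIGIBLE_DEFINITIONS:
        raise IncompatibleDefinitionError(
            f"repertoire comparison supports the cdr3, vcdr3 and jcdr3 "
            f"definitions, not {definition.id}"
        )
    return definition


def find_public_clonotypes(
    reps: Sequence[ClonotypeRepertoire],
    labels: Sequence[str] | None = None,
) -> PublicClonotypeTable:
    """Outer-join repertoires on the clonotype key and keep the clonotypes
    present in at least two of them.

    Each row carries the clonotype's relative frequency in every input
    repertoire (0 when absent) and its repertoire count.  Rows are ordered
    by decreasing repertoire count, then lexicographically by key.
    """
    if len(reps) < 2:
        raise ContractError("public clonotype detection needs >= 2 repertoires")
    definition = _check_definitions(reps)
    labs = _labels(reps, labels)
    freq_maps = [r.freq_by_key() for r in reps]
    all_keys: dict[tuple[str, ...], None] = {}
    for fm in freq_maps:
        for k in fm:
            all_keys.setdefault(k)
    rows = []
    for key in all_keys:
        freqs = tuple(fm.get(key, 0.0) for fm in freq_maps)
        count = sum(1 for f in freqs if f > 0.0)
        if count >= 2:
            rows.append(
                PublicClonotypeRow(key=key, freq_pct=freqs, repertoire_count=count)
            )
    rows.sort(key=lambda r: (-r.repertoire_count, r.key))
    return PublicClonotypeTable(definition=definition, labels=labs, rows=tuple(rows))


def find_exclusive_clonotypes(
    rep_first: ClonotypeRepertoire,
    rep_second: ClonotypeRepertoire,
    labels: Sequence[str] | None = None,
) -> ExclusiveClonotypeTable:
    """Clonotypes of the first repertoire that are absent from the second.

    Implemented as an anti-join on the key (a key present in the second
    repertoire always has a non-zero frequency there, so key membership and
    the non-zero-frequency test coincide).  The first repertoire's ordering
    and frequencies are preserved.
    """
    definition = _check_definitions([rep_first, rep_second])
    labs = _labels([rep_first, rep_second], labels)
    second_keys = rep_second.keys()
    rows = tuple(
        (r.key, r.rel_freq_pct)
        for r in rep_first.records
        if r.key not in second_keys
    )
    return ExclusiveClonotypeTable(
        definition=definition, label_first=labs[0], label_second=labs[1], rows=rows
    )


def compare_gene_usage(
    usages: Sequence[GeneUsageRepertoire],
    labels: Sequence[str] | None = None,
) -> GeneUsageComparisonTable:
    """Outer-join gene-usage repertoires on the gene and add the mean usage.

    The mean is the arithmetic mean over *all* input repertoires, counting
    0 for a repertoire in which the gene is unused; rows are ordered by
    decreasing mean, then gene name.
    """
    if len(usages) < 2:
        raise ContractError("gene-usage comparison needs >= 2 repertoires")
    subgroup = usages[0].subgroup
    if any(u.subgroup != subgroup for u in usages):
        raise ContractError("all compared usage repertoires must share one subgroup")
    labs = _labels(usages, labels)
    maps = [u.usage_by_gene() for u in usages]
    all_genes: dict[str, None] = {}
    for m in maps:
        for g in m:
            all_genes.setdefault(g)
    rows = []
    for gene in all_genes:
        pcts = tuple(m.get(gene, 0.0) for m in maps)
        rows.append(
            GeneUsageComparisonRow(
                gene=gene, usage_pct=pcts, mean_usage_pct=sum(pcts) / len(pcts)
            )
        )
    rows.sort(key=lambda r: (-r.mean_usage_pct, r.gene))
    return GeneUsageComparisonTable(subgroup=subgroup, labels=labs, rows=tuple(rows))


# ---------------------------------------------------------------------------
# serialization — one output file per comparison

def write_public_table(sink: str | Path | IO[str], table: PublicClonotypeTable) -> None:
    key_cols = table.definition.key_columns()
    schema = key_cols + tuple(f"freq_pct:{l}" for l in table.labels) + (
        "repertoire_count",
    )
    rows = []
    for r in table.rows:
        row: dict[str, object] = dict(zip(key_cols, r.key))
        for lab, f in zip(table.labels, r.freq_pct):
            row[f"freq_pct:{lab}"] = f
        row["repertoire_count"] = r.repertoire_count
        rows.append(row)
    write_table(sink, schema, rows)


def write_exclusive_table(
    sink: str | Path | IO[str], table: ExclusiveClonotypeTable
) -> None:
    key_cols = table.definition.key_columns()
    schema = key_cols + ("freq_pct",)
    rows = (
        {**dict(zip(key_cols, key)), "freq_pct": freq} for key, freq in table.rows
    )
    write_table(sink, schema, rows)


def write_usage_comparison(
    sink: str | Path | IO[str], table: GeneUsageComparisonTable
) -> None:
    schema = ("GENE",) + tuple(f"usage_pct:{l}" for l in table.labels) + (
        "mean_usage_pct",
    )
    rows = []
    for r in table.rows:
        row: dict[str, object] = {"GENE": r.gene, "mean_usage_pct": r.mean_usage_pct}
        for lab, p in zip(table.labels, r.usage_pct):
            row[f"usage_pct:{lab}"] = p
        rows.append(row)
    write_table(sink, schema, rows)
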
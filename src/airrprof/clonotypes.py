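"""Clonotype diversity and expression.

A clonotype is a unique tuple of receptor properties.  Five definitions are
supported, from the full (V-gene, D-gene, J-gene, CDR3-AA) tuple — the IMGT
clonotype (AA) with allele information discarded — down to the CDR3 AA
string alone.  The key tuple always leads with the CDR3: under V + J + CDR3
a clonotype is the triple (CDR3-AA, V-gene, J-gene).

Filtered-in reads are grouped by the key; group sizes give the clonotype
expression (absolute and relative read frequency), the set of groups gives
the diversity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import ContractError
from .imgt import ParsedRead, read_table, write_table

#: Key component -> output column header.
COMPONENT_COLUMNS = {
    "cdr3_aa": "CDR3",
    "v_gene": "V-GENE",
    "d_gene": "D-GENE",
    "j_gene": "J-GENE",
}


class ClonotypeDefinition(enum.Enum):
    """The five supported clonotype definitions.

    ``components`` is the ordered key layout; CDR3 always present and first.
    """

    VDJ_CDR3 = ("vdjcdr3", ("cdr3_aa", "v_gene", "d_gene", "j_gene"))
    VJ_CDR3 = ("vjcdr3", ("cdr3_aa", "v_gene", "j_gene"))
    V_CDR3 = ("vcdr3", ("cdr3_aa", "v_gene"))
    J_CDR3 = ("jcdr3", ("cdr3_aa", "j_gene"))
    CDR3 = ("cdr3", ("cdr3_aa",))

    def __init__(self, id_: str, components: tuple[str, ...]):
        self.id = id_
        self.components = components

    @classmethod
    def from_id(cls, id_: str) -> "ClonotypeDefinition":
        for d in cls:
            if d.id == id_:
                return d
        raise ContractError(
            f"unknown clonotype definition {id_!r}; "
            f"expected one of {[d.id for d in cls]}"
        )

    def key_columns(self) -> tuple[str, ...]:
        return tuple(COMPONENT_COLUMNS[c] for c in self.components)


@dataclass(frozen=True)
class ClonotypeRecord:
    key: tuple[str, ...]
    read_count: int
    rel_freq_pct: float


@dataclass(frozen=True)
class ClonotypeRepertoire:
    definition: ClonotypeDefinition
    total_reads: int
    records: tuple[ClonotypeRecord, ...]
    label: str = ""

    def keys(self) -> set[tuple[str, ...]]:
        return {r.key for r in self.records}

    def freq_by_key(self) -> dict[tuple[str, ...], float]:
        return {r.key: r.rel_freq_pct for r in self.records}


@dataclass(frozen=True)
class ClonotypeSummary:
    dominant_key: tuple[str, ...]
    dominant_freq_pct: float
    total_clonotypes: int
    expanded_clonotypes: int  # read_count >= 2
    singletons: int  # read_count == 1


def _read_key(read: ParsedRead, definition: ClonotypeDefinition) -> tuple[str, ...]:
    parts: list[str] = []
    for comp in definition.components:
        if comp == "cdr3_aa":
            parts.append(read.cdr3_aa)
        elif comp == "v_gene":
            gene = read.v.primary_gene
            if not gene:
                raise ContractError(
                    f"read {read.read_id!r} has no V gene assignment required by "
                    f"the {definition.id} definition (filter such reads first)"
                )
            parts.append(gene)
        elif comp == "j_gene":
            gene = read.j.primary_gene
            if not gene:
                raise ContractError(
                    f"read {read.read_id!r} has no J gene assignment required by "
                    f"the {definition.id} definition (filter such reads first)"
                )
            parts.append(gene)
        elif comp == "d_gene":
            # IMGT frequently leaves D unassigned; empty D is a legitimate
            # shared key value, not an error.
            parts.append(read.d.primary_gene)
    return tuple(parts)


def extract_clonotypes(
    reads: Iterable[ParsedRead],
    definition: ClonotypeDefinition,
    label: str = "",
) -> ClonotypeRepertoire:
    """Group reads into clonotypes under the given definition.

    Records are ordered by decreasing read count, ties broken
    lexicographically on the key, which makes output deterministic.
    """
    counts: dict[tuple[str, ...], int] = {}
    total = 0
    for read in reads:
        key = _read_key(read, definition)
        counts[key] = counts.get(key, 0) + 1
        total += 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    records = tuple(
        ClonotypeRecord(key=k, read_count=c, rel_freq_pct=100.0 * c / total)
        for k, c in ordered
    )
    return ClonotypeRepertoire(
        definition=definition, total_reads=total, records=records, label=label
    )


def top_clonotypes(
    rep: ClonotypeRepertoire, n: int = 10
) -> tuple[ClonotypeRecord, ...]:
    """The n highest-frequency clonotypes (all of them when fewer exist)."""
    if n < 1:
        raise ContractError("n must be >= 1")
    return rep.records[:n]


def summarize_repertoire(rep: ClonotypeRepertoire) -> ClonotypeSummary:
    """Dominant clonotype, total / expanded / singleton clonotype counts."""
    if not rep.records:
        raise ContractError("cannot summarize an empty repertoire")
    dominant = rep.records[0]
    singles = sum(1 for r in rep.records if r.read_count == 1)
    return ClonotypeSummary(
        dominant_key=dominant.key,
        dominant_freq_pct=dominant.rel_freq_pct,
        total_clonotypes=len(rep.records),
        expanded_clonotypes=len(rep.records) - singles,
        singletons=singles,
    )


# ---------------------------------------------------------------------------
# serialization

def _record_rows(rep: ClonotypeRepertoire, records: Sequence[ClonotypeRecord]):
    cols = rep.definition.key_columns()
    for rec in records:
        row: dict[str, object] = dict(zip(cols, rec.key))
        row["count"] = rec.read_count
        row["freq_pct"] = rec.rel_freq_pct
        yield row


def write_clonotype_repertoire(
    sink: str | Path | IO[str], rep: ClonotypeRepertoire, top_n: int | None = None
) -> None:
    records = rep.records if top_n is None else top_clonotypes(rep, top_n)
    schema = rep.definition.key_columns() + ("count", "freq_pct")
    write_table(sink, schema, _record_rows(rep, records))


def write_clonotype_summary(
    sink: str | Path | IO[str], rep: ClonotypeRepertoire
) -> None:
    s = summarize_repertoire(rep)
    rows = [
        {"key": "definition", "value": rep.definition.id},
        {"key": "total_reads", "value": rep.total_reads},
        {"key": "dominant_clonotype", "value": "|".join(s.dominant_key)},
        {"key": "dominant_freq_pct", "value": s.dominant_freq_pct},
        {"key": "total_clonotypes", "value": s.total_clonotypes},
        {"key": "expanded_clonotypes", "value": s.expanded_clonotypes},
        {"key": "singletons", "value": s.singletons},
    ]
    write_table(sink, ("key", "value"), rows)


def read_clonotype_repertoire(
    source: str | Path | IO[str], label: str = ""
) -> ClonotypeRepertoire:
    """Re-parse a clonotype list file; the definition is inferred from the
    key columns present.  Relative frequencies are recomputed from the
    counts, so the round trip is exact."""
    df = read_table(source)
    cols = list(df.columns)
    for d in ClonotypeDefinition:
        k = len(d.components)
        if cols[:k] == list(d.key_columns()) and cols[k : k + 1] == ["count"]:
            definition = d
            break
    else:
        raise ContractError(
            f"columns {cols} do not match any clonotype definition layout"
        )
    counts = []
    for rec in df.to_dict(orient="records"):
        key = tuple(rec[c] for c in definition.key_columns())
        counts.append((key, int(rec["count"])))
    total = sum(c for _, c in counts)
    records = tuple(
        ClonotypeRecord(key=k, read_count=c,
                        rel_freq_pct=100.0 * c / total if total else 0.0)
        for k, c in counts
    )
    return ClonotypeRepertoire(
        definition=definition, total_reads=total, records=records, label=label
    )
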
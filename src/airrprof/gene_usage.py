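"""Germline V / J gene usage over the distinct clonotypes of a repertoire.

Usage is *clonotype-weighted*: each distinct clonotype contributes exactly
one to its gene's count, regardless of how many reads support it.  A
read-weighted variant is deliberately not offered.  D-gene usage is
unsupported — D assignments are too often ambiguous (nucleotide trimming
and additions at the joins, plus the short length of many D genes) for a
usage tally to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

from .clonotypes import ClonotypeRepertoire
from .errors import (
    ContractError,
    IncompatibleDefinitionError,
    UnsupportedSubgroupError,
)
from .imgt import read_table, write_table

_SUBGROUP_COMPONENT = {"V": "v_gene", "J": "j_gene"}


@dataclass(frozen=True)
class GeneUsageRecord:
    gene: str
    clonotype_count: int
    usage_pct: float


@dataclass(frozen=True)
class GeneUsageRepertoire:
    subgroup: str  # "V" or "J"
    total_clonotypes: int
    records: tuple[GeneUsageRecord, ...]
    label: str = ""

    def usage_by_gene(self) -> dict[str, float]:
        return {r.gene: r.usage_pct for r in self.records}


def compute_gene_usage(rep: ClonotypeRepertoire, subgroup: str) -> GeneUsageRepertoire:
    """Tally each V (or J) gene over the distinct clonotypes of ``rep``.

    The repertoire's clonotype definition must include the requested gene —
    J usage cannot be computed from a V + CDR3 repertoire, for example.
    """
    subgroup = subgroup.upper()
    if subgroup == "D":
        raise UnsupportedSubgroupError("D gene usage is not supported")
    if subgroup not in _SUBGROUP_COMPONENT:
        raise UnsupportedSubgroupError(
            f"unknown gene subgroup {subgroup!r}; expected 'V' or 'J'"
        )
    component = _SUBGROUP_COMPONENT[subgroup]
    if component not in rep.definition.components:
        raise IncompatibleDefinitionError(
            f"{subgroup} gene usage cannot be computed from a repertoire "
            f"extracted under the {rep.definition.id} clonotype definition"
        )
    idx = rep.definition.components.index(component)
    counts: dict[str, int] = {}
    for rec in rep.records:
        gene = rec.key[idx]
        counts[gene] = counts.get(gene, 0) + 1
    total = len(rep.records)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    records = tuple(
        GeneUsageRecord(gene=g, clonotype_count=c,
                        usage_pct=100.0 * c / total if total else 0.0)
        for g, c in ordered
    )
    return GeneUsageRepertoire(
        subgroup=subgroup, total_clonotypes=total, records=records, label=rep.label
    )


def top_genes(usage: GeneUsageRepertoire, n: int = 10) -> tuple[GeneUsageRecord, ...]:
    """The n most used genes (all of them when fewer exist)."""
    if n < 1:
        raise ContractError("n must be >= 1")
    return usage.records[:n]


def summarize_usage(usage: GeneUsageRepertoire) -> tuple[str, float]:
    """The dominant gene of the subgroup and its usage percentage."""
    if not usage.records:
        raise ContractError("cannot summarize an empty gene-usage repertoire")
    top = usage.records[0]
    return top.gene, top.usage_pct


# ---------------------------------------------------------------------------
# serialization

USAGE_SCHEMA = ("GENE", "clonotype_count", "usage_pct")


def write_gene_usage(
    sink: str | Path | IO[str], usage: GeneUsageRepertoire, top_n: int | None = None
) -> None:
    records = usage.records if top_n is None else top_genes(usage, top_n)
    rows = (
        {"GENE": r.gene, "clonotype_count": r.clonotype_count, "usage_pct": r.usage_pct}
        for r in records
    )
    write_table(sink, USAGE_SCHEMA, rows)


def write_usage_summary(sink: str | Path | IO[str], usage: GeneUsageRepertoire) -> None:
    gene, pct = summarize_usage(usage)
    rows = [
        {"key": "subgroup", "value": usage.subgroup},
        {"key": "total_clonotypes", "value": usage.total_clonotypes},
        {"key": "dominant_gene", "value": gene},
        {"key": "dominant_usage_pct", "value": pct},
    ]
    write_table(sink, ("key", "value"), rows)


def read_gene_usage(
    source: str | Path | IO[str], subgroup: str, label: str = ""
) -> GeneUsageRepertoire:
    """Re-parse a gene-usage file; percentages are recomputed from counts."""
    df = read_table(source)
    counts = [(rec["GENE"], int(rec["clonotype_count"]))
              for rec in df.to_dict(orient="records")]
    total = sum(c for _, c in counts)
    records = tuple(
        GeneUsageRecord(gene=g, clonotype_count=c,
                        usage_pct=100.0 * c / total if total else 0.0)
        for g, c in counts
    )
    return GeneUsageRepertoire(
        subgroup=subgroup.upper(), total_clonotypes=total, records=records,
        label=label,
    )
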
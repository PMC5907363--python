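"""Read filtering: immunogenetic quality criteria plus dataset queries.

Eleven criteria are supported, each independently switchable.  Seven are
quality checks — conserved CDR3 anchors (cysteine 104 / phenylalanine or
tryptophan 118), in-frame junction, productive rearrangement, functional
V gene, high V-region identity, unambiguous V assignment, present and
unambiguous J assignment.  Four are queries over the dataset — V gene
whitelist, J gene whitelist, CDR3 AA length range (anchors included) and
CDR3 AA motif containment.

A read passes when it satisfies every *enabled* criterion.  Every enabled
criterion is evaluated for every read, so a rejected read carries the
complete list of reasons, and the per-reason summary counts are exact
tallies (a read may contribute to several reasons).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import ContractError
from .imgt import (
    ParsedRead,
    parse_gene_field,
    read_table,
    write_table,
)

#: Stable machine-readable criterion identifiers, in evaluation order.
CRITERIA: tuple[str, ...] = (
    "anchors",
    "in-frame",
    "functionality",
    "v-functional",
    "v-identity",
    "ambiguous-v",
    "missing-or-ambiguous-j",
    "v-whitelist",
    "j-whitelist",
    "cdr3-length",
    "cdr3-motif",
)

_ANCHOR_END = ("F", "W")
_NONFUNCTIONAL_LETTERS = {"P", "ORF"}


@dataclass(frozen=True)
class FilterConfig:
    """Which criteria are enabled and with what parameters.

    All criteria default to *off*; :meth:`quality` returns a configuration
    with the seven quality criteria enabled at conventional defaults
    (97% minimum V identity, ``{"productive"}`` functionality labels).
    The whitelist / length / motif query criteria are enabled by supplying
    their parameter.
    """

    require_anchors: bool = False
    require_in_frame: bool = False
    require_productive: bool = False
    allowed_functionality_labels: frozenset[str] = frozenset({"productive"})
    require_v_functional: bool = False
    check_v_identity: bool = False
    min_v_identity_pct: float = 97.0
    reject_ambiguous_v: bool = False
    reject_ambiguous_or_missing_j: bool = False
    v_gene_whitelist: frozenset[str] | None = None
    j_gene_whitelist: frozenset[str] | None = None
    cdr3_len_min: int | None = None
    cdr3_len_max: int | None = None
    cdr3_motif: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_v_identity_pct <= 100.0:
            raise ContractError("min_v_identity_pct must lie in [0, 100]")
        if (
            self.cdr3_len_min is not None
            and self.cdr3_len_max is not None
            and self.cdr3_len_min > self.cdr3_len_max
        ):
            raise ContractError("cdr3_len_min exceeds cdr3_len_max")

    @classmethod
    def quality(cls, **overrides) -> "FilterConfig":
        """The seven quality criteria enabled at their defaults."""
        cfg = cls(
            require_anchors=True,
            require_in_frame=True,
            require_productive=True,
            require_v_functional=True,
            check_v_identity=True,
            reject_ambiguous_v=True,
            reject_ambiguous_or_missing_j=True,
        )
        return replace(cfg, **overrides) if overrides else cfg

    def enabled_criteria(self) -> tuple[str, ...]:
        on = {
            "anchors": self.require_anchors,
            "in-frame": self.require_in_frame,
            "functionality": self.require_productive,
            "v-functional": self.require_v_functional,
            "v-identity": self.check_v_identity,
            "ambiguous-v": self.reject_ambiguous_v,
            "missing-or-ambiguous-j": self.reject_ambiguous_or_missing_j,
            "v-whitelist": self.v_gene_whitelist is not None,
            "j-whitelist": self.j_gene_whitelist is not None,
            "cdr3-length": self.cdr3_len_min is not None or self.cdr3_len_max is not None,
            "cdr3-motif": self.cdr3_motif is not None,
        }
        return tuple(c for c in CRITERIA if on[c])


def _functionality_token(text: str) -> str:
    """Leading whitespace/comma-delimited token of the Functionality field."""
    return text.replace(",", " ").split()[0].lower() if text.strip() else ""


def evaluate_criterion(read: ParsedRead, criterion: str, config: FilterConfig) -> bool:
    """Evaluate a single criterion on a read; True means the read passes it.

    Deterministic; data missing for an enabled criterion fails it (e.g. a
    missing V-identity percentage fails the identity criterion).
    """
    if criterion == "anchors":
        j = read.cdr3_aa
        return len(j) >= 2 and j.startswith("C") and j.endswith(_ANCHOR_END)
    if criterion == "in-frame":
        text = read.functionality_raw
        return bool(text.strip()) and "out-of-frame" not in text.lower()
    if criterion == "functionality":
        token = _functionality_token(read.functionality_raw)
        return token in {s.lower() for s in config.allowed_functionality_labels}
    if criterion == "v-functional":
        if not read.v.genes:
            return False
        return not any(
            letter in _NONFUNCTIONAL_LETTERS for letter in read.v.functionality_letters
        )
    if criterion == "v-identity":
        return (
            read.v_identity_pct is not None
            and read.v_identity_pct >= config.min_v_identity_pct
        )
    if criterion == "ambiguous-v":
        return len(read.v.genes) == 1
    if criterion == "missing-or-ambiguous-j":
        return len(read.j.genes) == 1
    if criterion == "v-whitelist":
        wl = config.v_gene_whitelist or frozenset()
        return read.v.primary_gene in wl
    if criterion == "j-whitelist":
        wl = config.j_gene_whitelist or frozenset()
        return read.j.primary_gene in wl
    if criterion == "cdr3-length":
        n = len(read.cdr3_aa)
        lo = config.cdr3_len_min if config.cdr3_len_min is not None else 0
        hi = config.cdr3_len_max if config.cdr3_len_max is not None else float("inf")
        return lo <= n <= hi
    if criterion == "cdr3-motif":
        return (config.cdr3_motif or "") in read.cdr3_aa
    raise ContractError(f"unknown filter criterion {criterion!r}")


@dataclass(frozen=True)
class FilterSummary:
    input_count: int
    passed_count: int
    rejected_count: int
    per_reason: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class FilterOutcome:
    passed: tuple[ParsedRead, ...]
    rejected: tuple[tuple[ParsedRead, tuple[str, ...]], ...]
    summary: FilterSummary


def apply_filters(reads: Iterable[ParsedRead], config: FilterConfig) -> FilterOutcome:
    """Partition reads into filtered-in and filtered-out (with reasons).

    Input order is preserved in both partitions; reason lists are complete
    (no short-circuiting).
    """
    enabled = config.enabled_criteria()
    passed: list[ParsedRead] = []
    rejected: list[tuple[ParsedRead, tuple[str, ...]]] = []
    per_reason = {c: 0 for c in enabled}
    n = 0
    for read in reads:
        n += 1
        reasons = tuple(
            c for c in enabled if not evaluate_criterion(read, c, config)
        )
        if reasons:
            rejected.append((read, reasons))
            for c in reasons:
                per_reason[c] += 1
        else:
            passed.append(read)
    summary = FilterSummary(
        input_count=n,
        passed_count=len(passed),
        rejected_count=len(rejected),
        per_reason=per_reason,
    )
    return FilterOutcome(tuple(passed), tuple(rejected), summary)


# ---------------------------------------------------------------------------
# serialization — three tab-delimited files mirroring the filtering tool

READ_SCHEMA: tuple[str, ...] = (
    "Read ID",
    "AA JUNCTION",
    "V-GENE and allele",
    "V-REGION identity %",
    "J-GENE and allele",
    "D-GENE and allele",
    "Functionality",
    "V-GENE",
    "J-GENE",
    "D-GENE",
)


def _read_row(read: ParsedRead) -> dict[str, object]:
    return {
        "Read ID": read.read_id,
        "AA JUNCTION": read.cdr3_aa,
        "V-GENE and allele": read.v.raw,
        "V-REGION identity %": read.v_identity_pct,
        "J-GENE and allele": read.j.raw,
        "D-GENE and allele": read.d.raw,
        "Functionality": read.functionality_raw,
        "V-GENE": read.v.primary_gene,
        "J-GENE": read.j.primary_gene,
        "D-GENE": read.d.primary_gene,
    }


def write_filtered_reads(
    sink: str | Path | IO[str], reads: Iterable[ParsedRead]
) -> None:
    write_table(sink, READ_SCHEMA, (_read_row(r) for r in reads))


def write_rejected_reads(
    sink: str | Path | IO[str],
    rejected: Iterable[tuple[ParsedRead, Sequence[str]]],
) -> None:
    schema = READ_SCHEMA + ("rejection_reasons",)
    rows = (
        {**_read_row(r), "rejection_reasons": ",".join(reasons)}
        for r, reasons in rejected
    )
    write_table(sink, schema, rows)


def write_filter_summary(sink: str | Path | IO[str], summary: FilterSummary) -> None:
    rows = [
        {"criterion": c, "rejected_count": n} for c, n in summary.per_reason.items()
    ]
    rows += [
        {"criterion": "total-input", "rejected_count": summary.input_count},
        {"criterion": "total-passed", "rejected_count": summary.passed_count},
        {"criterion": "total-rejected", "rejected_count": summary.rejected_count},
    ]
    write_table(sink, ("criterion", "rejected_count"), rows)


def read_filtered_reads(source: str | Path | IO[str]) -> list[ParsedRead]:
    """Re-parse a filtered-in (or filtered-out) reads file."""
    df = read_table(source)
    reads = []
    for rec in df.to_dict(orient="records"):
        ident = rec.get("V-REGION identity %", "")
        reads.append(
            ParsedRead(
                read_id=rec["Read ID"],
                cdr3_aa=rec["AA JUNCTION"],
                v=parse_gene_field(rec["V-GENE and allele"]),
                j=parse_gene_field(rec["J-GENE and allele"]),
                d=parse_gene_field(rec["D-GENE and allele"]),
                v_identity_pct=float(ident) if str(ident).strip() else None,
                functionality_raw=rec["Functionality"],
            )
        )
    return reads
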
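"""Reading and writing the tab-delimited dialects the pipeline speaks.

The primary input is the IMGT/HighV-QUEST *Summary Report*: one header row,
tab-separated, one row per annotated receptor read.  Six fields are consumed
(AA junction, V gene + allele, V-region identity %, J gene + allele,
D gene + allele, Functionality); any annotation source whose columns carry
the same semantics can be read through a column map.

Gene assignment strings follow the IMGT nomenclature style, e.g.::

    Homsap TRBV6-5*01 F
    Homsap IGHV3-23*01 F, or Homsap IGHV3-23D*01 F
    Homsap TRBV24-1*01 (see comment)

:func:`parse_gene_field` reduces such a string to the bare gene names —
species prefix, ``*allele`` designator, trailing functionality letters
(F / P / ORF, possibly bracketed) and parenthetical notes removed — keeping
all candidates of an ambiguous assignment in their stated preference order.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ContractError, FieldParseError, SchemaError

#: Canonical role -> default IMGT Summary Report header.
DEFAULT_COLUMN_MAP: dict[str, str | None] = {
    "aa_junction": "AA JUNCTION",
    "v_gene": "V-GENE and allele",
    "v_identity": "V-REGION identity %",
    "j_gene": "J-GENE and allele",
    "d_gene": "D-GENE and allele",
    "functionality": "Functionality",
}

#: Number of decimal places used when serializing percentages.
PCT_DECIMALS = 4

_FUNCTIONALITY_LETTERS = {"F", "P", "ORF"}

# Parenthetical notes like "(see comment)" are decoration; "(F)"-style
# bracketed functionality letters are kept for the token pass below.
_NOTE_RE = re.compile(r"\((?!(?:F|P|ORF)\))[^)]*\)")


@dataclass(frozen=True)
class AnnotatedRead:
    """One raw row of the Summary Report dialect."""

    read_id: str
    aa_junction: str
    v_gene_allele_raw: str
    v_identity_pct: float | None
    j_gene_allele_raw: str
    d_gene_allele_raw: str
    functionality_raw: str


@dataclass(frozen=True)
class GeneAssignment:
    """A parsed gene field: bare candidate gene names in stated order.

    ``functionality_letters`` keeps, per candidate, the trailing
    F / P / ORF annotation letter when one was present (used by the
    V-gene-functional filter criterion).
    """

    raw: str
    genes: tuple[str, ...]
    functionality_letters: tuple[str, ...] = ()

    @property
    def primary_gene(self) -> str:
        return self.genes[0] if self.genes else ""

    @property
    def is_ambiguous(self) -> bool:
        return len(self.genes) > 1


@dataclass(frozen=True)
class ParsedRead:
    """An annotated read after gene-field parsing.

    ``cdr3_aa`` is the AA junction string verbatim, anchors (the conserved
    cysteine at IMGT position 104 and tryptophan/phenylalanine at 118)
    included.
    """

    read_id: str
    cdr3_aa: str
    v: GeneAssignment
    j: GeneAssignment
    d: GeneAssignment
    v_identity_pct: float | None
    functionality_raw: str


def parse_gene_field(raw: str) -> GeneAssignment:
    """Reduce an IMGT-style gene/allele assignment string to bare gene names.

    Candidates separated by ``", or "`` (or a plain comma) are all kept, in
    order; duplicate bare names collapse to the first occurrence.  An empty
    or blank field yields an empty assignment.  Unrecognized tokens degrade
    to best-effort extraction (the last non-letter token of the candidate):
    parsing never raises.
    """
    raw = raw or ""
    text = _NOTE_RE.sub(" ", raw)
    genes: list[str] = []
    letters: list[str] = []
    for cand in text.split(","):
        cand = cand.strip()
        if cand.lower().startswith("or "):
            cand = cand[3:]
        tokens = cand.split()
        letter = ""
        while tokens and tokens[-1].strip("()[]") in _FUNCTIONALITY_LETTERS:
            letter = tokens.pop().strip("()[]")
        if not tokens:
            continue
        gene = tokens[-1].split("*", 1)[0]
        if not gene:
            continue
        if gene not in genes:
            genes.append(gene)
            letters.append(letter)
    return GeneAssignment(raw=raw, genes=tuple(genes),
                          functionality_letters=tuple(letters))


def read_summary_report(
    source: str | Path | IO[str],
    column_map: Mapping[str, str | None] | None = None,
) -> list[AnnotatedRead]:
    """Read a Summary Report (or equivalent) table into annotated reads.

    Parameters
    ----------
    source
        Path or text stream of a tab-delimited table with one header row.
    column_map
        Role -> source header.  Defaults to the IMGT headers
        (:data:`DEFAULT_COLUMN_MAP`).  The ``d_gene`` role may map to
        ``None`` when the source has no D column.  An optional ``read_id``
        role names an identifier column; otherwise identifiers are the
        1-based row index.

    Rows are returned in file order and never silently dropped; missing
    cells become empty strings (or a missing identity percentage).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]

    for role in ("aa_junction", "v_gene", "v_identity", "j_gene", "functionality"):
        col = cmap.get(role)
        if col is None or col not in df.columns:
            raise SchemaError(
                f"required column {col!r} (role {role!r}) not found; "
                f"available columns: {list(df.columns)}"
            )
    d_col = cmap.get("d_gene")
    if d_col is not None and d_col not in df.columns:
        raise SchemaError(f"mapped D-gene column {d_col!r} not found")
    id_col = cmap.get("read_id")
    if id_col is not None and id_col not in df.columns:
        raise SchemaError(f"mapped read-id column {id_col!r} not found")

    reads: list[AnnotatedRead] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        ident_cell = str(rec[cmap["v_identity"]]).strip()
        if ident_cell == "":
            ident: float | None = None
        else:
            try:
                ident = float(ident_cell)
            except ValueError:
                raise FieldParseError(
                    f"row {i + 1}: V-identity cell {ident_cell!r} is not numeric"
                ) from None
        reads.append(
            AnnotatedRead(
                read_id=str(rec[id_col]).strip() if id_col else str(i + 1),
                aa_junction=str(rec[cmap["aa_junction"]]).strip(),
                v_gene_allele_raw=str(rec[cmap["v_gene"]]).strip(),
                v_identity_pct=ident,
                j_gene_allele_raw=str(rec[cmap["j_gene"]]).strip(),
                d_gene_allele_raw=str(rec[d_col]).strip() if d_col else "",
                functionality_raw=str(rec[cmap["functionality"]]).strip(),
            )
        )
    return reads


def parse_reads(reads: Iterable[AnnotatedRead]) -> list[ParsedRead]:
    """Parse the gene fields of annotated reads."""
    return [
        ParsedRead(
            read_id=r.read_id,
            cdr3_aa=r.aa_junction,
            v=parse_gene_field(r.v_gene_allele_raw),
            j=parse_gene_field(r.j_gene_allele_raw),
            d=parse_gene_field(r.d_gene_allele_raw),
            v_identity_pct=r.v_identity_pct,
            functionality_raw=r.functionality_raw,
        )
        for r in reads
    ]


def format_cell(value: object) -> str:
    """Render one cell for tab-delimited output.

    Floats are written with :data:`PCT_DECIMALS` decimals (round-half-even);
    ``None`` becomes the empty string.  Text containing a tab or newline is
    rejected — the dialect has no quoting and silent escaping would corrupt
    naive downstream consumers.
    """
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return format(value, f".{PCT_DECIMALS}f")
    text = str(value)
    if "\t" in text or "\n" in text or "\r" in text:
        raise ContractError(f"field value contains a tab/newline: {text!r}")
    return text


def write_table(
    sink: str | Path | IO[str],
    schema: Sequence[str],
    rows: Iterable[Mapping[str, object]],
) -> None:
    """Write records as a tab-delimited table with a single header row.

    Every record must supply every schema column (a missing key is a
    contract error).  ``read_table(write_table(x))`` reproduces ``x``
    field for field, up to the documented percentage precision.
    """
    lines = ["\t".join(format_cell(c) for c in schema)]
    for rec in rows:
        cells = []
        for col in schema:
            if col not in rec:
                raise ContractError(f"record is missing schema column {col!r}")
            cells.append(format_cell(rec[col]))
        lines.append("\t".join(cells))
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)  # type: ignore[union-attr]
    else:
        Path(sink).write_text(text)


def read_table(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (all cells as text)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    return df
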
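"""Shared builders for hand-crafted reads and small random repertoires."""

from __future__ import annotations

import random

import pytest

from airrprof import ParsedRead, parse_gene_field


def make_read(
    read_id: str = "r1",
    cdr3: str = "CASSLGTDTQYF",
    v: str = "TRBV6-5",
    j: str = "TRBJ2-3",
    d: str = "TRBD1",
    identity: float | None = 99.0,
    functionality: str = "productive",
    v_raw: str | None = None,
    j_raw: str | None = None,
    d_raw: str | None = None,
) -> ParsedRead:
    """A ParsedRead with IMGT-style raw gene fields built from bare names."""
    if v_raw is None:
        v_raw = f"Homsap {v}*01 F" if v else ""
    if j_raw is None:
        j_raw = f"Homsap {j}*01 F" if j else ""
    if d_raw is None:
        d_raw = f"Homsap {d}*01 F" if d else ""
    return ParsedRead(
        read_id=read_id,
        cdr3_aa=cdr3,
        v=parse_gene_field(v_raw),
        j=parse_gene_field(j_raw),
        d=parse_gene_field(d_raw),
        v_identity_pct=identity,
        functionality_raw=functionality,
    )


AA = "ACDEFGHIKLMNPQRSTVWY"


def random_reads(rng: random.Random, n: int, n_cdr3: int = 20,
                 n_v: int = 6, n_j: int = 4) -> list[ParsedRead]:
    """Well-formed reads drawn from small pools (collisions intended)."""
    cdr3s = []
    while len(cdr3s) < n_cdr3:
        s = "C" + "".join(rng.choice(AA) for _ in range(rng.randint(6, 12))) \
            + rng.choice("FW")
        if s not in cdr3s:
            cdr3s.append(s)
    vs = [f"TRBV{i + 2}-1" for i in range(n_v)]
    js = [f"TRBJ1-{i + 1}" for i in range(n_j)]
    ds = ["TRBD1", "TRBD2", ""]
    return [
        make_read(
            read_id=str(i + 1),
            cdr3=rng.choice(cdr3s),
            v=rng.choice(vs),
            j=rng.choice(js),
            d=rng.choice(ds),
            identity=round(rng.uniform(97.0, 100.0), 2),
        )
        for i in range(n)
    ]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
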
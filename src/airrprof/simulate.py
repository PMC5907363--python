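"""Synthetic IMGT-dialect repertoires with known ground truth.

The generator emulates the Summary Report contract consumed by the
pipeline: clonal expansions with a configurable clone-size distribution,
IMGT-style gene/allele strings ("Homsap TRBV6-5*01 F"), CDR3 AA junctions
carrying the conserved anchors, and controllable rates of planted
quality-criterion failures.  It does *not* model V(D)J recombination,
somatic hypermutation or nucleotide-level sequencing error — it produces
tables that are structurally, not biologically, realistic.

Every quantity the pipeline later computes (clonotype maps per definition,
gene usage over distinct clonotypes, the reads failing each filter
criterion) is recorded in :class:`GroundTruth`, re-derived from the emitted
table by brute force at generation time as a self-check.

One planted failure mode interacts by necessity: an out-of-frame junction
is annotated "unproductive (out-of-frame junction)" — as real annotations
are — so those reads fail both the in-frame and the productivity criteria.
``GroundTruth.failing_read_ids`` records, per criterion, the exact read set
failing it; ``corrupted_read_ids`` records the planted sets, which are
pairwise disjoint.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigError
from .clonotypes import ClonotypeDefinition

#: Plausible human TR beta germline gene names (cosmetic — the pipeline's
#: semantics live in the structure of the strings, not the names).
DEFAULT_V_POOL: tuple[str, ...] = (
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV6-5",
    "TRBV7-2", "TRBV7-9", "TRBV9", "TRBV10-3", "TRBV11-2", "TRBV12-3",
    "TRBV13", "TRBV14", "TRBV15", "TRBV18", "TRBV19", "TRBV20-1",
    "TRBV24-1", "TRBV27",
)
DEFAULT_J_POOL: tuple[str, ...] = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
)
DEFAULT_D_POOL: tuple[str, ...] = ("TRBD1", "TRBD2")

# Random CDR3 interiors exclude the stop '*' — stops appear only through
# the planted unproductive/out-of-frame Functionality labels.
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Planted corruption name -> filter criterion reason-code it violates.
CORRUPTION_CRITERIA = {
    "anchor_loss": "anchors",
    "out_of_frame": "in-frame",
    "unproductive": "functionality",
    "low_identity": "v-identity",
    "ambiguous_v": "ambiguous-v",
    "missing_j": "missing-or-ambiguous-j",
}

IMGT_COLUMNS = (
    "AA JUNCTION",
    "V-GENE and allele",
    "V-REGION identity %",
    "J-GENE and allele",
    "D-GENE and allele",
    "Functionality",
)

_MAX_CDR3_RETRIES = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated repertoire.

    Defaults emulate a moderately expanded TR beta repertoire annotated by
    IMGT/HighV-QUEST: geometric clone-size decay, junction lengths of 9–20
    AA (anchors included), and a few percent of reads failing each quality
    criterion, in line with the problematic-read fraction typical of
    amplicon AIRR-seq runs.
    """

    n_reads: int = 1000
    n_clonotypes: int = 100
    clone_size_distribution: str = "geometric"  # uniform | geometric | explicit
    geometric_p: float = 0.05
    explicit_sizes: tuple[int, ...] | None = None
    v_pool: tuple[str, ...] = DEFAULT_V_POOL
    j_pool: tuple[str, ...] = DEFAULT_J_POOL
    d_pool: tuple[str, ...] = DEFAULT_D_POOL
    v_weights: tuple[float, ...] | None = None
    j_weights: tuple[float, ...] | None = None
    d_weights: tuple[float, ...] | None = None
    cdr3_length_range: tuple[int, int] = (9, 20)
    anchor_loss_rate: float = 0.02
    out_of_frame_rate: float = 0.05
    unproductive_rate: float = 0.03
    low_identity_rate: float = 0.02
    ambiguous_v_rate: float = 0.03
    missing_j_rate: float = 0.02
    identity_threshold_pct: float = 97.0
    seed: int = 0

    def corruption_rates(self) -> dict[str, float]:
        return {
            "anchor_loss": self.anchor_loss_rate,
            "out_of_frame": self.out_of_frame_rate,
            "unproductive": self.unproductive_rate,
            "low_identity": self.low_identity_rate,
            "ambiguous_v": self.ambiguous_v_rate,
            "missing_j": self.missing_j_rate,
        }

    def validate(self) -> None:
        if self.n_reads < 1 or self.n_clonotypes < 1:
            raise ConfigError("n_reads and n_clonotypes must be positive")
        if self.n_clonotypes > self.n_reads:
            raise ConfigError("n_clonotypes cannot exceed n_reads")
        if not self.v_pool or not self.j_pool or not self.d_pool:
            raise ConfigError("gene pools must be non-empty")
        rates = self.corruption_rates()
        if any(not 0.0 <= r <= 1.0 for r in rates.values()):
            raise ConfigError("corruption rates must lie in [0, 1]")
        if sum(rates.values()) > 1.0:
            raise ConfigError("corruption rates must sum to at most 1")
        lo, hi = self.cdr3_length_range
        if lo < 3 or hi < lo:
            raise ConfigError("cdr3_length_range must satisfy 3 <= lo <= hi")
        if self.clone_size_distribution == "explicit":
            if self.explicit_sizes is None:
                raise ConfigError("explicit distribution needs explicit_sizes")
            if len(self.explicit_sizes) != self.n_clonotypes:
                raise ConfigError("one explicit size per clonotype is required")
            if any(s < 1 for s in self.explicit_sizes):
                raise ConfigError("explicit clone sizes must be positive")
            if sum(self.explicit_sizes) != self.n_reads:
                raise ConfigError("explicit clone sizes must sum to n_reads")
        elif self.clone_size_distribution == "geometric":
            if not 0.0 < self.geometric_p < 1.0:
                raise ConfigError("geometric_p must lie in (0, 1)")
        elif self.clone_size_distribution != "uniform":
            raise ConfigError(
                f"unknown clone-size distribution {self.clone_size_distribution!r}"
            )
        # crude key-space bound for the CDR3 uniqueness requirement
        space = sum(
            len(_AA_ALPHABET) ** max(n - 2, 0) * 2
            for n in range(lo, hi + 1)
        )
        if self.n_clonotypes > space:
            raise ConfigError("n_clonotypes exceeds the distinct CDR3 key space")


@dataclass(frozen=True)
class PlantedClonotype:
    """A clonotype planted into specific repertoires of a cohort."""

    cdr3_aa: str
    v_gene: str
    j_gene: str
    d_gene: str = ""
    repertoires: tuple[int, ...] = (0, 1)
    reads_per_repertoire: int = 1

    def key(self, definition: ClonotypeDefinition) -> tuple[str, ...]:
        values = {
            "cdr3_aa": self.cdr3_aa,
            "v_gene": self.v_gene,
            "j_gene": self.j_gene,
            "d_gene": self.d_gene,
        }
        return tuple(values[c] for c in definition.components)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the pipeline should later recover from the table."""

    #: definition id -> clonotype key -> read count, over uncorrupted reads
    clonotype_counts: dict[str, dict[tuple[str, ...], int]]
    #: (definition id, subgroup) -> gene -> distinct-clonotype count
    gene_usage: dict[tuple[str, str], dict[str, int]]
    #: planted corruption name -> read ids (pairwise disjoint sets)
    corrupted_read_ids: dict[str, frozenset[str]]
    #: criterion reason-code -> read ids that fail it
    failing_read_ids: dict[str, frozenset[str]]
    clean_read_ids: frozenset[str]
    #: full (cdr3, v, d, j) identity and total read count of every clone
    clones: tuple[tuple[tuple[str, str, str, str], int], ...]


@dataclass(frozen=True)
class SimulatedRepertoire:
    table: pd.DataFrame  # IMGT Summary Report dialect
    truth: GroundTruth
    config: SimulationConfig

    def table_text(self) -> str:
        return self.table.to_csv(sep="\t", index=False)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.table_text())


def _weighted_choice(rng: random.Random, pool: Sequence[str],
                     weights: Sequence[float] | None) -> str:
    if weights is None:
        return pool[rng.randrange(len(pool))]
    return rng.choices(pool, weights=weights, k=1)[0]


def _random_cdr3(rng: random.Random, lo: int, hi: int) -> str:
    n = rng.randint(lo, hi)
    interior = "".join(rng.choice(_AA_ALPHABET) for _ in range(n - 2))
    return "C" + interior + rng.choice("FW")


def _apportion(n_reads: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n_reads over weights, >= 1 each."""
    k = len(weights)
    sizes = [1] * k
    remaining = n_reads - k
    total_w = sum(weights)
    quotas = [remaining * w / total_w for w in weights]
    floors = [int(q) for q in quotas]
    left = remaining - sum(floors)
    order = sorted(range(k), key=lambda i: (-(quotas[i] - floors[i]), i))
    for i in range(k):
        sizes[i] += floors[i]
    for i in order[:left]:
        sizes[i] += 1
    return sizes


def _clone_sizes(config: SimulationConfig) -> list[int]:
    if config.clone_size_distribution == "explicit":
        return list(config.explicit_sizes)  # type: ignore[arg-type]
    if config.clone_size_distribution == "uniform":
        weights = [1.0] * config.n_clonotypes
    else:  # geometric rank-decay
        q = 1.0 - config.geometric_p
        weights = [q**i for i in range(config.n_clonotypes)]
    return _apportion(config.n_reads, weights)


def generate_repertoire(
    config: SimulationConfig,
    _avoid_cdr3: set[str] | None = None,
    _planted: Sequence[tuple[tuple[str, str, str, str], int]] = (),
) -> SimulatedRepertoire:
    """Generate one annotated-read table plus its ground truth.

    Deterministic given ``config.seed`` (byte-identical output on repeated
    calls).  ``_avoid_cdr3`` and ``_planted`` are the cohort hooks: CDR3s in
    the avoid set are never drawn (bounded rejection sampling), and planted
    clones are appended with the stated read counts, uncorrupted.
    """
    config.validate()
    rng = random.Random(config.seed)
    lo, hi = config.cdr3_length_range
    avoid = set(_avoid_cdr3 or ())

    # clone identities, CDR3-unique within the repertoire and the avoid set
    clones: list[tuple[str, str, str, str]] = []
    seen: set[str] = set(avoid)
    for _ in range(config.n_clonotypes):
        for _attempt in range(_MAX_CDR3_RETRIES):
            cdr3 = _random_cdr3(rng, lo, hi)
            if cdr3 not in seen:
                break
        else:
            raise ConfigError(
                "could not draw a fresh CDR3 after "
                f"{_MAX_CDR3_RETRIES} attempts; key space too small"
            )
        seen.add(cdr3)
        clones.append(
            (
                cdr3,
                _weighted_choice(rng, config.v_pool, config.v_weights),
                _weighted_choice(rng, config.d_pool, config.d_weights),
                _weighted_choice(rng, config.j_pool, config.j_weights),
            )
        )
    sizes = _clone_sizes(config)
    clones_with_sizes = list(zip(clones, sizes)) + list(_planted)

    # expand to reads and shuffle
    read_clone: list[int] = []
    for ci, (_, size) in enumerate(clones_with_sizes):
        read_clone.extend([ci] * size)
    rng.shuffle(read_clone)
    n = len(read_clone)
    n_random = config.n_reads  # planted reads are never corrupted

    # disjoint corruption assignments over the random (non-planted) reads
    random_positions = [i for i in range(n) if read_clone[i] < config.n_clonotypes]
    rng.shuffle(random_positions)
    corruption_at: dict[int, str] = {}
    corrupted_ids: dict[str, set[str]] = {name: set() for name in CORRUPTION_CRITERIA}
    cursor = 0
    for name, rate in config.corruption_rates().items():
        count = round(rate * n_random)
        for pos in random_positions[cursor : cursor + count]:
            corruption_at[pos] = name
            corrupted_ids[name].add(str(pos + 1))
        cursor += count

    # render rows
    rows = []
    for pos in range(n):
        cdr3, v, d, j = clones_with_sizes[read_clone[pos]][0]
        corruption = corruption_at.get(pos)
        junction = cdr3
        v_str = f"Homsap {v}*0{rng.randint(1, 3)} F"
        j_str = f"Homsap {j}*01 F"
        d_str = f"Homsap {d}*01 F" if d else ""
        identity = round(rng.uniform(config.identity_threshold_pct, 100.0), 2)
        functionality = "productive"
        if corruption == "anchor_loss":
            junction = "G" + cdr3[1:]
        elif corruption == "out_of_frame":
            functionality = "unproductive (out-of-frame junction)"
        elif corruption == "unproductive":
            functionality = "unproductive (see comment)"
        elif corruption == "low_identity":
            hi_id = max(config.identity_threshold_pct - 0.1, 0.0)
            identity = round(rng.uniform(max(hi_id - 17.0, 0.0), hi_id), 2)
        elif corruption == "ambiguous_v":
            alternatives = [g for g in config.v_pool if g != v] or [v + "D"]
            v2 = alternatives[rng.randrange(len(alternatives))]
            v_str = f"Homsap {v}*01 F, or Homsap {v2}*01 F"
        elif corruption == "missing_j":
            j_str = ""
        rows.append(
            {
                "AA JUNCTION": junction,
                "V-GENE and allele": v_str,
                "V-REGION identity %": f"{identity:.2f}",
                "J-GENE and allele": j_str,
                "D-GENE and allele": d_str,
                "Functionality": functionality,
            }
        )
    table = pd.DataFrame(rows, columns=list(IMGT_COLUMNS))

    # ground truth over uncorrupted reads
    clean_ids = frozenset(
        str(pos + 1) for pos in range(n) if pos not in corruption_at
    )
    clean_key_counts: dict[tuple[str, str, str, str], int] = {}
    for pos in range(n):
        if pos in corruption_at:
            continue
        identity_tuple = clones_with_sizes[read_clone[pos]][0]
        clean_key_counts[identity_tuple] = clean_key_counts.get(identity_tuple, 0) + 1

    clonotype_counts: dict[str, dict[tuple[str, ...], int]] = {}
    comp_index = {"cdr3_aa": 0, "v_gene": 1, "d_gene": 2, "j_gene": 3}
    for definition in ClonotypeDefinition:
        agg: dict[tuple[str, ...], int] = {}
        for full_key, count in clean_key_counts.items():
            key = tuple(full_key[comp_index[c]] for c in definition.components)
            agg[key] = agg.get(key, 0) + count
        clonotype_counts[definition.id] = agg

    gene_usage: dict[tuple[str, str], dict[str, int]] = {}
    for definition in ClonotypeDefinition:
        for subgroup, comp in (("V", "v_gene"), ("J", "j_gene")):
            if comp not in definition.components:
                continue
            idx = definition.components.index(comp)
            tally: dict[str, int] = {}
            for key in clonotype_counts[definition.id]:
                tally[key[idx]] = tally.get(key[idx], 0) + 1
            gene_usage[(definition.id, subgroup)] = tally

    failing: dict[str, frozenset[str]] = {
        CORRUPTION_CRITERIA[name]: frozenset(ids)
        for name, ids in corrupted_ids.items()
    }
    # out-of-frame junctions are annotated unproductive, so they also fail
    # the productivity criterion
    failing["functionality"] = failing["functionality"] | frozenset(
        corrupted_ids["out_of_frame"]
    )

    truth = GroundTruth(
        clonotype_counts=clonotype_counts,
        gene_usage=gene_usage,
        corrupted_read_ids={k: frozenset(v) for k, v in corrupted_ids.items()},
        failing_read_ids=failing,
        clean_read_ids=clean_ids,
        clones=tuple(clones_with_sizes),
    )
    result = SimulatedRepertoire(table=table, truth=truth, config=config)
    _audit(result)
    return result


def _audit(sim: SimulatedRepertoire) -> None:
    """Re-derive the clean clonotype map from the emitted table by direct
    string inspection and compare with the recorded ground truth."""
    corrupted = set().union(*sim.truth.corrupted_read_ids.values())
    recounted: dict[tuple[str, ...], int] = {}
    for i, row in enumerate(sim.table.itertuples(index=False)):
        read_id = str(i + 1)
        if read_id in corrupted:
            continue
        junction, v_raw, _ident, j_raw, d_raw, _fn = row
        v = v_raw.split()[1].split("*")[0] if v_raw else ""
        j = j_raw.split()[1].split("*")[0] if j_raw else ""
        d = d_raw.split()[1].split("*")[0] if d_raw else ""
        key = (junction, v, d, j)
        recounted[key] = recounted.get(key, 0) + 1
    if recounted != sim.truth.clonotype_counts[ClonotypeDefinition.VDJ_CDR3.id]:
        raise ConfigError("generator self-check failed: table does not match truth")


@dataclass(frozen=True)
class SimulatedCohort:
    repertoires: tuple[SimulatedRepertoire, ...]
    planted: tuple[PlantedClonotype, ...]

    def expected_public_keys(
        self, definition: ClonotypeDefinition
    ) -> dict[tuple[str, ...], int]:
        """Planted key -> expected repertoire count (only plants in >= 2)."""
        out: dict[tuple[str, ...], int] = {}
        for p in self.planted:
            if len(p.repertoires) >= 2:
                out[p.key(definition)] = len(p.repertoires)
        return out


def generate_cohort(
    configs: Sequence[SimulationConfig],
    planted: Sequence[PlantedClonotype] = (),
) -> SimulatedCohort:
    """Generate >= 2 repertoires whose random clonotypes are pairwise
    CDR3-disjoint, with the given clonotypes planted into specific
    repertoires.  Planted reads are appended uncorrupted, so public and
    exclusive key sets are known exactly by construction."""
    if len(configs) < 2:
        raise ConfigError("a cohort needs at least 2 repertoire configs")
    planted_cdr3 = {p.cdr3_aa for p in planted}
    if len(planted_cdr3) != len(planted):
        raise ConfigError("planted clonotypes must have distinct CDR3s")
    for p in planted:
        if any(i < 0 or i >= len(configs) for i in p.repertoires):
            raise ConfigError("planted repertoire index out of range")
        if p.reads_per_repertoire < 1:
            raise ConfigError("planted clones need >= 1 read per repertoire")
    avoid: set[str] = set(planted_cdr3)
    reps: list[SimulatedRepertoire] = []
    for ri, config in enumerate(configs):
        plants = [
            ((p.cdr3_aa, p.v_gene, p.d_gene, p.j_gene), p.reads_per_repertoire)
            for p in planted
            if ri in p.repertoires
        ]
        sim = generate_repertoire(config, _avoid_cdr3=avoid, _planted=plants)
        # keep later repertoires' random CDR3s disjoint from this one's
        for (cdr3, _v, _d, _j), _size in sim.truth.clones:
            avoid.add(cdr3)
        reps.append(sim)
    return SimulatedCohort(repertoires=tuple(reps), planted=tuple(planted))


# ---------------------------------------------------------------------------
# ground-truth sidecar serialization (for the simulate CLI command)

def write_ground_truth(prefix: str | Path, truth: GroundTruth) -> list[Path]:
    from .imgt import write_table

    prefix = Path(prefix)
    written = []
    for definition in ClonotypeDefinition:
        path = prefix.parent / f"{prefix.name}_truth_clonotypes_{definition.id}.tsv"
        cols = definition.key_columns()
        rows = [
            {**dict(zip(cols, key)), "count": count}
            for key, count in sorted(
                truth.clonotype_counts[definition.id].items(),
                key=lambda kv: (-kv[1], kv[0]),
            )
        ]
        write_table(path, cols + ("count",), rows)
        written.append(path)
    path = prefix.parent / f"{prefix.name}_truth_corrupted.tsv"
    rows = [
        {"criterion": CORRUPTION_CRITERIA[name], "read_id": rid}
        for name, ids in truth.corrupted_read_ids.items()
        for rid in sorted(ids, key=int)
    ]
    write_table(path, ("criterion", "read_id"), rows)
    written.append(path)
    return written
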
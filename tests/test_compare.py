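"""Public / exclusive clonotypes and gene-usage comparison vs naive oracles."""

import random

import pytest

from airrprof import (
    ClonotypeDefinition,
    ContractError,
    IncompatibleDefinitionError,
    compare_gene_usage,
    compute_gene_usage,
    extract_clonotypes,
    find_exclusive_clonotypes,
    find_public_clonotypes,
)
from airrprof.compare import (
    write_exclusive_table,
    write_public_table,
    write_usage_comparison,
)
from airrprof.imgt import read_table

from conftest import AA, make_read


def _rep_from_cdr3s(cdr3s, definition=ClonotypeDefinition.CDR3, label=""):
    reads = [make_read(read_id=str(i), cdr3=c) for i, c in enumerate(cdr3s)]
    return extract_clonotypes(reads, definition, label=label)


def _random_rep(rng, n_keys, label):
    pool = ["C" + "".join(rng.choice(AA) for _ in range(6)) + "F"
            for _ in range(n_keys * 2)]
    cdr3s = [rng.choice(pool) for _ in range(n_keys * 3)]
    return _rep_from_cdr3s(cdr3s, label=label)


class TestPublicClonotypes:
    def test_shared_key_found_with_both_frequencies(self):
        rep1 = _rep_from_cdr3s(["CAAF", "CBBF"], label="r1")
        rep2 = _rep_from_cdr3s(["CBBF", "CCCF"], label="r2")
        table = find_public_clonotypes([rep1, rep2])
        assert [r.key for r in table.rows] == [("CBBF",)]
        row = table.rows[0]
        assert row.freq_pct == (50.0, 50.0)
        assert row.repertoire_count == 2

    def test_disjoint_repertoires_give_empty_table(self):
        table = find_public_clonotypes(
            [_rep_from_cdr3s(["CAAF"]), _rep_from_cdr3s(["CBBF"])])
        assert table.rows == ()

    def test_repertoire_count_matches_brute_force_membership(self, rng):
        reps = [_random_rep(rng, 30, f"r{i}") for i in range(3)]
        table = find_public_clonotypes(reps)
        all_keys = set().union(*(r.keys() for r in reps))
        for key in all_keys:
            count = sum(1 for r in reps if key in r.keys())
            if count >= 2:
                (row,) = [r for r in table.rows if r.key == key]
                assert row.repertoire_count == count
            else:
                assert key not in table.keys()

    def test_key_set_invariant_under_permutation(self, rng):
        reps = [_random_rep(rng, 25, f"r{i}") for i in range(3)]
        keys1 = find_public_clonotypes(reps).keys()
        keys2 = find_public_clonotypes(reps[::-1]).keys()
        assert keys1 == keys2

    def test_arity_and_definition_errors(self):
        rep = _rep_from_cdr3s(["CAAF"])
        with pytest.raises(ContractError):
            find_public_clonotypes([rep])
        vj = extract_clonotypes([make_read()], ClonotypeDefinition.VJ_CDR3)
        with pytest.raises(IncompatibleDefinitionError):
            find_public_clonotypes([vj, vj])
        vcdr3 = extract_clonotypes([make_read()], ClonotypeDefinition.V_CDR3)
        with pytest.raises(IncompatibleDefinitionError):
            find_public_clonotypes([rep, vcdr3])


class TestExclusiveClonotypes:
    def test_set_difference_semantics(self):
        rep1 = _rep_from_cdr3s(["CAAF", "CBBF"])
        rep2 = _rep_from_cdr3s(["CBBF", "CCCF"])
        table = find_exclusive_clonotypes(rep1, rep2)
        assert [k for k, _ in table.rows] == [("CAAF",)]

    def test_self_comparison_is_empty(self, rng):
        rep = _random_rep(rng, 20, "r")
        assert find_exclusive_clonotypes(rep, rep).rows == ()

    def test_against_empty_second_returns_all_of_first(self):
        rep = _rep_from_cdr3s(["CAAF", "CBBF"])
        empty = extract_clonotypes([], ClonotypeDefinition.CDR3)
        table = find_exclusive_clonotypes(rep, empty)
        assert table.keys() == rep.keys()

    def test_partition_identity(self, rng):
        rep_a = _random_rep(rng, 40, "a")
        rep_b = _random_rep(rng, 40, "b")
        excl = find_exclusive_clonotypes(rep_a, rep_b).keys()
        shared = rep_a.keys() & rep_b.keys()
        assert excl | shared == rep_a.keys()
        assert excl & shared == set()

    def test_first_repertoire_order_and_freqs_preserved(self, rng):
        rep_a = _random_rep(rng, 15, "a")
        rep_b = _random_rep(rng, 15, "b")
        table = find_exclusive_clonotypes(rep_a, rep_b)
        expected = [(r.key, r.rel_freq_pct) for r in rep_a.records
                    if r.key not in rep_b.keys()]
        assert list(table.rows) == expected


class TestCompareGeneUsage:
    def _usage(self, gene_counts, label):
        reads = []
        i = 0
        for gene, n in gene_counts.items():
            for k in range(n):
                reads.append(make_read(read_id=str(i), v=gene,
                                       cdr3=f"C{label}{i}AF"))
                i += 1
        rep = extract_clonotypes(reads, ClonotypeDefinition.V_CDR3, label=label)
        return compute_gene_usage(rep, "V")

    def test_identical_tables_mean_equals_each_column(self):
        u = self._usage({"TRBV9": 2, "TRBV2": 2}, "x")
        table = compare_gene_usage([u, u], labels=["a", "b"])
        for row in table.rows:
            assert row.mean_usage_pct == row.usage_pct[0] == row.usage_pct[1]

    def test_mean_includes_zero_for_absent_genes(self):
        # a gene at 10% in 1 of 4 repertoires has mean 2.5%
        u1 = self._usage({"TRBV20-1": 1, **{f"TRBV{i}": 1 for i in range(2, 11)}},
                         "a")
        assert u1.usage_by_gene()["TRBV20-1"] == pytest.approx(10.0)
        other = self._usage({f"TRBV{i}": 1 for i in range(2, 11)}, "b")
        table = compare_gene_usage([u1, other, other, other])
        (row,) = [r for r in table.rows if r.gene == "TRBV20-1"]
        assert row.usage_pct[1:] == (0.0, 0.0, 0.0)
        assert row.mean_usage_pct == pytest.approx(2.5)

    def test_union_of_genes_and_mean_match_brute_force(self, rng):
        usages = []
        for label in "abc":
            genes = {f"TRBV{rng.randint(2, 12)}": rng.randint(1, 4)
                     for _ in range(5)}
            usages.append(self._usage(genes, label))
        table = compare_gene_usage(usages)
        union = set().union(*(set(u.usage_by_gene()) for u in usages))
        assert {r.gene for r in table.rows} == union
        for row in table.rows:
            vals = [u.usage_by_gene().get(row.gene, 0.0) for u in usages]
            assert row.mean_usage_pct == pytest.approx(sum(vals) / 3, abs=1e-9)

    def test_mixed_subgroups_rejected(self):
        u = self._usage({"TRBV9": 1}, "a")
        reads = [make_read(read_id="0")]
        rep = extract_clonotypes(reads, ClonotypeDefinition.J_CDR3)
        uj = compute_gene_usage(rep, "J")
        with pytest.raises(ContractError, match="subgroup"):
            compare_gene_usage([u, uj])


class TestComparisonSerialization:
    def test_output_files_reparse_to_written_values(self, rng, tmp_path):
        rep_a = _random_rep(rng, 20, "a")
        rep_b = _random_rep(rng, 20, "b")
        pub = find_public_clonotypes([rep_a, rep_b], labels=["a", "b"])
        excl = find_exclusive_clonotypes(rep_a, rep_b, labels=["a", "b"])
        write_public_table(tmp_path / "pub.tsv", pub)
        write_exclusive_table(tmp_path / "excl.tsv", excl)
        df = read_table(tmp_path / "pub.tsv")
        assert list(df.columns) == ["CDR3", "freq_pct:a", "freq_pct:b",
                                    "repertoire_count"]
        assert len(df) == len(pub.rows)
        for row, rec in zip(pub.rows, df.to_dict(orient="records")):
            assert rec["CDR3"] == row.key[0]
            assert float(rec["freq_pct:a"]) == pytest.approx(
                row.freq_pct[0], abs=1e-4)
            assert int(rec["repertoire_count"]) == row.repertoire_count
        df2 = read_table(tmp_path / "excl.tsv")
        assert [r["CDR3"] for r in df2.to_dict(orient="records")] == [
            k[0] for k, _ in excl.rows
        ]
        reads = [make_read(read_id="0")]
        rep = extract_clonotypes(reads, ClonotypeDefinition.V_CDR3, label="x")
        u = compute_gene_usage(rep, "V")
        cmp_table = compare_gene_usage([u, u], labels=["x", "y"])
        write_usage_comparison(tmp_path / "cmp.tsv", cmp_table)
        df3 = read_table(tmp_path / "cmp.tsv")
        assert list(df3.columns) == ["GENE", "usage_pct:x", "usage_pct:y",
                                     "mean_usage_pct"]
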
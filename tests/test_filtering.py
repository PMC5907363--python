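"""The eleven filtering criteria and the partition they induce."""

import io
import random

import pytest

from airrprof import (
    CRITERIA,
    ContractError,
    FilterConfig,
    apply_filters,
    evaluate_criterion,
)
from airrprof.filtering import (
    read_filtered_reads,
    write_filtered_reads,
    write_rejected_reads,
)

from conftest import make_read, random_reads


class TestCriteria:
    @pytest.mark.parametrize(
        "cdr3, ok",
        [
            ("CASSLGTDTQYF", True),   # C...F
            ("CASSLGTDTQYW", True),   # C...W
            ("AASSLGTDTQYF", False),  # lost cysteine 104
            ("CASSLGTDTQYA", False),  # lost F/W 118
            ("", False),              # empty junction carries no anchors
            ("C", False),
            ("CF", True),
        ],
    )
    def test_anchor_criterion(self, cdr3, ok):
        read = make_read(cdr3=cdr3)
        assert evaluate_criterion(read, "anchors", FilterConfig()) is ok

    @pytest.mark.parametrize(
        "functionality, ok",
        [
            ("productive", True),
            ("productive (see comment)", True),
            ("unproductive (out-of-frame junction)", False),
            ("unknown (out-of-frame)", False),
            ("unproductive (see comment)", True),  # out of frame not stated
            ("", False),  # missing data fails the enabled criterion
        ],
    )
    def test_in_frame_criterion(self, functionality, ok):
        read = make_read(functionality=functionality)
        assert evaluate_criterion(read, "in-frame", FilterConfig()) is ok

    @pytest.mark.parametrize(
        "functionality, ok",
        [
            ("productive", True),
            ("Productive (see comment)", True),  # case-insensitive first token
            ("unproductive (see comment)", False),
            ("unproductive", False),
            ("No results", False),
            ("", False),
        ],
    )
    def test_productive_criterion_matches_leading_token(self, functionality, ok):
        read = make_read(functionality=functionality)
        assert evaluate_criterion(read, "functionality", FilterConfig()) is ok

    @pytest.mark.parametrize(
        "v_raw, ok",
        [
            ("Homsap TRBV6-5*01 F", True),
            ("Homsap TRBV1*01 P", False),          # pseudogene
            ("Homsap TRBV20-1*01 ORF", False),
            ("Homsap TRBV6-5*01 F, or Homsap TRBV6-6*01 P", False),
            ("Homsap TRBV9*01", True),             # no letter: not non-functional
            ("", False),                           # missing V assignment
        ],
    )
    def test_v_functional_criterion(self, v_raw, ok):
        read = make_read(v_raw=v_raw)
        assert evaluate_criterion(read, "v-functional", FilterConfig()) is ok

    @pytest.mark.parametrize(
        "identity, ok",
        [(96.9, False), (97.0, True), (100.0, True), (None, False)],
    )
    def test_v_identity_threshold_is_inclusive(self, identity, ok):
        read = make_read(identity=identity)
        cfg = FilterConfig(check_v_identity=True, min_v_identity_pct=97.0)
        assert evaluate_criterion(read, "v-identity", cfg) is ok

    def test_ambiguous_v_and_missing_j(self):
        cfg = FilterConfig()
        ambiguous = make_read(v_raw="Homsap TRBV6-5*01 F, or Homsap TRBV6-6*01 F")
        assert evaluate_criterion(ambiguous, "ambiguous-v", cfg) is False
        assert evaluate_criterion(make_read(), "ambiguous-v", cfg) is True
        no_j = make_read(j_raw="")
        assert evaluate_criterion(no_j, "missing-or-ambiguous-j", cfg) is False
        two_j = make_read(j_raw="Homsap TRBJ1-1*01 F, or Homsap TRBJ1-2*01 F")
        assert evaluate_criterion(two_j, "missing-or-ambiguous-j", cfg) is False

    def test_query_criteria(self):
        cfg = FilterConfig(
            v_gene_whitelist=frozenset({"TRBV6-5"}),
            j_gene_whitelist=frozenset({"TRBJ2-3"}),
            cdr3_len_min=10, cdr3_len_max=14,
            cdr3_motif="GTD",
        )
        read = make_read()  # CASSLGTDTQYF, TRBV6-5, TRBJ2-3, length 12
        for crit in ("v-whitelist", "j-whitelist", "cdr3-length", "cdr3-motif"):
            assert evaluate_criterion(read, crit, cfg) is True
        other = make_read(cdr3="CASF", v="TRBV9", j="TRBJ1-1")
        for crit in ("v-whitelist", "j-whitelist", "cdr3-length", "cdr3-motif"):
            assert evaluate_criterion(other, crit, cfg) is False

    def test_unknown_criterion_is_contract_error(self):
        with pytest.raises(ContractError, match="unknown"):
            evaluate_criterion(make_read(), "no-such-criterion", FilterConfig())

    def test_exactly_eleven_criteria_all_switchable(self):
        assert len(CRITERIA) == 11
        cfg = FilterConfig.quality(
            v_gene_whitelist=frozenset({"x"}), j_gene_whitelist=frozenset({"x"}),
            cdr3_len_min=1, cdr3_motif="A",
        )
        assert set(cfg.enabled_criteria()) == set(CRITERIA)
        assert FilterConfig().enabled_criteria() == ()


class TestApplyFilters:
    def test_vacuous_filter_passes_everything(self, rng):
        reads = random_reads(rng, 30)
        outcome = apply_filters(reads, FilterConfig())
        assert list(outcome.passed) == reads
        assert outcome.rejected == ()

    def test_partition_conserves_and_orders_input(self, rng):
        reads = random_reads(rng, 200)
        # plant anchor violations at known positions
        bad_positions = {3, 17, 90, 150}
        reads = [
            make_read(read_id=r.read_id, cdr3="A" + r.cdr3_aa[1:]) if i in bad_positions
            else r
            for i, r in enumerate(reads)
        ]
        outcome = apply_filters(reads, FilterConfig(require_anchors=True))
        assert outcome.summary.passed_count + outcome.summary.rejected_count == 200
        assert outcome.summary.per_reason == {"anchors": len(bad_positions)}
        assert [r.read_id for r, _ in outcome.rejected] == [
            reads[i].read_id for i in sorted(bad_positions)
        ]
        recombined = sorted(
            [r.read_id for r in outcome.passed]
            + [r.read_id for r, _ in outcome.rejected],
            key=int,
        )
        assert recombined == [r.read_id for r in reads]

    def test_reason_lists_are_complete_not_short_circuited(self):
        read = make_read(cdr3="ABad", identity=50.0,
                         functionality="unproductive (out-of-frame junction)")
        cfg = FilterConfig.quality()
        outcome = apply_filters([read], cfg)
        (_, reasons), = outcome.rejected
        assert set(reasons) == {"anchors", "in-frame", "functionality", "v-identity"}
        # summary counts one per reason for the single read
        assert sum(outcome.summary.per_reason.values()) == 4

    def test_enabling_a_criterion_never_increases_passes(self, rng):
        reads = random_reads(rng, 150)
        # corrupt a sprinkle of reads in different ways
        corrupted = []
        for i, r in enumerate(reads):
            if i % 11 == 0:
                corrupted.append(make_read(read_id=r.read_id, cdr3="X" + r.cdr3_aa))
            elif i % 13 == 0:
                corrupted.append(make_read(read_id=r.read_id, identity=90.0))
            else:
                corrupted.append(r)
        cfg_kwargs = [
            {"require_anchors": True},
            {"check_v_identity": True},
            {"require_productive": True},
            {"reject_ambiguous_v": True},
        ]
        enabled: dict = {}
        prev = len(corrupted)
        for kw in cfg_kwargs:
            enabled.update(kw)
            n_pass = apply_filters(corrupted, FilterConfig(**enabled)).summary.passed_count
            assert n_pass <= prev
            prev = n_pass

    def test_filtering_is_idempotent_on_passed_reads(self, rng):
        reads = random_reads(rng, 120)
        cfg = FilterConfig.quality()
        passed = apply_filters(reads, cfg).passed
        again = apply_filters(passed, cfg)
        assert again.passed == passed
        assert again.rejected == ()

    def test_filtered_files_round_trip(self, rng, tmp_path):
        reads = random_reads(rng, 40)
        cfg = FilterConfig(require_anchors=True)
        outcome = apply_filters(reads, cfg)
        fin = tmp_path / "in.tsv"
        fout = tmp_path / "out.tsv"
        write_filtered_reads(fin, outcome.passed)
        write_rejected_reads(fout, outcome.rejected)
        assert tuple(read_filtered_reads(fin)) == outcome.passed
        assert tuple(read_filtered_reads(fout)) == tuple(
            r for r, _ in outcome.rejected
        )
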
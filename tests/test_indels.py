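"""Amplicon indel pipeline: demultiplexing, filters, NHEJ calling, testing."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from zfnscan import (
    AlignScoring,
    Amplicon,
    AmpliconSimConfig,
    align_affine,
    assign_reads,
    call_indels,
    collapse_alignments,
    filter_alignments,
    quantify_indels,
    simulate_amplicon_reads,
)
from zfnscan import test_site as fisher_test_site
from zfnscan._dna import revcomp
from zfnscan.indels import depth_ok

from conftest import make_amplicon


@pytest.fixture(scope="module")
def amp():
    rng = np.random.default_rng(0)
    pad_l = "".join(rng.choice(list("ACGT"), 25))
    pad_r = "".join(rng.choice(list("ACGT"), 25))
    core = "GTCATCCTCATC" + "CTGAT" + "AAACTGCAAAAG"
    # spacer occupies reference coords [25+12, 25+17)
    return make_amplicon(core, pad_l, pad_r, 37, 42, name="locus1")


@pytest.fixture(scope="module")
def amp2():
    rng = np.random.default_rng(99)
    ref = "".join(rng.choice(list("ACGT"), 80))
    return Amplicon("locus2", ref, ref[:20], revcomp(ref[-20:]), 35, 40)


class TestAssignReads:
    def test_exact_forward_primer_assigned(self, amp):
        res = assign_reads([("r1", amp.reference_seq)], [amp])
        assert res.assigned["locus1"] == [("r1", amp.reference_seq)]

    def test_reverse_strand_read_reoriented(self, amp):
        res = assign_reads([("r1", revcomp(amp.reference_seq))], [amp])
        assert res.assigned["locus1"] == [("r1", amp.reference_seq)]

    def test_mismatch_budget(self, amp):
        flip = str.maketrans("ACGT", "CGTA")

        def mutate_prefix(seq, n):
            return seq[:n].translate(flip) + seq[n:]

        read2 = mutate_prefix(amp.reference_seq, 2)
        assert assign_reads([("r", read2)], [amp]).assigned["locus1"]
        read3 = mutate_prefix(amp.reference_seq, 3)
        res = assign_reads([("r", read3)], [amp], max_primer_mismatches=2)
        assert res.n_unassigned_nomatch == 1

    def test_prefix_matching_two_amplicons_is_ambiguous(self, amp):
        twin = Amplicon("twin", amp.reference_seq, amp.fwd_primer, amp.rev_primer, 37, 42)
        res = assign_reads([("r", amp.reference_seq)], [amp, twin])
        assert res.n_unassigned_ambiguous == 1
        assert not res.assigned["locus1"] and not res.assigned["twin"]

    def test_duplicate_amplicon_names_error(self, amp):
        with pytest.raises(ValueError, match="duplicate"):
            assign_reads([], [amp, amp])

    def test_empty_input(self, amp):
        res = assign_reads([], [amp])
        assert res.n_total == 0 and res.assigned["locus1"] == []


class TestFilters:
    def test_39_reference_bases_dropped_40_kept(self, amp):
        short39 = align_affine(amp.reference_seq[:39], amp.reference_seq[:39])
        exactly40 = align_affine(amp.reference_seq[:40], amp.reference_seq[:40])
        kept, dropped = filter_alignments([short39, exactly40], min_ref_bases=40)
        assert kept == [exactly40] and dropped == [short39]

    def test_depth_gate_strict_in_either_arm(self):
        assert not depth_ok(1499, 2000)
        assert not depth_ok(2000, 1499)
        assert depth_ok(1500, 1500)

    def test_full_length_reads_all_pass(self, amp):
        alns = [align_affine(amp.reference_seq, amp.reference_seq) for _ in range(5)]
        kept, dropped = filter_alignments(alns)
        assert len(kept) == 5 and not dropped


class TestCollapse:
    def test_identical_reads_condense_to_one_counted_record(self, amp):
        aln = align_affine(amp.reference_seq, amp.reference_seq, amplicon="locus1")
        collapsed, excluded = collapse_alignments([(aln, 1000)], amp, [amp])
        assert len(collapsed) == 1 and collapsed[0].count == 1000 and not excluded

    def test_read_matching_other_reference_better_is_excluded(self, amp, amp2):
        # a read that is amp2's reference but carries amp's forward primer
        chimera = amp.fwd_primer + amp2.reference_seq[20:]
        aln = align_affine(chimera, amp.reference_seq, amplicon="locus1")
        collapsed, excluded = collapse_alignments([(aln, 7)], amp, [amp, amp2])
        assert not collapsed and excluded == [(aln, 7)]

    def test_empty_input(self, amp):
        assert collapse_alignments([], amp, [amp]) == ([], [])


class TestCallIndels:
    def test_two_nt_deletion_inside_spacer_qualifies(self, amp):
        ref = amp.reference_seq
        read = ref[:38] + ref[40:]
        events, flag = call_indels(align_affine(read, ref), amp.spacer_interval)
        assert flag and any(e.qualifies and e.type == "del" and e.length == 2 for e in events)

    def test_one_nt_indels_never_qualify(self, amp):
        ref = amp.reference_seq
        for read in (ref[:38] + ref[39:], ref[:38] + "T" + ref[38:] if ref[38] != "T" else ref[:38] + "G" + ref[38:]):
            events, flag = call_indels(align_affine(read, ref), amp.spacer_interval)
            assert not flag
            assert all(not e.qualifies for e in events)

    def test_long_deletion_spanning_into_spacer_qualifies(self, amp):
        # 10-nt deletion starting 4 nt upstream of the spacer, ending inside
        ref = amp.reference_seq
        s, _ = amp.spacer_interval
        read = ref[: s - 4] + ref[s + 6 :]
        events, flag = call_indels(align_affine(read, ref), amp.spacer_interval)
        dels = [e for e in events if e.type == "del"]
        assert flag and dels[0].length == 10 and dels[0].qualifies

    def test_deletion_outside_spacer_does_not_qualify(self, amp):
        ref = amp.reference_seq
        read = ref[:22] + ref[25:]  # 3-nt deletion well upstream
        events, flag = call_indels(align_affine(read, ref), amp.spacer_interval)
        assert not flag and any(e.length == 3 and not e.qualifies for e in events)

    def test_insertion_boundaries_inclusive_at_both_spacer_ends(self, amp):
        s_start, s_end = amp.spacer_interval
        ref = amp.reference_seq
        for point, expect in ((s_start, True), (s_end, True), (s_start - 3, False)):
            # choose inserted bases unequal to the preceding reference base so
            # left-normalization cannot shift the insertion point
            ins_bases = "TT" if ref[point - 1] != "T" else "GG"
            read = ref[:point] + ins_bases + ref[point:]
            events, flag = call_indels(align_affine(read, ref), amp.spacer_interval)
            ins = [e for e in events if e.type == "ins" and e.length == 2]
            assert len(ins) == 1
            assert ins[0].qualifies == expect == flag


def hypergeometric_tail(k1, n1, k0, n0):
    """One-sided Fisher p by explicit hypergeometric summation (exact)."""
    K = k1 + k0
    total = n1 + n0
    denom = comb(total, n1)
    p = Fraction(0)
    for x in range(k1, min(K, n1) + 1):
        p += Fraction(comb(K, x) * comb(total - K, n1 - x), denom)
    return p


class TestSiteTest:
    def test_no_indels_anywhere_is_not_significant(self):
        res = fisher_test_site((0, 5000), (0, 5000))
        assert res.p_value == pytest.approx(1.0) and not res.significant

    def test_p_matches_hypergeometric_enumeration(self):
        for treated, control in [((10, 1000), (0, 1000)), ((5, 200), (2, 300)), ((0, 50), (3, 60))]:
            res = fisher_test_site(treated, control)
            expected = float(hypergeometric_tail(*treated, *control))
            assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_significance_is_strict_inequality(self):
        res = fisher_test_site((10, 1000), (1, 1000))
        # alpha exactly at p must NOT be significant; just above must be
        at_p = fisher_test_site((10, 1000), (1, 1000), alpha=res.p_value)
        above = fisher_test_site((10, 1000), (1, 1000), alpha=res.p_value * 1.0001)
        assert not at_p.significant and above.significant

    def test_zero_depth_arm_excluded(self):
        res = fisher_test_site((0, 0), (0, 100))
        assert res.status == "excluded_low_depth" and res.p_value is None and not res.significant

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            fisher_test_site((5, 3), (0, 100))


class TestPipeline:
    def test_clean_reads_yield_zero_qualifying_events(self, amp):
        cfg = AmpliconSimConfig(amplicon=amp, indel_rate=0.0, substitution_error_rate=0.01, n_reads=2000, seed=5)
        treated, control = simulate_amplicon_reads(cfg)
        report = quantify_indels([amp], treated, control, min_reads=100)
        r = report.results[0]
        assert r.treated_indel_reads == 0 and r.control_indel_reads == 0
        assert not r.significant

    def test_planted_rate_recovered_and_significant(self, amp):
        cfg = AmpliconSimConfig(
            amplicon=amp, indel_rate=0.05, indel_length_dist={3: 1.0}, insertion_fraction=0.0,
            n_reads=2000, seed=17,
        )
        treated, control = simulate_amplicon_reads(cfg)
        report = quantify_indels([amp], treated, control, min_reads=1500)
        r = report.results[0]
        assert r.status == "called"
        assert abs(r.indel_rate_treated - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert r.significant and r.indel_rate_control == 0.0

    def test_low_depth_amplicon_excluded(self, amp):
        cfg = AmpliconSimConfig(amplicon=amp, indel_rate=0.05, n_reads=1499, seed=3)
        treated, control = simulate_amplicon_reads(cfg)
        report = quantify_indels([amp], treated, control, min_reads=1500)
        assert report.results[0].status == "excluded_low_depth"

    def test_read_conservation_with_junk_short_and_cross_target_reads(self, amp, amp2):
        ref = amp.reference_seq
        reads = (
            [(f"ok{i}", ref) for i in range(20)]
            + [("junk", "T" * len(ref))]  # no primer match
            + [("short", ref[:30])]  # < 40 aligned reference bases
            + [("cross", amp.fwd_primer + amp2.reference_seq[20:])]  # better on locus2
        )
        report = quantify_indels([amp, amp2], reads, [("c", ref)], min_reads=1)
        acc = report.treated
        recovered = (
            acc.unassigned_nomatch
            + acc.unassigned_ambiguous
            + sum(acc.dropped_short.values())
            + sum(acc.cross_target.values())
            + sum(acc.retained.values())
        )
        assert acc.reads_total == len(reads) == recovered
        assert acc.dropped_short["locus1"] == 1
        assert acc.cross_target["locus1"] == 1
        assert acc.unassigned_nomatch == 1

    def test_pipeline_is_deterministic(self, amp):
        cfg = AmpliconSimConfig(amplicon=amp, indel_rate=0.03, n_reads=500, seed=8)
        treated, control = simulate_amplicon_reads(cfg)
        f1 = quantify_indels([amp], treated, control, min_reads=10).to_frame()
        f2 = quantify_indels([amp], treated, control, min_reads=10).to_frame()
        assert f1.equals(f2)
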
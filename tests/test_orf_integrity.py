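"""Alignment, indel events, and ORF integrity verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from l1screen import (
    AlignmentParams,
    AlignmentResult,
    InputError,
    LocusRecord,
    MutationSpec,
    OrfStatus,
    align_to_reference,
    apply_mutation,
    classify_orf,
    first_premature_stop,
    generate_cohort,
    is_full_length,
    translate_cds,
)


class TestAlignment:
    def test_self_alignment(self, human):
        aln = align_to_reference(LocusRecord("self", human.full_length_nt), human)
        assert aln.indel_events == []
        assert aln.reference_coverage == 1.0
        assert aln.five_prime_offset == 1

    def test_single_deletion_located_leftmost(self, human):
        """A 1-nt deletion is reported once, at the leftmost equivalent position.

        Oracle: enumerate every reference position whose deletion reproduces
        the locus string exactly; the reported event must be the minimum of
        that equivalence class.
        """
        ref = human.full_length_nt
        target_pos = 3000  # 1-based: delete ref base 3000
        locus = ref[: target_pos - 1] + ref[target_pos:]
        equivalent = [
            p for p in range(max(1, target_pos - 30), target_pos + 31)
            if ref[: p - 1] + ref[p:] == locus
        ]
        aln = align_to_reference(LocusRecord("d", locus), human)
        assert len(aln.indel_events) == 1
        ev = aln.indel_events[0]
        assert (ev.kind, ev.length) == ("deletion", 1)
        assert ev.position == min(equivalent)

    def test_five_prime_truncation_offset(self, human):
        aln = align_to_reference(LocusRecord("t", human.full_length_nt[500:]), human)
        assert aln.five_prime_offset == 501
        assert aln.indel_events == []  # terminal gap is not an internal event

    def test_invalid_inputs(self, human):
        with pytest.raises(InputError):
            align_to_reference(LocusRecord("s", "ACGT" * 10), human)  # < 100 nt

    def test_determinism(self, human):
        pairs = generate_cohort(human, 3, background_rate=0.02, seed=9)
        for rec, _ in pairs:
            a = align_to_reference(rec, human)
            b = align_to_reference(rec, human)
            assert a.aligned_pairs == b.aligned_pairs
            assert a.indel_events == b.indel_events

    def test_anchored_matches_full_engine(self, human):
        """The anchored engine must reproduce the full affine DP's indels."""
        ref = human.full_length_nt
        rng = np.random.default_rng(2)
        for _ in range(3):
            seq = list(ref[1500:2500])
            for i in rng.choice(len(seq), 20, replace=False):
                seq[int(i)] = str(rng.choice(list("ACGT")))
            del seq[400:402]
            seq[700:700] = list("TTT")
            locus = LocusRecord("w", ref[:200] + "".join(seq) + ref[5200:])
            a = align_to_reference(locus, human, AlignmentParams(engine="anchored"))
            f = align_to_reference(locus, human, AlignmentParams(engine="full"))
            assert a.indel_events == f.indel_events
            assert a.reference_coverage == f.reference_coverage


class TestClassifyOrf:
    def _status(self, human, seq, which):
        rec = LocusRecord("x", seq)
        aln = align_to_reference(rec, human)
        return classify_orf(aln, rec, human, which)

    def test_unmutated_reference_is_intact(self, human):
        st1 = self._status(human, human.full_length_nt, 1)
        st2 = self._status(human, human.full_length_nt, 2)
        assert st1.verdict == st2.verdict == "INTACT"
        assert st2.stop_positions_aa == ()

    def test_single_nonsense_maps_to_reference_aa(self, human):
        seq = apply_mutation(human, human.full_length_nt, MutationSpec("nonsense", 240, "TAG"))
        status = self._status(human, seq, 2)
        assert status.verdict == "PREMATURE_STOP"
        assert status.first_stop_aa == 240
        assert first_premature_stop(status) == 240

    def test_two_nt_insertion_is_frameshift(self, human):
        s, _ = human.orf1_span
        seq = apply_mutation(
            human, human.full_length_nt, MutationSpec("frameshift_indel", s + 150, "GG", 2)
        )
        status = self._status(human, seq, 1)
        assert status.verdict == "FRAMESHIFT"
        assert len(status.frameshift_positions) == 1

    def test_inframe_deletion_is_gap_and_outranks_stop(self, human):
        seq = apply_mutation(human, human.full_length_nt, MutationSpec("nonsense", 700, "TAA"))
        seq = apply_mutation(human, seq, MutationSpec("inframe_indel", human.orf2_span[0] + 90, None, 6))
        status = self._status(human, seq, 2)
        assert status.verdict == "GAP"
        # stops are still enumerated downstream of the gap
        assert 700 in status.stop_positions_aa

    def test_frameshift_outranks_gap(self, human):
        o2s = human.orf2_span[0]
        seq = apply_mutation(human, human.full_length_nt, MutationSpec("inframe_indel", o2s + 300, None, 3))
        seq = apply_mutation(human, seq, MutationSpec("frameshift_indel", o2s + 90, None, 1))
        status = self._status(human, seq, 2)
        assert status.verdict == "FRAMESHIFT"

    def test_missing_start_orf1_only_by_default(self, human):
        s1, _ = human.orf1_span
        seq = list(human.full_length_nt)
        seq[s1 - 1 : s1 + 2] = list("ATA")
        status = self._status(human, "".join(seq), 1)
        assert status.verdict == "MISSING_START"
        # ORF2 start is internal: same edit at ORF2 start is not MISSING_START
        s2, _ = human.orf2_span
        seq = list(human.full_length_nt)
        seq[s2 - 1 : s2 + 2] = list("ATA")
        status = self._status(human, "".join(seq), 2)
        assert status.verdict == "INTACT"

    def test_n_codons_are_never_stops(self, human):
        lo, hi = human.codon_nt_span(240, 2)
        seq = list(human.full_length_nt)
        seq[lo - 1 : hi] = list("NNN")
        status = self._status(human, "".join(seq), 2)
        assert status.verdict == "INTACT"
        assert status.n_run_spans == ((240, 240),)

    def test_locus_stop_at_reference_terminal_stop_is_ignored(self, human):
        status = self._status(human, human.full_length_nt, 2)
        assert status.stop_positions_aa == ()

    def test_not_covered_when_orf_missing(self, human):
        # truncate into ORF2: ORF1 entirely absent from the locus
        cut = human.orf2_span[0] + 600
        status = self._status(human, human.full_length_nt[cut:], 1)
        assert status.verdict == "NOT_COVERED"

    def test_which_orf_validated(self, human):
        rec = LocusRecord("x", human.full_length_nt)
        aln = align_to_reference(rec, human)
        with pytest.raises(InputError):
            classify_orf(aln, rec, human, 3)


class TestFirstStop:
    def test_minimum_rule(self, human):
        seq = apply_mutation(human, human.full_length_nt, MutationSpec("nonsense", 774, "TGA"))
        seq = apply_mutation(human, seq, MutationSpec("nonsense", 240, "TAG"))
        rec = LocusRecord("x", seq)
        status = classify_orf(align_to_reference(rec, human), rec, human, 2)
        assert set(status.stop_positions_aa) == {240, 774}
        assert first_premature_stop(status) == 240

    def test_none_when_no_stops(self):
        assert first_premature_stop(OrfStatus(verdict="INTACT")) is None

    def test_single_stop(self, human):
        seq = apply_mutation(human, human.full_length_nt, MutationSpec("nonsense", 377))
        rec = LocusRecord("x", seq)
        status = classify_orf(align_to_reference(rec, human), rec, human, 2)
        assert first_premature_stop(status) == 377

    @settings(deadline=None, max_examples=25)
    @given(data=st.data())
    def test_downstream_stop_never_changes_first_stop(self, human, data):
        """Adding a second stop strictly downstream leaves the first stop fixed."""
        first = data.draw(st.integers(2, human.orf2_aa_length - 1))
        second = data.draw(st.integers(first + 1, human.orf2_aa_length))
        base = apply_mutation(human, human.full_length_nt, MutationSpec("nonsense", first, "TAG"))
        both = apply_mutation(human, base, MutationSpec("nonsense", second, "TAA"))
        for seq in (base, both):
            rec = LocusRecord("x", seq)
            status = classify_orf(align_to_reference(rec, human), rec, human, 2)
            assert first_premature_stop(status) == first


class TestOracleEquivalence:
    def test_alignment_path_equals_direct_translation(self, human):
        """For substitution-only loci the aligned first stop equals a naive
        direct-translation scan of the locus ORF2."""
        pairs = generate_cohort(
            human, 120,
            class_mix={"screen_hit": 0.7, "intact_both_orfs": 0.3},
            background_rate=0.02, seed=21,
        )
        s, e = human.orf2_span
        for rec, _ in pairs:
            aln = align_to_reference(rec, human)
            status = classify_orf(aln, rec, human, 2)
            prot = translate_cds(rec.sequence[s - 1 : e])
            naive = next(
                (i + 1 for i, aa in enumerate(prot[: human.orf2_aa_length]) if aa == "*"),
                None,
            )
            assert first_premature_stop(status) == naive


class TestFullLength:
    def _stub(self, coverage, offset):
        return AlignmentResult(
            aligned_pairs=[], indel_events=[], reference_coverage=coverage,
            five_prime_offset=offset, ref_length=6050, locus_seq="",
            _loc_at_ref=np.zeros(1),
        )

    def test_thresholds(self, human):
        assert is_full_length(self._stub(1.0, 1), human)
        assert is_full_length(self._stub(0.91, 10), human)
        assert not is_full_length(self._stub(0.91, 200), human)
        assert not is_full_length(self._stub(0.5, 1), human)

    def test_real_full_copy_and_truncation(self, human):
        full = align_to_reference(LocusRecord("f", human.full_length_nt), human)
        assert is_full_length(full, human)
        cut = align_to_reference(LocusRecord("c", human.full_length_nt[2000:]), human)
        assert not is_full_length(cut, human)
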
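"""Read preprocessing: merging, quality trimming and primer filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saber.reads import (AmpliconReference, MergedRead, ReadPair, merge_pair,
                         primer_filter, process_sample, revcomp,
                         sliding_window_trim)


def _pair(seq1, seq2, q1=40, q2=40, rid="r"):
    return ReadPair(rid, seq1, seq2,
                    np.full(len(seq1), q1), np.full(len(seq2), q2))


def best_overlap_bruteforce(s1, s2rc, min_overlap, max_mm_frac):
    """Enumerate every ungapped overlap and score it as matches-mismatches."""
    best = (0, float("-inf"))
    for o in range(min_overlap, min(len(s1), len(s2rc)) + 1):
        a, b = s1[len(s1) - o:], s2rc[:o]
        mm = sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")
        if mm / o > max_mm_frac:
            continue
        score = o - 2 * mm
        if score >= best[1]:  # ties go to the longer overlap
            best = (o, score)
    return best


class TestMergePair:
    def test_exact_overlap_reconstructs_amplicon(self):
        rng = np.random.default_rng(0)
        amp = "".join(rng.choice(list("ACGT"), 30))
        pair = _pair(amp[:20], revcomp(amp[10:]))
        merged = merge_pair(pair, min_overlap=10)
        assert merged is not None
        assert merged.seq == amp
        assert merged.overlap_len == 10

    def test_no_acceptable_overlap_returns_none(self):
        pair = _pair("A" * 20, revcomp("C" * 20))
        assert best_overlap_bruteforce("A" * 20, "C" * 20, 10, 0.1)[0] == 0
        assert merge_pair(pair, min_overlap=10) is None

    def test_mismatch_resolved_by_quality(self):
        rng = np.random.default_rng(1)
        amp = "".join(rng.choice(list("ACGT"), 40))
        s1 = amp[:25]
        s2rc = amp[15:]
        mutated = s2rc[:3] + ("A" if s2rc[3] != "A" else "G") + s2rc[4:]
        # mate-2 copy carries the error at low quality: mate 1 must win
        pair = _pair(s1, revcomp(mutated), q1=40, q2=10)
        merged = merge_pair(pair)
        assert merged.seq == amp
        assert merged.qual[18] == 40
        # and with the qualities reversed, the erroneous base wins
        pair = _pair(s1, revcomp(mutated), q1=10, q2=40)
        merged = merge_pair(pair)
        assert merged.seq != amp
        assert merged.seq[18] == mutated[3]

    def test_chosen_overlap_maximises_score(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            amp = "".join(rng.choice(list("ACGT"), 60))
            o_true = int(rng.integers(12, 30))
            s1 = amp[:40]
            s2 = revcomp(amp[40 - o_true:])
            merged = merge_pair(_pair(s1, s2))
            o_bf, _ = best_overlap_bruteforce(s1, revcomp(s2), 10, 0.1)
            assert merged is not None
            assert merged.overlap_len == o_bf

    def test_mate_swap_symmetry(self):
        rng = np.random.default_rng(3)
        amp = "".join(rng.choice(list("ACGT"), 50))
        m1 = merge_pair(_pair(amp[:30], revcomp(amp[15:])))
        m2 = merge_pair(_pair(revcomp(amp[15:]), amp[:30]))
        assert m1 is not None and m2 is not None
        assert m2.seq == revcomp(m1.seq)

    def test_empty_read_errors(self):
        with pytest.raises(ValueError, match="empty read"):
            merge_pair(_pair("", "ACGT"))


class TestSlidingWindowTrim:
    def _read(self, quals):
        quals = np.asarray(quals)
        return MergedRead("r", "A" * len(quals), quals)

    def test_high_quality_read_unchanged(self):
        read = self._read(np.full(150, 40))
        out = sliding_window_trim(read, 4, 15, 100)
        assert out is read

    def test_truncation_below_min_len_drops_read(self):
        # first failing window starts at position 90
        quals = np.concatenate([np.full(90, 40), np.full(60, 14)])
        assert sliding_window_trim(self._read(quals), 4, 15, 100) is None
        out = sliding_window_trim(self._read(quals), 4, 15, 80)
        assert out is not None and len(out) == 90

    def test_short_read_dropped_by_min_len(self):
        assert sliding_window_trim(self._read(np.full(99, 40)), 4, 15, 100) is None

    @given(st.lists(st.integers(0, 41), min_size=1, max_size=60),
           st.integers(1, 6))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_window_scan(self, quals, window):
        read = self._read(quals)
        cut = len(quals)
        for start in range(len(quals) - window + 1):
            if np.mean(quals[start:start + window]) < 15:
                cut = start
                break
        out = sliding_window_trim(read, window, 15, min_len=0)
        assert len(out) == cut
        assert len(out) <= len(read)


class TestPrimerFilter:
    @pytest.fixture()
    def ref(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 120))
        return AmpliconReference(seq, seq[:20], revcomp(seq[-20:]))

    def _read(self, seq):
        return MergedRead("r", seq, np.full(len(seq), 35))

    def test_both_primers_removed(self, ref):
        out = primer_filter(self._read(ref.seq), ref)
        assert out is not None
        assert out.seq == ref.insert

    def test_absent_forward_primer_rejected(self, ref):
        out = primer_filter(self._read(ref.seq[25:]), ref)
        assert out is None

    def test_duplicated_primer_rejected(self, ref):
        out = primer_filter(self._read(ref.fwd_primer + ref.seq), ref)
        assert out is None

    def test_reverse_orientation_normalised(self, ref):
        out = primer_filter(self._read(revcomp(ref.seq)), ref)
        assert out is not None
        assert out.seq == ref.insert

    def test_one_error_within_tolerance_kept(self, ref):
        seq = list(ref.seq)
        seq[5] = "A" if seq[5] != "A" else "C"
        out = primer_filter(self._read("".join(seq)), ref, max_error_rate=0.1)
        assert out is not None
        assert out.seq == ref.insert
        # zero tolerance rejects the same read
        assert primer_filter(self._read("".join(seq)), ref,
                             max_error_rate=0.0) is None

    def test_output_never_contains_primers(self, ref):
        out = primer_filter(self._read(ref.seq), ref)
        assert ref.fwd_primer not in out.seq
        assert revcomp(ref.rev_primer) not in out.seq


def test_error_free_pipeline_recovers_insert_exactly(reference):
    """On error-free reads spanning the amplicon, merge -> trim -> primer
    filter returns exactly the insert for every read."""
    mol = reference.seq
    pairs = [ReadPair(f"r{i}", mol[:250], revcomp(mol)[:250],
                      np.full(250, 35), np.full(250, 35))
             for i in range(50)]
    survivors, fates = process_sample(pairs, reference)
    assert fates.surviving == fates.total == 50
    assert all(r.seq == reference.insert for r in survivors)
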
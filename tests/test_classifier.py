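import numpy as np
import pytest

from isomirflow import classify as cls
from isomirflow.io import SequenceRecord


def fams(*seqs):
    return cls.collapse_families(
        [SequenceRecord(f"m{i + 1}", s) for i, s in enumerate(seqs)])


M = "ACGTACGTACGTACGTACGTAC"  # 22 nt


def make_index(*extra, precursors=()):
    return cls.ReferenceIndex(fams(M, *extra), list(precursors))


class TestCollapseFamilies:
    def test_identical_sequences_collapse(self):
        families = fams("ACGTACGTACGTACGTAC", "ACGTACGTACGTACGTAC")
        assert len(families) == 1
        assert families[0].members == ("m1", "m2")
        assert families[0].id == "m1|m2"

    def test_distinct_sequences_stay_separate(self):
        families = fams("ACGTACGTACGTACGTAC", "TTTTACGTACGTACGTAC")
        assert len(families) == 2

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            cls.collapse_families([])


class TestCategoryRules:
    def test_identical_read(self):
        call = cls.classify_read(M, make_index())
        assert call.category == cls.C1_IDENTICAL and call.mirna_id == "m1"

    def test_three_base_trim_is_shorter(self):
        call = cls.classify_read(M[:-3], make_index())
        assert call.category == cls.C2_SHORTER
        assert call.edit_detail == "trim5=0,trim3=3"

    def test_six_base_trim_exceeds_rule(self):
        # more than 5 bases short is no longer a C2 match; with no precursor
        # it is unassigned, with a hosting precursor it falls through to C4
        short6 = M[:-6]
        assert cls.classify_read(short6, make_index()).category == cls.UNASSIGNED
        pre = SequenceRecord("m1", "TTGCA" + M + "GGCAT")
        call = cls.classify_read(short6, make_index(precursors=[pre]))
        assert call.category == cls.C4_PRECURSOR and call.mirna_id == "m1"

    def test_end_substitution(self):
        variant = M[:-1] + ("G" if M[-1] != "G" else "A")
        call = cls.classify_read(variant, make_index())
        assert (call.category, call.subtype) == (cls.C3_VARIANT,
                                                 cls.END_SUBSTITUTION)

    def test_internal_mismatch(self):
        variant = M[:10] + ("C" if M[10] != "C" else "G") + M[11:]
        call = cls.classify_read(variant, make_index())
        assert (call.category, call.subtype) == (cls.C3_VARIANT,
                                                 cls.INTERNAL_MISMATCH)
        # the difference is never at a terminal position for this subtype
        pos = int(call.edit_detail.split(",")[0].split("=")[1])
        assert 0 < pos < len(variant) - 1

    def test_end_addition(self):
        call = cls.classify_read(M + "TG", make_index())
        assert (call.category, call.subtype) == (cls.C3_VARIANT,
                                                 cls.END_ADDITION)
        assert call.edit_detail == "add5=0,add3=2"

    def test_two_internal_changes_unassigned(self):
        variant = list(M)
        variant[5] = "C" if M[5] != "C" else "G"
        variant[15] = "C" if M[15] != "C" else "G"
        call = cls.classify_read("".join(variant), make_index())
        assert call.category == cls.UNASSIGNED

    def test_read_with_n_never_matches(self):
        call = cls.classify_read(M[:-1] + "N", make_index())
        assert call.category == cls.UNASSIGNED

    def test_precedence_c1_beats_c3(self):
        # a read equal to one mature and one substitution away from another
        other = "T" + M[1:]
        call = cls.classify_read(M, make_index(other))
        assert call.category == cls.C1_IDENTICAL and call.mirna_id == "m1"

    def test_multi_mapped_when_two_families_tie(self):
        # two matures sharing the same 20-nt core: a core read is C2 for both
        core = M[1:-1]
        idx = cls.ReferenceIndex(fams("A" + core + "T", "G" + core + "C"))
        call = cls.classify_read(core, idx)
        assert call.category == cls.MULTI_MAPPED and call.mirna_id is None


class TestOracleEquivalence:
    def test_agreement_on_random_reads(self, ref_index):
        rng = np.random.default_rng(7)
        oracle = cls.BruteForceIndex(ref_index)
        matures = [f.sequence for f in ref_index.families]
        n_checked = 0
        for _ in range(2000):
            m = matures[rng.integers(len(matures))]
            seq = _random_edit(rng, m)
            a = cls.classify_read(seq, ref_index, "r")
            b = cls.classify_read_bruteforce(seq, oracle, "r")
            assert a == b, seq
            n_checked += 1
        assert n_checked == 2000

    def test_empty_precursor_set_never_yields_c4(self, reference_set):
        idx = cls.build_index(reference_set.mature, [])
        oracle = cls.BruteForceIndex(idx)
        rng = np.random.default_rng(8)
        for _ in range(300):
            m = reference_set.mature[rng.integers(len(reference_set.mature))]
            seq = _random_edit(rng, m.sequence)
            for call in (cls.classify_read(seq, idx),
                         cls.classify_read_bruteforce(seq, oracle)):
                assert call.category != cls.C4_PRECURSOR


def _random_edit(rng, m):
    """A random perturbation spanning all rule boundaries (including illegal
    edits that must fall out as unassigned)."""
    bases = "ACGTN"
    kind = rng.integers(7)
    if kind == 0:
        return m
    if kind == 1:  # trim 1..7 (beyond the legal 5)
        t = int(rng.integers(1, 8))
        t5 = int(rng.integers(0, t + 1))
        return m[t5:len(m) - (t - t5)] or "A"
    if kind == 2:  # substitute 1..2 positions anywhere, maybe N
        seq = list(m)
        for _ in range(int(rng.integers(1, 3))):
            p = int(rng.integers(len(seq)))
            seq[p] = bases[rng.integers(5)]
        return "".join(seq)
    if kind == 3:  # additions 1..3 (beyond the legal 2)
        t = int(rng.integers(1, 4))
        a5 = int(rng.integers(0, t + 1))
        extra = "".join(bases[rng.integers(4)] for _ in range(t))
        return extra[:a5] + m + extra[a5:]
    if kind == 4:  # random junk
        return "".join(bases[rng.integers(4)]
                       for _ in range(int(rng.integers(16, 30))))
    if kind == 5:  # trim + substitution combo
        t = int(rng.integers(1, 4))
        seq = list(m[t:])
        p = int(rng.integers(len(seq)))
        seq[p] = bases[rng.integers(4)]
        return "".join(seq)
    return m[::-1]  # reversed mature


class TestCounting:
    def test_merged_total_is_category_sum(self):
        calls = (
            [cls.IsomiRCall(f"a{i}", cls.C1_IDENTICAL, None, "m1", "exact")
             for i in range(10)]
            + [cls.IsomiRCall(f"b{i}", cls.C3_VARIANT, cls.END_ADDITION,
                              "m1", "add5=0,add3=1") for i in range(5)]
        )
        table = cls.count_mirnas(calls)
        assert table.merged["m1"] == 15
        assert table.table.loc["m1", cls.C1_IDENTICAL] == 10

    def test_all_multi_mapped_yields_empty_table(self):
        calls = [cls.IsomiRCall(f"r{i}", cls.MULTI_MAPPED) for i in range(4)]
        table = cls.count_mirnas(calls)
        assert len(table.table) == 0 and table.n_multi_mapped == 4

    def test_conservation(self, ref_index, mixed_reads):
        reads, _ = mixed_reads
        calls = [cls.classify_read(r.sequence, ref_index, r.id) for r in reads]
        table = cls.count_mirnas(calls)
        assert table.total_reads() == len(reads)
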
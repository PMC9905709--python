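"""Read cleanup stages and variant assignment."""

import numpy as np
import pytest

from prica._seq import revcomp, to_dna
from prica.backbones import RA3_ADAPTER_DNA
from prica.library_design import enumerate_variants
from prica.read_processing import (
    OS,
    PRODUCT,
    BackboneAssigner,
    ExhaustiveAssigner,
    ReadRecord,
    deduplicate,
    find_adapter,
    merge_pairs,
    quality_filter,
    strip_barcode,
    trim_adapters,
)


def _read(seq, qual=None, rid="r"):
    return ReadRecord(rid, seq, qual if qual is not None else "I" * len(seq))


# ---------------------------------------------------------------------------
# adapter trimming


def oracle_find_adapter(seq, adapter, max_error_rate=0.1, min_overlap=3):
    """Independent sliding-window Hamming oracle: rightmost admissible
    occurrence (full-length internal or 3'-terminal partial)."""
    best = None
    for start in range(len(seq)):
        ov = min(len(adapter), len(seq) - start)
        if ov < min_overlap:
            continue
        mm = sum(1 for a, b in zip(seq[start : start + ov], adapter) if a != b)
        if mm <= int(max_error_rate * ov):
            best = start
    return best


def test_exact_adapter_removed():
    frag = "ACGTACGTACGTACGT"
    pair = (_read(frag + RA3_ADAPTER_DNA), _read("A" * 20))
    r1, r2 = trim_adapters(pair, RA3_ADAPTER_DNA, "TTTTTTTTTT")
    assert r1.sequence == frag
    assert len(r1.quality) == len(frag)


def test_one_mismatch_21mer_still_trimmed():
    adapter = RA3_ADAPTER_DNA
    mutated = "A" + adapter[1:]
    assert mutated != adapter
    frag = "CCCGGGTTTAAACCCGGG"
    r1, _ = trim_adapters((_read(frag + mutated), _read("G" * 20)), adapter, "TTTT")
    assert r1.sequence == frag


def test_short_mate_discards_pair():
    pair = (_read("ACGTACGT" + RA3_ADAPTER_DNA), _read("C" * 30))
    assert trim_adapters(pair, RA3_ADAPTER_DNA, "TTTTTTTTTT") is None


def test_untrimmable_read_passes_through():
    pair = (_read("ACGT" * 10), _read("TGCA" * 10))
    r1, r2 = trim_adapters(pair, "GGGGGGGGGGGG", "CCCCCCCCCCCC")
    assert r1.sequence == "ACGT" * 10 and r2.sequence == "TGCA" * 10


def test_find_adapter_matches_sliding_window_oracle():
    rng = np.random.default_rng(5)
    bases = "ACGT"
    adapter = RA3_ADAPTER_DNA
    for _ in range(300):
        n = int(rng.integers(15, 90))
        seq = list(bases[i] for i in rng.integers(0, 4, size=n))
        if rng.random() < 0.7:  # implant a (possibly mutated, truncated) adapter
            pos = int(rng.integers(0, n))
            ins = list(adapter[: n - pos])
            for _ in range(int(rng.integers(0, 3))):
                j = int(rng.integers(0, len(ins)))
                ins[j] = bases[int(rng.integers(0, 4))]
            seq[pos : pos + len(ins)] = ins
        seq = "".join(seq)
        assert find_adapter(seq, adapter) == oracle_find_adapter(seq, adapter)


# ---------------------------------------------------------------------------
# pair merging


def oracle_merge(s1, s2rc, min_overlap=10, frac=0.1):
    """Independent overlap-choice oracle: exact overlaps longest-first, then
    mismatch-tolerant overlaps longest-first."""
    cands = range(min(len(s1), len(s2rc)), min_overlap - 1, -1)
    for ov in cands:
        if s1[len(s1) - ov :] == s2rc[:ov]:
            return ov
    for ov in cands:
        mm = sum(1 for a, b in zip(s1[len(s1) - ov :], s2rc) if a != b)
        if mm <= int(frac * ov):
            return ov
    return None


def test_perfect_overlap_merges_to_joint_length():
    insert = "TCCGATTGCAAGGCTGCAATCCGTAGGCTTGACAATGTCC"  # 40 nt, aperiodic
    r1 = _read(insert[:30])
    r2 = _read(revcomp(insert[10:]))
    merged = merge_pairs((r1, r2))
    assert merged is not None
    assert merged.sequence == insert


def test_non_overlapping_mates_discarded():
    merged = merge_pairs((_read("A" * 25), _read("C" * 25)))
    assert merged is None


def test_conflict_resolved_by_higher_quality():
    insert = "ACGTACGTACGTACGTACGTACGT"
    r1 = _read(insert, qual="#" * len(insert))  # low quality
    conflicted = "T" + insert[1:]
    r2 = _read(revcomp(conflicted), qual="I" * len(insert))
    merged = merge_pairs((r1, r2))
    assert merged is not None
    assert merged.sequence == conflicted  # R2's higher-quality base wins


def test_merge_overlap_matches_enumeration_oracle():
    rng = np.random.default_rng(9)
    bases = "ACGT"
    for _ in range(200):
        ln = int(rng.integers(30, 70))
        insert = "".join(bases[i] for i in rng.integers(0, 4, size=ln))
        rl = int(rng.integers(20, 50))
        s1 = list(insert[:rl])
        s2 = list(insert[max(0, ln - rl) :])
        for part in (s1, s2):
            if rng.random() < 0.3:
                j = int(rng.integers(0, len(part)))
                part[j] = bases[int(rng.integers(0, 4))]
        s1, s2 = "".join(s1), "".join(s2)
        merged = merge_pairs((_read(s1), _read(revcomp(s2))))
        ov = oracle_merge(s1, s2)
        if ov is None:
            assert merged is None
        else:
            assert merged is not None
            assert len(merged.sequence) == len(s1) + len(s2) - ov


# ---------------------------------------------------------------------------
# quality filter, dedup, barcode


def test_quality_filter_thresholds():
    assert quality_filter(_read("A" * 20, qual=chr(33 + 30) * 20))
    # 15% of bases at Q10 -> below the 90% requirement
    q = chr(33 + 10) * 3 + chr(33 + 30) * 17
    assert not quality_filter(_read("A" * 20, qual=q))
    # exactly 90% at Q20: boundary inclusive
    q = chr(33 + 19) * 2 + chr(33 + 20) * 18
    assert quality_filter(_read("A" * 20, qual=q))


def test_deduplicate_exact_sequence():
    reads = [_read("ACGT", rid="a"), _read("ACGT", rid="b"), _read("ACGG", rid="c")]
    kept = list(deduplicate(reads))
    assert [r.read_id for r in kept] == ["a", "c"]
    assert list(deduplicate([])) == []


def test_same_fragment_different_barcode_both_survive_dedup():
    frag = "ACGTACGTACGT"
    reads = [_read("AAAAAA" + frag), _read("CCCCCC" + frag)]
    assert len(list(deduplicate(reads))) == 2


def test_strip_barcode_lengths():
    frag = "ACGTACGTACGT"
    stripped, bc = strip_barcode(_read("TTTTTT" + frag), PRODUCT)
    assert stripped.sequence == frag and bc == "TTTTTT"
    stripped, bc = strip_barcode(_read("GGGG" + frag), OS)
    assert stripped.sequence == frag and bc == "GGGG"
    assert strip_barcode(_read("ACGTA"), PRODUCT) is None


# ---------------------------------------------------------------------------
# assignment


def test_exact_fragment_assigned_with_correct_start(library142):
    assigner = BackboneAssigner([library142])
    v = library142.variants[37]
    seq = to_dna(v.full_sequence)
    hit = assigner.assign(seq[60:])  # suffix spanning the randomized groups
    assert hit is not None
    assert hit.variant_id == v.variant_id
    assert hit.start == 61
    assert hit.distance == 0


def test_fragment_not_spanning_group_is_unassigned(library142):
    assigner = BackboneAssigner([library142])
    v = library142.variants[10]
    seq = to_dna(v.full_sequence)
    # first 40 nt lie upstream of all randomized groups: shared by group-mates
    assert assigner.assign(seq[:40]) is None


def test_one_mismatch_read_assigned(library142):
    assigner = BackboneAssigner([library142])
    v = library142.variants[123]
    seq = to_dna(v.full_sequence)
    frag = list(seq[60:])
    frag[5] = "A" if frag[5] != "A" else "G"
    hit = assigner.assign("".join(frag))
    assert hit is not None
    assert hit.variant_id == v.variant_id
    assert hit.distance == 1


def test_backbone_assigner_equals_exhaustive(library142):
    """The group-decomposition assigner is exactly equivalent to the
    exhaustive placement scan, including mutated and N-containing reads."""
    fast = BackboneAssigner([library142], memoize=False)
    slow = ExhaustiveAssigner([library142])
    rng = np.random.default_rng(17)
    bases = "ACGT"
    n_assigned = 0
    for _ in range(250):
        v = library142.variants[int(rng.integers(0, len(library142)))]
        seq = to_dna(v.full_sequence)
        start = int(rng.integers(0, len(seq) - 19))
        ln = int(rng.integers(15, len(seq) - start + 1))
        frag = list(seq[start : start + ln])
        for _ in range(int(rng.integers(0, 4))):
            j = int(rng.integers(0, len(frag)))
            frag[j] = bases[int(rng.integers(0, 4))]
        if rng.random() < 0.05:
            frag[int(rng.integers(0, len(frag)))] = "N"
        got_fast = fast.assign("".join(frag))
        got_slow = slow.assign("".join(frag))
        assert got_fast == got_slow
        n_assigned += got_fast is not None
    assert n_assigned > 30  # the comparison exercises real assignments
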
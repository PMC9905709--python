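"""CNNC / 17-CRC detection, dot-bracket parsing and S0-S4b classification."""

import itertools
import re

import numpy as np
import pytest

from prica.errors import InputError, PricaError
from prica.motif_structure import (
    STRUCTURE_CLASSES,
    MotifHit,
    PrimiRNARecord,
    SecondaryStructure,
    annotate_primirna_set,
    classify_cnnc_structure,
    find_cnnc,
    find_crc17,
    offset_to_index,
    pair_table_from_dotbracket,
    primary_cnnc_hit,
    read_dotbracket_file,
    record_with_flanks,
    write_dotbracket_file,
)


def flank_sequence(flank: str, upstream: int = 30) -> tuple[str, int]:
    """Build a sequence whose 3' flank (offset -1, -2, ...) equals ``flank``."""
    return "G" * upstream + flank, upstream + 1


# ---------------------------------------------------------------------------
# motif windows


def test_cnnc_at_minus17_detected():
    flank = list("A" * 30)
    for k, base in zip(range(17, 21), "CAGC"):
        flank[k - 1] = base
    seq, cl0 = flank_sequence("".join(flank))
    hits = find_cnnc(seq, cl0)
    assert len(hits) == 1
    assert hits[0].first_offset == -17
    assert hits[0].motif_seq == "CAGC"


def test_non_cnnc_pattern_not_detected():
    flank = list("A" * 30)
    for k, base in zip(range(17, 21), "CAGU"):
        flank[k - 1] = base
    seq, cl0 = flank_sequence("".join(flank))
    assert find_cnnc(seq, cl0) == []


def test_cnnc_span_must_stay_inside_window():
    # first C at -14: the motif exits the [-22, -15] window
    flank = list("A" * 30)
    for k, base in zip(range(14, 18), "CAAC"):
        flank[k - 1] = base
    seq, cl0 = flank_sequence("".join(flank))
    assert find_cnnc(seq, cl0) == []


def test_short_sequence_yields_empty_result():
    seq, cl0 = flank_sequence("CAGC")  # flank far too short
    assert find_cnnc(seq, cl0) == []


def test_find_cnnc_matches_regex_window_oracle():
    rng = np.random.default_rng(23)
    bases = "ACGU"
    for _ in range(2000):
        flank = "".join(bases[i] for i in rng.integers(0, 4, size=30))
        seq, cl0 = flank_sequence(flank)
        hits = {h.first_offset for h in find_cnnc(seq, cl0)}
        window = flank[14:22]  # offsets -15..-22
        oracle = {
            -(15 + m.start()) for m in re.finditer(r"(?=(C..C))", window)
        }
        assert hits == oracle


def test_crc17_window_is_fixed():
    flank = list("A" * 30)
    flank[16], flank[17], flank[18] = "C", "A", "C"  # offsets -17..-19
    seq, cl0 = flank_sequence("".join(flank))
    hit = find_crc17(seq, cl0)
    assert hit is not None and hit.first_offset == -17
    flank[17] = "C"  # R must be A or G
    seq, cl0 = flank_sequence("".join(flank))
    assert find_crc17(seq, cl0) is None
    flank = list("A" * 30)
    flank[17], flank[18], flank[19] = "C", "A", "C"  # shifted to -18..-20
    seq, cl0 = flank_sequence("".join(flank))
    assert find_crc17(seq, cl0) is None


def test_primary_hit_closest_to_minus17():
    h16 = MotifHit("CNNC", -16, "CAAC", (-16, -17, -18, -19), (1, 2, 3, 4))
    h19 = MotifHit("CNNC", -19, "CAAC", (-19, -20, -21, -22), (4, 5, 6, 7))
    assert primary_cnnc_hit([h19, h16]) is h16
    assert primary_cnnc_hit([]) is None


# ---------------------------------------------------------------------------
# dot-bracket parsing


def test_pair_table_examples():
    t = pair_table_from_dotbracket("((..))")
    assert t[1] == 6 and t[6] == 1 and t[2] == 5 and t[5] == 2
    assert t[3] == 0 and t[4] == 0
    assert all(p == 0 for p in pair_table_from_dotbracket("....")[1:])
    with pytest.raises(InputError):
        pair_table_from_dotbracket("((.)")
    with pytest.raises(InputError):
        pair_table_from_dotbracket(".))")


def test_pair_table_symmetry_on_random_structures():
    rng = np.random.default_rng(4)
    for _ in range(100):
        n = int(rng.integers(2, 30))
        db = []
        open_count = 0
        for _ in range(n):
            c = rng.choice(list("(.)"))
            if c == ")" and open_count == 0:
                c = "."
            if c == "(":
                open_count += 1
            elif c == ")":
                open_count -= 1
            db.append(c)
        db.extend(")" * open_count)
        table = pair_table_from_dotbracket("".join(db))
        for i in range(1, table[0] + 1):
            if table[i]:
                assert table[table[i]] == i


# ---------------------------------------------------------------------------
# structure classification


def _hit_at(positions):
    return MotifHit("CNNC", -16, "CNNC", (-16, -17, -18, -19), tuple(positions))


def _db(length, pairs):
    chars = ["."] * length
    for a, b in pairs:
        chars[a - 1], chars[b - 1] = "(", ")"
    return "".join(chars)


def test_classify_examples():
    hit = _hit_at((11, 12, 13, 14))
    assert classify_cnnc_structure(_db(20, []), hit).label == "S0"
    assert classify_cnnc_structure(_db(20, [(5, 11)]), hit).label == "S1"
    # positions 1,2 of the motif paired into one helix
    assert classify_cnnc_structure(_db(20, [(5, 11), (4, 12)]), hit).label == "S2a"
    # positions 1 and 3 paired, 2 unpaired -> split
    assert classify_cnnc_structure(_db(20, [(5, 11), (4, 13)]), hit).label == "S2b"
    # contiguous motif block but partners on two helices -> b
    assert (
        classify_cnnc_structure(_db(20, [(5, 11), (2, 12)]), hit).label == "S2b"
    )


def test_classifier_image_is_exactly_eight_classes():
    """Exhaustive enumeration over pairing masks and nested partner
    arrangements yields exactly the labels S0..S4b."""
    motif = (21, 22, 23, 24)
    hit = _hit_at(motif)
    seen = set()
    partner_pool = list(range(12, 2, -1))  # descending keeps pairs nested
    for mask in itertools.product([0, 1], repeat=4):
        paired_positions = [m for m, keep in zip(motif, mask) if keep]
        k = len(paired_positions)
        for partners in itertools.combinations(partner_pool, k):
            pairs = list(zip(partners, paired_positions))
            label = classify_cnnc_structure(_db(30, pairs), hit).label
            assert label.startswith(f"S{k}")
            seen.add(label)
    assert seen == set(STRUCTURE_CLASSES)


def test_classifier_ignores_nucleotide_identity():
    hit = _hit_at((11, 12, 13, 14))
    db = _db(20, [(5, 11), (4, 12)])
    a = classify_cnnc_structure(SecondaryStructure("A" * 20, db), hit)
    b = classify_cnnc_structure(SecondaryStructure("C" * 20, db), hit)
    assert a == b


def test_classify_motif_outside_structure_errors():
    with pytest.raises(PricaError):
        classify_cnnc_structure(_db(10, []), _hit_at((8, 9, 10, 11)))


# ---------------------------------------------------------------------------
# annotation


def test_annotate_synthetic_set_recovers_constructed_classes():
    from prica.synthetic_data import realise_structure

    records, structures, expected = [], {}, {}
    flank = list("A" * 30)
    for k, base in zip(range(16, 20), "CAGC"):
        flank[k - 1] = base
    seq, cl0 = flank_sequence("".join(flank), upstream=60)
    motif_positions = tuple(offset_to_index(cl0, -(16 + i)) for i in range(4))
    for i, cls in enumerate(STRUCTURE_CLASSES):
        rid = f"rec{i}"
        records.append(PrimiRNARecord(rid, seq, cl0))
        structures[rid] = realise_structure(len(seq), motif_positions, cls)
        expected[rid] = cls
    # a record with no CNNC: excluded from the class denominator
    records.append(PrimiRNARecord("plain", "G" * 60 + "A" * 30, 61))
    structures["plain"] = "." * 90
    table, fractions = annotate_primirna_set(records, structures)
    got = dict(zip(table.record_id, table.structure_class))
    for rid, cls in expected.items():
        assert got[rid] == cls
    assert not table.loc[table.record_id == "plain", "has_cnnc"].iloc[0]
    assert sum(fractions.values()) == pytest.approx(1.0)
    assert all(f == pytest.approx(1 / 8) for f in fractions.values())
    # determinism
    table2, fractions2 = annotate_primirna_set(records, structures)
    assert table.equals(table2) and fractions == fractions2


def test_annotate_flags_provider_failures():
    flank = list("A" * 30)
    for k, base in zip(range(16, 20), "CAGC"):
        flank[k - 1] = base
    seq, cl0 = flank_sequence("".join(flank))
    records = [PrimiRNARecord("ok", seq, cl0), PrimiRNARecord("missing", seq, cl0)]
    structures = {"ok": "." * len(seq)}
    table, fractions = annotate_primirna_set(records, structures)
    assert table.set_index("record_id").loc["missing", "flagged"]
    assert fractions["S0"] == 1.0  # only the intact record counts


def test_record_with_flanks():
    seq = "A" * 100
    rec = record_with_flanks("r", seq, premirna_span=(50, 60), flank=40)
    assert len(rec.sequence) == 40 + 11 + 40
    assert rec.cl0_ref == rec.premirna_span[1] + 1
    # near the sequence end the extension is truncated, not padded
    rec2 = record_with_flanks("r", seq, premirna_span=(80, 95), flank=40)
    assert len(rec2.sequence) == 40 + 16 + 5


def test_dotbracket_file_roundtrip(tmp_path):
    entries = [("a", "ACGU", "(..)"), ("b", "GGGG", "....")]
    path = tmp_path / "structures.txt"
    write_dotbracket_file(path, entries)
    assert read_dotbracket_file(path) == {"a": "(..)", "b": "...."}
    with pytest.raises(InputError):
        write_dotbracket_file(path, [("c", "ACGU", "(.)")])
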
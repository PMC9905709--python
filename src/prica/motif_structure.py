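"""CNNC / 17-CRC motif detection and CNNC secondary-structure classification.

Offsets on the 3' flank are counted from the 3'-strand cut: the first
nucleotide 3' of the CL0 cut is offset -1, so offset -k corresponds to
sequence index ``cl0_ref + k - 1`` (1-based).  CNNC (C-N-N-C) is searched
with its full 4-nt span inside offsets [-22, -15]; the 17-CRC motif
(C-(A|G)-C) occupies offsets -17, -18, -19 exactly.

A CNNC occurrence in a secondary structure is classified by how many of its
four nucleotides are base-paired (S0..S4) and, for two or more pairs,
whether the paired nucleotides form one uninterrupted helix — a contiguous
block of motif positions whose partners are a strictly contiguous
antiparallel run — ("a") or not ("b").  Classification depends only on the
pairing pattern, never on nucleotide identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from ._seq import to_rna
from .errors import InputError, PricaError

CNNC_WINDOW = (-22, -15)  # full motif span must lie inside this offset window
CRC17_OFFSETS = (-17, -18, -19)
STRUCTURE_CLASSES = ("S0", "S1", "S2a", "S2b", "S3a", "S3b", "S4a", "S4b")

CNNC = "CNNC"
CRC17 = "CRC17"


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence on the 3' flank.

    ``first_offset`` is the (negative) offset of the motif's 5'-most
    nucleotide; ``positions`` are the matching 1-based sequence indices.
    """

    motif_kind: str
    first_offset: int
    motif_seq: str
    span: tuple[int, ...]  # offsets covered, e.g. (-16, -17, -18, -19)
    positions: tuple[int, ...]  # 1-based sequence indices


@dataclass(frozen=True)
class StructureClass:
    label: str
    n_paired: int
    consecutive: bool | None  # None for S0/S1 (no a/b split)


def offset_to_index(cl0_ref: int, offset: int) -> int:
    """1-based sequence index of flank offset -k (offset must be negative)."""
    if offset >= 0:
        raise PricaError("flank offsets are negative (-1 = first nt 3' of the cut)")
    return cl0_ref - offset - 1


def find_cnnc(sequence: str, cl0_ref: int) -> list[MotifHit]:
    """All C-N-N-C occurrences whose span lies within offsets [-22, -15].

    Ordered by |first_offset| (closest to the cut first).  Returns an empty
    list when the sequence does not extend far enough past the cut.
    """
    seq = to_rna(sequence)
    lo, hi = CNNC_WINDOW  # -22, -15
    hits = []
    for first in range(-hi, -lo - 2):  # first offset magnitude 15..20, span check below
        offsets = tuple(-(first + i) for i in range(4))
        if offsets[-1] < lo:
            continue
        idx = tuple(offset_to_index(cl0_ref, o) for o in offsets)
        if idx[-1] > len(seq):
            continue
        bases = "".join(seq[i - 1] for i in idx)
        if bases[0] == "C" and bases[3] == "C":
            hits.append(MotifHit(CNNC, -first, bases, offsets, idx))
    return hits


def find_crc17(sequence: str, cl0_ref: int) -> MotifHit | None:
    """The 17-CRC motif: C,(A|G),C at offsets -17, -18, -19 exactly."""
    seq = to_rna(sequence)
    idx = tuple(offset_to_index(cl0_ref, o) for o in CRC17_OFFSETS)
    if idx[-1] > len(seq):
        return None
    bases = "".join(seq[i - 1] for i in idx)
    if bases[0] == "C" and bases[1] in "AG" and bases[2] == "C":
        return MotifHit(CRC17, CRC17_OFFSETS[0], bases, CRC17_OFFSETS, idx)
    return None


def primary_cnnc_hit(hits: Sequence[MotifHit]) -> MotifHit | None:
    """The hit used for structure classification: closest to offset -17
    (the distance at which the motif is typically found), ties toward the cut."""
    if not hits:
        return None
    return min(hits, key=lambda h: (abs(h.first_offset + 17), abs(h.first_offset)))


# ---------------------------------------------------------------------------
# secondary structure


def pair_table_from_dotbracket(db: str) -> list[int]:
    """1-based pair table from a dot-bracket string.

    Returns a list of length len(db)+1; entry i is the partner of position i
    (0 when unpaired); entry 0 holds the length.  Only '.', '(' and ')' are
    accepted; unbalanced brackets raise :class:`InputError`.
    """
    n = len(db)
    table = [0] * (n + 1)
    table[0] = n
    stack: list[int] = []
    for i, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise InputError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise InputError(f"unsupported character {ch!r} at position {i}")
    if stack:
        raise InputError(f"unbalanced '(' at position {stack[-1]}")
    return table


@dataclass(frozen=True)
class SecondaryStructure:
    """A dot-bracket annotation of a sequence, with its pair table."""

    sequence: str
    dotbracket: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise InputError("sequence and structure lengths differ")

    @property
    def pair_table(self) -> list[int]:
        return pair_table_from_dotbracket(self.dotbracket)


def classify_cnnc_structure(
    structure: SecondaryStructure | str, hit: MotifHit
) -> StructureClass:
    """Classify a CNNC occurrence into S0..S4b from its pairing pattern.

    n_paired counts motif nucleotides with a partner.  For n_paired >= 2 the
    class is 'a' (consecutive) iff the paired motif positions form one
    contiguous block and their partners descend strictly one-by-one (a single
    antiparallel helix); otherwise 'b'.
    """
    table = (
        pair_table_from_dotbracket(structure)
        if isinstance(structure, str)
        else structure.pair_table
    )
    n = table[0]
    if any(p < 1 or p > n for p in hit.positions):
        raise PricaError("motif positions lie outside the structure span")
    paired = [(p, table[p]) for p in hit.positions if table[p] != 0]
    k = len(paired)
    if k <= 1:
        return StructureClass(f"S{k}", k, None)
    pos = [p for p, _ in paired]
    partners = [q for _, q in paired]
    contiguous_block = pos[-1] - pos[0] == len(pos) - 1
    antiparallel_run = all(
        partners[i + 1] == partners[i] - 1 for i in range(len(partners) - 1)
    )
    consecutive = contiguous_block and antiparallel_run
    return StructureClass(f"S{k}{'a' if consecutive else 'b'}", k, consecutive)


# ---------------------------------------------------------------------------
# annotation of pri-miRNA sets


@dataclass(frozen=True)
class PrimiRNARecord:
    """A hairpin to annotate: sequence, cut reference, optional pre-miRNA span."""

    record_id: str
    sequence: str
    cl0_ref: int
    premirna_span: tuple[int, int] | None = None


def record_with_flanks(
    record_id: str,
    full_sequence: str,
    premirna_span: tuple[int, int],
    flank: int = 40,
) -> PrimiRNARecord:
    """Cut a hairpin record down to pre-miRNA plus ``flank``-nt extensions
    (shorter where the supplied sequence ends), with cl0 at the first
    nucleotide 3' of the pre-miRNA."""
    lo, hi = premirna_span
    start = max(1, lo - flank)
    end = min(len(full_sequence), hi + flank)
    sub = full_sequence[start - 1 : end]
    return PrimiRNARecord(
        record_id=record_id,
        sequence=sub,
        cl0_ref=hi - start + 2,  # first nt 3' of the pre-miRNA, in sub coords
        premirna_span=(lo - start + 1, hi - start + 1),
    )


StructureProvider = Callable[[PrimiRNARecord], str]


class FileStructureProvider:
    """Dot-bracket lookup backed by a dict or a structures file."""

    def __init__(self, structures: Mapping[str, str]):
        self._structures = dict(structures)

    @classmethod
    def from_file(cls, path: str | Path) -> "FileStructureProvider":
        return cls(read_dotbracket_file(path))

    def __call__(self, record: PrimiRNARecord) -> str:
        try:
            return self._structures[record.record_id]
        except KeyError as exc:
            raise InputError(f"no structure for record {record.record_id}") from exc


def annotate_primirna_set(
    records: Iterable[PrimiRNARecord],
    structure_provider: StructureProvider | Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Motif hits and structure classes for a set of hairpin records.

    Returns the per-record annotation table and the class fractions among
    CNNC-containing records.  Records whose structure provider fails are
    flagged and excluded from the fractions.
    """
    if isinstance(structure_provider, Mapping):
        structure_provider = FileStructureProvider(structure_provider)
    rows = []
    for rec in records:
        cnnc_hits = find_cnnc(rec.sequence, rec.cl0_ref)
        crc = find_crc17(rec.sequence, rec.cl0_ref)
        primary = primary_cnnc_hit(cnnc_hits)
        row = dict(
            record_id=rec.record_id,
            has_cnnc=bool(cnnc_hits),
            n_cnnc_hits=len(cnnc_hits),
            cnnc_offset=primary.first_offset if primary else pd.NA,
            cnnc_seq=primary.motif_seq if primary else "",
            has_crc17=crc is not None,
            motif_kind=CNNC if cnnc_hits else (CRC17 if crc else "none"),
            structure_class="",
            flagged=False,
        )
        if primary is not None:
            try:
                db = structure_provider(rec)
                structure = SecondaryStructure(rec.sequence, db)
                row["structure_class"] = classify_cnnc_structure(structure, primary).label
            except (InputError, PricaError):
                row["flagged"] = True
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table.has_cnnc & ~table.flagged]
    total = len(ok)
    fractions = {
        cls: (float((ok.structure_class == cls).sum()) / total if total else 0.0)
        for cls in STRUCTURE_CLASSES
    }
    return table, fractions


# ---------------------------------------------------------------------------
# dot-bracket file I/O  (FASTA-like: >id / sequence / structure)


def read_dotbracket_file(path: str | Path) -> dict[str, str]:
    structures: dict[str, str] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise InputError(f"{path}: expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise InputError(f"{path}: truncated record {lines[i]!r}")
        structures[lines[i][1:].split()[0]] = lines[i + 2]
        i += 3
    return structures


def write_dotbracket_file(
    path: str | Path, entries: Iterable[tuple[str, str, str]]
) -> None:
    """Write (id, sequence, dotbracket) triples."""
    with open(path, "w") as fh:
        for rid, seq, db in entries:
            if len(seq) != len(db):
                raise InputError(f"{rid}: sequence/structure length mismatch")
            fh.write(f">{rid}\n{seq}\n{db}\n")
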
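"""Small sequence-alphabet helpers.

Substrates are RNA, sequencing reads are DNA; everything is normalized to one
alphabet at module boundaries (RNA/U inside backbone specs, DNA/T at the read
level and in FASTA output).
"""

from __future__ import annotations

_RNA_TRANS = str.maketrans("acgtuT", "ACGUUU")
_DNA_TRANS = str.maketrans("acgtuU", "ACGTTT")
_DNA_COMP = str.maketrans("ACGTN", "TGCAN")

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGTN")


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.translate(_RNA_TRANS)


def to_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.translate(_DNA_TRANS)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N stays N)."""
    return seq.translate(_DNA_COMP)[::-1]
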
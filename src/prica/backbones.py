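"""Built-in synthetic demo backbones.

The published assay used pri-miR-142 and pri-miR-191 with three randomized
groups in and around the CNNC motif of the 3' flank; the complete scaffolds
are not available as machine-readable text, so the shipped backbones are
synthetic hairpins that reproduce the published layout:

* group 1 sits on the CNNC motif (offsets -16..-19 from the 3'-strand cut),
* group 2 immediately upstream (offsets -12..-15, toward the cut),
* group 3 immediately downstream (offsets -20..-23),
* basal canonical sites {CL0, CL1} for the miR-142-like backbone and {CL0}
  for the miR-191-like backbone,
* a 3' RA3 adapter on the library construct.

Each wild-type flank carries exactly one CNNC occurrence inside the
[-22, -15] detection window and no 17-CRC, so motif gains and losses are
driven entirely by the randomized groups.

Offset convention: the first nucleotide 3' of the CL0 cut is offset -1, i.e.
offset -k is sequence index ``cl0_ref + k - 1`` (1-based).
"""

from __future__ import annotations

from .library_design import BackboneSpec, RandomizedGroup

RA3_ADAPTER_DNA = "TGGAATTCTCGGGTGCCAAGG"
RA5_ADAPTER_RC_DNA = "GATCGTCGGACTGTAGAACTCTGAAC"  # R2 3' adapter (rc of RA5 end)


def _assemble(flank5: str, stem5: str, loop: str, stem3: str, flank3: str) -> str:
    return flank5 + stem5 + loop + stem3 + flank3


# 103-nt scaffolds: 20-nt 5' flank, 24-nt 5p strand, 12-nt loop, 24-nt 3p
# strand, 23-nt 3' flank.  cl0_ref = 81 (first nt 3' of the basal cut).
_SEQ_142 = _assemble(
    "GGGAAGAGUACACGCCGACG",
    "GACAGUGCAGUCUAGCACUGGUCA",
    "UUCAAGACUGAA",
    "UGACCAGUGCUAGACUGCACUGUC",
    # offsets -1..-11, then group2 (-12..-15), group1/CNNC (-16..-19),
    # group3 (-20..-23)
    "AUCUCAUCCAU" + "GGUA" + "CAGC" + "AGUU",
)

_SEQ_191 = _assemble(
    "GGGACUGAUCCGGUCAAUCG",
    "CAUCGGAUCUGGAGCUUAGCCAUA",
    "CGAAUCUUCGGA",
    "UAUGGCUAAGCUCCAGAUCCGAUG",
    "UACUAUCCUAU" + "ACUA" + "CUAC" + "GAUU",
)


def _groups(cl0: int) -> tuple[RandomizedGroup, ...]:
    def span(first_offset: int) -> tuple[int, ...]:
        # offsets first_offset..first_offset-3, ascending sequence index
        return tuple(cl0 + k - 1 for k in range(first_offset, first_offset + 4))

    return (
        RandomizedGroup(1, span(16)),  # CNNC position, offsets -16..-19
        RandomizedGroup(2, span(12)),  # upstream, offsets -12..-15
        RandomizedGroup(3, span(20)),  # downstream, offsets -20..-23
    )


def mir142_like() -> BackboneSpec:
    """Synthetic backbone emulating the pri-miR-142 design (canonical CL0, CL1)."""
    return BackboneSpec(
        name="syn142",
        sequence=_SEQ_142,
        groups=_groups(81),
        cl0_ref=81,
        canonical_sites=frozenset({0, 1}),
        premirna_span=(21, 80),
        adapter_3p=RA3_ADAPTER_DNA,
    )


def mir191_like() -> BackboneSpec:
    """Synthetic backbone emulating the pri-miR-191 design (canonical CL0)."""
    return BackboneSpec(
        name="syn191",
        sequence=_SEQ_191,
        groups=_groups(81),
        cl0_ref=81,
        canonical_sites=frozenset({0}),
        premirna_span=(21, 80),
        adapter_3p=RA3_ADAPTER_DNA,
    )


def demo_backbones() -> list[BackboneSpec]:
    """The two shipped demo backbones (miR-142-like and miR-191-like)."""
    return [mir142_like(), mir191_like()]
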
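"""Backbone definitions and randomized variant-library enumeration.

A *backbone* is a pri-miRNA scaffold carrying one or more randomized groups of
exactly four nucleotide positions.  Substituting every 4-mer over {A,C,G,U} at
each group and collapsing identical full-length sequences yields the variant
library that all downstream read assignment and scoring is anchored to.  With
three disjoint groups sharing one wild-type sequence this gives
3 x 4^4 - 2 = 766 unique variants per backbone (the WT sequence arises once in
every group and is kept once).

Coordinates are 1-based throughout.  ``cl0_ref`` is the index of the first
nucleotide of the canonical 3'-cleavage product (the F3 fragment), i.e. the
nucleotide immediately 3' of the canonical 3'-strand cut.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import RNA_ALPHABET, to_dna, to_rna
from .errors import ConfigError, PricaError

RNA_BASES = "ACGU"
GROUP_WIDTH = 4  # library design is fixed-width by construction


@dataclass(frozen=True)
class RandomizedGroup:
    """One randomized block of four positions within a backbone."""

    group_id: int
    positions: tuple[int, ...]  # 1-based, strictly increasing
    wt_nt: str = ""  # filled in by BackboneSpec validation

    def __post_init__(self) -> None:
        if len(self.positions) != GROUP_WIDTH:
            raise ConfigError(
                f"group {self.group_id}: randomized groups are fixed at "
                f"{GROUP_WIDTH} positions, got {len(self.positions)}"
            )
        if list(self.positions) != sorted(set(self.positions)):
            raise ConfigError(
                f"group {self.group_id}: positions must be strictly increasing"
            )


@dataclass(frozen=True)
class BackboneSpec:
    """A pri-miRNA scaffold with randomized groups and cleavage reference.

    Attributes
    ----------
    name:
        Identifier, used as a prefix for variant ids.
    sequence:
        Full pri-miRNA sequence, 5'->3', normalized to RNA (U) on construction.
    groups:
        Randomized groups (disjoint position sets).
    cl0_ref:
        1-based index of the first nucleotide of the canonical F3 fragment.
    canonical_sites:
        CLx indices counted as basal-canonical cleavage (subset of [-3, 3]).
    premirna_span:
        1-based closed interval of the pre-miRNA within ``sequence``.
    adapter_3p:
        Literal 3' adapter appended downstream in library constructs.
    """

    name: str
    sequence: str
    groups: tuple[RandomizedGroup, ...]
    cl0_ref: int
    canonical_sites: frozenset[int]
    premirna_span: tuple[int, int]
    adapter_3p: str = ""

    def __post_init__(self) -> None:
        seq = to_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "adapter_3p", to_rna(self.adapter_3p))
        object.__setattr__(self, "canonical_sites", frozenset(self.canonical_sites))
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ConfigError(f"{self.name}: non-ACGU/T characters {sorted(bad)!r}")
        n = len(seq)
        if not 1 <= self.cl0_ref <= n:
            raise ConfigError(f"{self.name}: cl0_ref {self.cl0_ref} outside 1..{n}")
        if not self.canonical_sites <= set(range(-3, 4)):
            raise ConfigError(f"{self.name}: canonical_sites must lie in [-3, 3]")
        lo, hi = self.premirna_span
        if not 1 <= lo <= hi <= n:
            raise ConfigError(f"{self.name}: invalid premirna_span {self.premirna_span}")
        seen: set[int] = set()
        groups = []
        for g in sorted(self.groups, key=lambda g: g.group_id):
            if any(p < 1 or p > n for p in g.positions):
                raise ConfigError(
                    f"{self.name}: group {g.group_id} positions outside sequence"
                )
            if seen & set(g.positions):
                raise ConfigError(f"{self.name}: randomized groups overlap")
            seen |= set(g.positions)
            wt = "".join(seq[p - 1] for p in g.positions)
            if g.wt_nt and to_rna(g.wt_nt) != wt:
                raise ConfigError(
                    f"{self.name}: group {g.group_id} wt_nt {g.wt_nt!r} does not "
                    f"match backbone sequence {wt!r}"
                )
            groups.append(RandomizedGroup(g.group_id, tuple(g.positions), wt))
        object.__setattr__(self, "groups", tuple(groups))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wt_mer(self, group_id: int) -> str:
        for g in self.groups:
            if g.group_id == group_id:
                return g.wt_nt
        raise KeyError(group_id)


@dataclass(frozen=True)
class Variant:
    """One library member: a backbone with a single group substituted."""

    variant_id: str
    backbone: str
    group_id: int
    substituted_nt: str
    full_sequence: str
    wt: bool = False


@dataclass
class VariantLibrary:
    """All unique variants of one backbone, with a sequence index."""

    backbone: BackboneSpec
    variants: list[Variant] = field(default_factory=list)
    index: dict[str, str] = field(default_factory=dict)  # full_sequence -> variant_id

    @property
    def name(self) -> str:
        return self.backbone.name

    def __len__(self) -> int:
        return len(self.variants)

    def by_id(self) -> dict[str, Variant]:
        return {v.variant_id: v for v in self.variants}


def enumerate_variants(backbone: BackboneSpec) -> VariantLibrary:
    """Enumerate every 4-mer substitution at every randomized group.

    Identical full sequences are collapsed to a single :class:`Variant`
    keeping the first-encountered group's record (the WT sequence arises in
    every group and is retained once, tagged ``wt=True``).  Ordering is
    deterministic: by group_id, then lexicographic 4-mer.
    """
    if not backbone.groups:
        raise ConfigError(f"{backbone.name}: backbone has no randomized groups")
    lib = VariantLibrary(backbone=backbone)
    seq = backbone.sequence
    for g in backbone.groups:
        for mer_t in itertools.product(RNA_BASES, repeat=GROUP_WIDTH):
            mer = "".join(mer_t)
            chars = list(seq)
            for pos, nt in zip(g.positions, mer):
                chars[pos - 1] = nt
            full = "".join(chars)
            if full in lib.index:
                continue
            vid = f"{backbone.name}_g{g.group_id}_{to_dna(mer)}"
            lib.variants.append(
                Variant(
                    variant_id=vid,
                    backbone=backbone.name,
                    group_id=g.group_id,
                    substituted_nt=mer,
                    full_sequence=full,
                    wt=(full == seq),
                )
            )
            lib.index[full] = vid
    return lib


def build_reference_set(
    libraries: VariantLibrary | Iterable[VariantLibrary],
    include_adapter: bool = False,
) -> list[SeqRecord]:
    """One DNA record per variant (id = variant_id), suitable for FASTA output."""
    if isinstance(libraries, VariantLibrary):
        libraries = [libraries]
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for lib in libraries:
        if not lib.variants:
            raise PricaError(f"library {lib.name} is empty")
        adapter = to_dna(lib.backbone.adapter_3p) if include_adapter else ""
        for v in lib.variants:
            if v.variant_id in seen:
                raise PricaError(f"duplicate variant_id {v.variant_id}")
            seen.add(v.variant_id)
            records.append(
                SeqRecord(
                    Seq(to_dna(v.full_sequence) + adapter),
                    id=v.variant_id,
                    description="",
                )
            )
    return records


def write_reference_fasta(
    libraries: VariantLibrary | Iterable[VariantLibrary],
    path: str | Path,
    include_adapter: bool = False,
) -> int:
    records = build_reference_set(libraries, include_adapter=include_adapter)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return len(records)


# ---------------------------------------------------------------------------
# config I/O


def _backbone_to_dict(bb: BackboneSpec) -> dict:
    return {
        "name": bb.name,
        "sequence": bb.sequence,
        "cl0_ref": bb.cl0_ref,
        "canonical_sites": sorted(bb.canonical_sites),
        "premirna_span": list(bb.premirna_span),
        "adapter_3p": bb.adapter_3p,
        "groups": [
            {"group_id": g.group_id, "positions": list(g.positions)}
            for g in bb.groups
        ],
    }


def _backbone_from_dict(d: dict) -> BackboneSpec:
    try:
        groups = tuple(
            RandomizedGroup(int(g["group_id"]), tuple(int(p) for p in g["positions"]))
            for g in d["groups"]
        )
        return BackboneSpec(
            name=str(d["name"]),
            sequence=str(d["sequence"]),
            groups=groups,
            cl0_ref=int(d["cl0_ref"]),
            canonical_sites=frozenset(int(x) for x in d["canonical_sites"]),
            premirna_span=tuple(int(x) for x in d["premirna_span"]),  # type: ignore[arg-type]
            adapter_3p=str(d.get("adapter_3p", "")),
        )
    except KeyError as exc:
        raise ConfigError(f"backbone config missing field {exc}") from exc


def load_backbone_config(path: str | Path) -> list[BackboneSpec]:
    """Load and validate backbone specs from a YAML file.

    The file holds ``backbones: [...]`` with keys name, sequence,
    groups[].positions, cl0_ref, canonical_sites, premirna_span, adapter_3p.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "backbones" not in data:
        raise ConfigError(f"{path}: expected a top-level 'backbones' list")
    return [_backbone_from_dict(d) for d in data["backbones"]]


def save_backbone_config(backbones: Sequence[BackboneSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"backbones": [_backbone_to_dict(bb) for bb in backbones]},
            fh,
            sort_keys=False,
        )
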
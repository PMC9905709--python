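"""Cleavage-site calling and per-variant count profiles.

The 3'-strand cut of Microprocessor is read out by the 5' end of the cleaved
F3 fragment.  Sites are indexed as CLx with x = cl0_ref - start: CL0 is the
annotated canonical cut, positive x runs toward the apical loop (apical
cleavage appears at CL8..CL14 because those F3 fragments start further 5' on
the hairpin), negative x lies 3' of the canonical cut.

Categories partition the integers: basal sites span CL-3..CL3 (canonical if
listed in the backbone's canonical set, alternative otherwise), apical sites
span CL8..CL14, everything else is "other" (e.g. CL-4 and CL5).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import PricaError
from .library_design import BackboneSpec
from .read_processing import OS, PRODUCT, ProcessedFragment

BASAL_RANGE = range(-3, 4)
APICAL_RANGE = range(8, 15)

BASAL_CANONICAL = "BASAL_CANONICAL"
BASAL_ALTERNATIVE = "BASAL_ALTERNATIVE"
APICAL = "APICAL"
OTHER = "OTHER"


def call_site(fragment: ProcessedFragment, backbone: BackboneSpec) -> int:
    """CLx index of a product fragment: x = cl0_ref - start."""
    if fragment.library_kind != PRODUCT:
        raise PricaError("call_site is defined for PRODUCT fragments only")
    return backbone.cl0_ref - fragment.start


def categorize_site(x: int, backbone: BackboneSpec) -> str:
    if x in backbone.canonical_sites:
        return BASAL_CANONICAL
    if x in BASAL_RANGE:
        return BASAL_ALTERNATIVE
    if x in APICAL_RANGE:
        return APICAL
    return OTHER


@dataclass
class CleavageProfile:
    """Counts for one (variant, condition, replicate).

    ``n_s`` counts original-substrate fragments, ``counts`` maps CLx to
    product fragment counts; values may be raw counts or CPM.
    """

    variant_id: str
    backbone: str
    condition: str
    replicate: int
    n_s: float = 0.0
    counts: dict[int, float] = field(default_factory=dict)

    @property
    def n_p(self) -> float:
        return sum(self.counts.values())


def build_profiles(
    fragments: Iterable[ProcessedFragment],
    variant_backbone: Mapping[str, BackboneSpec],
    condition: str,
    replicate: int,
) -> list[CleavageProfile]:
    """Tally fragments of one sequencing run into per-variant profiles.

    OS fragments increment ``n_s``; PRODUCT fragments increment the count of
    their called site.  Fragments referencing unknown variants raise.
    """
    profiles: dict[str, CleavageProfile] = {}
    for frag in fragments:
        bb = variant_backbone.get(frag.variant_id)
        if bb is None:
            raise PricaError(f"fragment references unknown variant {frag.variant_id}")
        prof = profiles.get(frag.variant_id)
        if prof is None:
            prof = profiles[frag.variant_id] = CleavageProfile(
                frag.variant_id, bb.name, condition, replicate
            )
        if frag.library_kind == OS:
            prof.n_s += 1
        else:
            x = call_site(frag, bb)
            prof.counts[x] = prof.counts.get(x, 0) + 1
    return [profiles[k] for k in sorted(profiles)]


def canonical_alternative_ratio(
    profile: CleavageProfile, backbone: BackboneSpec
) -> float | None:
    """Canonical / basal-alternative product-count ratio; None when no
    alternative counts exist (apical and other sites are excluded)."""
    canon = sum(c for x, c in profile.counts.items() if x in backbone.canonical_sites)
    alt = sum(
        c
        for x, c in profile.counts.items()
        if x in BASAL_RANGE and x not in backbone.canonical_sites
    )
    if alt == 0:
        return None
    return canon / alt


def cl_minus2_ratio(profile: CleavageProfile) -> float | None:
    """CL-2 / (CL0 + CL1) isoform ratio; None when the denominator is zero."""
    denom = profile.counts.get(0, 0) + profile.counts.get(1, 0)
    if denom == 0:
        return None
    return profile.counts.get(-2, 0) / denom


def category_summary(
    profiles: Iterable[CleavageProfile],
    backbones: Mapping[str, BackboneSpec],
) -> pd.DataFrame:
    """Product-read fractions per cleavage category, by backbone and condition."""
    agg: dict[tuple[str, str], dict[str, float]] = defaultdict(
        lambda: {BASAL_CANONICAL: 0.0, BASAL_ALTERNATIVE: 0.0, APICAL: 0.0, OTHER: 0.0}
    )
    for prof in profiles:
        bb = backbones[prof.backbone]
        cell = agg[(prof.backbone, prof.condition)]
        for x, c in prof.counts.items():
            cell[categorize_site(x, bb)] += c
    rows = []
    for (backbone, condition), cats in sorted(agg.items()):
        total = sum(cats.values())
        row = {"backbone": backbone, "condition": condition, "n_product": total}
        for cat, c in cats.items():
            row[f"frac_{cat.lower()}"] = c / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: Iterable[CleavageProfile]) -> pd.DataFrame:
    """Tidy long-format table: one row per (variant, condition, replicate, site),
    plus n_s repeated; inverse of :func:`frame_to_profiles`."""
    rows = []
    for p in profiles:
        if not p.counts:
            rows.append(
                dict(
                    variant_id=p.variant_id, backbone=p.backbone, condition=p.condition,
                    replicate=p.replicate, site=pd.NA, count=0.0, n_s=p.n_s,
                )
            )
        for x in sorted(p.counts):
            rows.append(
                dict(
                    variant_id=p.variant_id, backbone=p.backbone, condition=p.condition,
                    replicate=p.replicate, site=x, count=p.counts[x], n_s=p.n_s,
                )
            )
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[CleavageProfile]:
    out: list[CleavageProfile] = []
    keys = ["variant_id", "backbone", "condition", "replicate"]
    for (vid, bb, cond, rep), grp in df.groupby(keys, sort=True):
        counts = {
            int(r.site): float(r.count)
            for r in grp.itertuples()
            if pd.notna(r.site) and r.count
        }
        out.append(
            CleavageProfile(vid, bb, cond, int(rep), float(grp.n_s.iloc[0]), counts)
        )
    return out
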
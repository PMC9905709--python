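"""Count normalization and cleavage efficiency / accuracy scoring.

Counts are normalized to CPM (counts per million) independently within each
sequencing library (OS and product libraries separately, per condition and
replicate).  Scores per variant and condition:

* global efficiency  E_P = log2(N_P + 0.1) - log2(N_S + 0.1)
* local efficiency   E_X = log2(N_X + 0.1) - log2(N_S + 0.1)
* accuracy           A_X = N_X / N_P          (undefined when N_P = 0)

with the 0.1 pseudocount applied on the CPM scale.  Scores are averaged over
replicates cell-wise; cells undefined in a replicate are excluded from that
cell's mean.  Cofactor effects are plain differences against the MP-alone
condition: dA_X = A_X[MP+cofactor] - A_X[MP], and likewise dE_P, dE_X.

The human-library filtering step works on external score rows (cleavage
efficiency = productive products / substrate; homogeneity = maximum cleavage
ratio among productive sites) with strict thresholds efficiency > 1 and
homogeneity > 0.1.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cleavage_calling import CleavageProfile
from .errors import PricaError

PSEUDOCOUNT = 0.1
CPM_SCALE = 1_000_000.0
DEFAULT_SITE_DOMAIN = tuple(range(-3, 4)) + tuple(range(8, 15))


def normalize_cpm(profiles: Iterable[CleavageProfile]) -> list[CleavageProfile]:
    """CPM-normalize profiles; OS and product libraries independently.

    Within each (condition, replicate): substrate counts are scaled by the
    total substrate reads of that library, product counts by the total
    product reads, each to one million.  Empty libraries yield zeros.
    """
    profiles = list(profiles)
    os_totals: dict[tuple[str, int], float] = {}
    p_totals: dict[tuple[str, int], float] = {}
    for p in profiles:
        key = (p.condition, p.replicate)
        os_totals[key] = os_totals.get(key, 0.0) + p.n_s
        p_totals[key] = p_totals.get(key, 0.0) + p.n_p
    out = []
    for p in profiles:
        key = (p.condition, p.replicate)
        os_t, p_t = os_totals[key], p_totals[key]
        out.append(
            CleavageProfile(
                p.variant_id,
                p.backbone,
                p.condition,
                p.replicate,
                n_s=p.n_s * CPM_SCALE / os_t if os_t else 0.0,
                counts={
                    x: c * CPM_SCALE / p_t if p_t else 0.0
                    for x, c in p.counts.items()
                },
            )
        )
    return out


def compute_scores(
    norm_profiles: Iterable[CleavageProfile],
    site_domain: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-replicate score table from CPM-normalized profiles.

    Returns a tidy frame with one row per (variant, condition, replicate,
    site) carrying N_S/N_X/N_P and E_P/E_X/A_X.  The site domain defaults to
    the basal and apical ranges plus every observed site, so that A_X sums
    to one over the rows of any variant with products.
    """
    norm_profiles = list(norm_profiles)
    observed = sorted(
        set(DEFAULT_SITE_DOMAIN if site_domain is None else site_domain)
        | {x for p in norm_profiles for x in p.counts}
    )
    rows = []
    for p in norm_profiles:
        if p.n_s < 0 or any(c < 0 for c in p.counts.values()):
            raise PricaError("negative counts")
        n_p = p.n_p
        e_p = math.log2(n_p + PSEUDOCOUNT) - math.log2(p.n_s + PSEUDOCOUNT)
        for x in observed:
            n_x = p.counts.get(x, 0.0)
            rows.append(
                dict(
                    backbone=p.backbone,
                    variant_id=p.variant_id,
                    condition=p.condition,
                    replicate=p.replicate,
                    site=x,
                    n_s=p.n_s,
                    n_x=n_x,
                    n_p=n_p,
                    e_p=e_p,
                    e_x=math.log2(n_x + PSEUDOCOUNT) - math.log2(p.n_s + PSEUDOCOUNT),
                    a_x=n_x / n_p if n_p > 0 else np.nan,
                )
            )
    return pd.DataFrame(rows)


def average_replicates(scores: pd.DataFrame) -> pd.DataFrame:
    """Cell-wise arithmetic mean over replicates.

    Cells undefined in a replicate (A_X with N_P = 0) are excluded from that
    cell's mean; ``n_defined`` counts contributing replicates and is 0 for
    variants with no products in any replicate.
    """
    keys = ["backbone", "variant_id", "condition", "site"]
    per_variant = scores.groupby(["backbone", "variant_id", "condition"])[
        "replicate"
    ].nunique()
    expected = per_variant.groupby(["backbone", "variant_id"]).max()
    if (per_variant.groupby(["backbone", "variant_id"]).min() != expected).any():
        raise PricaError("replicate sets differ between conditions for some variants")
    agg = scores.groupby(keys, sort=True).agg(
        e_p=("e_p", "mean"),
        e_x=("e_x", "mean"),
        a_x=("a_x", "mean"),  # pandas mean skips NaN: masked mean
        n_defined=("a_x", "count"),
        n_reps=("replicate", "nunique"),
    )
    return agg.reset_index()


def delta_scores(
    averaged: pd.DataFrame, cofactor_condition: str, baseline: str = "MP"
) -> pd.DataFrame:
    """Cofactor-minus-baseline differences on replicate-averaged tables.

    Undefined cells (NaN) propagate into undefined deltas.
    """
    keys = ["backbone", "variant_id", "site"]
    cols = keys + ["e_p", "e_x", "a_x"]
    mp = averaged.loc[averaged.condition == baseline, cols]
    cf = averaged.loc[averaged.condition == cofactor_condition, cols]
    if cf.empty:
        raise PricaError(f"no rows for condition {cofactor_condition!r}")
    merged = cf.merge(mp, on=keys, suffixes=("_cf", "_mp"), how="inner")
    merged["cofactor"] = cofactor_condition
    merged["delta_e_p"] = merged.e_p_cf - merged.e_p_mp
    merged["delta_e_x"] = merged.e_x_cf - merged.e_x_mp
    merged["delta_a_x"] = merged.a_x_cf - merged.a_x_mp
    return merged[keys + ["cofactor", "delta_e_p", "delta_e_x", "delta_a_x"]]


def homogeneity(
    profile: CleavageProfile, productive_sites: Iterable[int]
) -> float | None:
    """Maximum cleavage ratio N_X / N_P over the productive window; None when
    the variant has no products at all."""
    n_p = profile.n_p
    if n_p == 0:
        return None
    return max(profile.counts.get(x, 0.0) for x in productive_sites) / n_p


def productive_window(canonical_sites: Iterable[int], margin: int = 3) -> list[int]:
    """Sites within +/- ``margin`` of any annotated canonical site."""
    sites = {c + d for c in canonical_sites for d in range(-margin, margin + 1)}
    return sorted(sites)


def select_processed_primirnas(
    rows: pd.DataFrame,
    min_efficiency: float = 1.0,
    min_homogeneity: float = 0.1,
) -> pd.DataFrame:
    """Keep rows with cleavage efficiency and homogeneity strictly above the
    thresholds (defaults 1 and 0.1)."""
    return rows[
        (rows["cleavage_efficiency"] > min_efficiency)
        & (rows["homogeneity"] > min_homogeneity)
    ].reset_index(drop=True)


def variants_with_min_coverage(
    raw_profiles: Iterable[CleavageProfile], min_os_reads: float = 100
) -> set[str]:
    """Variants with more than ``min_os_reads`` OS reads in at least one
    (condition, replicate) of the raw-count profiles."""
    best: dict[str, float] = {}
    for p in raw_profiles:
        best[p.variant_id] = max(best.get(p.variant_id, 0.0), p.n_s)
    return {vid for vid, n in best.items() if n > min_os_reads}
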
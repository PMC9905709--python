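"""Synthetic HT-priCA sequencing libraries with matching ground truth.

The generator emulates the read anatomy of the high-throughput cleavage
assay: original-substrate (OS) reads carry a 4-nt random barcode in front of
the full variant sequence; cleaved-product (F3) reads carry a 6-nt random
barcode in front of the fragment that starts at the drawn cleavage site;
both are emitted as overlapping paired-end reads with the 3' sequencing
adapters appended, optional substitution errors and PCR duplicates.

Count model: sequencing depth is fixed per library (it is set at library
preparation), so for every condition and replicate the product library is
drawn Multinomial(product_depth, shares ∝ p·β) and the OS library
Multinomial(os_depth, shares ∝ 1 − p·β), where p is the basal cleavage
probability and β the cofactor effect of the variant.  Sites within a
variant follow a multinomial over the basal (CL-3..CL3), apical (CL8..CL14)
and outlying sites, with the cofactor boosting the canonical-site mass by β.

Effect model: β = β_CNNC for CNNC variants, β_CRC for 17-CRC variants,
1 otherwise — and forced to 1 when the variant's CNNC motif adopts the
fully base-paired S4a structure (cofactors cannot engage a fully paired
CNNC).  Structure classes are drawn per variant from a configurable class
distribution (S4a default 0.14) and realised as concrete dot-bracket
strings, so the annotation stage can recover them from the emitted
structures file.

All randomness flows from the single seed in :class:`SimulationConfig`;
outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp, to_dna
from .backbones import RA3_ADAPTER_DNA, RA5_ADAPTER_RC_DNA
from .errors import ConfigError, InputError
from .library_design import BackboneSpec, VariantLibrary, enumerate_variants
from .motif_structure import (
    CNNC,
    CRC17,
    STRUCTURE_CLASSES,
    find_cnnc,
    find_crc17,
    primary_cnnc_hit,
    write_dotbracket_file,
)
from .read_processing import OS, PRODUCT, ReadRecord

CONDITIONS = ("MP", "MP+SRSF7", "MP+SRSF3")
S4A = "S4a"

DEFAULT_CLASS_WEIGHTS = {
    "S0": 0.25,
    "S1": 0.18,
    "S2a": 0.12,
    "S2b": 0.08,
    "S3a": 0.08,
    "S3b": 0.05,
    "S4a": 0.14,  # matches the fraction reported for human CNNC hairpins
    "S4b": 0.10,
}

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def default_site_distribution(canonical_sites: Iterable[int]) -> dict[int, float]:
    """Baseline site distribution π0 for a backbone.

    Canonical sites share 0.45 of the mass (CL0 double-weighted), basal
    alternatives 0.27, apical sites 0.21 (uniform over CL8..CL14) and
    outlying sites CL-4 and CL5 the remaining 0.07.
    """
    canonical = sorted(canonical_sites)
    pi: dict[int, float] = {}
    wts = {c: (2.0 if c == 0 else 1.0) for c in canonical}
    wsum = sum(wts.values())
    for c, w in wts.items():
        pi[c] = 0.45 * w / wsum
    alt = {-3: 0.02, -2: 0.12, -1: 0.06, 1: 0.04, 2: 0.02, 3: 0.01}
    for c in canonical:
        alt.pop(c, None)
    asum = sum(alt.values())
    for x, w in alt.items():
        pi[x] = 0.27 * w / asum
    for x in range(8, 15):
        pi[x] = 0.21 / 7
    pi[-4] = 0.03
    pi[5] = 0.04
    assert abs(sum(pi.values()) - 1.0) < 1e-9
    return dict(sorted(pi.items()))


def boost_canonical(
    pi: dict[int, float], canonical_sites: Iterable[int], beta: float
) -> dict[int, float]:
    """Multiply the canonical-site mass by beta and renormalize."""
    canonical = set(canonical_sites)
    raw = {x: (p * beta if x in canonical else p) for x, p in pi.items()}
    z = sum(raw.values())
    return {x: p / z for x, p in raw.items()}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated HT-priCA experiment."""

    backbones: list[BackboneSpec]
    conditions: tuple[str, ...] = CONDITIONS
    replicates: int = 3
    product_depth: int = 100_000  # product read pairs per condition/replicate
    os_depth: int = 150_000  # OS read pairs per condition/replicate
    read_length: int = 76
    p0: float = 0.3  # basal cleavage probability per substrate molecule
    beta_cnnc: float = 1.8
    beta_crc: float = 1.4
    error_rate: float = 0.001  # per-base substitution rate
    pcr_duplication_rate: float = 0.05
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.backbones:
            raise ConfigError("at least one backbone required")
        if not 0.0 <= self.p0 <= 1.0:
            raise ConfigError("p0 must lie in [0, 1]")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ConfigError("error_rate must lie in [0, 0.05]")
        if set(self.class_weights) != set(STRUCTURE_CLASSES):
            raise ConfigError("class_weights must cover exactly S0..S4b")
        if abs(sum(self.class_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("class_weights must sum to 1")
        if min(self.beta_cnnc, self.beta_crc) < 1.0:
            raise ConfigError("cofactor effects are stimulatory (beta >= 1)")


@dataclass
class GroundTruth:
    """True per-variant cleavage parameters of a simulation.

    ``variants``: one row per (backbone, variant, condition) with motif kind,
    structure class, effect size beta and cleavage probability p.
    ``sites``: one row per (backbone, variant, condition, site) with the true
    site probability pi.
    """

    variants: pd.DataFrame
    sites: pd.DataFrame


@dataclass
class SimulationResult:
    fastq: dict[tuple[str, str, int], tuple[Path, Path]]
    truth: GroundTruth
    structures_path: Path
    libraries: list[VariantLibrary]


# ---------------------------------------------------------------------------
# structure realisation

_PAIR_PATTERNS: dict[str, list[tuple[int, int]]] = {
    # (motif position index 0..3, partner offset below the anchor)
    "S0": [],
    "S1": [(0, 0)],
    "S2a": [(0, 0), (1, 1)],
    "S2b": [(0, 0), (2, 1)],
    "S3a": [(0, 0), (1, 1), (2, 2)],
    "S3b": [(0, 0), (1, 1), (3, 2)],
    "S4a": [(0, 0), (1, 1), (2, 2), (3, 3)],
    "S4b": [(0, 0), (1, 1), (2, 2), (3, 5)],
}


def realise_structure(
    length: int, motif_positions: Sequence[int], label: str, anchor: int = 45
) -> str:
    """A dot-bracket string whose CNNC pairing pattern classifies as ``label``.

    Partners are placed on a descending run below ``anchor`` (upstream of the
    motif); everything else is left unpaired.
    """
    db = ["."] * length
    for mi, drop in _PAIR_PATTERNS[label]:
        q = anchor - drop
        m = motif_positions[mi]
        if not 1 <= q < m <= length:
            raise ConfigError("partner anchor collides with the motif")
        db[q - 1] = "("
        db[m - 1] = ")"
    return "".join(db)


# ---------------------------------------------------------------------------
# FASTQ output


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Plain 4-line FASTQ; validates the base alphabet; returns record count."""
    n = 0
    with open(path, "w") as fh:
        for r in records:
            if set(r.sequence) - set("ACGTN"):
                raise InputError(f"{r.read_id}: non-ACGTN base in sequence")
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterable[ReadRecord]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(rid.split()[0], seq, qual)


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterable[tuple[ReadRecord, ReadRecord]]:
    yield from zip(read_fastq(r1_path), read_fastq(r2_path))


# ---------------------------------------------------------------------------
# the simulator


def _effect_beta(motif: str, cls: str, config: SimulationConfig) -> float:
    if motif == CNNC:
        return 1.0 if cls == S4A else config.beta_cnnc
    if motif == CRC17:
        return config.beta_crc
    return 1.0


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    chars = list(seq)
    for pos in rng.integers(0, len(seq), size=k):
        cur = _BASE_IDX.get(chars[pos], 0)
        chars[pos] = _BASES[(cur + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(chars)


def _barcode(rng: np.random.Generator, k: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=k))


def simulate_experiment(
    config: SimulationConfig, outdir: str | Path
) -> SimulationResult:
    """Generate FASTQ libraries, ground truth and structures under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    libraries = [enumerate_variants(bb) for bb in config.backbones]

    # --- per-variant truth: motif, structure class, per-condition p and pi
    class_labels = list(STRUCTURE_CLASSES)
    class_p = np.array([config.class_weights[c] for c in class_labels])
    variant_meta: list[dict] = []  # one entry per variant (all backbones)
    structures: list[tuple[str, str, str]] = []
    for lib in libraries:
        bb = lib.backbone
        for v in lib.variants:
            hits = find_cnnc(v.full_sequence, bb.cl0_ref)
            primary = primary_cnnc_hit(hits)
            if primary is not None:
                motif = CNNC
                cls = class_labels[
                    int(rng.choice(len(class_labels), p=class_p))
                ]
                db = realise_structure(bb.length, primary.positions, cls)
            else:
                motif = CRC17 if find_crc17(v.full_sequence, bb.cl0_ref) else "none"
                cls = ""
                db = "." * bb.length
            structures.append((v.variant_id, to_dna(v.full_sequence), db))
            variant_meta.append(
                dict(
                    backbone=bb.name,
                    variant_id=v.variant_id,
                    variant_dna=to_dna(v.full_sequence),
                    cl0_ref=bb.cl0_ref,
                    motif_kind=motif,
                    structure_class=cls,
                    pi0=default_site_distribution(bb.canonical_sites),
                    canonical=bb.canonical_sites,
                )
            )
    structures_path = outdir / "structures.txt"
    write_dotbracket_file(structures_path, structures)

    truth_var_rows = []
    truth_site_rows = []
    per_condition: dict[str, list[dict]] = {}
    for cond in config.conditions:
        entries = []
        for meta in variant_meta:
            beta = (
                1.0
                if cond == "MP"
                else _effect_beta(meta["motif_kind"], meta["structure_class"], config)
            )
            p_eff = min(config.p0 * beta, 0.95)
            pi = (
                meta["pi0"]
                if beta == 1.0
                else boost_canonical(meta["pi0"], meta["canonical"], beta)
            )
            sites = sorted(pi)
            entries.append(
                dict(meta, beta=beta, p=p_eff, pi=pi, sites=sites,
                     pi_vec=np.array([pi[x] for x in sites]))
            )
            truth_var_rows.append(
                dict(
                    backbone=meta["backbone"],
                    variant_id=meta["variant_id"],
                    condition=cond,
                    motif_kind=meta["motif_kind"],
                    structure_class=meta["structure_class"],
                    beta=beta,
                    p=p_eff,
                )
            )
            truth_site_rows.extend(
                dict(
                    backbone=meta["backbone"],
                    variant_id=meta["variant_id"],
                    condition=cond,
                    site=x,
                    pi=pi[x],
                )
                for x in sites
            )
        per_condition[cond] = entries

    truth = GroundTruth(
        variants=pd.DataFrame(truth_var_rows),
        sites=pd.DataFrame(truth_site_rows),
    )
    truth.variants.to_csv(outdir / "ground_truth_variants.tsv", sep="\t", index=False)
    truth.sites.to_csv(outdir / "ground_truth_sites.tsv", sep="\t", index=False)

    # --- read generation
    fastq: dict[tuple[str, str, int], tuple[Path, Path]] = {}
    rl = config.read_length
    for cond in config.conditions:
        entries = per_condition[cond]
        p_vec = np.array([e["p"] for e in entries])
        os_share = (1.0 - p_vec) / (1.0 - p_vec).sum()
        prod_share = p_vec / p_vec.sum()
        for rep in range(1, config.replicates + 1):
            os_counts = rng.multinomial(config.os_depth, os_share)
            prod_counts = rng.multinomial(config.product_depth, prod_share)
            for kind, counts in ((OS, os_counts), (PRODUCT, prod_counts)):
                tag = f"{kind}_{cond}_rep{rep}"
                p1 = outdir / f"{tag}_R1.fastq"
                p2 = outdir / f"{tag}_R2.fastq"
                with open(p1, "w") as f1, open(p2, "w") as f2:
                    serial = 0
                    for e, n in zip(entries, counts):
                        if n == 0:
                            continue
                        if kind == OS:
                            frag_starts = [None] * int(n)
                        else:
                            site_counts = rng.multinomial(int(n), e["pi_vec"])
                            frag_starts = [
                                e["cl0_ref"] - x
                                for x, c in zip(e["sites"], site_counts)
                                for _ in range(c)
                            ]
                        for start in frag_starts:
                            serial += 1
                            if kind == OS:
                                insert = _barcode(rng, 4) + e["variant_dna"]
                            else:
                                insert = _barcode(rng, 6) + e["variant_dna"][start - 1 :]
                            r1s = (insert + RA3_ADAPTER_DNA)[:rl]
                            r2s = (revcomp(insert) + RA5_ADAPTER_RC_DNA)[:rl]
                            r1s = _mutate(r1s, rng, config.error_rate)
                            r2s = _mutate(r2s, rng, config.error_rate)
                            rid = f"{tag}.{serial}"
                            block1 = f"@{rid}\n{r1s}\n+\n{'I' * len(r1s)}\n"
                            block2 = f"@{rid}\n{r2s}\n+\n{'I' * len(r2s)}\n"
                            f1.write(block1)
                            f2.write(block2)
                            if rng.random() < config.pcr_duplication_rate:
                                f1.write(block1)
                                f2.write(block2)
                fastq[(kind, cond, rep)] = (p1, p2)
    return SimulationResult(
        fastq=fastq, truth=truth, structures_path=structures_path, libraries=libraries
    )


# ---------------------------------------------------------------------------
# synthetic external score table (stand-in for the human cleavage library)


def simulate_external_score_table(
    n: int,
    seed: int,
    planting_rate: float = 0.5,
    flank_length: int = 30,
) -> pd.DataFrame:
    """Synthetic per-pri-miRNA score rows with random 3' flanks.

    Efficiency is LogNormal(0, 0.8) (median 1), homogeneity Beta(2, 5); with
    probability ``planting_rate`` a CNNC motif is planted at a random offset
    inside the detection window.  Flank offsets run -1, -2, ... from the
    string's first character, so in the offset convention of
    :mod:`prica.motif_structure` the flank is scanned with cl0_ref = 1
    (1-based index k corresponds to offset -k).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        flank = list("".join(_BASES[j] for j in rng.integers(0, 4, size=flank_length)))
        if rng.random() < planting_rate:
            first = int(rng.integers(15, 20))  # first-C offset magnitude
            flank[first - 1] = "C"
            flank[first + 2] = "C"
        rows.append(
            dict(
                primirna_id=f"synthetic_{i + 1:04d}",
                cleavage_efficiency=float(rng.lognormal(0.0, 0.8)),
                homogeneity=float(rng.beta(2.0, 5.0)),
                flank3="".join(flank),
            )
        )
    return pd.DataFrame(rows)
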
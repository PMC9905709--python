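"""End-to-end orchestration: design -> (simulate) -> process -> call -> score
-> annotate -> report.

A run is driven by one :class:`PipelineConfig`; all randomness flows from its
seed, and a rerun with the same configuration reproduces every output table
bit-for-bit.  Per-stage read counters are conserved and recorded in the run
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .backbones import RA3_ADAPTER_DNA, RA5_ADAPTER_RC_DNA, demo_backbones
from .cleavage_calling import (
    CleavageProfile,
    build_profiles,
    category_summary,
    profiles_to_frame,
)
from .errors import InputError
from .library_design import BackboneSpec, VariantLibrary, enumerate_variants, write_reference_fasta
from .motif_structure import (
    PrimiRNARecord,
    annotate_primirna_set,
    read_dotbracket_file,
)
from .read_processing import OS, PRODUCT, BackboneAssigner, process_pairs
from .scoring import (
    average_replicates,
    compute_scores,
    delta_scores,
    normalize_cpm,
    variants_with_min_coverage,
)
from .synthetic_data import SimulationConfig, read_fastq_pairs, simulate_experiment
from ._seq import to_dna


@dataclass
class PipelineConfig:
    outdir: Path
    backbones: list[BackboneSpec] = field(default_factory=demo_backbones)
    simulate: bool = True
    sim: SimulationConfig | None = None  # default built from backbones + seed
    input_manifest: Path | None = None  # TSV: kind, condition, replicate, r1, r2
    structures: Path | None = None  # dot-bracket file; simulator output if simulating
    seed: int = 0
    d_max: int = 2
    min_os_reads: float = 100
    adapter_r1: str = RA3_ADAPTER_DNA
    adapter_r2: str = RA5_ADAPTER_RC_DNA
    write_fragments: bool = False  # per-fragment TSV can be large at full depth


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    profiles: list[CleavageProfile]
    scores: pd.DataFrame  # per-replicate
    averaged: pd.DataFrame
    deltas: pd.DataFrame
    annotation: pd.DataFrame | None
    class_fractions: dict[str, float] | None
    categories: pd.DataFrame
    report: dict


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        "backbones": [(bb.name, bb.sequence, bb.cl0_ref) for bb in config.backbones],
        "simulate": config.simulate,
        "seed": config.seed,
        "d_max": config.d_max,
        "min_os_reads": config.min_os_reads,
    }
    if config.sim is not None:
        payload["sim"] = {
            k: v
            for k, v in vars(config.sim).items()
            if isinstance(v, (int, float, str, tuple, dict))
        }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_input_manifest(path: Path) -> dict[tuple[str, str, int], tuple[Path, Path]]:
    df = pd.read_csv(path, sep="\t")
    required = {"kind", "condition", "replicate", "r1", "r2"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: input manifest needs columns {sorted(required)}")
    layout = {}
    for row in df.itertuples():
        for p in (row.r1, row.r2):
            if not Path(p).exists():
                raise InputError(f"input FASTQ not found: {p}")
        layout[(row.kind, row.condition, int(row.replicate))] = (
            Path(row.r1),
            Path(row.r2),
        )
    return layout


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- design
    libraries = [enumerate_variants(bb) for bb in config.backbones]
    n_refs = write_reference_fasta(libraries, outdir / "references.fasta")
    variant_backbone: dict[str, BackboneSpec] = {}
    for lib in libraries:
        for v in lib.variants:
            variant_backbone[v.variant_id] = lib.backbone

    # --- inputs
    structures_path = config.structures
    if config.simulate:
        sim = config.sim or SimulationConfig(
            backbones=config.backbones, seed=config.seed
        )
        sim_result = simulate_experiment(sim, outdir / "sim")
        fastq = sim_result.fastq
        if structures_path is None:
            structures_path = sim_result.structures_path
    else:
        if config.input_manifest is None:
            raise InputError("simulate=false requires an input manifest")
        fastq = _load_input_manifest(Path(config.input_manifest))

    # --- process + call
    assigner = BackboneAssigner(libraries, d_max=config.d_max)
    profiles: list[CleavageProfile] = []
    stage_counts: dict[str, dict[str, int]] = {}
    fragment_frames = []
    cond_reps = sorted({(cond, rep) for (_, cond, rep) in fastq})
    for cond, rep in cond_reps:
        frags = []
        for kind in (OS, PRODUCT):
            key = (kind, cond, rep)
            if key not in fastq:
                continue
            r1, r2 = fastq[key]
            lib_frags, counters = process_pairs(
                read_fastq_pairs(r1, r2),
                kind,
                assigner,
                config.adapter_r1,
                config.adapter_r2,
            )
            if not counters.conserved():  # pragma: no cover - internal invariant
                raise InputError(f"counter conservation violated for {key}")
            stage_counts[f"{kind}_{cond}_rep{rep}"] = counters.as_dict()
            frags.extend(lib_frags)
        if config.write_fragments:
            fragment_frames.append(
                pd.DataFrame(frags).assign(condition=cond, replicate=rep)
            )
        profiles.extend(build_profiles(frags, variant_backbone, cond, rep))
    if config.write_fragments and fragment_frames:
        pd.concat(fragment_frames).to_csv(
            outdir / "fragments.tsv", sep="\t", index=False
        )

    profiles_to_frame(profiles).to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    backbones_by_name = {bb.name: bb for bb in config.backbones}
    categories = category_summary(profiles, backbones_by_name)
    categories.to_csv(outdir / "category_summary.tsv", sep="\t", index=False)

    # --- score
    kept = variants_with_min_coverage(profiles, min_os_reads=config.min_os_reads)
    norm = normalize_cpm(profiles)
    scores = compute_scores(norm)
    scores = scores[scores.variant_id.isin(kept)].reset_index(drop=True)
    averaged = average_replicates(scores) if len(scores) else pd.DataFrame(
        columns=["backbone", "variant_id", "condition", "site", "e_p", "e_x", "a_x"]
    )
    scores.to_csv(outdir / "scores_per_replicate.tsv", sep="\t", index=False)
    averaged.to_csv(outdir / "scores_averaged.tsv", sep="\t", index=False)
    cofactors = sorted(set(averaged.condition.unique()) - {"MP"}) if len(averaged) else []
    deltas = (
        pd.concat([delta_scores(averaged, cf) for cf in cofactors])
        if cofactors
        else pd.DataFrame(
            columns=["backbone", "variant_id", "site", "cofactor",
                     "delta_e_p", "delta_e_x", "delta_a_x"]
        )
    )
    deltas.to_csv(outdir / "delta_scores.tsv", sep="\t", index=False)

    # --- annotate
    annotation = None
    class_fractions = None
    if structures_path is not None:
        structures = read_dotbracket_file(structures_path)
        records = [
            PrimiRNARecord(v.variant_id, to_dna(v.full_sequence), lib.backbone.cl0_ref)
            for lib in libraries
            for v in lib.variants
        ]
        annotation, class_fractions = annotate_primirna_set(records, structures)
        annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        with open(outdir / "class_fractions.json", "w") as fh:
            json.dump(class_fractions, fh, indent=2)

    # --- report + manifest
    report = write_report(
        averaged, deltas, annotation, categories, outdir / "report.md"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_reference_records": n_refs,
        "n_variants_kept": len(kept),
        "stage_counts": stage_counts,
        "counts_conserved": True,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(
        outdir=outdir,
        manifest=manifest,
        profiles=profiles,
        scores=scores,
        averaged=averaged,
        deltas=deltas,
        annotation=annotation,
        class_fractions=class_fractions,
        categories=categories,
        report=report,
    )


# ---------------------------------------------------------------------------
# report


def _stratum_stats(df: pd.DataFrame) -> dict:
    return {
        "n": int(df.variant_id.nunique()),
        "median_delta_a_cl0": float(df.delta_a_x.median()) if len(df) else float("nan"),
        "median_delta_e_p": float(df.delta_e_p.median()) if len(df) else float("nan"),
    }


def write_report(
    averaged: pd.DataFrame,
    deltas: pd.DataFrame,
    annotation: pd.DataFrame | None,
    categories: pd.DataFrame,
    path: str | Path,
) -> dict:
    """Summarize cofactor effects stratified by motif and structure class.

    Writes a human-readable markdown report and returns the summary as a
    nested dict (per cofactor: median dA at CL0 and median dE_P by motif
    group CNNC / CRC17 / none and by CNNC structure class).
    """
    lines = ["# HT-priCA run report", ""]
    summary: dict = {"cofactors": {}}
    if len(deltas) == 0 or annotation is None:
        lines.append("No scored variants or no annotation available: no data.")
        Path(path).write_text("\n".join(lines) + "\n")
        return summary

    ann = annotation.set_index("record_id")
    d0 = deltas[deltas.site == 0].copy()
    d0["motif_kind"] = d0.variant_id.map(ann.motif_kind)
    d0["structure_class"] = d0.variant_id.map(ann.structure_class)

    lines.append("## Cleavage categories (product-read fractions)\n")
    lines.append(categories.to_markdown(index=False))
    lines.append("")
    for cf in sorted(d0.cofactor.unique()):
        sub = d0[d0.cofactor == cf]
        by_motif = {
            m: _stratum_stats(sub[sub.motif_kind == m])
            for m in ("CNNC", "CRC17", "none")
        }
        cnnc = sub[sub.motif_kind == "CNNC"]
        by_class = {
            cls: _stratum_stats(cnnc[cnnc.structure_class == cls])
            for cls in sorted(cnnc.structure_class.dropna().unique())
        }
        summary["cofactors"][cf] = {"by_motif": by_motif, "by_class": by_class}
        lines.append(f"## {cf} vs MP\n")
        lines.append("| stratum | n | median dA(CL0) | median dE_P |")
        lines.append("|---|---|---|---|")
        for name, st in list(by_motif.items()) + list(by_class.items()):
            lines.append(
                f"| {name} | {st['n']} | {st['median_delta_a_cl0']:.4f} "
                f"| {st['median_delta_e_p']:.4f} |"
            )
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")
    return summary
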
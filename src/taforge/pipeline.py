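"""End-to-end orchestration: simulate -> process -> call -> enrich -> motif.

A run compares two transposase conditions (an unfused control and a
nucleolus-targeted fusion, by default) end to end on one synthetic genome and
writes plain-text artifacts plus a machine-readable manifest.  Everything is
deterministic under the run seed: per-stage seeds are derived from it, and no
output embeds a timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np

from . import __version__
from .genome import (GenomeConfig, GenomeModel, TargetModel, build_genome,
                     default_config, simulate_insertions, write_truth_bed)
from .library import LibraryParams, make_backbone, simulate_junction_library, \
    write_fastq_pair
from .mapping import build_index, call_sites, map_reads, write_sites_bed
from .motif import pfm_from_sites
from .readproc import ProcessParams, process_library, write_junction_fasta, \
    write_stats_tsv
from .enrichment import (binned_rpkm_profile, compare_conditions, expand_peaks,
                         write_profile_tsv, write_results)

logger = logging.getLogger(__name__)

PEAK_SETS = ("UBTF_peak", "POL2_peak", "POL3_peak")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and reason."""


@dataclass
class PipelineConfig:
    seed: int = 0
    n_insertions: int = 2000  # per condition
    conditions: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "SB100X": {},
            "B23-SB100X": {"acro_p_arm": 1.64},
        }
    )
    palindrome_weight: float = 1.0
    mapping_mode: str = "random"  # desk-scale depth; see methods note
    min_support: int = 1
    max_mismatch_frac: float = 0.05
    kmer_size: int = 31
    peak_pad: int = 500
    region_labels: tuple = ("acro_p_arm", "non_acro_p_arm", "p13", "p12",
                            "p11.2", "NAD", "LAD_A", "LAD_B") + PEAK_SETS
    error_rate: float = 0.001
    pcr_duplication_rate: float = 0.5
    backbone_fraction: float = 0.02
    logo_flank: int = 10
    genome: GenomeConfig | None = None  # default_config(seed) when None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise PipelineError(f"config: unknown keys {sorted(bad)}")
        d = dict(d)
        if "region_labels" in d:
            d["region_labels"] = tuple(d["region_labels"])
        return cls(**d)


def _region_sets(genome: GenomeModel, config: PipelineConfig):
    sets = {}
    for label in config.region_labels:
        regions = genome.regions(label)
        if label in PEAK_SETS:
            regions = expand_peaks(regions, config.peak_pad, genome)
        sets[label] = regions
    return sets


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write the report bundle into ``outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Raises :class:`PipelineError` when a stage cannot proceed, e.g. when no
    junction reads survive processing.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {
        "package": "taforge",
        "version": __version__,
        "seed": seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "genome"
        },
        "stages": {},
    }

    # --- genome ------------------------------------------------------------
    gconf = config.genome or default_config(seed)
    genome = build_genome(gconf, seed=seed)
    genome.write_fasta(out / "genome.fa")
    genome.write_cytobands_bed(out / "cytobands.bed")
    for label in genome.annotations:
        genome.write_annotations_bed(out / f"annotation_{label}.bed", label)
    manifest["stages"]["genome"] = {
        "chromosomes": len(genome.names()),
        "total_bp": sum(genome.length(n) for n in genome.names()),
        "ta_sites": int(sum(genome.ta_sites(n).size for n in genome.names())),
    }

    backbone = make_backbone(np.random.default_rng(seed + 101), genome=genome)
    index = build_index(genome, config.kmer_size)
    region_sets = _region_sets(genome, config)

    sites_by_condition = {}
    for i, (label, bias) in enumerate(sorted(config.conditions.items())):
        tag = label.replace("/", "_")
        model = TargetModel(region_bias=dict(bias),
                            palindrome_weight=config.palindrome_weight,
                            condition_label=label)
        truth = simulate_insertions(genome, model, config.n_insertions,
                                    seed=seed + 1000 + i)
        write_truth_bed(truth, out / f"truth_{tag}.bed")

        params = LibraryParams(
            pcr_duplication_rate=config.pcr_duplication_rate,
            error_rate=config.error_rate,
            backbone_fraction=config.backbone_fraction,
            backbone=backbone,
            seed=seed + 2000 + i,
        )
        pairs = simulate_junction_library(truth, genome, params)
        write_fastq_pair(pairs, out / f"reads_{tag}_R1.fastq.gz",
                         out / f"reads_{tag}_R2.fastq.gz")

        pparams = ProcessParams(
            barcode_map=params.barcode_map, primer=params.primer,
            ir_sequence=params.ir_sequence, backbone=backbone,
        )
        junctions_by, stats_by = process_library(pairs, pparams)
        junctions, stats = junctions_by["S1"], stats_by["S1"]
        write_junction_fasta(junctions, out / f"junctions_{tag}.fa")
        write_stats_tsv(stats_by, out / f"filter_stats_{tag}.tsv")
        if not junctions:
            raise PipelineError(
                f"read_processing[{label}]: no junction reads survived"
            )

        mapped, map_stats = map_reads(
            junctions, index, mode=config.mapping_mode,
            max_mismatch_frac=config.max_mismatch_frac, seed=seed + 3000 + i,
        )
        sites = call_sites(mapped, genome, min_support=config.min_support,
                           mode=config.mapping_mode)
        write_sites_bed(sites, out / f"sites_{tag}.bed", seed=seed)
        if not sites:
            raise PipelineError(f"site_calling[{label}]: no sites called")
        sites_by_condition[label] = sites

        pfm, n_ctx = pfm_from_sites(sites, genome, config.logo_flank)
        pfm.to_frame().to_csv(out / f"pfm_{tag}.tsv", sep="\t", index=False)

        manifest["stages"][f"condition:{label}"] = {
            "truth_molecules": len(truth),
            "read_pairs": len(pairs),
            "junction_reads": len(junctions),
            "filter_stats": stats.as_dict(),
            "mapping": map_stats,
            "sites": len(sites),
            "logo_contexts": n_ctx,
        }

    # --- enrichment ----------------------------------------------------------
    labels = sorted(config.conditions)
    if len(labels) != 2:
        raise PipelineError("region_enrichment: exactly two conditions required")
    ctrl, fused = labels if "B23" not in labels[0] else labels[::-1]
    results = compare_conditions(
        sites_by_condition[ctrl], sites_by_condition[fused], region_sets,
        genome,
    )
    write_results(results, out / "enrichment.tsv", out / "enrichment.json")
    manifest["stages"]["enrichment"] = {
        "control": ctrl, "fusion": fused, "regions": len(results),
    }

    # per-cytoband insertion-density profile over the acrocentric p-arms
    for chrom, s, e in genome.regions("acro_p_arm"):
        if e - s >= 300:
            prof = binned_rpkm_profile(
                sites_by_condition[fused], (chrom, s, e), n_bins=300,
                label=f"{chrom}:p-arm",
            )
            write_profile_tsv(prof, out / f"profile_p_arm_{chrom}.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
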
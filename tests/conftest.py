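"""Shared fixtures: a small fast genome and hand-built micro-genomes."""

import numpy as np
import pytest

from taforge.genome import (AnnotationSpec, BandSpec, ChromosomeSpec,
                            GenomeConfig, GenomeModel, build_genome)


def small_genome_config(seed: int = 5) -> GenomeConfig:
    """Two 40 kb acrocentric chromosomes (p12 = 20 tandem copies of a 500 bp
    low-TA unit) plus one 40 kb ordinary chromosome."""
    acro_bands = (
        BandSpec("p13", 2 / 40, 0.05),
        BandSpec("p12", 10 / 40, 0.008),
        BandSpec("p11.2", 2 / 40, 0.05),
        BandSpec("q", 26 / 40, 0.05),
    )
    nonacro_bands = (BandSpec("p", 0.4, 0.05), BandSpec("q", 0.6, 0.05))
    chroms = (
        ChromosomeSpec("chrA", 40_000, True, acro_bands),
        ChromosomeSpec("chrB", 40_000, True, acro_bands),
        ChromosomeSpec("chrC", 40_000, False, nonacro_bands),
    )
    annotations = {
        "NAD": AnnotationSpec(8, 2000, 0.70),
        "LAD_A": AnnotationSpec(8, 2500, 0.35),
        "LAD_B": AnnotationSpec(6, 2500, 0.35),
        "UBTF_peak": AnnotationSpec(12, 300, 0.80),
        "POL2_peak": AnnotationSpec(12, 300, 0.10),
        "POL3_peak": AnnotationSpec(12, 300, 0.10),
    }
    return GenomeConfig(chromosomes=chroms, annotations=annotations, seed=seed)


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    return build_genome(small_genome_config())


def manual_genome(sequences: dict) -> GenomeModel:
    """Wrap literal sequences as a one-band-per-chromosome GenomeModel."""
    chroms = list(sequences.items())
    return GenomeModel(
        chromosomes=chroms,
        acrocentric={name: False for name in sequences},
        cytobands={name: [(0, len(seq), "q")] for name, seq in chroms},
        annotations={},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def distinct_unique_region_truth(genome, n, seed, replicates=1):
    """Truth insertions at distinct TA coordinates outside the tandem-repeat
    band (so unique mapping is well-posed and no two molecules can produce
    byte-identical read pairs), optionally replicated per site with fresh
    molecule ids."""
    from taforge.genome import TargetModel, TruthInsertion, simulate_insertions

    repeat_spans = {}
    for name in genome.names():
        repeat_spans[name] = [
            (s, e) for s, e, lab in genome.cytobands[name] if lab == "p12"
        ]
    seen = set()
    picked = []
    for ins in simulate_insertions(genome, TargetModel(), 4 * n, seed=seed):
        key = (ins.chrom, ins.position)
        if key in seen:
            continue
        if any(s <= ins.position < e for s, e in repeat_spans[ins.chrom]):
            continue
        seen.add(key)
        picked.append(ins)
        if len(picked) == n:
            break
    out = []
    mol = 0
    for ins in picked:
        for _ in range(replicates):
            out.append(TruthInsertion(ins.chrom, ins.position, ins.strand, mol))
            mol += 1
    return out
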
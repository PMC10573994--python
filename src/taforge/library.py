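"""Paired-end junction-library read simulation.

Each ground-truth insertion becomes one sequenced molecule: genomic DNA is
sheared (Normal around 600 bp, rejection-sampled into the 200-500 bp
size-selection window), the transposon inverted-repeat (IR) end retained at
the junction is appended to a sample barcode, and the genomic flank starting
exactly at the target TA fills the rest of the fragment.  Reads are 2x150:
read1 is the fragment 5' end (barcode + IR + flank start), read2 the reverse
complement of the fragment 3' end.  PCR duplicates are byte-identical copies
of the parent pair made after the parent's sequencing errors are injected
(each copy may then gain further errors at a tenth of the base error rate),
so exact-sequence deduplication can remove them.  A configurable fraction of
pairs carries plasmid-backbone sequence after the IR instead of genome.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from . import dna
from .genome import GenomeModel, TruthInsertion

logger = logging.getLogger(__name__)

# 40 nt synthetic transposon IR end as presented on read1; the first 20 nt
# are the nested-PCR primer landing site.
DEFAULT_IR = "GTGTCATGCACAAAGTAGATGTCCTAACTGACTTGCCAAA"
DEFAULT_PRIMER = DEFAULT_IR[:20]


@dataclass(frozen=True)
class LibraryParams:
    ir_sequence: str = DEFAULT_IR
    primer: str = DEFAULT_PRIMER
    barcode_map: Dict[str, str] = field(default_factory=lambda: {"S1": "ACGTCA"})
    shear_mean: float = 600.0
    shear_sd: float | None = None  # default shear_mean / 4
    size_select: Tuple[int, int] = (200, 500)
    read_length: int = 150
    pcr_duplication_rate: float = 0.0
    error_rate: float = 0.0
    backbone_fraction: float = 0.0
    backbone: str = ""
    seed: int = 0

    def __post_init__(self):
        if not self.ir_sequence:
            raise ValueError("ir_sequence must be non-empty")
        if not self.ir_sequence.startswith(self.primer):
            raise ValueError("primer must be a prefix of the read-side IR sequence")
        for name, rate in (
            ("error_rate", self.error_rate),
            ("backbone_fraction", self.backbone_fraction),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.size_select[0] > self.size_select[1]:
            raise ValueError("size_select min must be <= max")

    @property
    def sd(self) -> float:
        return self.shear_mean / 4 if self.shear_sd is None else self.shear_sd


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    sample: str


def make_backbone(rng: np.random.Generator, length: int = 3000,
                  genome: GenomeModel | None = None, k: int = 25) -> str:
    """Random plasmid-backbone sequence sharing no k-mer with the genome."""
    for _ in range(20):
        seq = dna.decode(rng.choice(4, size=length).astype(np.uint8))
        if genome is None:
            return seq
        gkmers = set()
        for name, gseq in genome.chromosomes:
            gkmers.update(gseq[i:i + k] for i in range(len(gseq) - k + 1))
        kmers = {seq[i:i + k] for i in range(length - k + 1)}
        kmers |= {dna.revcomp(s) for s in kmers}
        if not (kmers & gkmers):
            return seq
    raise RuntimeError("could not build a genome-disjoint backbone")


def _sample_shear(rng: np.random.Generator, params: LibraryParams) -> int:
    lo, hi = params.size_select
    while True:
        x = int(round(rng.normal(params.shear_mean, params.sd)))
        if lo <= x <= hi:
            return x


def _genomic_flank(genome: GenomeModel, ins: TruthInsertion, length: int) -> str:
    seq = genome.seq(ins.chrom)
    if ins.strand == "+":
        return seq[ins.position:ins.position + length]
    lo = max(ins.position + 2 - length, 0)
    return dna.revcomp(seq[lo:ins.position + 2])


_MUT = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    chars = list(seq)
    for i in rng.choice(len(seq), size=n, replace=False):
        chars[i] = _MUT[chars[i]][rng.integers(3)]
    return "".join(chars)


def simulate_junction_library(
    truth: Sequence[TruthInsertion],
    genome: GenomeModel,
    params: LibraryParams,
    sample: str = "S1",
) -> List[ReadPair]:
    """Emit read pairs for every truth molecule of one sample.

    Fragment = barcode + IR + genomic flank, with flank length equal to the
    size-selected shear length minus the IR length.  Molecules whose flank
    length would be non-positive are dropped with a warning.
    """
    if not truth:
        raise ValueError("truth is empty")
    barcode = params.barcode_map[sample]
    rng = np.random.default_rng(params.seed)
    R = params.read_length
    pairs: List[ReadPair] = []
    dropped = 0
    for ins in truth:
        shear = _sample_shear(rng, params)
        flank_len = shear - len(params.ir_sequence)
        if flank_len <= 0:
            dropped += 1
            continue
        if rng.random() < params.backbone_fraction:
            off = int(rng.integers(0, max(len(params.backbone) - flank_len, 1)))
            flank = params.backbone[off:off + flank_len]
            base_id = f"bb{ins.molecule_id}"
        else:
            flank = _genomic_flank(genome, ins, flank_len)
            base_id = (
                f"mol{ins.molecule_id}:{ins.chrom}:{ins.position}:"
                f"{ins.strand}:{shear}"
            )
        fragment = barcode + params.ir_sequence + flank
        seq1 = _inject_errors(fragment[:R], params.error_rate, rng)
        seq2 = _inject_errors(dna.revcomp(fragment)[:R], params.error_rate, rng)
        parent = ReadPair(base_id, seq1, seq2, "I" * len(seq1), "I" * len(seq2), sample)
        pairs.append(parent)
        # PCR duplicates copy the parent AFTER its errors, then may pick up
        # further substitutions at a tenth of the base error rate
        for j in range(rng.poisson(params.pcr_duplication_rate)):
            d1 = _inject_errors(parent.seq1, params.error_rate / 10, rng)
            d2 = _inject_errors(parent.seq2, params.error_rate / 10, rng)
            pairs.append(
                ReadPair(f"{base_id}.dup{j}", d1, d2, "I" * len(d1), "I" * len(d2), sample)
            )
    if dropped:
        logger.warning("dropped %d molecules with non-positive flank length", dropped)
    return pairs


# ---------------------------------------------------------------------------
# FASTQ i/o — gzip written with mtime=0 so outputs are byte-stable
# ---------------------------------------------------------------------------

def _open_fastq_out(path):
    if str(path).endswith(".gz"):
        raw = open(path, "wb")
        return gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
    return open(path, "wb")


def write_fastq_pair(pairs: Iterable[ReadPair], path1, path2) -> None:
    with _open_fastq_out(path1) as f1, _open_fastq_out(path2) as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n".encode())
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n".encode())


def read_fastq_pair(path1, path2, sample: str = "") -> List[ReadPair]:
    def _read(path):
        op = gzip.open if str(path).endswith(".gz") else open
        with op(path, "rt") as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        return [
            (lines[i][1:].rsplit("/", 1)[0], lines[i + 1], lines[i + 3])
            for i in range(0, len(lines) - 3, 4)
        ]

    r1, r2 = _read(path1), _read(path2)
    if len(r1) != len(r2):
        raise ValueError("FASTQ mates have different read counts")
    return [
        ReadPair(id1, s1, s2, q1, q2, sample)
        for (id1, s1, q1), (_, s2, q2) in zip(r1, r2)
    ]
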
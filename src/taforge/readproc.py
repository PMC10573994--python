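"""Pre-mapping cleanup of raw junction-library read pairs.

Stage order mirrors the wet-lab pipeline the simulator emulates:
demultiplex -> IR-primer filter (Hamming, 6 mismatches allowed) -> residual
IR verification and trim -> plasmid-backbone discard -> exact-sequence PCR
deduplication (on raw pairs, before merging) -> overlap merge of the pair
(or keep read1 alone) -> minimum-length (>= 30 bp) cut.

The surviving record is a junction sequence that begins at the genomic TA,
plus a shear key (the read2 sequence) that identifies the sonication break
point for downstream independent-read support counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import dna
from .library import ReadPair

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ProcessParams:
    barcode_map: Dict[str, str]
    primer: str
    ir_sequence: str
    backbone: str = ""
    primer_max_mismatch: int = 6
    ir_max_mismatch: int = 2
    backbone_k: int = 25
    min_len: int = 30
    min_overlap: int = 10
    max_overlap_mismatch_frac: float = 0.1


@dataclass
class JunctionRead:
    id: str
    seq: str  # junction sequence, first base = T of the target TA
    shear_key: str
    merged: bool
    sample: str


@dataclass
class ProcessStats:
    """Per-sample filter accounting; reason codes partition the input."""

    input: int = 0
    primer_rejected: int = 0
    primer_too_short: int = 0
    ir_rejected: int = 0
    backbone_discarded: int = 0
    duplicates_removed: int = 0
    too_short: int = 0
    survivors: int = 0
    merged: int = 0
    read1_only: int = 0

    def rejected_total(self) -> int:
        return (
            self.primer_rejected + self.primer_too_short + self.ir_rejected
            + self.backbone_discarded + self.duplicates_removed + self.too_short
        )

    def conserved(self) -> bool:
        return self.input == self.survivors + self.rejected_total()

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# individual operations
# ---------------------------------------------------------------------------

def demultiplex(
    pairs: Iterable[ReadPair], barcode_map: Dict[str, str]
) -> Dict[str, List[ReadPair]]:
    """Assign each pair to the sample whose barcode equals the read1 prefix.

    Non-matching pairs go to the ``"undetermined"`` bin.  Barcodes must be
    equal-length and mutually distinct.
    """
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ConfigError("duplicate barcode sequences")
    if len({len(b) for b in barcodes}) > 1:
        raise ConfigError("barcodes must be equal length")
    by_prefix = {b: s for s, b in barcode_map.items()}
    blen = len(barcodes[0])
    out: Dict[str, List[ReadPair]] = {s: [] for s in barcode_map}
    out["undetermined"] = []
    for p in pairs:
        sample = by_prefix.get(p.seq1[:blen], "undetermined")
        out[sample].append(p)
    for sample, lst in out.items():
        logger.info("demultiplex: %s -> %d pairs", sample, len(lst))
    return out


def primer_filter(
    read1: str, primer: str, max_mismatch: int = 6, offset: int = 0
) -> Tuple[bool, int, str]:
    """Hamming-match the IR-specific primer at its expected offset.

    Returns (accepted, end offset one past the primer, reason code).
    """
    segment = read1[offset:offset + len(primer)]
    if len(segment) < len(primer):
        return False, -1, "too_short"
    mm = dna.hamming(segment, primer)
    if mm > max_mismatch:
        return False, -1, "primer_mismatch"
    return True, offset + len(primer), "ok"


def ir_verify_and_trim(
    read1: str, ir_sequence: str, primer: str, max_mismatch: int = 2,
    offset: int = 0,
) -> Optional[str]:
    """Verify the residual IR between primer end and junction; trim it off.

    Returns the genomic flank (read1 with barcode+primer+IR removed, i.e.
    beginning at the TA), or None for non-specific amplification.
    """
    residual = ir_sequence[len(primer):]
    start = offset + len(primer)
    segment = read1[start:start + len(residual)]
    if len(segment) < len(residual):
        return None
    if dna.hamming(segment, residual) > max_mismatch:
        return None
    return read1[offset + len(ir_sequence):]


def backbone_kmers(backbone: str, k: int = 25) -> frozenset:
    kmers = {backbone[i:i + k] for i in range(len(backbone) - k + 1)}
    return frozenset(kmers | {dna.revcomp(s) for s in kmers})


def backbone_filter(flank: str, kmers: frozenset, k: int = 25,
                    probe_len: int = 50) -> bool:
    """True = keep.  Discard if any k-mer of the flank's first ``probe_len``
    nt occurs in the backbone (either strand).  Flanks too short to judge
    are kept."""
    window = flank[:probe_len]
    if len(window) < k:
        return True
    return not any(window[i:i + k] in kmers for i in range(len(window) - k + 1))


def deduplicate(pairs: Sequence[ReadPair]) -> List[ReadPair]:
    """Collapse byte-identical (seq1, seq2) pairs to one representative.

    The representative is the lexicographically smallest read id within each
    identity class, so the output is independent of input order.
    """
    best: Dict[Tuple[str, str], ReadPair] = {}
    for p in pairs:
        key = (p.seq1, p.seq2)
        prev = best.get(key)
        if prev is None or p.id < prev.id:
            best[key] = p
    kept = sorted(best.values(), key=lambda p: p.id)
    logger.info("deduplicate: %d -> %d pairs", len(list(pairs)), len(kept))
    return kept


def merge_pair(
    seq1: str, seq2: str, min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Optional[str]:
    """Reconstruct the fragment by overlapping read1 with revcomp(read2).

    Scans overlaps from longest to shortest and accepts the first whose
    mismatch fraction is within budget; mismatching positions take read1's
    base.  Returns None if no acceptable overlap exists.
    """
    r2 = dna.revcomp(seq2)
    a = np.frombuffer(seq1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(r2.encode("ascii"), dtype=np.uint8)
    max_ov = min(len(a), len(b))
    for ov in range(max_ov, min_overlap - 1, -1):
        mm = int(np.count_nonzero(a[len(a) - ov:] != b[:ov]))
        if mm <= max_mismatch_frac * ov:
            return seq1 + r2[ov:]
    return None


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def process_sample(
    pairs: Sequence[ReadPair], sample: str, params: ProcessParams
) -> Tuple[List[JunctionRead], ProcessStats]:
    """Run one demultiplexed sample through the full cleanup chain."""
    stats = ProcessStats(input=len(pairs))
    barcode = params.barcode_map[sample]
    blen = len(barcode)
    prefix_len = blen + len(params.ir_sequence)
    bb_kmers = backbone_kmers(params.backbone, params.backbone_k) \
        if params.backbone else frozenset()

    passed: List[ReadPair] = []
    for p in pairs:
        ok, _, reason = primer_filter(
            p.seq1, params.primer, params.primer_max_mismatch, offset=blen
        )
        if not ok:
            if reason == "too_short":
                stats.primer_too_short += 1
            else:
                stats.primer_rejected += 1
            continue
        flank = ir_verify_and_trim(
            p.seq1, params.ir_sequence, params.primer,
            params.ir_max_mismatch, offset=blen,
        )
        if flank is None:
            stats.ir_rejected += 1
            continue
        if bb_kmers and not backbone_filter(flank, bb_kmers, params.backbone_k):
            stats.backbone_discarded += 1
            continue
        passed.append(p)

    unique = deduplicate(passed)
    stats.duplicates_removed = len(passed) - len(unique)

    out: List[JunctionRead] = []
    for p in unique:
        merged_frag = merge_pair(
            p.seq1, p.seq2, params.min_overlap, params.max_overlap_mismatch_frac
        )
        if merged_frag is not None:
            junction = merged_frag[prefix_len:]
            merged = True
        else:
            junction = p.seq1[prefix_len:]
            merged = False
        if len(junction) < params.min_len:
            stats.too_short += 1
            continue
        stats.merged += int(merged)
        stats.read1_only += int(not merged)
        out.append(JunctionRead(p.id, junction, p.seq2, merged, sample))

    stats.survivors = len(out)
    assert stats.conserved(), "filter accounting does not partition the input"
    return out, stats


def process_library(
    pairs: Iterable[ReadPair], params: ProcessParams
) -> Tuple[Dict[str, List[JunctionRead]], Dict[str, ProcessStats]]:
    """Demultiplex then clean every sample; returns per-sample outputs."""
    demux = demultiplex(pairs, params.barcode_map)
    junctions: Dict[str, List[JunctionRead]] = {}
    stats: Dict[str, ProcessStats] = {}
    for sample in params.barcode_map:
        junctions[sample], stats[sample] = process_sample(
            demux[sample], sample, params
        )
    und = ProcessStats(input=len(demux["undetermined"]))
    und.survivors = 0
    und.primer_rejected = und.input  # undetermined pairs count as rejected
    stats["undetermined"] = und
    return junctions, stats


def write_junction_fasta(reads: Sequence[JunctionRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id} merged={int(r.merged)}\n{r.seq}\n")


def write_stats_tsv(stats: Dict[str, ProcessStats], path) -> None:
    keys = list(ProcessStats().__dict__)
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(keys) + "\n")
        for sample in sorted(stats):
            d = stats[sample].as_dict()
            fh.write(sample + "\t" + "\t".join(str(d[k]) for k in keys) + "\n")
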
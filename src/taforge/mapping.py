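"""k-mer seed mapping of junction sequences and insertion-site calling.

A desk-scale substitute for a general short-read aligner: an exact 31-mer
index over the genome seeds candidate loci, which are then verified by
full-length Hamming comparison (the library simulator emits substitutions
only, so gapped alignment is unnecessary).  Two regimes mirror common
practice for non-repetitive vs. repetitive targets:

* ``unique``  — a read is kept only if exactly one best locus exists;
* ``random``  — one of the tied best loci is chosen uniformly at random
  with a seeded generator.

Sites are called per (chromosome, TA coordinate), pooling both strands, and
supported by the number of distinct sonication shear keys among their reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import dna
from .genome import GenomeModel
from .readproc import JunctionRead

_SEP = np.uint8(8)  # inter-chromosome separator code (never matches a query)


def _rolling_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-window of 2-bit codes into a uint64 (4**k <= 2**62)."""
    n = len(codes) - k + 1
    powers = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    out = np.empty(n, dtype=np.uint64)
    win = sliding_window_view(codes, k)
    step = 1 << 16
    for i in range(0, n, step):
        out[i:i + step] = win[i:i + step].astype(np.uint64) @ powers
    return out


class KmerIndex:
    """Exact k-mer -> sorted genome locus index (plus-strand windows).

    Reverse-strand hits are found by querying the reverse complement of the
    read, so each genomic window is stored once.
    """

    def __init__(self, genome: GenomeModel, k: int = 31):
        if k < 1 or k > 31:
            raise ValueError("k must be in [1, 31]")
        self.genome = genome
        self.k = k
        self.chrom_names = genome.names()
        self._chrom_codes = [genome.codes(n) for n in self.chrom_names]
        lengths = [len(c) for c in self._chrom_codes]
        # concatenate with separators so windows never span chromosomes
        sep = np.full(k - 1, _SEP, dtype=np.uint8)
        chunks: List[np.ndarray] = []
        starts: List[int] = []
        pos = 0
        for codes in self._chrom_codes:
            starts.append(pos)
            chunks.append(codes)
            chunks.append(sep)
            pos += len(codes) + k - 1
        cat = np.concatenate(chunks)
        self._starts = np.asarray(starts, dtype=np.int64)
        self._lengths = np.asarray(lengths, dtype=np.int64)

        hashes = _rolling_hashes(cat, k)
        bad = np.cumsum(np.concatenate([[0], (cat > 3).astype(np.int64)]))
        valid = (bad[k:] - bad[:-k]) == 0
        pos_all = np.nonzero(valid)[0]
        hs = hashes[pos_all]
        order = np.argsort(hs, kind="stable")
        hs_sorted = hs[order]
        pos_sorted = pos_all[order]
        uniq, first = np.unique(hs_sorted, return_index=True)
        groups = np.split(pos_sorted, first[1:])
        self._map: Dict[int, np.ndarray] = {
            int(h): np.sort(g) for h, g in zip(uniq, groups)
        }

    def lookup(self, kmer_codes: np.ndarray) -> List[Tuple[int, int]]:
        """Loci of an exact k-mer as (chromosome index, 0-based offset)."""
        h = int(kmer_codes.astype(np.uint64) @
                (4 ** np.arange(self.k - 1, -1, -1, dtype=np.uint64)))
        hits = self._map.get(h)
        if hits is None:
            return []
        ci = np.searchsorted(self._starts, hits, side="right") - 1
        return [(int(c), int(p - self._starts[c])) for c, p in zip(ci, hits)]

    def lookup_seq(self, kmer: str) -> List[Tuple[int, int]]:
        return self.lookup(dna.encode(kmer))


def build_index(genome: GenomeModel, k: int = 31) -> KmerIndex:
    return KmerIndex(genome, k)


@dataclass
class MappedRead:
    read_id: str
    chrom: str
    position: int  # 0-based coordinate of the junction's first base (T of TA)
    strand: str
    n_candidate_loci: int
    shear_key: str
    mismatches: int


@dataclass
class InsertionSite:
    chrom: str
    position: int
    strand: str
    support: int
    mode: str
    is_ta: bool


def map_junction(
    seq: str,
    index: KmerIndex,
    mode: str = "unique",
    max_mismatch_frac: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    shear_key: str = "",
    read_id: str = "",
) -> Optional[MappedRead]:
    """Map one junction sequence; None means unmapped (or ambiguous in
    unique mode).

    Candidates are seeded at k-spaced offsets on both strands, deduplicated,
    verified full-length within the Hamming budget, and ranked by mismatch
    count.  Random mode draws uniformly among the tied best loci from ``rng``
    after sorting candidates canonically, so results are reproducible and
    independent of read order.
    """
    if mode not in ("unique", "random"):
        raise ValueError("mode must be 'unique' or 'random'")
    k = index.k
    L = len(seq)
    if L < k:
        return None
    q_fwd = dna.encode(seq)
    q_rev = dna.revcomp_codes(q_fwd)
    budget = int(max_mismatch_frac * L)

    offsets = list(range(0, L - k + 1, k))
    candidates = set()
    for strand, q in (("+", q_fwd), ("-", q_rev)):
        for off in offsets:
            for ci, p in index.lookup(q[off:off + k]):
                start = p - off
                if start < 0 or start + L > index._lengths[ci]:
                    continue
                candidates.add((ci, start, strand))

    scored: List[Tuple[int, int, int, str]] = []
    for ci, start, strand in candidates:
        ref = index._chrom_codes[ci][start:start + L]
        q = q_fwd if strand == "+" else q_rev
        mm = int(np.count_nonzero(ref != q))
        if mm <= budget:
            scored.append((mm, ci, start, strand))
    if not scored:
        return None
    best_mm = min(s[0] for s in scored)
    best = sorted(s for s in scored if s[0] == best_mm)

    if mode == "unique":
        if len(best) != 1:
            return None
        pick = best[0]
    else:
        if rng is None:
            raise ValueError("random mode requires an rng")
        pick = best[int(rng.integers(len(best)))]

    mm, ci, start, strand = pick
    position = start if strand == "+" else start + L - 2
    return MappedRead(
        read_id=read_id,
        chrom=index.chrom_names[ci],
        position=int(position),
        strand=strand,
        n_candidate_loci=len(best),
        shear_key=shear_key,
        mismatches=mm,
    )


def map_reads(
    reads: Sequence[JunctionRead],
    index: KmerIndex,
    mode: str = "unique",
    max_mismatch_frac: float = 0.05,
    seed: int = 0,
) -> Tuple[List[MappedRead], Dict[str, int]]:
    """Map a batch of junction reads in a canonical order.

    Reads are sorted by id before any random draws, so random-mode output is
    invariant to input permutation under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    mapped: List[MappedRead] = []
    stats = {"input": len(reads), "mapped": 0, "unique": 0, "multi": 0,
             "unmapped": 0}
    for r in sorted(reads, key=lambda x: x.id):
        m = map_junction(
            r.seq, index, mode=mode, max_mismatch_frac=max_mismatch_frac,
            rng=rng, shear_key=r.shear_key, read_id=r.id,
        )
        if m is None:
            stats["unmapped"] += 1
            continue
        stats["mapped"] += 1
        if m.n_candidate_loci == 1:
            stats["unique"] += 1
        else:
            stats["multi"] += 1
        mapped.append(m)
    return mapped, stats


def call_sites(
    mapped: Sequence[MappedRead],
    genome: GenomeModel,
    min_support: int = 5,
    mode: str = "unique",
) -> List[InsertionSite]:
    """Group mapped reads by (chromosome, TA coordinate) and call sites.

    Support is the number of distinct shear keys (independent sonication
    break points) in the group; both strands pool into one site.  Sites whose
    reference dinucleotide is not TA are retained but flagged, so downstream
    enrichment can exclude them.
    """
    groups: Dict[Tuple[str, int], set] = {}
    for m in mapped:
        groups.setdefault((m.chrom, m.position), set()).add(m.shear_key)
    sites: List[InsertionSite] = []
    for (chrom, pos), shear_keys in sorted(groups.items()):
        support = len(shear_keys)
        if support < min_support:
            continue
        seq = genome.seq(chrom)
        is_ta = seq[pos:pos + 2] == "TA"
        sites.append(InsertionSite(chrom, pos, ".", support, mode, is_ta))
    return sites


def write_sites_bed(sites: Sequence[InsertionSite], path, seed=None) -> None:
    """BED6: name = calling mode (suffixed for non-TA flags), score = support."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# taforge sites; seed={seed}\n")
        for s in sites:
            name = s.mode if s.is_ta else f"{s.mode};non-TA"
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 2}\t{name}\t"
                f"{s.support}\t{s.strand}\n"
            )


def read_sites_bed(path) -> List[InsertionSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, _end, name, score, strand = line.split("\t")[:6]
            mode, _, flag = name.partition(";")
            sites.append(
                InsertionSite(chrom, int(start), strand.strip(), int(score),
                              mode, flag != "non-TA")
            )
    return sites
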
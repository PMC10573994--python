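"""Synthetic genome construction and ground-truth insertion sampling.

The generator builds a desk-scale multi-chromosome genome whose acrocentric
chromosomes carry a nucleolus-organizer-like structure: a short p-arm split
into p13 / p12 / p11.2 cytobands, where the central p12 band is TA-poor and
built from exact tandem copies of a single repeat unit (so that reads from it
multi-map), flanked by TA-normal bands.  Interval annotation sets emulating
nucleolus-associated domains (NAD), lamina-associated domains (LAD) and
transcription-factor ChIP peaks are laid down preferentially on the
acrocentric p-arm neighbourhoods, so a p-arm-targeted insertion bias
propagates into them.

TA-dinucleotide density is controlled exactly: band backgrounds are sampled
TA-free from the configured base composition and the requested number of TA
dinucleotides is then planted on a non-overlapping grid, so the measured
density equals the configured one to rounding.

Insertions follow the Sleeping Beauty target rule: the probability of
integrating anywhere that is not the first base of a genomic TA is zero.
Eligible TA sites carry a weight equal to the product of the multiplicative
biases of every configured region containing them, times a palindrome weight
when the 8-mer window centred on the TA is exactly ``ATATATAT``.

Coordinates are 0-based, half-open throughout.  An insertion's coordinate is
the offset of the T of the target TA on the + strand, for either insertion
orientation (the transposase duplicates the TA, so both orientations share
one coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import dna
from .dna import A, C, G, T

PALINDROME_CONTEXT = "ATATATAT"  # 8-mer centred on the TA target


class ConfigError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSpec:
    """One cytoband: its label, fraction of the chromosome, and TA density.

    ``ta_density`` is TA dinucleotides per base pair; the theoretical maximum
    on the planting grid is slightly under 0.5.
    """

    label: str
    fraction: float
    ta_density: float = 0.05


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int
    acrocentric: bool
    bands: Tuple[BandSpec, ...]


@dataclass(frozen=True)
class AnnotationSpec:
    """Placement recipe for one named interval set."""

    n_intervals: int
    length: int
    acro_p_fraction: float  # probability an interval lands near an acro p-arm


@dataclass(frozen=True)
class GenomeConfig:
    chromosomes: Tuple[ChromosomeSpec, ...]
    repeat_unit_length: int = 500
    repeat_band: str = "p12"
    # base composition (A, C, G, T); human-like AT-rich default
    base_comp: Tuple[float, float, float, float] = (0.295, 0.205, 0.205, 0.295)
    annotations: Dict[str, AnnotationSpec] = field(default_factory=dict)
    seed: int = 0


def default_annotation_specs() -> Dict[str, AnnotationSpec]:
    return {
        "NAD": AnnotationSpec(25, 4000, 0.70),
        "LAD_A": AnnotationSpec(30, 5000, 0.35),
        "LAD_B": AnnotationSpec(20, 5000, 0.35),
        "UBTF_peak": AnnotationSpec(40, 300, 0.80),
        "POL2_peak": AnnotationSpec(40, 300, 0.10),
        "POL3_peak": AnnotationSpec(40, 300, 0.10),
    }


def default_config(seed: int = 0) -> GenomeConfig:
    """The study-condition genome.

    Five acrocentric chromosomes (98 kb each: 2 kb p13, 10 kb p12 built from
    20 copies of a 500 bp low-TA repeat unit, 2 kb p11.2, 84 kb q) and two
    non-acrocentric 150 kb chromosomes with ordinary p/q arms.  The resulting
    acrocentric p-arms hold a small share (~4%) of the genome's TA weight,
    mirroring the smallness of the real NOR-bearing arms relative to the
    genome.
    """
    acro_bands = (
        BandSpec("p13", 2 / 98, 0.05),
        BandSpec("p12", 10 / 98, 0.008),
        BandSpec("p11.2", 2 / 98, 0.05),
        BandSpec("q", 84 / 98, 0.05),
    )
    nonacro_bands = (BandSpec("p", 0.4, 0.05), BandSpec("q", 0.6, 0.05))
    chroms = tuple(
        ChromosomeSpec(name, 98_000, True, acro_bands)
        for name in ("chr13", "chr14", "chr15", "chr21", "chr22")
    ) + tuple(
        ChromosomeSpec(name, 150_000, False, nonacro_bands)
        for name in ("chr1", "chr2")
    )
    return GenomeConfig(
        chromosomes=chroms, annotations=default_annotation_specs(), seed=seed
    )


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """A built genome: sequences, cytobands and annotation interval sets."""

    chromosomes: List[Tuple[str, str]]  # (name, sequence)
    acrocentric: Dict[str, bool]
    cytobands: Dict[str, List[Tuple[int, int, str]]]
    annotations: Dict[str, List[Tuple[str, int, int]]]
    config: GenomeConfig | None = None
    _codes: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _ta: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    # -- accessors ---------------------------------------------------------
    def names(self) -> List[str]:
        return [name for name, _ in self.chromosomes]

    def seq(self, chrom: str) -> str:
        for name, s in self.chromosomes:
            if name == chrom:
                return s
        raise KeyError(f"unknown chromosome {chrom!r}")

    def length(self, chrom: str) -> int:
        return len(self.seq(chrom))

    def codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._codes:
            self._codes[chrom] = dna.encode(self.seq(chrom))
        return self._codes[chrom]

    def ta_sites(self, chrom: str) -> np.ndarray:
        """0-based positions of the T of every TA on the chromosome."""
        if chrom not in self._ta:
            self._ta[chrom] = dna.ta_positions(self.codes(chrom))
        return self._ta[chrom]

    def ta_density(self, chrom: str, start: int, end: int) -> float:
        sites = self.ta_sites(chrom)
        n = int(np.searchsorted(sites, end - 1) - np.searchsorted(sites, start))
        return n / max(end - start, 1)

    # -- region resolution -------------------------------------------------
    def p_arm_end(self, chrom: str) -> int:
        """End coordinate of the last p-band (0 if the chromosome has none)."""
        end = 0
        for s, e, label in self.cytobands[chrom]:
            if label.startswith("p"):
                end = max(end, e)
        return end

    def regions(self, label: str) -> List[Tuple[str, int, int]]:
        """Resolve a region label to a list of (chrom, start, end) intervals.

        Labels may name an annotation set, a cytoband label (``p13``, ``q``,
        ...), or the synthetic unions ``acro_p_arm`` / ``non_acro_p_arm``.
        """
        if label in self.annotations:
            return list(self.annotations[label])
        if label in ("acro_p_arm", "non_acro_p_arm"):
            want_acro = label == "acro_p_arm"
            out = []
            for name in self.names():
                if self.acrocentric[name] != want_acro:
                    continue
                end = self.p_arm_end(name)
                if end > 0:
                    out.append((name, 0, end))
            return out
        out = [
            (name, s, e)
            for name in self.names()
            for s, e, lab in self.cytobands[name]
            if lab == label
        ]
        if not out:
            raise KeyError(f"unknown region label {label!r}")
        return out

    # -- emission ----------------------------------------------------------
    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def write_cytobands_bed(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.names():
                for s, e, label in self.cytobands[name]:
                    fh.write(f"{name}\t{s}\t{e}\t{label}\n")

    def write_annotations_bed(self, path, which: str) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.annotations[which]:
                fh.write(f"{chrom}\t{s}\t{e}\t{which}\t0\t.\n")

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Assert the structural invariants of the model (cheap, exact)."""
        for name in self.names():
            bands = self.cytobands[name]
            if bands[0][0] != 0 or bands[-1][1] != self.length(name):
                raise AssertionError(f"cytobands do not tile {name}")
            for (s1, e1, _), (s2, e2, _) in zip(bands, bands[1:]):
                if e1 != s2 or s1 >= e1:
                    raise AssertionError(f"cytobands unsorted/overlapping on {name}")
        for label, ivals in self.annotations.items():
            for chrom, s, e in ivals:
                if not (0 <= s < e <= self.length(chrom)):
                    raise AssertionError(f"{label} interval out of bounds on {chrom}")


@dataclass(frozen=True)
class TargetModel:
    """Sleeping Beauty insertion probability law.

    ``region_bias`` maps a region label (cytoband label, annotation name, or
    ``acro_p_arm``) to a multiplicative weight applied to every TA site the
    region contains.  ``palindrome_weight`` multiplies TA sites whose 8-mer
    context is exactly ``ATATATAT``.  Probability is zero off TA sites and
    proportional to the product of applicable weights on them.
    """

    region_bias: Dict[str, float] = field(default_factory=dict)
    palindrome_weight: float = 1.0
    condition_label: str = "SB100X"

    def __post_init__(self):
        for label, w in self.region_bias.items():
            if not np.isfinite(w) or w < 0:
                raise ConfigError(f"region bias for {label!r} must be finite and >= 0")
        if not np.isfinite(self.palindrome_weight) or self.palindrome_weight < 1:
            raise ConfigError("palindrome_weight must be finite and >= 1")


@dataclass(frozen=True)
class TruthInsertion:
    chrom: str
    position: int  # 0-based T of the target TA
    strand: str  # '+' or '-'
    molecule_id: int


# ---------------------------------------------------------------------------
# sequence assembly
# ---------------------------------------------------------------------------

def _background_no_ta(rng: np.random.Generator, length: int,
                      comp: Sequence[float]) -> np.ndarray:
    """i.i.d. bases from ``comp`` with every TA dinucleotide broken."""
    codes = rng.choice(4, size=length, p=np.asarray(comp) / np.sum(comp)).astype(np.uint8)
    idx = np.nonzero((codes[:-1] == T) & (codes[1:] == A))[0]
    if idx.size:
        codes[idx + 1] = rng.choice([C, G], size=idx.size).astype(np.uint8)
    # breaking an A cannot create a new TA, so one pass suffices
    if codes.size and codes[0] == A:
        codes[0] = G  # avoid TA forming across a band junction
    return codes


def _plant_ta(codes: np.ndarray, rng: np.random.Generator, density: float) -> None:
    """Overwrite non-overlapping positions with TA to hit ``density`` exactly."""
    length = len(codes)
    n_ta = int(round(density * length))
    slots = np.arange(0, length - 1, 2)
    if n_ta > slots.size:
        raise ConfigError(
            f"TA density {density} exceeds the maximum plantable on {length} bp"
        )
    chosen = rng.choice(slots, size=n_ta, replace=False)
    codes[chosen] = T
    codes[chosen + 1] = A


def _build_band(rng: np.random.Generator, length: int, density: float,
                comp: Sequence[float]) -> np.ndarray:
    codes = _background_no_ta(rng, length, comp)
    _plant_ta(codes, rng, density)
    return codes


def _band_lengths(spec: ChromosomeSpec) -> List[int]:
    fracs = [b.fraction for b in spec.bands]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ConfigError(
            f"band fractions on {spec.name} sum to {sum(fracs)}, expected 1"
        )
    lens = [int(round(f * spec.length)) for f in fracs[:-1]]
    lens.append(spec.length - sum(lens))
    if min(lens) <= 0:
        raise ConfigError(f"degenerate band length on {spec.name}")
    return lens


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_genome(config: GenomeConfig, seed: int | None = None) -> GenomeModel:
    """Build a :class:`GenomeModel` from a :class:`GenomeConfig`.

    Deterministic under a fixed seed (``config.seed`` unless overridden).
    The band named ``config.repeat_band`` is assembled from exact tandem
    copies of a single repeat unit, so its band length must be a multiple of
    ``config.repeat_unit_length``.
    """
    n_acro = sum(c.acrocentric for c in config.chromosomes)
    n_non = sum(not c.acrocentric for c in config.chromosomes)
    if n_acro < 2 or n_non < 1:
        raise ConfigError("need >=2 acrocentric and >=1 non-acrocentric chromosomes")
    for c in config.chromosomes:
        if c.length < 30_000:
            raise ConfigError(f"{c.name}: chromosome length must be >= 30 kb")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    chromosomes: List[Tuple[str, str]] = []
    cytobands: Dict[str, List[Tuple[int, int, str]]] = {}
    acro_flags: Dict[str, bool] = {}

    for spec in config.chromosomes:
        lens = _band_lengths(spec)
        parts: List[np.ndarray] = []
        bands: List[Tuple[int, int, str]] = []
        pos = 0
        for band, blen in zip(spec.bands, lens):
            if band.label == config.repeat_band:
                unit_len = config.repeat_unit_length
                if blen % unit_len != 0:
                    raise ConfigError(
                        f"{spec.name}:{band.label} length {blen} is not a "
                        f"multiple of the repeat unit length {unit_len}"
                    )
                unit = _build_band(rng, unit_len, band.ta_density, config.base_comp)
                codes = np.tile(unit, blen // unit_len)
            else:
                codes = _build_band(rng, blen, band.ta_density, config.base_comp)
            parts.append(codes)
            bands.append((pos, pos + blen, band.label))
            pos += blen
        seq = dna.decode(np.concatenate(parts))
        chromosomes.append((spec.name, seq))
        cytobands[spec.name] = bands
        acro_flags[spec.name] = spec.acrocentric

    model = GenomeModel(chromosomes, acro_flags, cytobands, {}, config)
    model.annotations = _place_annotations(model, config, rng)
    model.validate()
    _check_density_ordering(model, config)
    return model


def _check_density_ordering(model: GenomeModel, config: GenomeConfig) -> None:
    """Generator guarantee: the repeat band is TA-poorer than its flanks."""
    for spec in config.chromosomes:
        bands = {label: (s, e) for s, e, label in model.cytobands[spec.name]}
        if config.repeat_band not in bands:
            continue
        rep = model.ta_density(spec.name, *bands[config.repeat_band])
        for flank in ("p13", "p11.2"):
            if flank in bands:
                if not rep < model.ta_density(spec.name, *bands[flank]):
                    raise AssertionError(
                        f"{spec.name}: {config.repeat_band} TA density is not "
                        f"below that of {flank}"
                    )


def _place_annotations(model: GenomeModel, config: GenomeConfig,
                       rng: np.random.Generator) -> Dict[str, List[Tuple[str, int, int]]]:
    acro = [n for n in model.names() if model.acrocentric[n]]
    non_acro = [n for n in model.names() if not model.acrocentric[n]]
    out: Dict[str, List[Tuple[str, int, int]]] = {}
    for label, spec in config.annotations.items():
        ivals: List[Tuple[str, int, int]] = []
        for _ in range(spec.n_intervals):
            if rng.random() < spec.acro_p_fraction:
                chrom = acro[rng.integers(len(acro))]
                # within or just distal of the p-arm neighbourhood
                hi = min(model.p_arm_end(chrom) + 5000, model.length(chrom))
            else:
                chrom = non_acro[rng.integers(len(non_acro))]
                hi = model.length(chrom)
            length = min(spec.length, hi)
            start = int(rng.integers(0, max(hi - length, 1)))
            ivals.append((chrom, start, start + length))
        ivals.sort()
        out[label] = ivals
    return out


def insertion_weights(genome: GenomeModel, model: TargetModel):
    """Per-TA-site sampling weights for ``model`` over ``genome``.

    Returns (chrom_index, positions, weights) over every TA site genome-wide,
    in chromosome order.  Exposed separately from the sampler so tests can
    compute exact expected proportions.
    """
    chrom_idx: List[np.ndarray] = []
    positions: List[np.ndarray] = []
    weights: List[np.ndarray] = []
    pat = dna.encode(PALINDROME_CONTEXT)
    for ci, name in enumerate(genome.names()):
        pos = genome.ta_sites(name)
        w = np.ones(pos.size, dtype=float)
        codes = genome.codes(name)
        if model.palindrome_weight != 1.0 and pos.size:
            ok = (pos >= 3) & (pos + 5 <= len(codes))
            idx = pos[ok]
            match = np.ones(idx.size, dtype=bool)
            for j in range(8):
                match &= codes[idx - 3 + j] == pat[j]
            full = np.zeros(pos.size, dtype=bool)
            full[ok] = match
            w[full] *= model.palindrome_weight
        for label, theta in model.region_bias.items():
            for chrom, s, e in genome.regions(label):
                if chrom != name:
                    continue
                inside = (pos >= s) & (pos < e)
                w[inside] *= theta
        chrom_idx.append(np.full(pos.size, ci, dtype=np.int32))
        positions.append(pos)
        weights.append(w)
    return (
        np.concatenate(chrom_idx) if chrom_idx else np.empty(0, np.int32),
        np.concatenate(positions) if positions else np.empty(0, np.int64),
        np.concatenate(weights) if weights else np.empty(0, float),
    )


def simulate_insertions(genome: GenomeModel, model: TargetModel, n: int,
                        seed: int) -> List[TruthInsertion]:
    """Sample ``n`` i.i.d. ground-truth insertions from the target model.

    Sites may recur (independent transposition events).  Raises if the genome
    has no TA site or every weight is zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    chrom_idx, positions, weights = insertion_weights(genome, model)
    if positions.size == 0:
        raise ValueError("genome contains no TA dinucleotide")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all insertion weights are zero")
    rng = np.random.default_rng(seed)
    picks = rng.choice(positions.size, size=n, p=weights / total)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    names = genome.names()
    return [
        TruthInsertion(names[chrom_idx[i]], int(positions[i]), str(strands[j]), j)
        for j, i in enumerate(picks)
    ]


def write_truth_bed(truth: Sequence[TruthInsertion], path) -> None:
    """BED6 with the molecule id in the name field."""
    with open(path, "w") as fh:
        for ins in truth:
            fh.write(
                f"{ins.chrom}\t{ins.position}\t{ins.position + 2}\t"
                f"mol{ins.molecule_id}\t0\t{ins.strand}\n"
            )
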
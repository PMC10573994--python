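# Methods

## The target model

*Sleeping Beauty* transposase integrates its cargo at TA dinucleotides and
duplicates the TA on insertion. `taforge` encodes this as a discrete
probability law over genomic positions: the insertion probability is zero at
any position that is not the first base of a TA, and at TA site *i* it is
proportional to

    w_i = Π_r θ_r(i) · [ w_pal if the 8-mer centred on the TA is ATATATAT ]

where θ_r ≥ 0 is a multiplicative bias attached to a named region set
(cytoband label, annotation set, or the `acro_p_arm` union) containing *i*,
and `w_pal ≥ 1` models the transposase's preference for an AT-palindromic
context. Probabilities normalize over all TA sites genome-wide; insertions
are sampled i.i.d., so a site can recur (independent transposition events).
Because the TA is duplicated, both insertion orientations share one
coordinate: the 0-based offset of the T on the plus strand, which is the
canonical key for deduplication, support counting and region overlap
throughout (all coordinates 0-based, half-open).

The palindrome test is an exact 8-mer match; partial matches get weight 1.
This is the simplest rule that reproduces the expected logo shape. No
quantitative estimate of the context effect exists to calibrate against, so
`w_pal` defaults to 1 and is exposed as a parameter; a directional test
(weight 8 vs 1 raises flanking A/T frequencies) is the contract, not a
magnitude.

A fusion-transposase retargeting experiment is modelled as a pair of target
models sharing a genome: a control with θ ≡ 1 and a fusion condition with,
e.g., `{"acro_p_arm": 1.64}`. Note that because the law renormalizes, a
per-TA-site bias ratio θ does not reproduce θ−1 exactly as the measured
percent increase of in-region insertion *proportions*: the expectation is
100·(θ(W+O)/(θW+O) − 1), where W and O are the in/out-of-region TA weight
shares. With the default genome (W ≈ 3.7% on the acrocentric p-arms) a 1.64×
bias yields an expected measured increase of ≈ 60%, and the package reports
what it measures.

## The synthetic genome

`default_config()` builds five acrocentric chromosomes (98 kb: 2 kb p13,
10 kb p12, 2 kb p11.2, 84 kb q) and two ordinary 150 kb chromosomes (p/q
arms). Band sequences are sampled i.i.d. from an AT-rich base composition
(A=T=0.295, C=G=0.205, human-like), every incidental TA is broken, and the
configured number of TAs is then planted on a non-overlapping grid — so
measured TA density equals the configured one to rounding, exactly
controllable per band. Defaults: 0.05 TA/bp everywhere except the p12-like
band at 0.008 TA/bp, making the NOR-like band TA-poor relative to its
flanks by construction (asserted at build time). The p12 band is exact
tandem copies of a single 500 bp unit (20 copies by default), so reads from
it genuinely multi-map with a known copy number. Annotation sets (NAD,
LAD_A, LAD_B, UBTF/POL2/POL3 peaks) are placed interval-by-interval, with a
configurable probability of landing in the acrocentric p-arm
neighbourhood (p-arm + 5 kb), so a p-arm-targeted bias propagates into them.

Scale rationale: chromosome sizes (≥30 kb enforced) keep a full end-to-end
run in seconds while leaving ~37k TA sites genome-wide, enough that 50,000
sampled insertions per condition give in-region counts in the thousands.
The p-arm TA-weight share (~3.7%) was chosen so that a 1.64× bias is
measurable with a small renormalization offset (expected ≈60%, see above)
at useful statistical power.

What the generator does **not** emulate: real rDNA repeat sequence or
karyotype proportions, N bases (the alphabet is ACGT only, so TA eligibility
is always defined), diploidy and copy-number variation of the repeat
arrays, indels and structural errors in reads, quality-score error profiles
(read 2 qualities are constant), optical duplicates, and adapter
read-through. Passing tests therefore demonstrate the statistical machinery
(filter semantics, support counting, regime behaviour on repeats, exactness
of the test), not robustness to every artifact of real libraries.

## Library simulation

Each molecule: sonication shear length ~ Normal(600, 150) bp,
rejection-sampled into the 200–500 bp size-selection window; fragment =
barcode + 40 nt retained IR (whose first 20 nt are the nested-PCR primer) +
genomic flank starting exactly at the TA, flank length = shear − IR length.
Read 1 is the first 150 nt of the fragment, read 2 the reverse complement of
its last 150 nt. PCR duplicates are emitted as byte-identical copies of the
parent *after* the parent's substitution errors (each copy may gain further
errors at error_rate/10), so exact-sequence deduplication is the correct
inverse — mirroring how sequence-identity dedup tools are meant to be used.
A configurable fraction of pairs carries plasmid backbone (a random sequence
verified to share no 25-mer with the genome) after the IR.

## Read processing

Order: demultiplex (exact barcode prefix) → primer Hamming filter (≤6
mismatches at the expected offset) → residual-IR verification (budget 2,
exposed — the primer budget is documented at 6, the residual-IR budget is
not, so it is a parameter) → backbone discard (any 25-mer of the flank's
first 50 nt occurring in the backbone, either strand) → exact (seq1, seq2)
deduplication *before* merging → overlap merge (≥10 nt, ≤10% mismatch,
read 1 wins ties; longest acceptable overlap) or read 1 kept alone →
junction sequences < 30 nt dropped. Quality trimming is deliberately a
no-op: simulated qualities are constant and the only quality step with
analytical consequence is the ≥30 bp rule. Reason-code counts partition the
input exactly, and the surviving set is invariant to input order (dedup
representatives and output ordering are canonical by read id).

The shear key carried forward for support counting is the read-2 sequence:
distinct sonication break points give distinct read-2 content whether or not
the pair merges.

## Mapping and site calling

An exact 31-mer index over the genome seeds candidates at k-spaced offsets
on both strands; candidates are verified full-length by Hamming distance
(≤5% of read length; the simulator emits substitutions only, so no gapped
alignment). `unique` mode keeps a read only when exactly one best locus
exists; `random` mode draws uniformly among tied best loci with a seeded
generator after canonical sorting, so batch output is permutation-invariant
under a fixed seed. "Tied best" means equal minimal Hamming distance within
budget — the notion of "equally good quality" used for the repeat regime.

Sites are called per (chromosome, TA coordinate), pooling strands
(orientation is uninformative given the TA duplication); support is the
number of distinct shear keys, i.e. independent molecules post-dedup.
Default thresholds: support ≥5 in unique mode, ≥1 in random mode (the
repeat-tolerant regime). Called positions whose reference dinucleotide is
not TA (possible via sequencing error) are kept but flagged and excluded
from enrichment by default, honouring the transposase's absolute TA
requirement.

The end-to-end demo (`taforge all`) defaults to the random/support-1 regime:
at desk-scale depth (thousands of insertions over tens of thousands of TA
sites) almost no site accrues five independent molecules, so the unique/≥5
regime is exercised where it is well-posed — on clustered truth with ≥5
molecules per site, as in the fidelity tests.

## Enrichment statistics

The two-sided Fisher exact p is computed by full enumeration of the
hypergeometric conditional distribution (vectorized log-gamma binomials),
summing all tables at most as probable as the observed one with the
customary 1 + 1e-7 relative tie tolerance — the same convention as the
widely used implementations, which agree with this one to ~1e-13 and serve
as an independent cross-check in the tests. Per-region p-values are raw
(matching single-region reporting practice); Benjamini–Hochberg is available
behind a flag. `pct_increase` is exactly the normalized-proportion formula;
when the control has zero in-region insertions it is reported as +inf (p is
still computed). Peak sets are expanded by 500 nt per side, clamped, and
merged before counting; sites are points, counted once under overlapping
regions.

RPKM profiles split a region into 300 near-equal windows (remainder spread
over leading windows): value = count / window-kb / (total sites / 10⁶), so
proportional scaling of counts and totals leaves profiles unchanged. TA
density profiles count overlapping TA start offsets per window, normalize by
window length, min-max scale to [0, 1] (all-0.5 by convention when
constant), then smooth with lowess (default span 0.3, chosen to visibly
smooth 300 bins; deterministic fit).

## Determinism and numerics

Every stochastic step takes an explicit seed; pipeline stages derive their
seeds from the run seed by fixed offsets. FASTQ gzip members are written
with mtime 0 and no filename, and no artifact embeds a timestamp, so two
runs with one seed are byte-identical. Hash packing of 31-mers fits uint64
(4³¹ < 2⁶²); windows spanning chromosome boundaries are masked out of the
index. Degenerate inputs fail loudly and early: band fractions not summing
to one, TA density above the plantable maximum, all-zero insertion weights,
empty site sets, regions shorter than the bin count, and a fully
contaminated library ("no junction reads survived") all raise typed errors.

## Known limitations

The mapper is a Hamming-verified seed index, not a general aligner: reads
with indels or with errors in every seed position go unmapped. Support
counting assumes dedup ran first; running `call_sites` on raw duplicated
reads overstates independence. The renormalization offset described above
means measured percent increases understate the generating per-site bias as
the targeted region's TA-weight share grows — a property of the proportion
statistic itself, which the package reports without correction. Logo output
is a frequency/information table; rendering is left to external tools.
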
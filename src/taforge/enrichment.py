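"""Region-level insertion enrichment statistics and density profiles.

Two insertion-site sets (a control transposase condition A and a fusion
condition B) are compared over labelled interval sets with a two-sided
Fisher exact test on the 2x2 table [in_A, out_A; in_B, out_B].  The headline
effect measure is the percent increase of the in-region insertion
proportion, pct = 100 * ((in_B/total_B) / (in_A/total_A) - 1); insertion
totals normalize each condition, so sequencing-depth differences cancel.

Density profiles split a region into a fixed number of near-equal windows
(300 by default) and normalize insertion counts by the RPKM principle:
count / window-kb / (total insertions / 1e6).  TA-dinucleotide density
profiles over the same windows are length-normalized, min-max scaled to
[0, 1] and smoothed with loess (locally weighted regression).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeModel

Interval = Tuple[str, int, int]


@dataclass
class EnrichmentResult:
    region_label: str
    count_in_a: int
    total_a: int
    count_in_b: int
    total_b: int
    pct_increase: float
    p_value: float
    odds_ratio: float
    p_adjusted: float | None = None


@dataclass
class BinnedProfile:
    region_label: str
    n_bins: int
    values: np.ndarray  # per-bin RPKM-normalized densities
    counts: np.ndarray = field(default=None, repr=False)
    window_lengths: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# interval utilities
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of half-open intervals, sorted, overlaps and abutments merged."""
    out: List[Interval] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], e))
        else:
            out.append((chrom, s, e))
    return out


def expand_peaks(peaks: Iterable[Interval], pad: int,
                 genome: GenomeModel) -> List[Interval]:
    """Grow each interval by ``pad`` nt on both sides, clamp to the
    chromosome, and merge the result."""
    grown = [
        (chrom, max(s - pad, 0), min(e + pad, genome.length(chrom)))
        for chrom, s, e in peaks
    ]
    return merge_intervals(grown)


def _sites_as_points(sites) -> List[Tuple[str, int]]:
    pts = []
    for s in sites:
        if getattr(s, "is_ta", True):
            pts.append((s.chrom, s.position))
    return pts


def count_in_regions(sites, regions: Iterable[Interval],
                     valid_chroms: Sequence[str] | None = None) -> int:
    """Number of sites whose TA coordinate lies in the union of ``regions``.

    Each site is counted once even when regions overlap.  Sites on
    chromosomes outside ``valid_chroms`` (when given) raise an error naming
    the offenders.
    """
    pts = _sites_as_points(sites)
    if valid_chroms is not None:
        bad = sorted({c for c, _ in pts} - set(valid_chroms))
        if bad:
            raise ValueError(f"sites on unknown chromosomes: {bad}")
    merged = merge_intervals(regions)
    by_chrom: Dict[str, List[int]] = {}
    for chrom, pos in pts:
        by_chrom.setdefault(chrom, []).append(pos)
    n = 0
    for chrom in by_chrom:
        ivals = [(s, e) for c, s, e in merged if c == chrom]
        if not ivals:
            continue
        starts = np.array([s for s, _ in ivals])
        ends = np.array([e for _, e in ivals])
        pos = np.asarray(by_chrom[chrom])
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = i >= 0
        n += int(np.count_nonzero(ok & (pos < ends[np.maximum(i, 0)])))
    return n


# ---------------------------------------------------------------------------
# the exact test
# ---------------------------------------------------------------------------

_lgamma_cache = np.zeros(1)


def _lgamma_table(n: int) -> np.ndarray:
    """gammaln(0..n) cached; grows on demand."""
    global _lgamma_cache
    if _lgamma_cache.size <= n:
        from scipy.special import gammaln

        _lgamma_cache = gammaln(np.arange(max(n + 1, 2 * _lgamma_cache.size)))
    return _lgamma_cache


def fisher_exact_two_sided(count_in_a: int, total_a: int, count_in_b: int,
                           total_b: int) -> float:
    """Two-sided exact p for the table [in_A, out_A; in_B, out_B].

    Enumerates the full hypergeometric conditional distribution of the
    top-left cell given the margins and sums the probabilities of every
    table at most as probable as the observed one, with the customary
    relative tolerance of 1e-7 for ties.
    """
    r1, r2, c1 = total_a, total_b, count_in_a + count_in_b
    n = r1 + r2
    lg = _lgamma_table(n + 1)

    def lchoose(nn, kk):
        return lg[nn + 1] - lg[kk + 1] - lg[nn - kk + 1]

    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logpmf = lchoose(r1, k) + lchoose(r2, c1 - k) - lchoose(n, c1)
    pmf = np.exp(logpmf)
    p_obs = pmf[count_in_a - k[0]]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def enrichment_test(count_in_a: int, total_a: int, count_in_b: int,
                    total_b: int, region_label: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test on [in_A, out_A; in_B, out_B].

    pct_increase follows the definition above exactly; it is +inf when
    condition A has no in-region insertions but B does, and 0 when both have
    none.  The odds ratio is reported for condition B relative to A.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= count_in_a <= total_a and 0 <= count_in_b <= total_b):
        raise ValueError("counts must lie within their totals")
    out_a = total_a - count_in_a
    out_b = total_b - count_in_b
    p = fisher_exact_two_sided(count_in_a, total_a, count_in_b, total_b)
    if count_in_a == 0:
        pct = math.inf if count_in_b > 0 else 0.0
    else:
        pct = 100.0 * ((count_in_b / total_b) / (count_in_a / total_a) - 1.0)
    num = count_in_b * out_a
    den = count_in_a * out_b
    odds = math.inf if den == 0 and num > 0 else (num / den if den else math.nan)
    return EnrichmentResult(region_label, count_in_a, total_a, count_in_b,
                            total_b, pct, float(min(p, 1.0)), odds)


def compare_conditions(
    sites_a, sites_b,
    region_sets: Dict[str, List[Interval]],
    genome: GenomeModel | None = None,
    adjust: bool = False,
) -> List[EnrichmentResult]:
    """One enrichment test per region label.

    Per-region p-values are reported raw; ``adjust=True`` adds a
    Benjamini-Hochberg column without altering them.
    """
    pts_a = _sites_as_points(sites_a)
    pts_b = _sites_as_points(sites_b)
    if not pts_a or not pts_b:
        raise ValueError("empty insertion-site set")
    chroms = genome.names() if genome is not None else None
    total_a, total_b = len(pts_a), len(pts_b)
    results = []
    for label, regions in region_sets.items():
        a = count_in_regions(sites_a, regions, chroms)
        b = count_in_regions(sites_b, regions, chroms)
        results.append(enrichment_test(a, total_a, b, total_b, label))
    if adjust:
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, padj):
            r.p_adjusted = float(q)
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def write_results(results: Sequence[EnrichmentResult], tsv_path=None,
                  json_path=None) -> None:
    df = results_to_frame(results)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# binned profiles
# ---------------------------------------------------------------------------

def _window_bounds(start: int, end: int, n_bins: int) -> np.ndarray:
    """Near-equal windows; the remainder is spread over the leading ones."""
    length = end - start
    base, rem = divmod(length, n_bins)
    sizes = np.full(n_bins, base, dtype=np.int64)
    sizes[:rem] += 1
    return start + np.concatenate([[0], np.cumsum(sizes)])


def binned_rpkm_profile(
    sites, region: Interval, n_bins: int = 300,
    total_sites: int | None = None, label: str = "",
) -> BinnedProfile:
    """Insertion density over a region, RPKM-normalized per window."""
    chrom, start, end = region
    if end - start < n_bins:
        raise ValueError(
            f"region length {end - start} < n_bins {n_bins}; use fewer bins"
        )
    pts = np.sort([p for c, p in _sites_as_points(sites) if c == chrom])
    if total_sites is None:
        total_sites = len(_sites_as_points(sites))
    bounds = _window_bounds(start, end, n_bins)
    counts = np.diff(np.searchsorted(pts, bounds)).astype(np.int64)
    wlen = np.diff(bounds)
    per_million = total_sites / 1e6
    values = counts / (wlen / 1000.0) / per_million
    return BinnedProfile(label or chrom, n_bins, values, counts, wlen)


def ta_density_profile(
    genome: GenomeModel, region: Interval, n_bins: int = 300,
    loess_span: float = 0.3,
) -> np.ndarray:
    """Window-normalized TA density, scaled to [0, 1] and loess-smoothed.

    Overlapping TA occurrences are counted by their start offset.  A
    constant-density region yields all 0.5 by convention.
    """
    chrom, start, end = region
    if end - start < n_bins:
        raise ValueError("region shorter than n_bins; use fewer bins")
    sites = genome.ta_sites(chrom)
    bounds = _window_bounds(start, end, n_bins)
    # a TA at offset i belongs to the window containing i (i+1 must be in-region)
    inside = sites[(sites >= start) & (sites < end - 1)]
    counts = np.diff(np.searchsorted(inside, bounds))
    density = counts / np.diff(bounds)
    lo, hi = density.min(), density.max()
    if hi == lo:
        return np.full(n_bins, 0.5)
    scaled = (density - lo) / (hi - lo)
    from statsmodels.nonparametric.smoothers_lowess import lowess

    smoothed = lowess(scaled, np.arange(n_bins), frac=loess_span,
                      return_sorted=False)
    return smoothed


def write_profile_tsv(profile: BinnedProfile, path) -> None:
    df = pd.DataFrame({
        "bin": np.arange(profile.n_bins),
        "count": profile.counts,
        "window_length": profile.window_lengths,
        "rpkm": profile.values,
    })
    df.to_csv(path, sep="\t", index=False)
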
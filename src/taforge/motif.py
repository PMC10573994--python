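"""Target-site sequence context: position frequency matrix and information
content (the logo-style QC of the TA targeting rule).

Contexts are plus-strand windows around the called TA coordinate; because
site coordinates pool both strands onto the single canonical TA and the
expected AT-palindromic motif is strand-symmetric, one strand suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeModel

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"


@dataclass
class PositionFrequencyMatrix:
    freqs: np.ndarray  # shape (4, L), columns sum to 1
    n_sites: int
    flank: int

    @property
    def length(self) -> int:
        return self.freqs.shape[1]

    def frequency(self, base: str, column: int) -> float:
        return float(self.freqs[ALPHABET.index(base), column])

    def information_content(self) -> np.ndarray:
        """Per-column logo height in bits: 2 + sum_b f log2 f (0 log 0 = 0)."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + term.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs.T, columns=list(ALPHABET))
        df.insert(0, "column", np.arange(self.length))
        df["information_bits"] = self.information_content()
        return df


def extract_contexts(sites, genome: GenomeModel, flank: int = 10) -> List[str]:
    """Plus-strand windows [position - flank, position + 2 + flank) per site.

    Sites too close to a chromosome edge for a full window are skipped and
    counted in the log.
    """
    contexts: List[str] = []
    skipped = 0
    for s in sites:
        seq = genome.seq(s.chrom)
        lo = s.position - flank
        hi = s.position + 2 + flank
        if lo < 0 or hi > len(seq):
            skipped += 1
            continue
        contexts.append(seq[lo:hi])
    if skipped:
        logger.info("extract_contexts: skipped %d edge sites", skipped)
    return contexts


def build_pfm(contexts: Sequence[str], flank: int | None = None
              ) -> PositionFrequencyMatrix:
    """Column base frequencies over equal-length context windows."""
    if not contexts:
        raise ValueError("no contexts supplied")
    L = len(contexts[0])
    if any(len(c) != L for c in contexts):
        raise ValueError("contexts have unequal lengths")
    arr = np.frombuffer("".join(contexts).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(contexts), L)
    counts = np.stack([(arr == ord(b)).sum(axis=0) for b in ALPHABET])
    freqs = counts / len(contexts)
    if flank is None:
        flank = (L - 2) // 2
    return PositionFrequencyMatrix(freqs.astype(float), len(contexts), flank)


def pfm_from_sites(sites, genome: GenomeModel, flank: int = 10
                   ) -> Tuple[PositionFrequencyMatrix, int]:
    contexts = extract_contexts(sites, genome, flank)
    pfm = build_pfm(contexts, flank)
    return pfm, len(contexts)
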
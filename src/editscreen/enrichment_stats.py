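"""Enrichment of A-G mismatches among highly conserved stems.

Stems are binned by conservation score; the mismatch fraction of the
lowest-conservation bin serves as the background rate of spurious A-G
mismatches (sequencing error, polymorphism), and the background-corrected
excess in a high bin estimates how many of its stems carry true editing.
The significance of a fraction gap between two bins is bounded with
Hoeffding's inequality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

BIN_LABELS = ["<50", "50-60", "60-70", "70-80", "80-90", ">=90"]
_BIN_EDGES = [50.0, 60.0, 70.0, 80.0, 90.0]


@dataclass
class BinSummary:
    label: str
    n_stems: int
    n_with_mismatch: int

    @property
    def fraction(self) -> float:
        return self.n_with_mismatch / self.n_stems if self.n_stems else 0.0


def conservation_bin(score: float) -> str:
    """Half-open bins [lo, hi); the top bin is [90, inf)."""
    for edge, label in zip(_BIN_EDGES, BIN_LABELS[:-1]):
        if score < edge:
            return label
    return BIN_LABELS[-1]


def bin_stems(stems_with_scores) -> list[BinSummary]:
    """Partition (conservation score, has-mismatch flag) pairs into the six
    conservation bins."""
    counts = {label: [0, 0] for label in BIN_LABELS}
    for score, has_mismatch in stems_with_scores:
        label = conservation_bin(float(score))
        counts[label][0] += 1
        counts[label][1] += int(bool(has_mismatch))
    return [
        BinSummary(label, n_stems=c[0], n_with_mismatch=c[1])
        for label, c in ((lb, counts[lb]) for lb in BIN_LABELS)
    ]


def excess_edited_estimate(
    n_with_mismatch: int | BinSummary,
    n_stems: int | None = None,
    background_fraction: float = 0.0,
) -> float:
    """Background-corrected count of truly edited stems in a bin:
    n_with_mismatch - background_fraction * n_stems, floored at 0.

    Accepts either a BinSummary or explicit counts.  Rounding to an
    integer happens only in human-readable reports.
    """
    if isinstance(n_with_mismatch, BinSummary):
        summary = n_with_mismatch
        if n_stems is not None:  # called as (BinSummary, background_fraction)
            background_fraction = float(n_stems)
        n_with_mismatch, n_stems = summary.n_with_mismatch, summary.n_stems
    if not (0.0 <= background_fraction <= 1.0):
        raise ValueError("background fraction must be in [0, 1]")
    return max(0.0, n_with_mismatch - background_fraction * n_stems)


def hoeffding_pvalue(f1: float, n1: int, f2: float, n2: int) -> float:
    """Two-sample Hoeffding bound on the probability of a fraction gap
    |f2 - f1| between samples of sizes n1 and n2 under a common mean:
    exp(-2 t^2 / (1/n1 + 1/n2)), capped at 1."""
    for f in (f1, f2):
        if not (0.0 <= f <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
    if min(n1, n2) < 1:
        raise ValueError("counts must be >= 1")
    t = abs(f2 - f1)
    bound = math.exp(-2.0 * t * t / (1.0 / n1 + 1.0 / n2))
    return min(1.0, bound)


def log10_hoeffding_pvalue(f1: float, n1: int, f2: float, n2: int) -> float:
    """log10 of the Hoeffding bound (usable far below float underflow)."""
    t = abs(f2 - f1)
    return min(0.0, -2.0 * t * t / (1.0 / n1 + 1.0 / n2) / math.log(10.0))


def enrichment_table(stems_with_scores, background_bin: str = "<50"):
    """Table-shaped summary: per-bin counts/fractions plus the
    background-corrected excess for each bin against ``background_bin``."""
    import pandas as pd

    bins = bin_stems(stems_with_scores)
    background = next(b for b in bins if b.label == background_bin).fraction
    rows = []
    for b in bins:
        rows.append(
            {
                "bin": b.label,
                "n_stems": b.n_stems,
                "n_with_mismatch": b.n_with_mismatch,
                "fraction": b.fraction,
                "excess_edited": excess_edited_estimate(
                    b.n_with_mismatch, b.n_stems, background
                ),
            }
        )
    return pd.DataFrame(rows)
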
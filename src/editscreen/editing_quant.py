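"""Editing quantification from amplicon reads.

The editing frequency at a site is #G / (#A + #G) over the reads covering
it; reads calling other bases do not enter the denominator.  Whether the
observed G calls could all be sequencing errors is bounded by the product
of the per-read phred error probabilities, and a site is reported when
that probability falls below 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .formats_io import GenomicRegion

DEFAULT_P_THRESHOLD = 1e-4


def phred_to_error_prob(q: float) -> float:
    """p_error = 10^(-q/10); q=20 -> 1%, q=25 -> 10^-2.5, q=30 -> 0.1%."""
    if q < 0:
        raise ValueError("phred score must be >= 0")
    return 10.0 ** (-q / 10.0)


@dataclass
class SitePileup:
    """Per-site base calls with phred qualities."""

    site: GenomicRegion
    reads: list  # (called base, phred quality)
    name: str = ""

    def counts(self) -> tuple[int, int, int]:
        a = sum(1 for b, _ in self.reads if b == "A")
        g = sum(1 for b, _ in self.reads if b == "G")
        other = len(self.reads) - a - g
        return a, g, other

    @property
    def coverage(self) -> int:
        return len(self.reads)

    def g_phreds(self) -> list:
        return [q for b, q in self.reads if b == "G"]


@dataclass
class EditingCall:
    name: str
    site: GenomicRegion
    coverage: int
    n_a: int
    n_g: int
    frequency: float | None  # percent of informative reads, None if no A/G
    error_pvalue: float
    reported: bool


def editing_frequency(pileup: SitePileup) -> float:
    """Editing frequency in percent: 100 * #G / (#A + #G)."""
    a, g, _ = pileup.counts()
    if a + g == 0:
        raise ValueError("no informative (A/G) reads at site")
    return 100.0 * g / (a + g)


def all_error_pvalue(g_read_phreds) -> float:
    """Probability that every G call is a sequencing error: the product of
    the per-read phred error probabilities (1.0 for no G reads)."""
    p = 1.0
    for q in g_read_phreds:
        p *= phred_to_error_prob(q)
    return min(1.0, p)


def report_sites(
    pileups: list[SitePileup], p_threshold: float = DEFAULT_P_THRESHOLD
) -> pd.DataFrame:
    """Editing calls for a set of site pileups, sorted by frequency
    (descending).  A site is flagged ``reported`` when the probability
    that all its G calls are errors is below ``p_threshold``."""
    calls = []
    for pu in pileups:
        a, g, other = pu.counts()
        freq = 100.0 * g / (a + g) if (a + g) else None
        p = all_error_pvalue(pu.g_phreds()) if g else 1.0
        calls.append(
            EditingCall(
                name=pu.name,
                site=pu.site,
                coverage=pu.coverage,
                n_a=a,
                n_g=g,
                frequency=freq,
                error_pvalue=p,
                reported=bool(g) and p < p_threshold,
            )
        )
    rows = [
        {
            "name": c.name,
            "chrom": c.site.chrom,
            "pos": c.site.start,
            "coverage": c.coverage,
            "n_G": c.n_g,
            "n_A": c.n_a,
            "freq_G_percent": c.frequency,
            "error_pvalue": c.error_pvalue,
            "reported": c.reported,
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "name",
            "chrom",
            "pos",
            "coverage",
            "n_G",
            "n_A",
            "freq_G_percent",
            "error_pvalue",
            "reported",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["freq_G_percent", "name"], ascending=[False, True], na_position="last"
        ).reset_index(drop=True)
    return df


def pileups_from_alignment_table(table: pd.DataFrame) -> list[SitePileup]:
    """Build site pileups from a read-site alignment table with columns
    (read_id, chrom, pos, base, quality[, name])."""
    pileups: dict = {}
    for row in table.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        if key not in pileups:
            name = getattr(row, "name_", None) or getattr(row, "site_name", "") or ""
            pileups[key] = SitePileup(
                site=GenomicRegion(key[0], key[1], key[1] + 1),
                reads=[],
                name=str(name),
            )
        pileups[key].reads.append((str(row.base).upper(), int(row.quality)))
    return [pileups[k] for k in sorted(pileups)]
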
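"""Six-bit candidate scoring of putative edited sites, plus the
information-content profile that motivates the downstream-G bit.

A candidate stem first has to clear a conservation cutoff (>= 75 by
default); it is then scored with six 0/1 bits: two further conservation
thresholds (>= 80, >= 90), a phylogenetic A-G mutation signature (distant
species carry a genomic G where the focal lineage has the editable A), A-G
mismatches on both stem arms, an annotated amino-acid change, and a
guanosine immediately 3' of the site -- the strongest neighborhood
preference of the ADAR enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .formats_io import SpeciesTree

_BASES = "ACGT"


@dataclass
class CandidateScore:
    cons_80: int = 0
    cons_90: int = 0
    ag_mutation: int = 0
    ag_both: int = 0
    annotated_aa_change: int = 0
    ds_g: int = 0

    def __post_init__(self) -> None:
        for name in ("cons_80", "cons_90", "ag_mutation", "ag_both", "annotated_aa_change", "ds_g"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"bit {name} must be 0 or 1")

    @property
    def total(self) -> int:
        return (
            self.cons_80
            + self.cons_90
            + self.ag_mutation
            + self.ag_both
            + self.annotated_aa_change
            + self.ds_g
        )

    def as_dict(self) -> dict:
        return {
            "cons_80": self.cons_80,
            "cons_90": self.cons_90,
            "ag_mutation": self.ag_mutation,
            "ag_both": self.ag_both,
            "annotated_aa_change": self.annotated_aa_change,
            "ds_g": self.ds_g,
            "total": self.total,
        }


def bit_conservation(stem_score: float) -> tuple[int, int]:
    """(cons_80, cons_90): inclusive thresholds on the stem conservation."""
    return int(stem_score >= 80), int(stem_score >= 90)


def default_clade_partition(tree: SpeciesTree) -> tuple[set, list[set]]:
    """Default (near species, distant clades) for the A-G mutation bit.

    Near = the focal species plus the leaves of its immediate sister
    group; distant = the leaves of the two most basal clades, i.e. the
    first two subtrees branching off the root-to-focal path.  Both are
    configurable as explicit leaf sets.
    """
    focal = tree.focal_species
    leaf = next(
        lf for lf in tree.tree.leaf_node_iter() if lf.taxon.label == focal
    )
    near = {focal}
    for sib in leaf.parent_node.child_nodes():
        for lf in sib.leaf_iter():
            near.add(lf.taxon.label)
    # path root -> focal; collect off-path subtrees in root-first order
    path = []
    node = leaf
    while node is not None:
        path.append(node)
        node = node.parent_node
    path.reverse()  # root ... focal
    distant: list[set] = []
    for parent, child in zip(path[:-1], path[1:]):
        for sib in parent.child_nodes():
            if sib is child:
                continue
            distant.append({lf.taxon.label for lf in sib.leaf_iter()})
        if len(distant) >= 2:
            break
    return near, distant[:2]


def bit_ag_mutation(
    column: dict,
    tree: SpeciesTree,
    near_species: set | None = None,
    distant_clades: list[set] | None = None,
) -> int:
    """1 iff the focal lineage carries the editable A while some distant
    clade carries a permanent (fixed among its aligned members) genomic G.

    The focal species must show A in the column; requires at least one
    other near species with A, and a distant clade whose aligned members
    are all G.
    """
    if column.get(tree.focal_species) != "A":
        raise ValueError("A-G mutation bit requires a focal A at the site")
    if near_species is None or distant_clades is None:
        near_default, distant_default = default_clade_partition(tree)
        near_species = near_species or near_default
        distant_clades = distant_clades or distant_default
    near_a = any(
        column.get(sp) == "A" for sp in near_species if sp != tree.focal_species
    )
    if not near_a:
        return 0
    for clade in distant_clades:
        aligned = [column[sp] for sp in clade if column.get(sp, "-") in _BASES]
        if aligned and all(b == "G" for b in aligned):
            return 1
    return 0


def bit_ag_both(stem, calls) -> int:
    """1 iff at least one A-G mismatch call falls on each stem arm."""
    on1 = any(stem.arm1.contains(c.position.start) for c in calls)
    on2 = any(stem.arm2.contains(c.position.start) for c in calls)
    return int(on1 and on2)


def bit_annotated_aa_change(
    cds_sequence: str, reading_frame: int, call_position: int
) -> int:
    """1 iff replacing the called A with G changes the encoded amino acid.

    ``call_position`` indexes into ``cds_sequence`` (transcript
    orientation); ``reading_frame`` is the offset of the first full codon.
    Calls outside the CDS (or in a partial terminal codon) score 0.
    """
    if not (0 <= call_position < len(cds_sequence)):
        return 0
    if call_position < reading_frame:
        return 0
    codon_start = reading_frame + 3 * ((call_position - reading_frame) // 3)
    codon = cds_sequence[codon_start : codon_start + 3]
    if len(codon) < 3:
        return 0
    offset = call_position - codon_start
    if codon[offset] != "A":
        raise ValueError(f"call position has base {codon[offset]!r}, expected A")
    edited = codon[:offset] + "G" + codon[offset + 1 :]
    return int(str(Seq(codon).translate()) != str(Seq(edited).translate()))


def bit_ds_g(transcript_sequence: str, site_position: int) -> int:
    """1 iff the base immediately 3' of the site is G (transcript
    orientation); terminal sites score 0."""
    if site_position >= len(transcript_sequence) - 1:
        return 0
    return int(transcript_sequence[site_position + 1] == "G")


@dataclass
class ScoredCandidate:
    gene: str
    codon_change: str
    conservation: float
    score: CandidateScore
    site: int | None = None


def total_score_and_select(
    candidates: list[ScoredCandidate],
    cutoff_conservation: float = 75.0,
    min_score: int = 3,
) -> pd.DataFrame:
    """Ranked candidate table.

    Candidates below the conservation cutoff are excluded before scoring;
    the survivors are ranked by total bit score (ties broken by
    conservation, both descending).
    """
    rows = []
    for c in candidates:
        if c.conservation < cutoff_conservation:
            continue
        if c.score.total < min_score:
            continue
        row = {"gene": c.gene, "codon_change": c.codon_change, "conservation": c.conservation}
        row.update(c.score.as_dict())
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "codon_change",
            "conservation",
            "cons_80",
            "cons_90",
            "ag_mutation",
            "ag_both",
            "annotated_aa_change",
            "ds_g",
            "total",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["total", "conservation", "gene"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Information content around edited sites


@dataclass
class InfoProfile:
    offsets: np.ndarray  # l in [-halfwidth, +halfwidth]
    frequencies: np.ndarray  # (positions, 4), rows sum to 1
    entropy: np.ndarray  # H(l) in bits
    information: np.ndarray  # I(l) = 2 - H(l)


def information_profile(
    aligned_site_sequences: list[str], halfwidth: int = 200
) -> InfoProfile:
    """Per-offset entropy/information for sequences centered on an edited A.

    Every sequence must have length 2*halfwidth + 1; H(l) =
    -sum_n f(n,l) log2 f(n,l) with 0*log0 = 0 and I(l) = 2 - H(l).
    """
    width = 2 * halfwidth + 1
    if not aligned_site_sequences:
        raise ValueError("need at least one sequence")
    if any(len(s) != width for s in aligned_site_sequences):
        raise ValueError(f"all sequences must have length {width}")
    counts = np.zeros((width, 4))
    for seq in aligned_site_sequences:
        for i, ch in enumerate(seq):
            j = _BASES.find(ch)
            if j >= 0:
                counts[i, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logs).sum(axis=1)
    return InfoProfile(
        offsets=np.arange(-halfwidth, halfwidth + 1),
        frequencies=freqs,
        entropy=entropy,
        information=2.0 - entropy,
    )
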
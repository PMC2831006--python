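"""Synthetic inputs for every pipeline stage.

Generators are pure functions of (config, seed).  One global seed fans out
to independent per-generator streams: each stream seeds a PCG64 generator
with ``SeedSequence([seed, crc32(stream name)])``, so adding a generator
never perturbs the output of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .conservation import BASES, HKYModel
from .formats_io import GenomicRegion, MsaBlock, SnpRecord, SpeciesTree
from .stem_prediction import reverse_complement


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent, named random stream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class PlantedStem:
    arm_length: int = 30
    loop_length: int = 60
    mutations_per_arm: int = 0
    start: int | None = None  # arm1 start; placed automatically if None
    arm1_sequence: str | None = None  # explicit arm1 (arm2 = its revcomp)


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 2000
    planted_stems: list = field(default_factory=list)
    conserved_windows: list = field(default_factory=list)  # (start, end)
    edit_sites: list = field(default_factory=list)  # (position, frequency)
    read_count: int = 500
    read_quality: int | None = 30  # None = error-free
    est_count: int = 20
    est_quality: int | None = None  # None = error-free ESTs
    background_freqs: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        for pos, freq in self.edit_sites:
            if not (0.0 <= freq <= 1.0):
                raise ValueError("edit frequencies must be in [0, 1]")


def random_sequence(length: int, rng: np.random.Generator, freqs=(0.25,) * 4) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=list(freqs)))


# ---------------------------------------------------------------------------
# Genomes with planted stems


def make_genome_with_stems(config: SimulationConfig):
    """(genome sequence, truth records) with planted inverted repeats.

    Each planted stem contributes arm1, a loop, and arm2 =
    reverse_complement(arm1), with optional per-arm point mutations.
    Truth records carry the planted arm coordinates.
    """
    rng = stream(config.seed, "genome")
    seq = list(random_sequence(config.genome_length, rng, config.background_freqs))
    placed: list[tuple[int, int]] = []
    truth = []
    cursor = 100
    for k, stem in enumerate(config.planted_stems):
        arm1 = stem.arm1_sequence or random_sequence(stem.arm_length, rng)
        arm_len = len(arm1)
        span = 2 * arm_len + stem.loop_length
        start = stem.start if stem.start is not None else cursor
        cursor = start + span + 150
        end = start + span
        if end > config.genome_length:
            raise ValueError(f"planted stem {k} extends past the genome end")
        for s, e in placed:
            if start < e and s < end:
                raise ValueError(f"planted stem {k} overlaps another planted feature")
        placed.append((start, end))
        arm2 = reverse_complement(arm1)
        for arm_seq, arm_start in ((arm1, start), (arm2, start + arm_len + stem.loop_length)):
            arm = list(arm_seq)
            if stem.mutations_per_arm:
                pos_choices = rng.choice(len(arm), size=stem.mutations_per_arm, replace=False)
                for p in pos_choices:
                    others = [b for b in BASES if b != arm[p]]
                    arm[int(p)] = others[int(rng.integers(3))]
            seq[arm_start : arm_start + len(arm)] = arm
        truth.append(
            {
                "stem": k,
                "arm1_start": start,
                "arm1_end": start + arm_len,
                "arm2_start": start + arm_len + stem.loop_length,
                "arm2_end": end,
            }
        )
    return "".join(seq), truth


# ---------------------------------------------------------------------------
# Simulated multiple alignments


def simulate_msa(
    tree: SpeciesTree,
    length: int | None = None,
    hky: HKYModel | None = None,
    conserved_mask=None,
    seed: int = 0,
    root_sequence: str | None = None,
    anchor_focal: bool = False,
    clade_substitutions=None,
    chrom: str = "ref",
    focal_start: int = 0,
) -> MsaBlock:
    """Evolve an alignment block along the species tree under HKY.

    Root bases are drawn from the stationary frequencies (or taken from
    ``root_sequence``); columns flagged in ``conserved_mask`` do not evolve.
    With ``anchor_focal`` the focal row is pinned to the root sequence
    (emulating a reference genome the others are aligned to).
    ``clade_substitutions`` is a list of (column, species collection, base)
    applied after evolution, emulating clade-restricted substitutions.
    """
    hky = hky or HKYModel()
    rng = stream(seed, "msa")
    if root_sequence is not None:
        length = len(root_sequence)
        root = np.fromiter((BASES.index(c) for c in root_sequence), dtype=np.int64)
    else:
        if length is None:
            raise ValueError("need length or root_sequence")
        root = rng.choice(4, size=length, p=hky.freqs)
    mask = np.zeros(length, dtype=bool)
    if conserved_mask is not None:
        mask[:] = np.asarray(conserved_mask, dtype=bool)
    rows: dict[str, str] = {}
    species: list[str] = []

    def walk(node, states):
        if node is not tree.tree.seed_node:
            t = node.edge.length or 0.0
            P = hky.transition_matrix(t)
            new = states.copy()
            free = ~mask
            for a in range(4):
                sel = free & (states == a)
                k = int(sel.sum())
                if k:
                    new[sel] = rng.choice(4, size=k, p=P[a])
            states = new
        if node.is_leaf():
            label = node.taxon.label
            if anchor_focal and label == tree.focal_species:
                states = root
            species.append(label)
            rows[label] = "".join(BASES[s] for s in states)
            return
        for child in node.child_nodes():
            walk(child, states)

    walk(tree.tree.seed_node, root)
    if clade_substitutions:
        for col, clade, base in clade_substitutions:
            for sp in clade:
                row = rows[sp]
                rows[sp] = row[:col] + base + row[col + 1 :]
    return MsaBlock(
        species=species,
        rows=rows,
        focal_species=tree.focal_species,
        chrom=chrom,
        focal_start=focal_start,
    )


# ---------------------------------------------------------------------------
# ESTs and reads with planted editing


def _apply_edits_and_errors(template, edit_sites, quality, rng):
    seq = list(template)
    edited = {}
    for pos, freq in edit_sites:
        hit = bool(rng.random() < freq)
        edited[pos] = hit
        if hit:
            seq[pos] = "G"
    if quality is not None:
        p_err = 10.0 ** (-quality / 10.0)
        errs = rng.random(len(seq)) < p_err
        for i in np.flatnonzero(errs):
            others = [b for b in BASES if b != seq[i]]
            seq[int(i)] = others[int(rng.integers(3))]
    return "".join(seq), edited


def simulate_ests_and_reads(transcript: str, edit_sites, config: SimulationConfig):
    """(ESTs, reads, truth rows) with planted A->G editing.

    Every EST/read is a full-length copy of the transcript carrying a G at
    each edit site independently with that site's frequency; sequencing
    errors are substitutions drawn at the phred-implied rate.  Truth rows
    record each read's drawn edit status per site.
    """
    for pos, _ in edit_sites:
        if transcript[pos] != "A":
            raise ValueError(f"edit position {pos} is {transcript[pos]!r}, not A")
    rng_est = stream(config.seed, "ests")
    rng_read = stream(config.seed, "reads")
    ests = []
    truth = []
    for i in range(config.est_count):
        seq, edited = _apply_edits_and_errors(
            transcript, edit_sites, config.est_quality, rng_est
        )
        ests.append((f"est_{i}", seq))
        for pos, _ in edit_sites:
            truth.append({"source": f"est_{i}", "pos": pos, "edited": edited[pos]})
    reads = []
    q = config.read_quality
    for i in range(config.read_count):
        seq, edited = _apply_edits_and_errors(transcript, edit_sites, q, rng_read)
        quals = [q if q is not None else 93] * len(seq)
        reads.append((f"read_{i}", seq, quals))
        for pos, _ in edit_sites:
            truth.append({"source": f"read_{i}", "pos": pos, "edited": edited[pos]})
    return ests, reads, truth


def write_fastq(reads, path) -> None:
    """Write (id, sequence, qualities) reads as Sanger-encoded FASTQ."""
    with open(path, "w") as fh:
        for name, seq, quals in reads:
            qstr = "".join(chr(min(q, 93) + 33) for q in quals)
            fh.write(f"@{name}\n{seq}\n+\n{qstr}\n")


def read_fastq(path):
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            (rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
        )
    return out


# ---------------------------------------------------------------------------
# SNP tables


def make_snp_table(positions, origins, chrom: str = "ref", alleles=("A", "G")) -> list[SnpRecord]:
    """SNP records at the given positions with the given origins."""
    if len(positions) != len(origins):
        raise ValueError("positions and origins must have equal length")
    return [
        SnpRecord(
            position=GenomicRegion(chrom, pos, pos + 1),
            alleles=tuple(alleles),
            origin=origin,
        )
        for pos, origin in zip(positions, origins)
    ]
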
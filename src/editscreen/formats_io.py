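"""Readers/writers for the standard formats the screen touches, plus shared
coordinate conventions.

All genomic coordinates are 0-based half-open internally.  BED output keeps
that convention; human-readable reports are written 1-based.  Gap characters
in alignments are ``'-'``; ``'N'`` aligns to nothing for conservation
purposes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicRegion:
    """Half-open genomic interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class SpeciesTree:
    """Rooted species tree with branch lengths (substitutions/site) and a
    designated focal species (the genome being screened)."""

    tree: dendropy.Tree
    focal_species: str

    def __post_init__(self) -> None:
        labels = set(self.leaf_labels())
        if self.focal_species not in labels:
            raise ValueError(f"focal species {self.focal_species!r} is not a leaf")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())


@dataclass
class MsaBlock:
    """One multiple-alignment block with a focal (reference) row.

    ``focal_start`` is the 0-based position of the first non-gap focal
    column on the forward strand of the focal genome.
    """

    species: list[str]
    rows: dict[str, str]
    focal_species: str
    chrom: str = "ref"
    focal_start: int = 0
    flagged_low_species: bool = False

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise FormatError("alignment rows have unequal lengths")
        if self.focal_species not in self.rows:
            raise FormatError(f"focal species {self.focal_species!r} missing from block")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.focal_species])

    @property
    def n_species(self) -> int:
        return len(self.species)

    def column(self, i: int) -> dict[str, str]:
        return {sp: self.rows[sp][i] for sp in self.species}

    def focal_positions(self) -> list[int | None]:
        """Per-column focal genome position (None at focal-gap columns)."""
        out: list[int | None] = []
        pos = self.focal_start
        for ch in self.rows[self.focal_species]:
            if ch == GAP:
                out.append(None)
            else:
                out.append(pos)
                pos += 1
        return out

    def column_of_position(self, pos: int) -> int:
        """Inverse of :meth:`focal_positions` for non-gap columns."""
        for col, p in enumerate(self.focal_positions()):
            if p == pos:
                return col
        raise KeyError(f"position {pos} not covered by block")


@dataclass(frozen=True)
class SnpRecord:
    position: GenomicRegion
    alleles: tuple[str, str]
    origin: str  # 'genomic' | 'est_verified'

    ORIGINS = ("genomic", "est_verified")

    def __post_init__(self) -> None:
        if len(self.position) != 1:
            raise ValueError("SNP position must have length 1")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError("SNP alleles must be distinct")
        if self.origin not in self.ORIGINS:
            raise FormatError(f"unknown SNP origin {self.origin!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (identifier, uppercase sequence) pairs.

    Sequences are restricted to the {A,C,G,T,N} alphabet.
    """
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"record {i + 1}: empty FASTA header")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {rec.id!r}: invalid characters {sorted(bad)} in sequence"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# MAF


def read_maf(path, focal_species: str, min_species: int = 10) -> list[MsaBlock]:
    """Read MAF blocks, flagging those aligning fewer than ``min_species``
    species (conservation later zeroes flagged blocks; they are retained).

    The focal species must appear in every block; its row anchors focal
    genome coordinates (forward strand).
    """
    from Bio import AlignIO

    blocks: list[MsaBlock] = []
    try:
        alignments = list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise FormatError(f"malformed MAF: {exc}") from exc
    for aln in alignments:
        species = []
        rows = {}
        chrom = "ref"
        focal_start = None
        for rec in aln:
            name = rec.id.split(".")[0]
            species.append(name)
            rows[name] = str(rec.seq).upper()
            if name == focal_species:
                focal_start = int(rec.annotations.get("start", 0))
                chrom = rec.id.split(".", 1)[1] if "." in rec.id else rec.id
                if rec.annotations.get("strand", 1) not in (1, "+"):
                    raise FormatError("focal MAF row must be on the + strand")
        if focal_start is None:
            raise FormatError(f"block missing focal species {focal_species!r}")
        blocks.append(
            MsaBlock(
                species=species,
                rows=rows,
                focal_species=focal_species,
                chrom=chrom,
                focal_start=focal_start,
                flagged_low_species=len(species) < min_species,
            )
        )
    return blocks


def write_maf(blocks: list[MsaBlock], path) -> None:
    """Write blocks in minimal MAF (score omitted, srcSize from row content)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("a\n")
            for sp in b.species:
                row = b.rows[sp]
                ungapped = len(row) - row.count(GAP)
                if sp == b.focal_species:
                    src = f"{sp}.{b.chrom}"
                    start = b.focal_start
                else:
                    src = sp
                    start = 0
                fh.write(
                    f"s {src} {start} {ungapped} + {start + ungapped} {row}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path_or_string, focal_species: str, default_length: float | None = None) -> SpeciesTree:
    """Read a Newick species tree with branch lengths.

    Missing branch lengths raise unless ``default_length`` is given.
    """
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        data = src
    else:
        with open(src) as fh:
            data = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if default_length is None:
                raise FormatError("branch without length (set default_length to allow)")
            edge.length = default_length
    return SpeciesTree(tree=tree, focal_species=focal_species)


# ---------------------------------------------------------------------------
# SNP table + generic TSV report

SNP_COLUMNS = ["chrom", "pos", "allele1", "allele2", "origin"]


def read_snps(path) -> list[SnpRecord]:
    """Read a TSV SNP table (chrom, pos [0-based], allele1, allele2, origin)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"SNP table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        if row.origin not in SnpRecord.ORIGINS:
            raise FormatError(f"unknown SNP origin {row.origin!r}")
        records.append(
            SnpRecord(
                position=GenomicRegion(str(row.chrom), int(row.pos), int(row.pos) + 1),
                alleles=(str(row.allele1).upper(), str(row.allele2).upper()),
                origin=row.origin,
            )
        )
    return records


def write_snps(records: list[SnpRecord], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "chrom": r.position.chrom,
                "pos": r.position.start,
                "allele1": r.alleles[0],
                "allele2": r.alleles[1],
                "origin": r.origin,
            }
            for r in records
        ],
        columns=SNP_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_report(rows, path, columns: list[str] | None = None) -> None:
    """Write a deterministic TSV report: fixed column order, header first."""
    import pandas as pd

    df = pd.DataFrame(list(rows))
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_report(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
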
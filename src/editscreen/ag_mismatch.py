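"""A->G mismatch calling between genomic mRNA and expressed sequences.

Editing deaminates adenosine to inosine, which sequencers and the
translation machinery read as guanosine, so candidate edited sites show an
A in the genomic template and a G in expressed sequence.  All logic here
runs in transcript orientation: minus-strand genes are reverse-complemented
at extraction time.  Calls supported by known genomic-origin A/G SNPs are
removed; SNPs verified only in ESTs are kept (they may themselves be
editing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import Align

from .formats_io import GenomicRegion, SnpRecord
from .stem_prediction import reverse_complement


@dataclass
class AlignESTParams:
    """BLASTN-like local alignment scoring for mRNA vs EST."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_score: int = 40


@dataclass
class TranscriptAlignment:
    genomic_mrna_id: str
    est_id: str
    length: int  # alignment columns, gaps included
    mismatches: int
    pairs: list  # (mrna position, genomic base, est base) at aligned columns
    score: float = 0.0


@dataclass
class AGMismatch:
    position: GenomicRegion  # length 1; transcript orientation via strand
    genomic_base: str
    est_base: str
    support: int
    snp_status: str = "none"  # none | genomic | est_verified

    def __post_init__(self) -> None:
        if self.genomic_base != "A" or self.est_base != "G":
            raise ValueError("A-G mismatch must be genomic A / expressed G")
        if self.support < 1:
            raise ValueError("a call needs at least one supporting EST")


def extract_transcript(genome_sequence: str, gene: GenomicRegion) -> str:
    """Gene sequence in transcript orientation (revcomp for '-' genes)."""
    seq = genome_sequence[gene.start : gene.end]
    return reverse_complement(seq) if gene.strand == "-" else seq


def transcript_to_genome(pos: int, gene: GenomicRegion) -> int:
    """Map a transcript-orientation offset to a forward-strand genome
    position."""
    if gene.strand == "+":
        return gene.start + pos
    return gene.end - 1 - pos


def align_est(
    genomic_mrna: str,
    est: str,
    params: AlignESTParams | None = None,
    mrna_id: str = "mrna",
    est_id: str = "est",
) -> TranscriptAlignment | None:
    """Best local alignment of an EST against the genomic mRNA.

    Returns None when no alignment reaches ``min_score``.
    """
    params = params or AlignESTParams()
    if not genomic_mrna or not est:
        raise ValueError("both sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    alignments = aligner.align(genomic_mrna, est)
    if len(alignments) == 0 or alignments.score < params.min_score:
        return None
    aln = alignments[0]
    pairs = []
    mismatches = 0
    length = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            a, b = genomic_mrna[t0 + k], est[q0 + k]
            pairs.append((t0 + k, a, b))
            if a != b:
                mismatches += 1
    # alignment length including internal gap columns
    tstarts, tends = aln.aligned[0][:, 0], aln.aligned[0][:, 1]
    qstarts, qends = aln.aligned[1][:, 0], aln.aligned[1][:, 1]
    length = sum(int(e - s) for s, e in zip(tstarts, tends))
    for i in range(1, len(tstarts)):
        length += int(tstarts[i] - tends[i - 1]) + int(qstarts[i] - qends[i - 1])
    return TranscriptAlignment(
        genomic_mrna_id=mrna_id,
        est_id=est_id,
        length=length,
        mismatches=mismatches,
        pairs=pairs,
        score=float(alignments.score),
    )


def filter_alignments(
    alignments: list[TranscriptAlignment],
    min_length: int = 100,
    max_mismatches: int = 20,
) -> list[TranscriptAlignment]:
    """Quality filter: drop alignments shorter than ``min_length`` nt or
    with >= ``max_mismatches`` mismatches."""
    return [
        a
        for a in alignments
        if a is not None and a.length >= min_length and a.mismatches < max_mismatches
    ]


def call_ag_mismatches(
    alignments: list[TranscriptAlignment],
    gene: GenomicRegion | None = None,
) -> list[AGMismatch]:
    """One call per transcript position where the genomic base is A and at
    least one EST shows G (G->A is never called).  When ``gene`` is given,
    positions are mapped to forward-strand genome coordinates, recording
    the transcript orientation in the strand field."""
    support: dict[int, int] = {}
    for aln in alignments:
        for pos, a, b in aln.pairs:
            if a == "A" and b == "G":
                support[pos] = support.get(pos, 0) + 1
    calls = []
    for pos in sorted(support):
        if gene is None:
            region = GenomicRegion("transcript", pos, pos + 1)
        else:
            gpos = transcript_to_genome(pos, gene)
            region = GenomicRegion(gene.chrom, gpos, gpos + 1, strand=gene.strand)
        calls.append(
            AGMismatch(
                position=region,
                genomic_base="A",
                est_base="G",
                support=support[pos],
            )
        )
    return calls


def apply_snp_filter(
    calls: list[AGMismatch], snps: list[SnpRecord]
) -> list[AGMismatch]:
    """Remove calls explained by genomic-origin A/G polymorphisms.

    A SNP masks a call only when it sits at the call position and its
    alleles are the A/G pair in the call's transcript orientation (T/C on
    the genome strand for minus-strand genes).  EST-verified A/G SNPs do
    not mask: they are retained and annotated, since such SNPs are often
    themselves unrecognized editing.
    """
    by_pos = {(s.position.chrom, s.position.start): s for s in snps}
    kept = []
    for call in calls:
        snp = by_pos.get((call.position.chrom, call.position.start))
        if snp is None:
            kept.append(call)
            continue
        expected = {"A", "G"} if call.position.strand == "+" else {"T", "C"}
        if set(snp.alleles) != expected:
            kept.append(call)
            continue
        if snp.origin == "genomic":
            continue  # removed: polymorphic genomic origin
        kept.append(replace(call, snp_status="est_verified"))
    return kept
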
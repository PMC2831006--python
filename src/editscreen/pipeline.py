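"""Orchestration of the screen.

Explorative stage: stem prediction over the gene sequence, a conservation
track from the multiple alignment, and per-stem conservation scores.
Refinement stage: EST alignment and A-G mismatch calling with SNP
filtering, the six candidate bits, and the ranked candidate table.
Intermediates persist as TSV so each stage can be re-run from checkpoints.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ag_mismatch as agm
from . import conservation as cons
from . import site_scoring as scoring
from . import stem_prediction as sp
from . import synthetic_data as synth
from .formats_io import GenomicRegion, MsaBlock, SpeciesTree


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ExplorativeResult:
    stems: list  # StemCandidate with conservation attached
    track: cons.ConservationTrack
    provenance: dict


@dataclass
class ScreenResult:
    candidates: pd.DataFrame
    provenance: dict
    stage_counts: dict


def run_explorative_screen(
    genome: str,
    blocks: list[MsaBlock],
    tree: SpeciesTree,
    align_params: sp.AlignParams | None = None,
    stem_params: sp.StemParams | None = None,
    cons_params: cons.ConservationParams | None = None,
    chrom: str = "ref",
) -> ExplorativeResult:
    """Stems + conservation track + per-stem conservation scores."""
    align_params = align_params or sp.AlignParams()
    stem_params = stem_params or sp.StemParams()
    cons_params = cons_params or cons.ConservationParams()
    if not genome:
        track = cons.ConservationTrack(chrom, 0, np.zeros(0), np.zeros(0), np.zeros(0, dtype=int))
        return ExplorativeResult(stems=[], track=track, provenance={"stage_counts": {}})
    try:
        stems = sp.predict_stems(genome, chrom, align_params, stem_params)
    except Exception as exc:
        raise RuntimeError(f"stem_prediction stage failed: {exc}") from exc
    try:
        track = cons.conservation_score_track(blocks, tree, cons_params)
    except Exception as exc:
        raise RuntimeError(f"conservation stage failed: {exc}") from exc
    for st in stems:
        if (
            st.arm1.start >= track.start
            and st.arm2.end <= track.end
            and len(track.score)
        ):
            st.conservation = cons.stem_conservation(st, track)
        else:
            st.conservation = 0.0
    provenance = {
        "config_hash": _config_hash(
            {
                "align": vars(align_params),
                "stem": stem_params.__dict__,
                "cons": cons_params.__dict__,
            }
        ),
        "seed": cons_params.seed,
        "stage_counts": {"stems": len(stems)},
    }
    return ExplorativeResult(stems=stems, track=track, provenance=provenance)


def run_refinement(
    genome: str,
    gene: GenomicRegion,
    explorative: ExplorativeResult,
    blocks: list[MsaBlock],
    tree: SpeciesTree,
    ests: list,
    snps: list,
    cds_frame: int = 0,
    cutoff_conservation: float = 75.0,
    min_score: int = 3,
    est_params: agm.AlignESTParams | None = None,
) -> ScreenResult:
    """A-G mismatch calling, six-bit scoring and candidate ranking for the
    stems surviving the conservation cutoff."""
    transcript = agm.extract_transcript(genome, gene)
    alignments = []
    for est_id, est_seq in ests:
        aln = agm.align_est(transcript, est_seq, est_params, mrna_id=gene.chrom, est_id=est_id)
        if aln is not None:
            alignments.append(aln)
    filtered = agm.filter_alignments(alignments)
    calls = agm.call_ag_mismatches(filtered, gene)
    n_raw = len(calls)
    calls = agm.apply_snp_filter(calls, snps)
    conserved = [
        st
        for st in explorative.stems
        if st.conservation is not None and st.conservation >= cutoff_conservation
    ]
    candidates = []
    for st in conserved:
        arm_calls = [
            c
            for c in calls
            if st.arm1.contains(c.position.start) or st.arm2.contains(c.position.start)
        ]
        ag_both = scoring.bit_ag_both(st, calls)
        c80, c90 = scoring.bit_conservation(st.conservation)
        for call in arm_calls:
            tpos = _genome_to_transcript(call.position.start, gene)
            ag_mut = 0
            column = _column_at(blocks, call.position.start)
            if column is not None and column.get(tree.focal_species) == "A":
                ag_mut = scoring.bit_ag_mutation(column, tree)
            aa = scoring.bit_annotated_aa_change(transcript, cds_frame, tpos)
            dsg = scoring.bit_ds_g(transcript, tpos)
            bits = scoring.CandidateScore(
                cons_80=c80,
                cons_90=c90,
                ag_mutation=ag_mut,
                ag_both=ag_both,
                annotated_aa_change=aa,
                ds_g=dsg,
            )
            candidates.append(
                scoring.ScoredCandidate(
                    gene=gene.chrom,
                    codon_change=_codon_change(transcript, cds_frame, tpos),
                    conservation=st.conservation,
                    score=bits,
                    site=call.position.start,
                )
            )
    table = scoring.total_score_and_select(candidates, cutoff_conservation, min_score)
    if len(table):
        table.insert(2, "site", [c.site for c in _ranked(candidates, cutoff_conservation, min_score)])
    stage_counts = {
        "stems": len(explorative.stems),
        "conserved_stems": len(conserved),
        "est_alignments": len(filtered),
        "ag_mismatches": n_raw,
        "high_quality_mismatches": len(calls),
        "candidates": len(table),
    }
    provenance = dict(explorative.provenance)
    provenance["stage_counts"] = {**provenance.get("stage_counts", {}), **stage_counts}
    return ScreenResult(candidates=table, provenance=provenance, stage_counts=stage_counts)


def _ranked(candidates, cutoff, min_score):
    kept = [
        c
        for c in candidates
        if c.conservation >= cutoff and c.score.total >= min_score
    ]
    return sorted(kept, key=lambda c: (-c.score.total, -c.conservation, c.gene))


def _genome_to_transcript(pos: int, gene: GenomicRegion) -> int:
    if gene.strand == "+":
        return pos - gene.start
    return gene.end - 1 - pos


def _column_at(blocks: list[MsaBlock], pos: int):
    for block in blocks:
        positions = block.focal_positions()
        for col, p in enumerate(positions):
            if p == pos:
                return block.column(col)
    return None


def _codon_change(transcript: str, frame: int, tpos: int) -> str:
    from Bio.Seq import Seq

    if tpos < frame or tpos >= len(transcript):
        return "nc"
    start = frame + 3 * ((tpos - frame) // 3)
    codon = transcript[start : start + 3]
    if len(codon) < 3 or codon[tpos - start] != "A":
        return "nc"
    off = tpos - start
    edited = codon[:off] + "G" + codon[off + 1 :]
    aa1, aa2 = str(Seq(codon).translate()), str(Seq(edited).translate())
    return "syn" if aa1 == aa2 else f"{aa1}:{aa2}"


# ---------------------------------------------------------------------------
# Persistence


def write_stems(stems, path) -> None:
    rows = []
    for st in stems:
        s1 = "".join(a if a is not None else "-" for a, _ in st.pairing)
        s2 = "".join(b if b is not None else "-" for _, b in st.pairing)
        rows.append(
            {
                "chrom": st.arm1.chrom,
                "arm1_start": st.arm1.start,
                "arm1_end": st.arm1.end,
                "arm2_start": st.arm2.start,
                "arm2_end": st.arm2.end,
                "score": st.score,
                "energy": st.energy,
                "conservation": "" if st.conservation is None else st.conservation,
                "aligned_arm1": s1,
                "aligned_arm2": s2,
                "pairing": sp.pairing_string(st.pairing),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "arm1_start",
            "arm1_end",
            "arm2_start",
            "arm2_end",
            "score",
            "energy",
            "conservation",
            "aligned_arm1",
            "aligned_arm2",
            "pairing",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_stems(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    stems = []
    for row in df.itertuples(index=False):
        pairing = [
            (None if a == "-" else a, None if b == "-" else b)
            for a, b in zip(row.aligned_arm1, row.aligned_arm2)
        ]
        st = sp.StemCandidate(
            arm1=GenomicRegion(row.chrom, int(row.arm1_start), int(row.arm1_end)),
            arm2=GenomicRegion(row.chrom, int(row.arm2_start), int(row.arm2_end)),
            pairing=pairing,
            energy=float(row.energy),
            score=int(row.score),
        )
        if not pd.isna(row.conservation) and row.conservation != "":
            st.conservation = float(row.conservation)
        stems.append(st)
    return stems


def write_track(track: cons.ConservationTrack, path) -> None:
    pd.DataFrame(
        {
            "chrom": track.chrom,
            "pos": np.arange(track.start, track.end),
            "parsimony_term": track.parsimony,
            "tree_term": track.tree_term,
            "score": track.score,
            "n_aligned": track.n_aligned,
        }
    ).to_csv(path, sep="\t", index=False)


def read_track(path) -> cons.ConservationTrack:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return cons.ConservationTrack(
        chrom=str(df["chrom"].iloc[0]) if len(df) else "ref",
        start=int(df["pos"].iloc[0]) if len(df) else 0,
        parsimony=df["parsimony_term"].to_numpy(),
        tree_term=df["tree_term"].to_numpy(),
        n_aligned=df["n_aligned"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Synthetic screen fixture


@dataclass
class ScreenFixture:
    genome: str
    gene: GenomicRegion
    tree: SpeciesTree
    blocks: list
    ests: list
    snps: list
    edit_sites: list  # (transcript position, frequency)
    truth_stem: dict
    cds_frame: int = 0


# arm1 of the planted substrate: codon boundary at offset 3 ("ATA", edited at
# its third base -> ATG, Ile->Met) followed by a G (the ds_G preference)
_FIXTURE_ARM1 = "GCTATAGGCTCGACTGCATCGGATCTAGCA"


def make_screen_fixture(
    seed: int = 0,
    edit_frequency: float = 0.5,
    est_count: int = 30,
    genome_length: int = 400,
) -> ScreenFixture:
    """Synthetic single-gene substrate exercising the full screen.

    One perfect 30-bp stem (loop 60 nt) is planted with: an editable A at a
    codon third position of arm1 whose A->G change is non-synonymous and is
    followed by G; a second editable A on arm2; cross-species conservation
    over both arms (+/-10 nt); and a clade-restricted genomic G in the fish
    clade at the arm1 edit column.  ESTs carry the planted edits at
    ``edit_frequency``; an EST-verified A/G SNP sits at the arm2 site.
    """
    arm1 = _FIXTURE_ARM1
    arm_len = len(arm1)
    loop = 60
    arm1_start = 90
    arm2_start = arm1_start + arm_len + loop
    config = synth.SimulationConfig(
        seed=seed,
        genome_length=genome_length,
        planted_stems=[
            synth.PlantedStem(
                arm_length=arm_len, loop_length=loop, start=arm1_start, arm1_sequence=arm1
            )
        ],
        est_count=est_count,
    )
    genome, truth = synth.make_genome_with_stems(config)
    assert genome[arm1_start + 5] == "A"
    arm2 = genome[arm2_start : arm2_start + arm_len]
    arm2_a_offset = arm2.rindex("A")
    site1 = arm1_start + 5
    site2 = arm2_start + arm2_a_offset
    tree = cons.default_species_tree()
    mask = np.zeros(genome_length, dtype=bool)
    mask[arm1_start - 10 : arm1_start + arm_len + 10] = True
    mask[arm2_start - 10 : arm2_start + arm_len + 10] = True
    # distant-clade genomic G at the arm1 edit column, as seen at known
    # edited sites where fish and amphibians carry a template G
    basal_clade = {"frog", "zebrafish", "tetraodon", "fugu"}
    block = synth.simulate_msa(
        tree,
        root_sequence=genome,
        conserved_mask=mask,
        seed=seed,
        anchor_focal=True,
        clade_substitutions=[(site1, basal_clade, "G")],
        chrom="geneX",
    )
    gene = GenomicRegion("geneX", 0, genome_length, strand="+")
    edit_sites = [(site1, edit_frequency), (site2, edit_frequency)]
    ests, _, _ = synth.simulate_ests_and_reads(genome, edit_sites, config)
    snps = synth.make_snp_table([site2], ["est_verified"], chrom="geneX")
    return ScreenFixture(
        genome=genome,
        gene=gene,
        tree=tree,
        blocks=[block],
        ests=ests,
        snps=snps,
        edit_sites=edit_sites,
        truth_stem=truth[0],
    )
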
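import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editscreen import stem_prediction as sp
from editscreen import synthetic_data as synth
from editscreen.formats_io import GenomicRegion


def oracle_aligner():
    """Independent local aligner (Biopython) with the same pairing matrix
    and affine penalties as find_inverted_pairs."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    matrix = sp.PairingWeightMatrix()
    arr = substitution_matrices.Array("ACGTN", 2)
    for a in "ACGTN":
        for b in "ACGTN":
            arr[a, b] = matrix.score(a, b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = arr
    aligner.open_gap_score = -250.0
    aligner.extend_gap_score = -100.0
    return aligner


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAGCT", "AGCTT"), ("ACGT", "ACGT"), ("N", "N"), ("", "")],
    )
    def test_examples(self, seq, expected):
        assert sp.reverse_complement(seq) == expected

    @given(st.text(alphabet="ACGTN", max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_involution(self, seq):
        assert sp.reverse_complement(sp.reverse_complement(seq)) == seq

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            sp.reverse_complement("ACGU")


class TestFindInvertedPairs:
    def test_planted_repeat_reported_once(self):
        cfg = synth.SimulationConfig(
            seed=11,
            genome_length=1000,
            planted_stems=[synth.PlantedStem(arm_length=30, loop_length=100, start=300)],
        )
        genome, (truth,) = synth.make_genome_with_stems(cfg)
        pairs = sp.find_inverted_pairs(genome)
        covering = [
            p
            for p in pairs
            if p.arm1.start <= truth["arm1_start"]
            and p.arm1.end >= truth["arm1_end"]
            and p.arm2.start <= truth["arm2_start"]
            and p.arm2.end >= truth["arm2_end"]
        ]
        assert len(covering) == 1

    def test_sequence_shorter_than_word_is_empty(self):
        assert sp.find_inverted_pairs("ACGTA") == []

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_top_score_matches_bruteforce_oracle(self, seed):
        """On 300-nt sequences with a strong planted pair spanning the two
        halves, the top arm-pair score equals the best local alignment of
        half1 vs revcomp(half2) computed by an independent aligner."""
        cfg = synth.SimulationConfig(
            seed=seed,
            genome_length=300,
            planted_stems=[synth.PlantedStem(arm_length=30, loop_length=120, start=60)],
        )
        genome, _ = synth.make_genome_with_stems(cfg)
        aligner = oracle_aligner()
        oracle_best = aligner.align(
            genome[:150], sp.reverse_complement(genome[150:])
        ).score
        mine = sp.find_inverted_pairs(genome)
        assert mine, "planted pair not found"
        assert mine[0].score == int(oracle_best)

    def test_pairing_columns_consume_arm_lengths(self):
        cfg = synth.SimulationConfig(
            seed=3,
            genome_length=600,
            planted_stems=[synth.PlantedStem(arm_length=25, loop_length=80, start=150)],
        )
        genome, _ = synth.make_genome_with_stems(cfg)
        for pair in sp.find_inverted_pairs(genome):
            n1 = sum(1 for a, _ in pair.pairing if a is not None)
            n2 = sum(1 for _, b in pair.pairing if b is not None)
            assert n1 == len(pair.arm1)
            assert n2 == len(pair.arm2)
            assert pair.arm2.start - pair.arm1.end >= 4  # minimum hairpin loop


def perfect_stem(arm_length, chrom="seq", start=0, loop=50, base_pattern="GC"):
    """A perfectly paired synthetic stem with known arm sequence."""
    arm1 = (base_pattern * arm_length)[:arm_length]
    arm2 = sp.reverse_complement(arm1)
    pairing = list(zip(arm1, arm2[::-1]))
    stem = sp.StemCandidate(
        arm1=GenomicRegion(chrom, start, start + arm_length),
        arm2=GenomicRegion(chrom, start + arm_length + loop, start + 2 * arm_length + loop),
        pairing=pairing,
    )
    sequence = arm1 + "A" * loop + arm2
    stem.energy = sp.duplex_energy(arm1, arm2, pairing)
    return stem, sequence


class TestDuplexEnergy:
    def test_empty_duplex_is_zero(self):
        assert sp.duplex_energy("", "", []) == 0.0

    def test_gc_duplex_more_stable_than_au(self):
        gc, _ = perfect_stem(20, base_pattern="GC")
        au, _ = perfect_stem(20, base_pattern="AT")
        assert gc.energy < au.energy < 0

    def test_monotone_in_length_and_matches_stack_sum(self):
        """Energy of a perfect duplex decreases with length and equals the
        sum over the embedded stacking table (independent re-summation)."""
        prev = 0.0
        rna = str.maketrans("T", "U")
        for n in range(2, 30):
            stem, _ = perfect_stem(n, base_pattern="GCAT")
            assert stem.energy <= prev
            pairs = [(a + b).translate(rna) for a, b in stem.pairing]
            expected = sum(
                sp._stack_energy(p1, p2) for p1, p2 in zip(pairs[:-1], pairs[1:])
            )
            assert stem.energy == pytest.approx(expected, abs=0.01)
            prev = stem.energy

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sp.duplex_energy("ACG", "CGT", [("A", "T")])


class TestFilterBoundaries:
    def test_arm_length_16_vs_15(self):
        keep, _ = perfect_stem(16)
        drop, _ = perfect_stem(15)
        kept = sp.filter_stems([keep, drop])
        assert keep in kept and drop not in kept

    def test_energy_threshold_exact(self):
        stem, _ = perfect_stem(20)
        stem.energy = -15.0
        assert sp.filter_stems([stem])
        stem.energy = -14.9
        assert not sp.filter_stems([stem])

    @pytest.mark.parametrize("bulge,expected_kept", [(5, True), (6, False)])
    def test_single_strand_bulge_5_vs_6(self, bulge, expected_kept):
        stem, _ = perfect_stem(20)
        mid = len(stem.pairing) // 2
        bulged = stem.pairing[:mid] + [("A", None)] * bulge + stem.pairing[mid:]
        stem = sp.StemCandidate(
            arm1=GenomicRegion("seq", 0, 20 + bulge),
            arm2=stem.arm2,
            pairing=bulged,
            energy=-30.0,
        )
        assert bool(sp.filter_stems([stem])) is expected_kept

    def test_total_unpaired_budget(self):
        stem, _ = perfect_stem(24)
        mid = len(stem.pairing) // 2
        # two 4-nt bulges on one strand: each within the single-run bound,
        # 8 nt in total exceeds the both-strand budget of 7
        bulged = (
            stem.pairing[:8]
            + [("A", None)] * 4
            + stem.pairing[8:16]
            + [("A", None)] * 4
            + stem.pairing[16:]
        )
        stem = sp.StemCandidate(
            arm1=GenomicRegion("seq", 0, 32),
            arm2=stem.arm2,
            pairing=bulged,
            energy=-30.0,
        )
        assert not sp.filter_stems([stem])


class TestGlueBoundaries:
    def _two_stems(self, gap):
        arm = "GCGCGCGCGCGCGCGCGCGC"  # 20 nt
        spacer1 = "A" * gap
        spacer2 = "T" * gap
        loop = "T" * 40
        seq = arm + spacer1 + arm + loop + sp.reverse_complement(arm) + spacer2 + sp.reverse_complement(arm)
        a = len(arm)

        def pairing_for(arm1_seq, arm2_seq):
            return list(zip(arm1_seq, arm2_seq[::-1]))

        s1 = sp.StemCandidate(
            arm1=GenomicRegion("seq", 0, a),
            arm2=GenomicRegion("seq", len(seq) - a, len(seq)),
            pairing=pairing_for(arm, seq[len(seq) - a :]),
        )
        s2 = sp.StemCandidate(
            arm1=GenomicRegion("seq", a + gap, 2 * a + gap),
            arm2=GenomicRegion("seq", len(seq) - 2 * a - gap, len(seq) - a - gap),
            pairing=pairing_for(arm, seq[len(seq) - 2 * a - gap : len(seq) - a - gap]),
        )
        sp.attach_energies([s1, s2], seq)
        return [s1, s2], seq

    def test_glue_at_10_not_11(self):
        stems, seq = self._two_stems(gap=10)
        glued = sp.glue_stems(stems, sequence=seq)
        assert len(glued) == 1
        assert glued[0].arm1.start == 0 and len(glued[0].arm1) == 50

        stems, seq = self._two_stems(gap=11)
        glued = sp.glue_stems(stems, sequence=seq)
        assert len(glued) == 2

    def test_weak_merged_stem_discarded(self):
        stems, seq = self._two_stems(gap=10)
        glued = sp.glue_stems(stems, sequence=seq)
        assert glued[0].energy <= -15.0
        glued[0].energy = -12.0
        assert sp.glue_stems(glued, sequence=seq) == []


class TestSelectCandidates:
    @pytest.mark.parametrize("span,kept", [(4999, True), (5001, False)])
    def test_span_boundary(self, span, kept):
        stem, _ = perfect_stem(20)
        stem.arm2 = GenomicRegion("seq", span - 20, span)
        assert bool(sp.select_candidates([stem])) is kept

    def test_empty_input(self):
        assert sp.select_candidates([]) == []


class TestFullStage:
    @pytest.mark.parametrize("arm_length", [20, 30])
    def test_planted_perfect_repeat_survives(self, arm_length):
        cfg = synth.SimulationConfig(
            seed=21,
            genome_length=800,
            planted_stems=[synth.PlantedStem(arm_length=arm_length, loop_length=90, start=200)],
        )
        genome, (truth,) = synth.make_genome_with_stems(cfg)
        stems = sp.predict_stems(genome)
        covering = [
            st
            for st in stems
            if st.arm1.start <= truth["arm1_start"] < truth["arm1_end"] <= st.arm1.end
            and st.arm2.start <= truth["arm2_start"] < truth["arm2_end"] <= st.arm2.end
        ]
        assert len(covering) == 1

    def test_all_survivors_satisfy_bounds(self):
        cfg = synth.SimulationConfig(
            seed=8,
            genome_length=1500,
            planted_stems=[synth.PlantedStem(arm_length=25, loop_length=70, start=400)],
        )
        genome, _ = synth.make_genome_with_stems(cfg)
        params = sp.StemParams()
        for st in sp.predict_stems(genome, stem_params=params):
            assert len(st.arm1) >= params.min_arm_length
            assert len(st.arm2) >= params.min_arm_length
            assert st.energy <= params.max_filter_energy
            assert st.span <= params.max_candidate_span
            assert st.arm1.end <= st.arm2.start
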
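import itertools

import numpy as np
import pytest

from editscreen import conservation as cons
from editscreen import synthetic_data as synth
from editscreen.formats_io import GenomicRegion, MsaBlock, read_newick
from editscreen.stem_prediction import StemCandidate


def exhaustive_parsimony(column, tree):
    """Oracle: minimum substitution count over all internal-node labelings
    (brute force; trees up to ~6 leaves)."""
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    informative = [
        n for n in leaves if column.get(n.taxon.label, "-") in "ACGT"
    ]
    if len(informative) < 2:
        return 0
    best = None
    for assignment in itertools.product("ACGT", repeat=len(internal)):
        states = {id(n): b for n, b in zip(internal, assignment)}
        for n in informative:
            states[id(n)] = column[n.taxon.label]
        cost = 0
        for n in nodes:
            parent = n.parent_node
            if parent is None or id(n) not in states:
                continue
            if states[id(n)] != states[id(parent)]:
                cost += 1
        best = cost if best is None else min(best, cost)
    return best


class TestFitch:
    def test_identical_column_scores_zero(self, four_leaf_tree):
        col = {sp: "A" for sp in "ABCD"}
        assert cons.fitch_score(col, four_leaf_tree) == 0

    def test_one_deviant_leaf_scores_one(self, four_leaf_tree):
        col = {"A": "A", "B": "A", "C": "A", "D": "G"}
        assert cons.fitch_score(col, four_leaf_tree) == 1

    def test_two_fixed_sister_clades_score_one(self, four_leaf_tree):
        col = {"A": "A", "B": "A", "C": "G", "D": "G"}
        assert cons.fitch_score(col, four_leaf_tree) == 1

    def test_fewer_than_two_informative_scores_zero(self, four_leaf_tree):
        assert cons.fitch_score({"A": "A"}, four_leaf_tree) == 0
        assert cons.fitch_score({"A": "A", "B": "-"}, four_leaf_tree) == 0

    @pytest.mark.parametrize(
        "newick,focal",
        [
            ("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);", "A"),
            ("(((A:0.1,B:0.1):0.1,C:0.2):0.1,(D:0.1,(E:0.1,F:0.1):0.1):0.1);", "A"),
            ("((A:0.1,(B:0.1,C:0.1):0.1):0.1,(D:0.1,E:0.1):0.1);", "A"),
        ],
    )
    def test_matches_exhaustive_enumeration(self, newick, focal, rng):
        tree = read_newick(newick, focal_species=focal)
        labels = tree.leaf_labels()
        for _ in range(40):
            col = {
                sp: rng.choice(list("ACGT-"), p=[0.22, 0.22, 0.22, 0.22, 0.12])
                for sp in labels
            }
            assert cons.fitch_score(col, tree) == exhaustive_parsimony(col, tree)


class TestParsimonyTerm:
    def test_fully_conserved_window_scores_high(self, species_tree, parsimony_null):
        cols = [{sp: "C" for sp in species_tree.leaf_labels()}] * 21
        term = cons.parsimony_term(cols, species_tree, null=parsimony_null)
        assert term > 30  # deep in the null tail

    def test_term_monotone_nonincreasing_in_score(self, parsimony_null):
        logcdf = parsimony_null.window_logcdf(21)
        assert np.all(np.diff(logcdf) >= 0)  # p grows with S, term falls

    def test_montecarlo_backend_capped_and_seeded(self, species_tree):
        params = cons.ConservationParams(null_backend="montecarlo", null_replicates=99, seed=7)
        null = cons.ParsimonyNull(species_tree, params)
        cols = [{sp: "C" for sp in species_tree.leaf_labels()}] * 21
        t1 = cons.parsimony_term(cols, species_tree, params, null)
        t2 = cons.parsimony_term(cols, species_tree, params, null)
        assert t1 == t2 == pytest.approx(-np.log10(1 / 100))

    def test_uninformative_window_scores_zero(self, species_tree, parsimony_null):
        cols = [{"mouse": "A"}] * 21
        assert cons.parsimony_term(cols, species_tree, null=parsimony_null) == 0.0


class TestTreeTerm:
    def make_cols(self, species_tree, deviations):
        """21 conserved columns with {column: {species: base}} overrides."""
        labels = species_tree.leaf_labels()
        cols = [{sp: "A" for sp in labels} for _ in range(21)]
        for col, subs in deviations.items():
            cols[col].update(subs)
        return cols

    def test_whole_tree_coverage_gives_zero(self, species_tree):
        # deviations in mouse and fugu: smallest covering clade is the root
        cols = self.make_cols(
            species_tree, {3: {"mouse": "G"}, 10: {"fugu": "G"}}
        )
        assert cons.tree_term(cols, species_tree) == pytest.approx(0.0)

    def test_concentrated_deviations_beat_scattered(self, species_tree):
        concentrated = self.make_cols(
            species_tree, {i: {"tetraodon": "G"} for i in range(5)}
        )
        scattered = self.make_cols(
            species_tree,
            {0: {"tetraodon": "G"}, 1: {"human": "G"}, 2: {"tetraodon": "G"},
             3: {"human": "G"}, 4: {"tetraodon": "G"}},
        )
        assert cons.tree_term(concentrated, species_tree) > cons.tree_term(
            scattered, species_tree
        )

    def test_no_deviations_gives_full_term(self, species_tree):
        cols = self.make_cols(species_tree, {})
        expected = 10.0 * np.log2(species_tree.n_leaves)
        assert cons.tree_term(cols, species_tree) == pytest.approx(expected)

    def test_window_stats_fields(self, species_tree):
        cols = self.make_cols(species_tree, {i: {"tetraodon": "G"} for i in range(5)})
        stats = cons.window_stats(cols, species_tree)
        assert stats.n == 17
        assert stats.m == 1  # single-leaf subtree
        assert stats.total_deviations == 5
        assert stats.k_cols == 21


class TestTrack:
    def test_low_species_sites_score_zero(self, species_tree):
        labels = species_tree.leaf_labels()
        aligned = labels[:9]  # below the 10-of-17 rule
        rows = {sp: ("A" * 30 if sp in aligned else "-" * 30) for sp in labels}
        block = MsaBlock(species=labels, rows=rows, focal_species="mouse")
        track = cons.conservation_score_track([block], species_tree)
        assert np.all(track.score == 0)
        assert np.all(track.n_aligned == 9)

    def test_score_is_sum_of_components(self, screen_run):
        _, explorative, _ = screen_run
        track = explorative.track
        assert np.allclose(track.score, track.parsimony + track.tree_term)
        assert np.all(track.score >= 0)

    def test_conserved_window_outscores_neutral(self, species_tree):
        mask = np.zeros(60, dtype=bool)
        mask[:30] = True
        block = synth.simulate_msa(species_tree, length=60, conserved_mask=mask, seed=4)
        track = cons.conservation_score_track([block], species_tree)
        assert track.score[10:20].mean() > track.score[40:50].mean()


class TestSegmentAreas:
    def naive_areas(self, score, threshold, gap):
        high = [i for i, s in enumerate(score) if s >= threshold]
        if not high:
            return []
        groups = [[high[0]]]
        for pos in high[1:]:
            if pos - groups[-1][-1] - 1 < gap:
                groups[-1].append(pos)
            else:
                groups.append([pos])
        return [(g[0], g[-1] + 1) for g in groups]

    def _track(self, score):
        return cons.ConservationTrack(
            "ref", 0, np.asarray(score, dtype=float), np.zeros(len(score)), np.zeros(len(score), dtype=int)
        )

    def test_single_high_site(self):
        score = [0.0] * 50 + [9.0] + [0.0] * 50
        areas = cons.segment_areas(self._track(score), threshold=5, gap=50)
        assert [(a.start, a.end) for a in areas] == [(50, 51)]

    @pytest.mark.parametrize("low_between,n_areas", [(49, 1), (50, 2)])
    def test_gap_boundary(self, low_between, n_areas):
        score = [9.0] + [0.0] * low_between + [9.0]
        areas = cons.segment_areas(self._track(score), threshold=5, gap=50)
        assert len(areas) == n_areas

    def test_matches_naive_scan_on_random_tracks(self, rng):
        for _ in range(100):
            score = (rng.random(400) < 0.03) * 10.0
            track = self._track(score)
            got = [(a.start, a.end) for a in cons.segment_areas(track, 5, gap=50)]
            assert got == self.naive_areas(score, 5, 50)


class TestStemConservation:
    def _track(self, score):
        n = len(score)
        return cons.ConservationTrack(
            "ref", 0, np.asarray(score, dtype=float), np.zeros(n), np.zeros(n, dtype=int)
        )

    def test_min_of_arm_maxima(self):
        score = np.zeros(100)
        score[10] = 90.0  # arm1 max
        score[60] = 80.0  # arm2 max
        stem = StemCandidate(
            arm1=GenomicRegion("ref", 5, 25),
            arm2=GenomicRegion("ref", 50, 70),
            pairing=[],
        )
        assert cons.stem_conservation(stem, self._track(score)) == 80.0

    def test_equal_arms_and_unaligned_arm(self):
        score = np.zeros(100)
        score[10] = 77.0
        score[60] = 77.0
        stem = StemCandidate(
            arm1=GenomicRegion("ref", 5, 25),
            arm2=GenomicRegion("ref", 50, 70),
            pairing=[],
        )
        assert cons.stem_conservation(stem, self._track(score)) == 77.0
        score[60] = 0.0
        score[50:70] = 0.0
        assert cons.stem_conservation(stem, self._track(score)) == 0.0

    def test_arm_outside_track_is_error(self):
        stem = StemCandidate(
            arm1=GenomicRegion("ref", 5, 25),
            arm2=GenomicRegion("ref", 90, 120),
            pairing=[],
        )
        with pytest.raises(ValueError):
            cons.stem_conservation(stem, self._track(np.zeros(100)))
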
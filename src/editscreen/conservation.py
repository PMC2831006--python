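"""Cross-species conservation scoring of focal-genome sites.

Each aligned site receives a *conservation score* = parsimony term + tree
term, computed over a sliding window of 2k+1 alignment columns:

* the **parsimony term** is -log10 of the p-value of the windowed sum of
  per-column Fitch parsimony scores under neutral HKY evolution on the
  species tree.  The default null is exact: a dynamic program over the tree
  yields the per-column Fitch-score distribution under HKY, and the window
  null is its convolution.  A seeded Monte-Carlo null is available as an
  alternative backend.
* the **tree term** rewards windows whose deviations from the column
  consensus are confined to a small subtree: with n leaves in total, m
  leaves in the smallest clade containing every deviating leaf, d_i
  deviations in column i and k columns, the term is
  w_tt * (sum_i d_i / k) * log2(n / m), and w_tt * log2(n) when the window
  is deviation-free.

Sites aligned in fewer than ``min_species`` species score zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .formats_io import GenomicRegion, MsaBlock, SpeciesTree

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Default 17-taxon vertebrate species tree (focal species: mouse).  Branch
# lengths are neutral substitutions/site of realistic magnitude for this
# species set; override with any user Newick.
DEFAULT_TREE_NEWICK = (
    "((((((((mouse:0.084,rat:0.091):0.271,rabbit:0.206):0.107,"
    "((human:0.065,chimp:0.068):0.027,macaque:0.092):0.111):0.025,"
    "(dog:0.132,cow:0.187):0.033):0.021,"
    "(armadillo:0.153,(elephant:0.122,tenrec:0.268):0.035):0.024):0.141,"
    "opossum:0.372):0.262,chicken:0.474):0.304,"
    "(frog:0.691,(zebrafish:0.731,(tetraodon:0.224,fugu:0.203):0.497):0.292):0.117);"
)


def default_species_tree() -> SpeciesTree:
    from .formats_io import read_newick

    return read_newick(DEFAULT_TREE_NEWICK, focal_species="mouse")


@dataclass
class ConservationParams:
    window_halfwidth: int = 10  # k; window width 2k+1 columns
    min_species: int = 10
    null_replicates: int = 1000
    seed: int = 0
    hky_kappa: float = 2.0
    hky_base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    tree_term_weight: float = 10.0  # w_tt
    null_backend: str = "exact"  # 'exact' | 'montecarlo'

    def __post_init__(self) -> None:
        if self.window_halfwidth < 0:
            raise ValueError("window halfwidth must be >= 0")
        if abs(sum(self.hky_base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


@dataclass
class WindowStats:
    n: int
    m: int
    d: list
    k_cols: int

    @property
    def total_deviations(self) -> int:
        return int(sum(self.d))


# ---------------------------------------------------------------------------
# HKY model


def hky_rate_matrix(kappa: float, freqs) -> np.ndarray:
    """HKY85 rate matrix (A,C,G,T order), normalized to 1 expected
    substitution per site per unit branch length."""
    pi = np.asarray(freqs, dtype=float)
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.dot(pi, np.diag(q))
    return q / rate


class HKYModel:
    def __init__(self, kappa: float = 2.0, freqs=(0.25, 0.25, 0.25, 0.25)):
        self.kappa = kappa
        self.freqs = np.asarray(freqs, dtype=float)
        self.Q = hky_rate_matrix(kappa, freqs)
        self._pcache: dict[float, np.ndarray] = {}

    def transition_matrix(self, t: float) -> np.ndarray:
        key = round(float(t), 12)
        if key not in self._pcache:
            self._pcache[key] = expm(self.Q * float(t))
        return self._pcache[key]


# ---------------------------------------------------------------------------
# Fitch parsimony


def fitch_score(column: dict, tree: SpeciesTree) -> int:
    """Minimum substitution count (Fitch) for one alignment column on the
    tree restricted to leaves with an unambiguous base.  Columns with fewer
    than two informative leaves score 0."""
    score, informative = _fitch(column, tree)
    return score if informative >= 2 else 0


def _fitch(column: dict, tree: SpeciesTree) -> tuple[int, int]:
    score = 0
    informative = 0

    def visit(node):
        nonlocal score, informative
        if node.is_leaf():
            base = column.get(node.taxon.label, "-")
            if base in _BASE_INDEX:
                informative += 1
                return 1 << _BASE_INDEX[base]
            return 0
        acc = 0
        for child in node.child_nodes():
            child_set = visit(child)
            if child_set == 0:
                continue
            if acc == 0:
                acc = child_set
            elif acc & child_set:
                acc &= child_set
            else:
                acc |= child_set
                score += 1
        return acc

    visit(tree.tree.seed_node)
    return score, informative


# ---------------------------------------------------------------------------
# Null distribution of windowed parsimony sums


class ParsimonyNull:
    """Null model for the windowed Fitch-score sum under HKY on the tree.

    The exact backend computes the per-column Fitch-score pmf by a dynamic
    program over (Fitch state set, score) pairs and convolves it across
    window columns (columns are independent under the null).  The
    Monte-Carlo backend simulates whole columns instead.
    """

    def __init__(self, tree: SpeciesTree, params: ConservationParams):
        self.tree = tree
        self.params = params
        self.model = HKYModel(params.hky_kappa, params.hky_base_freqs)
        self._column_pmf: np.ndarray | None = None
        self._window_cdfs: dict[int, np.ndarray] = {}

    def column_pmf(self) -> np.ndarray:
        """Exact pmf of the per-column Fitch score under HKY (full tree)."""
        if self._column_pmf is not None:
            return self._column_pmf
        max_score = self.tree.n_leaves  # loose upper bound

        def subtree_dist(node):
            """For each possible base at the node (after its edge), the
            distribution over (fitch_set, score) of its subtree."""
            if node.is_leaf():
                return [{(1 << b, 0): 1.0} for b in range(4)]
            child_dists = []
            for child in node.child_nodes():
                below = subtree_dist(child)
                P = self.model.transition_matrix(child.edge.length or 0.0)
                # marginalize the child's own base given the parent's base
                merged = [dict() for _ in range(4)]
                for a in range(4):
                    for b in range(4):
                        w = P[a, b]
                        if w == 0.0:
                            continue
                        for state, p in below[b].items():
                            merged[a][state] = merged[a].get(state, 0.0) + w * p
                child_dists.append(merged)
            out = []
            for a in range(4):
                acc = {(0, 0): 1.0}
                for dist in child_dists:
                    nxt: dict = {}
                    for (f1, s1), p1 in acc.items():
                        for (f2, s2), p2 in dist[a].items():
                            if f1 == 0:
                                state = (f2, s1 + s2)
                            elif f1 & f2:
                                state = (f1 & f2, s1 + s2)
                            else:
                                state = (f1 | f2, s1 + s2 + 1)
                            nxt[state] = nxt.get(state, 0.0) + p1 * p2
                    acc = nxt
                out.append(acc)
            return out

        root_dist = subtree_dist(self.tree.tree.seed_node)
        pmf = np.zeros(max_score + 1)
        for a in range(4):
            for (f, s), p in root_dist[a].items():
                pmf[s] += self.model.freqs[a] * p
        pmf /= pmf.sum()
        self._column_pmf = pmf
        return pmf

    def window_logcdf(self, n_columns: int) -> np.ndarray:
        """log10 mid-p lower-tail values for the sum S of ``n_columns`` iid
        column scores: P(S < s) + P(S = s)/2.

        The mid-p convention keeps p-values of the discrete statistic
        approximately uniform under the null instead of conservative.
        """
        if n_columns not in self._window_cdfs:
            pmf = self.column_pmf()
            acc = np.array([1.0])
            for _ in range(n_columns):
                acc = np.convolve(acc, pmf)
            midp = np.cumsum(acc) - 0.5 * acc
            midp = np.clip(midp, 1e-300, 1.0)
            self._window_cdfs[n_columns] = np.log10(midp)
        return self._window_cdfs[n_columns]

    def pvalue_exact(self, s: int, n_columns: int) -> float:
        logcdf = self.window_logcdf(n_columns)
        s = min(int(s), len(logcdf) - 1)
        return float(10.0 ** logcdf[s])

    # -- Monte-Carlo backend

    def simulate_columns(self, n_columns: int, rng: np.random.Generator) -> list[dict]:
        """Draw iid neutral columns (dict species -> base) under HKY."""
        labels = []
        cols = [dict() for _ in range(n_columns)]

        def walk(node, states):
            t = node.edge.length or 0.0
            if node is not self.tree.tree.seed_node:
                P = self.model.transition_matrix(t)
                new = np.empty_like(states)
                for a in range(4):
                    mask = states == a
                    k = int(mask.sum())
                    if k:
                        new[mask] = rng.choice(4, size=k, p=P[a])
                states = new
            if node.is_leaf():
                label = node.taxon.label
                labels.append(label)
                for i, st in enumerate(states):
                    cols[i][label] = BASES[st]
                return
            for child in node.child_nodes():
                walk(child, states)

        root_states = rng.choice(4, size=n_columns, p=self.model.freqs)
        walk(self.tree.tree.seed_node, root_states)
        return cols

    def null_sums(self, n_columns: int, rng: np.random.Generator) -> np.ndarray:
        reps = self.params.null_replicates
        cols = self.simulate_columns(n_columns * reps, rng)
        scores = np.fromiter(
            (fitch_score(c, self.tree) for c in cols), dtype=np.int64
        )
        return scores.reshape(reps, n_columns).sum(axis=1)

    def pvalue_montecarlo(self, s: int, n_columns: int, rng: np.random.Generator) -> float:
        sums = self.null_sums(n_columns, rng)
        return (1 + int((sums <= s).sum())) / (len(sums) + 1)


def parsimony_term(
    window_columns: list[dict],
    tree: SpeciesTree,
    params: ConservationParams | None = None,
    null: ParsimonyNull | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """-log10 p-value of the window's Fitch-score sum under the HKY null."""
    params = params or ConservationParams()
    null = null or ParsimonyNull(tree, params)
    scores = [fitch_score(c, tree) for c in window_columns]
    if all(s == 0 for s in scores) and not any(
        sum(1 for v in c.values() if v in _BASE_INDEX) >= 2 for c in window_columns
    ):
        return 0.0
    s = int(sum(scores))
    if params.null_backend == "montecarlo":
        rng = rng or np.random.default_rng(params.seed)
        p = null.pvalue_montecarlo(s, len(window_columns), rng)
        p = max(p, 1.0 / (params.null_replicates + 1))
    else:
        p = null.pvalue_exact(s, len(window_columns))
    return float(-np.log10(p))


# ---------------------------------------------------------------------------
# Tree term


def _clade_table(tree: SpeciesTree):
    """(leaf-index map, list of (bitmask, leaf count) for every node)."""
    leaves = tree.leaf_labels()
    index = {label: i for i, label in enumerate(leaves)}
    clades = []
    for node in tree.tree.postorder_node_iter():
        mask = 0
        for lf in node.leaf_iter():
            mask |= 1 << index[lf.taxon.label]
        clades.append((mask, bin(mask).count("1")))
    return index, clades


def column_deviations(column: dict, tree: SpeciesTree, leaf_index: dict) -> tuple[int, int]:
    """(bitmask of deviating leaves, deviation count) for one column.

    Deviation is measured against the column majority among informative
    leaves; majority ties break toward the focal species' base when it is
    among the tied bases, else toward the alphabetically first tied base.
    """
    counts = {}
    present = []
    for sp, base in column.items():
        if base in _BASE_INDEX and sp in leaf_index:
            counts[base] = counts.get(base, 0) + 1
            present.append((sp, base))
    if not counts:
        return 0, 0
    top = max(counts.values())
    tied = sorted(b for b, c in counts.items() if c == top)
    focal_base = column.get(tree.focal_species, "-")
    majority = focal_base if focal_base in tied else tied[0]
    mask = 0
    d = 0
    for sp, base in present:
        if base != majority:
            mask |= 1 << leaf_index[sp]
            d += 1
    return mask, d


def tree_term(
    window_columns: list[dict],
    tree: SpeciesTree,
    params: ConservationParams | None = None,
    _tables=None,
) -> float:
    """Subtree-concentration reward for a window of columns (see module
    docstring for the formula)."""
    params = params or ConservationParams()
    leaf_index, clades = _tables or _clade_table(tree)
    n = tree.n_leaves
    union = 0
    total_d = 0
    for col in window_columns:
        mask, d = column_deviations(col, tree, leaf_index)
        union |= mask
        total_d += d
    w = params.tree_term_weight
    if total_d == 0:
        return float(w * np.log2(n))
    m = min(cnt for cmask, cnt in clades if (cmask & union) == union)
    k_cols = len(window_columns)
    return float(w * (total_d / k_cols) * np.log2(n / m))


def window_stats(window_columns: list[dict], tree: SpeciesTree) -> WindowStats:
    leaf_index, clades = _clade_table(tree)
    ds = []
    union = 0
    for col in window_columns:
        mask, d = column_deviations(col, tree, leaf_index)
        union |= mask
        ds.append(d)
    if union:
        m = min(cnt for cmask, cnt in clades if (cmask & union) == union)
    else:
        m = tree.n_leaves
    return WindowStats(n=tree.n_leaves, m=m, d=ds, k_cols=len(window_columns))


# ---------------------------------------------------------------------------
# Track


@dataclass
class ConservationTrack:
    """Per-site conservation scores over [start, start+len) of one sequence."""

    chrom: str
    start: int
    parsimony: np.ndarray
    tree_term: np.ndarray
    n_aligned: np.ndarray

    @property
    def score(self) -> np.ndarray:
        return self.parsimony + self.tree_term

    @property
    def end(self) -> int:
        return self.start + len(self.parsimony)

    def site_score(self, pos: int) -> float:
        if not (self.start <= pos < self.end):
            raise IndexError(f"position {pos} outside track [{self.start}, {self.end})")
        return float(self.score[pos - self.start])


def conservation_score_track(
    blocks: list[MsaBlock],
    tree: SpeciesTree,
    params: ConservationParams | None = None,
    null: ParsimonyNull | None = None,
) -> ConservationTrack:
    """Score every focal site covered by ``blocks``.

    Sites aligned in fewer than ``min_species`` species (or not covered at
    all) score zero; windows are truncated at block edges.
    """
    params = params or ConservationParams()
    null = null or ParsimonyNull(tree, params)
    tables = _clade_table(tree)
    leaf_index, clades = tables
    if not blocks:
        return ConservationTrack("ref", 0, np.zeros(0), np.zeros(0), np.zeros(0, dtype=int))
    chrom = blocks[0].chrom
    positions = [p for b in blocks for p in b.focal_positions() if p is not None]
    lo, hi = min(positions), max(positions) + 1
    pars = np.zeros(hi - lo)
    tt = np.zeros(hi - lo)
    n_aligned = np.zeros(hi - lo, dtype=int)
    k = params.window_halfwidth
    rng = np.random.default_rng(params.seed)
    for block in blocks:
        ncol = block.n_columns
        cols = [block.column(i) for i in range(ncol)]
        counts = np.array(
            [sum(1 for v in c.values() if v in _BASE_INDEX) for c in cols]
        )
        fitch = np.array([fitch_score(c, tree) for c in cols])
        devs = [column_deviations(c, tree, leaf_index) for c in cols]
        focal_pos = block.focal_positions()
        for i, pos in enumerate(focal_pos):
            if pos is None:
                continue
            n_aligned[pos - lo] = counts[i]
            if counts[i] < params.min_species:
                continue
            w0, w1 = max(0, i - k), min(ncol, i + k + 1)
            s = int(fitch[w0:w1].sum())
            if params.null_backend == "montecarlo":
                p = null.pvalue_montecarlo(s, w1 - w0, rng)
                p = max(p, 1.0 / (params.null_replicates + 1))
            else:
                p = null.pvalue_exact(s, w1 - w0)
            pars[pos - lo] = -np.log10(p)
            union = 0
            total_d = 0
            for mask, d in devs[w0:w1]:
                union |= mask
                total_d += d
            w = params.tree_term_weight
            n = tree.n_leaves
            if total_d == 0:
                tt[pos - lo] = w * np.log2(n)
            else:
                m = min(cnt for cmask, cnt in clades if (cmask & union) == union)
                tt[pos - lo] = w * (total_d / (w1 - w0)) * np.log2(n / m)
    return ConservationTrack(chrom, lo, pars, tt, n_aligned)


# ---------------------------------------------------------------------------
# Areas and stem conservation


def segment_areas(
    track: ConservationTrack, threshold: float, gap: int = 50
) -> list[GenomicRegion]:
    """Maximal conserved segments: each contains at least one site scoring
    >= threshold and is bounded on each side by >= ``gap`` consecutive
    sites scoring below it (track edges also bound)."""
    score = track.score
    n = len(score)
    areas = []
    i = 0
    while i < n:
        if score[i] < threshold:
            i += 1
            continue
        # extend right: the area continues while the next high site is
        # fewer than `gap` low sites away
        start = i
        end = i
        j = i + 1
        low_run = 0
        while j < n and low_run < gap:
            if score[j] >= threshold:
                end = j
                low_run = 0
            else:
                low_run += 1
            j += 1
        areas.append(
            GenomicRegion(track.chrom, track.start + start, track.start + end + 1)
        )
        i = max(j, end + 1)
    return areas


def stem_conservation(stem, track: ConservationTrack) -> float:
    """Stem conservation = the highest-scoring site on the lower-scoring of
    the two arms (min over arms of the per-arm max)."""
    maxima = []
    for arm in (stem.arm1, stem.arm2):
        if arm.start < track.start or arm.end > track.end:
            raise ValueError(f"arm {arm} outside track [{track.start}, {track.end})")
        seg = track.score[arm.start - track.start : arm.end - track.start]
        maxima.append(float(seg.max()))
    return min(maxima)
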
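"""Prediction of candidate RNA stems: near-reverse-complementary arm pairs
within a genic sequence.

The search aligns a sequence against its own reverse complement with a
pairing-aware scoring matrix, so that an alignment "match" corresponds to a
Watson-Crick or G.U wobble base pair in the folded stem.  Retained arm pairs
are scored with a built-in nearest-neighbor duplex energy model and passed
through arm-length / energy / bulge filters, a gluing step that joins nearby
stems, and a maximal-span selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats_io import GenomicRegion

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Canonical duplex pairs (DNA alphabet; T plays U): Watson-Crick + G.U wobble.
CANONICAL_PAIRS = frozenset(
    [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")]
)


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PairingWeightMatrix:
    """Base-pairing scores indexed (base in arm 1, base in the reverse
    complement of arm 2).

    Identities reward Watson-Crick pairs (A/A -> A:U etc.); the two
    asymmetric off-diagonal rewards encode the G.U wobble (G/A and T/C under
    reverse-complement indexing).  Used as printed, without symmetrization.
    """

    scores: dict = field(
        default_factory=lambda: {
            ("A", "A"): 80,
            ("C", "C"): 120,
            ("G", "G"): 120,
            ("T", "T"): 80,
            ("G", "A"): 20,
            ("T", "C"): 20,
        }
    )
    mismatch: int = -100

    def score(self, a: str, b: str) -> int:
        return self.scores.get((a, b), self.mismatch)

    def as_array(self) -> np.ndarray:
        arr = np.full((5, 5), self.mismatch, dtype=np.int32)
        idx = {b: i for i, b in enumerate("ACGTN")}
        for (a, b), s in self.scores.items():
            arr[idx[a], idx[b]] = s
        arr[4, :] = self.mismatch  # N never rewards
        arr[:, 4] = self.mismatch
        return arr


@dataclass(frozen=True)
class AlignParams:
    """Self-revcomp alignment parameters (affine gaps as penalties)."""

    gap_open: int = 150
    gap_extend: int = 100
    msp_score_K: int = 500
    gapped_threshold_L: int = 500
    word_size: int = 6
    min_loop: int = 4  # minimum nt between the two arms
    max_alignments: int = 64

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend, self.msp_score_K, self.gapped_threshold_L) <= 0:
            raise ValueError("alignment penalties/thresholds must be positive")
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")


@dataclass(frozen=True)
class StemParams:
    min_arm_length: int = 16
    max_energy: float = -15.0
    max_bulge_size: int = 5
    max_bulge_bases: int = 7
    max_glue_distance: int = 10
    max_filter_energy: float = -15.0
    max_candidate_span: int = 5000

    def __post_init__(self) -> None:
        if self.min_arm_length < 1:
            raise ValueError("min_arm_length must be >= 1")
        if self.max_energy >= 0:
            raise ValueError("max_energy must be negative")


@dataclass
class StemCandidate:
    """Two near-reverse-complementary arms on one sequence.

    ``pairing`` is a list of aligned columns (arm1 base or None, arm2 base or
    None); arm1 is read 5'->3' and arm2 3'->5' (descending forward
    coordinate), so a column with both bases present is a putative pair.
    """

    arm1: GenomicRegion
    arm2: GenomicRegion
    pairing: list
    energy: float = 0.0
    score: int = 0
    conservation: float | None = None

    @property
    def loop_span(self) -> int:
        return self.arm2.start - self.arm1.end

    @property
    def span(self) -> int:
        return self.arm2.end - self.arm1.start

    def arm_sequences(self, sequence: str) -> tuple[str, str]:
        return (
            sequence[self.arm1.start : self.arm1.end],
            sequence[self.arm2.start : self.arm2.end],
        )


# ---------------------------------------------------------------------------
# Local alignment of a sequence against its reverse complement


def _gotoh_matrices(
    s1: np.ndarray,
    s2: np.ndarray,
    sub: np.ndarray,
    open_cost: int,
    extend_cost: int,
    min_sep: int = 0,
):
    """Affine-gap local alignment (Gotoh) score matrices.

    A gap of length k costs open_cost + k * extend_cost.  With s2 the
    reverse complement of s1, ``min_sep`` masks all cells whose arm1
    position is not at least ``min_sep`` nt upstream of its aligned arm2
    position: alignments then cannot self-overlap, and each arm pair
    appears exactly once (its mirror image lies in the masked triangle).
    """
    n, m = len(s1), len(s2)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    Iy = np.full((n + 1, m + 1), np.iinfo(np.int32).min // 2, dtype=np.int32)
    Ix = np.full((n + 1, m + 1), np.iinfo(np.int32).min // 2, dtype=np.int32)
    neg = np.iinfo(np.int32).min // 2
    col_idx = np.arange(1, m + 1, dtype=np.int64) * extend_cost
    for i in range(1, n + 1):
        subs = sub[s1[i - 1], s2]  # length m
        M[i, 1:] = np.maximum(H[i - 1, :-1] + subs, 0)
        Iy[i, 1:] = np.maximum(H[i - 1, 1:] - open_cost, Iy[i - 1, 1:]) - extend_cost
        # horizontal gaps via prefix max: Ix[i,j] = max_k<j (G[i,k] + k*e) - open - j*e
        G = np.maximum(M[i], Iy[i]).astype(np.int64)
        G[0] = 0
        run = np.maximum.accumulate(G[:-1] + np.concatenate(([0], col_idx[:-1])))
        Ix[i, 1:] = (run - open_cost - col_idx).astype(np.int32)
        H[i] = np.maximum(np.maximum(M[i], Ix[i]), np.maximum(Iy[i], 0))
        if min_sep:
            cut = max(0, m - i - min_sep + 1)
            H[i, cut:] = 0
            M[i, cut:] = 0
            Ix[i, cut:] = neg
            Iy[i, cut:] = neg
    return H, M, Ix, Iy


def _traceback(i, j, s1, s2, sub, open_cost, extend_cost, H, M, Ix, Iy):
    """Trace one local alignment ending at (i, j); returns (i0, j0, columns).

    Columns are (char from s1 | None, char from s2 | None).
    """
    cols = []
    # start in whichever state attains H[i, j]
    state = "M"
    if H[i, j] == Ix[i, j]:
        state = "X"
    elif H[i, j] == Iy[i, j]:
        state = "Y"
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] == 0:
                break
            cols.append((s1[i - 1], s2[j - 1]))
            i, j = i - 1, j - 1
            if H[i, j] == 0:
                break
            if M[i, j] == H[i, j]:
                state = "M"
            elif Ix[i, j] == H[i, j]:
                state = "X"
            else:
                state = "Y"
        elif state == "X":  # gap in s1: consume s2
            cols.append((None, s2[j - 1]))
            opened = max(M[i, j - 1], Iy[i, j - 1]) - open_cost - extend_cost
            extended = Ix[i, j - 1] - extend_cost
            j -= 1
            if opened >= extended:
                state = "M" if M[i, j] >= Iy[i, j] else "Y"
            else:
                state = "X"
        else:  # gap in s2: consume s1
            cols.append((s1[i - 1], None))
            opened = max(M[i - 1, j], Ix[i - 1, j]) - open_cost - extend_cost
            extended = Iy[i - 1, j] - extend_cost
            i -= 1
            if opened >= extended:
                state = "M" if M[i, j] >= Ix[i, j] else "X"
            else:
                state = "Y"
    cols.reverse()
    return i, j, cols


def _best_ungapped_segment(cols, matrix: PairingWeightMatrix) -> int:
    """Kadane max over the gap-free runs of an alignment column list."""
    best = 0
    run = 0
    for a, b in cols:
        if a is None or b is None:
            run = 0
            continue
        run = max(0, run) + matrix.score(a, b)
        best = max(best, run)
    return best


def _has_seed(cols, word_size: int) -> bool:
    run = 0
    for a, b in cols:
        if a is not None and a == b:
            run += 1
            if run >= word_size:
                return True
        else:
            run = 0
    return False


def find_inverted_pairs(
    sequence: str,
    params: AlignParams | None = None,
    matrix: PairingWeightMatrix | None = None,
) -> list[StemCandidate]:
    """Find near-reverse-complementary arm pairs within ``sequence``.

    The sequence is locally aligned to its own reverse complement under the
    pairing matrix with affine gap penalties.  An arm pair is reported when
    its gapped score reaches ``gapped_threshold_L``, it contains an exact
    ``word_size``-mer seed and a gap-free segment scoring ``msp_score_K``
    (the seeding contract), and the two arms are disjoint with at least
    ``min_loop`` nt between them.  Arms are reported in forward-strand
    coordinates with arm1 upstream; energies are not yet attached.
    """
    params = params or AlignParams()
    matrix = matrix or PairingWeightMatrix()
    L = len(sequence)
    if L < params.word_size:
        return []
    rc = reverse_complement(sequence)
    idx = {b: i for i, b in enumerate("ACGTN")}
    s1 = np.fromiter((idx[c] for c in sequence), dtype=np.int8, count=L)
    s2 = np.fromiter((idx[c] for c in rc), dtype=np.int8, count=L)
    sub = matrix.as_array()
    open_cost, extend_cost = params.gap_open, params.gap_extend
    H, M, Ix, Iy = _gotoh_matrices(
        s1, s2, sub, open_cost, extend_cost, min_sep=params.min_loop
    )

    results: list[StemCandidate] = []
    footprints: list[tuple[int, int]] = []  # forward-coordinate intervals used
    reported = 0
    # pick alignment regions best-first; zero out each traced region so
    # near-duplicate end cells of the same region are not re-traced
    Hwork = H.copy()
    for _ in range(2000):
        if reported >= params.max_alignments:
            break
        cell = int(np.argmax(Hwork))
        score = int(Hwork.ravel()[cell])
        if score < params.gapped_threshold_L:
            break
        i, j = divmod(cell, H.shape[1])
        i0, j0, cols = _traceback(
            i, j, sequence, rc, sub, open_cost, extend_cost, H, M, Ix, Iy
        )
        Hwork[max(0, i0 - 2) : i + 3, max(0, j0 - 2) : j + 3] = 0
        if not cols:
            continue
        a1s, a1e = i0, i
        a2s, a2e = L - j, L - j0  # forward coordinates of the rc segment
        # canonical orientation: arm1 strictly upstream, disjoint, min loop
        if a1s >= a2s:
            continue
        if a2s - a1e < params.min_loop:
            continue
        if any(s < hi and lo < e for s, e in ((a1s, a1e), (a2s, a2e)) for lo, hi in footprints):
            continue
        if not _has_seed(cols, params.word_size):
            continue
        if _best_ungapped_segment(cols, matrix) < params.msp_score_K:
            continue
        # rewrite columns with arm2 bases in forward orientation
        pairing = [
            (a, None if b is None else b.translate(_COMPLEMENT)) for a, b in cols
        ]
        results.append(
            StemCandidate(
                arm1=GenomicRegion("seq", a1s, a1e),
                arm2=GenomicRegion("seq", a2s, a2e),
                pairing=pairing,
                score=score,
            )
        )
        footprints.extend([(a1s, a1e), (a2s, a2e)])
        reported += 1
    results.sort(key=lambda st: (-st.score, st.arm1.start))
    return results


# ---------------------------------------------------------------------------
# Nearest-neighbor duplex energy

# Turner-style Watson-Crick nearest-neighbor stack free energies, kcal/mol at
# 37C.  Keys are (pair1, pair2) for the step 5'-b1 b1'-3' paired with
# 3'-b2 b2'-5', each pair written arm1-base + arm2-base in RNA letters.
_WC_STACKS = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
}
_WOBBLE_SINGLE = -1.3  # one G.U pair in the step (approximate)
_WOBBLE_DOUBLE = -0.5  # both pairs wobble

_BULGE_PENALTY = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_ILOOP_PENALTY = {2: 1.5, 3: 1.6, 4: 1.7, 5: 2.0, 6: 2.0}


def _rev_pair(p: str) -> str:
    return p[::-1]


def _stack_energy(p1: str, p2: str) -> float:
    wob = (p1 in ("GU", "UG")) + (p2 in ("GU", "UG"))
    if wob == 2:
        return _WOBBLE_DOUBLE
    if wob == 1:
        return _WOBBLE_SINGLE
    if (p1, p2) in _WC_STACKS:
        return _WC_STACKS[(p1, p2)]
    return _WC_STACKS.get((_rev_pair(p2), _rev_pair(p1)), _WOBBLE_SINGLE)


def _loop_penalty(n1: int, n2: int) -> float:
    if n1 == 0 and n2 == 0:
        return 0.0
    if n1 == 0 or n2 == 0:  # bulge
        n = n1 + n2
        if n in _BULGE_PENALTY:
            return _BULGE_PENALTY[n]
        return 4.4 + 1.08 * float(np.log(n / 6.0))
    n = n1 + n2  # internal loop (includes 1x1 mismatches)
    if n in _ILOOP_PENALTY:
        return _ILOOP_PENALTY[n]
    return 2.0 + 1.08 * float(np.log(n / 6.0))


def duplex_energy(arm1_sequence: str, arm2_sequence: str, pairing: list) -> float:
    """Free energy (kcal/mol) of the duplex described by ``pairing``.

    arm1 is consumed 5'->3', arm2 3'->5'.  Stacks over consecutive canonical
    pairs use the embedded nearest-neighbor table; unpaired stretches incur
    additive bulge/internal-loop penalties.  Terminal unpaired columns are
    ignored; an empty duplex has energy 0.
    """
    n1 = sum(1 for a, _ in pairing if a is not None)
    n2 = sum(1 for _, b in pairing if b is not None)
    if n1 != len(arm1_sequence) or n2 != len(arm2_sequence):
        raise ValueError(
            f"pairing consumes {n1}/{n2} bases but arms have "
            f"{len(arm1_sequence)}/{len(arm2_sequence)}"
        )
    rna = str.maketrans("T", "U")
    canonical = [
        k
        for k, (a, b) in enumerate(pairing)
        if a is not None and b is not None and (a, b) in CANONICAL_PAIRS
    ]
    if len(canonical) < 2:
        return 0.0
    energy = 0.0
    for prev, nxt in zip(canonical[:-1], canonical[1:]):
        pa, pb = pairing[prev], pairing[nxt]
        p1 = (pa[0] + pa[1]).translate(rna)
        p2 = (pb[0] + pb[1]).translate(rna)
        if nxt == prev + 1:
            energy += _stack_energy(p1, p2)
        else:
            u1 = sum(1 for a, _ in pairing[prev + 1 : nxt] if a is not None)
            u2 = sum(1 for _, b in pairing[prev + 1 : nxt] if b is not None)
            energy += _loop_penalty(u1, u2)
    return round(energy, 2)


def attach_energies(stems: list[StemCandidate], sequence: str) -> list[StemCandidate]:
    for st in stems:
        a1, a2 = st.arm_sequences(sequence)
        st.energy = duplex_energy(a1, a2, st.pairing)
    return stems


# ---------------------------------------------------------------------------
# Filtering, gluing, selection


def split_into_stems(
    pairs: list[StemCandidate],
    params: StemParams | None = None,
    sequence: str | None = None,
) -> list[StemCandidate]:
    """Decompose raw arm-pair alignments into stems.

    A gapped alignment may chain well-paired helices across mismatch- and
    gap-rich stretches; a stem, by contrast, tolerates only small bulges.
    Helices (maximal runs of canonical pairs) are chained left to right for
    as long as the bulge budget holds -- no intervening unpaired run above
    ``max_bulge_size`` nt on either strand and no more than
    ``max_bulge_bases`` unpaired nt in total -- and a fresh stem starts
    whenever the budget would be exceeded.  Terminal unpaired columns are
    trimmed and energies computed per piece.  Nearby pieces can later be
    rejoined by :func:`glue_stems`.
    """
    params = params or StemParams()
    out: list[StemCandidate] = []
    for st in pairs:
        cols = st.pairing
        n = len(cols)

        def is_pair(k):
            a, b = cols[k]
            return a is not None and b is not None and (a, b) in CANONICAL_PAIRS

        # maximal runs of consecutive canonical pairs (helices), and the
        # unpaired nt counts of the gaps between them
        helices: list[tuple[int, int]] = []
        k = 0
        while k < n:
            if is_pair(k):
                start = k
                while k < n and is_pair(k):
                    k += 1
                helices.append((start, k - 1))
            else:
                k += 1

        def gap_cost(h_prev, h_next):
            n1 = n2 = 0
            for a, b in cols[h_prev[1] + 1 : h_next[0]]:
                n1 += a is not None
                n2 += b is not None
            return n1, n2

        # chain helices left to right while the bulge budget holds:
        # pieces are [running unpaired total, first pair column, last pair column]
        pieces: list[list[int]] = []
        for h in helices:
            if pieces:
                prev = pieces[-1]
                n1, n2 = gap_cost((0, prev[2]), (h[0], 0))
                if (
                    max(n1, n2) <= params.max_bulge_size
                    and prev[0] + n1 + n2 <= params.max_bulge_bases
                ):
                    prev[0] += n1 + n2
                    prev[2] = h[1]
                    continue
            pieces.append([0, h[0], h[1]])
        # map pieces back to coordinates, trimming terminal unpaired columns
        pos1 = st.arm1.start
        pos2 = st.arm2.end  # arm2 consumed descending
        col_coords = []
        for a, b in cols:
            c1 = pos1 if a is not None else None
            if a is not None:
                pos1 += 1
            if b is not None:
                pos2 -= 1
                c2 = pos2
            else:
                c2 = None
            col_coords.append((c1, c2))
        for _, lo, hi in pieces:
            sub = cols[lo : hi + 1]
            a1s = col_coords[lo][0]
            a1e = col_coords[hi][0] + 1
            a2s = col_coords[hi][1]
            a2e = col_coords[lo][1] + 1
            if a2s - a1e < 1:
                continue
            piece_stem = StemCandidate(
                arm1=GenomicRegion(st.arm1.chrom, a1s, a1e),
                arm2=GenomicRegion(st.arm2.chrom, a2s, a2e),
                pairing=sub,
                score=st.score,
            )
            if sequence is not None:
                s1, s2 = piece_stem.arm_sequences(sequence)
                piece_stem.energy = duplex_energy(s1, s2, piece_stem.pairing)
            out.append(piece_stem)
    return out


def _bulge_stats(pairing) -> tuple[int, int]:
    """(largest single-strand unpaired run, total unpaired nt on both strands)."""
    max_run = 0
    total = 0
    run1 = run2 = 0
    for a, b in pairing:
        paired = a is not None and b is not None and (a, b) in CANONICAL_PAIRS
        if paired:
            run1 = run2 = 0
            continue
        if a is not None:
            run1 += 1
            total += 1
        if b is not None:
            run2 += 1
            total += 1
        if a is None:
            run1 = 0
        if b is None:
            run2 = 0
        max_run = max(max_run, run1, run2)
    return max_run, total


def filter_stems(stems: list[StemCandidate], params: StemParams | None = None) -> list[StemCandidate]:
    """Keep stems satisfying arm-length, energy and bulge bounds."""
    params = params or StemParams()
    kept = []
    for st in stems:
        if len(st.arm1) < params.min_arm_length or len(st.arm2) < params.min_arm_length:
            continue
        if st.energy > params.max_energy:
            continue
        max_run, total = _bulge_stats(st.pairing)
        if max_run > params.max_bulge_size or total > params.max_bulge_bases:
            continue
        kept.append(st)
    return kept


def glue_stems(
    stems: list[StemCandidate],
    params: StemParams | None = None,
    sequence: str | None = None,
) -> list[StemCandidate]:
    """Join adjacent stems whose corresponding arms lie within
    ``max_glue_distance`` of each other; re-score merged stems and drop
    merges above ``max_filter_energy``.

    ``sequence`` is needed to fill the unpaired gap bases of a merge.
    """
    params = params or StemParams()
    stems = sorted(stems, key=lambda s: s.arm1.start)
    out: list[StemCandidate] = []
    cur: StemCandidate | None = None
    for st in stems:
        if cur is None:
            cur = st
            continue
        gap1 = st.arm1.start - cur.arm1.end
        gap2 = cur.arm2.start - st.arm2.end
        if 0 <= gap1 <= params.max_glue_distance and 0 <= gap2 <= params.max_glue_distance:
            if sequence is None:
                raise ValueError("gluing requires the source sequence")
            mid1 = sequence[cur.arm1.end : st.arm1.start]
            mid2 = sequence[st.arm2.end : cur.arm2.start]
            pairing = (
                list(cur.pairing)
                + [(c, None) for c in mid1]
                + [(None, c) for c in reversed(mid2)]
                + list(st.pairing)
            )
            merged = StemCandidate(
                arm1=GenomicRegion(cur.arm1.chrom, cur.arm1.start, st.arm1.end),
                arm2=GenomicRegion(cur.arm2.chrom, st.arm2.start, cur.arm2.end),
                pairing=pairing,
                score=cur.score + st.score,
            )
            a1, a2 = merged.arm_sequences(sequence)
            merged.energy = duplex_energy(a1, a2, merged.pairing)
            cur = merged
        else:
            out.append(cur)
            cur = st
    if cur is not None:
        out.append(cur)
    return [st for st in out if st.energy <= params.max_filter_energy]


def select_candidates(stems: list[StemCandidate], params: StemParams | None = None) -> list[StemCandidate]:
    """Keep stems whose total span (arm1 start to arm2 end) is bounded."""
    params = params or StemParams()
    return [st for st in stems if st.span <= params.max_candidate_span]


def predict_stems(
    sequence: str,
    chrom: str = "seq",
    align_params: AlignParams | None = None,
    stem_params: StemParams | None = None,
    matrix: PairingWeightMatrix | None = None,
) -> list[StemCandidate]:
    """Full stem stage: inverted-pair search -> energy -> filter -> glue ->
    span selection.  Stems are sorted by (energy, arm1 start)."""
    stem_params = stem_params or StemParams()
    pairs = find_inverted_pairs(sequence, align_params, matrix)
    for st in pairs:
        st.arm1 = replace(st.arm1, chrom=chrom)
        st.arm2 = replace(st.arm2, chrom=chrom)
    stems = split_into_stems(pairs, stem_params, sequence)
    stems = filter_stems(stems, stem_params)
    stems = glue_stems(stems, stem_params, sequence)
    stems = select_candidates(stems, stem_params)
    stems.sort(key=lambda s: (s.energy, s.arm1.start))
    return stems


def pairing_string(pairing) -> str:
    """Compact pairing notation: '|' pair, ':' aligned non-pair, '1'/'2'
    bulged base in arm1/arm2."""
    out = []
    for a, b in pairing:
        if a is not None and b is not None:
            out.append("|" if (a, b) in CANONICAL_PAIRS else ":")
        elif a is not None:
            out.append("1")
        else:
            out.append("2")
    return "".join(out)
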
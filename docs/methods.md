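# Methods

## Overview

`editscreen` models a site-selectively edited substrate as an imperfect
intramolecular RNA stem whose sequence is conserved across vertebrates and
which accumulates A→G discrepancies between genome and transcriptome.  The
screen has an explorative stage (structure + conservation) and a
refinement stage (expression evidence + heuristic bit scoring), followed
by quantification of editing from amplicon reads.  This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Stem prediction

**Search.**  A gene sequence S is locally aligned against its own reverse
complement with the Gotoh affine-gap algorithm.  The substitution matrix
is written in reverse-complement indexing so that alignment identities are
helix pairs: A/A→A:U and T/T→U:A score 80, C/C→C:G and G/G→G:C score 120,
and the two wobble entries G/A→G·U and T/C→U·G score 20; all other
combinations score −100.  The matrix is used exactly as printed,
asymmetric, with no symmetrization.  Gaps cost 150 to open plus 100 per
nt.  An arm pair is reported when its gapped score reaches 500 and it
contains both an exact 6-mer seed and a gap-free segment scoring ≥ 500
(the seeding contract of a seed-and-extend aligner, enforced as a
post-condition on the optimal alignments).

DP cells whose arm1 position is fewer than 4 nt (the minimum hairpin
loop) upstream of the aligned arm2 position are masked.  This makes
self-overlapping alignments — a hairpin region aligned against itself
straight through the anti-diagonal — unrepresentable, and as a side
effect each physical duplex appears exactly once, because its
mirror-image alignment always falls in the masked triangle.  Alignment
regions are extracted best-first; the traced region is zeroed before the
next extraction so near-duplicate end cells are not re-traced.

**Decomposition into stems.**  At these deliberately permissive
thresholds an optimal gapped alignment frequently chains well-paired
helices across mismatch-rich stretches (random 2-kb sequences routinely
produce alignments scoring far above 500).  Alignments are therefore
decomposed before filtering: maximal runs of canonical pairs (helices)
are chained left to right for as long as the bulge budget holds — no
intervening unpaired run above MAX_BULGE_SIZE = 5 nt on either strand,
and at most MAX_BULGE_BASES = 7 unpaired nt in total — and a fresh stem
starts when the budget would be exceeded.  Aligned non-canonical columns
count as one unpaired nt on each strand.  This decomposition is what
makes the arm-length/bulge filters coherent with a gluing step defined on
"stems from disjoint structures".

**Filters.**  Stems are kept iff both arms are ≥ 16 nt, ΔG ≤ −15.0
kcal/mol, no single-strand bulge exceeds 5 nt and total unpaired ≤ 7 nt.
Adjacent stems whose corresponding arms are each within 10 nt are glued
(the gap bases enter the pairing as an internal loop), re-scored, and
dropped if the merged ΔG exceeds −15.0.  Candidates are limited to a
5,000-nt span from arm1 start to arm2 end (the span value is
configurable).  Surviving overlapping stems are all reported; ties order
by (energy, arm1 start).

**Energy model.**  ΔG of a duplex is the sum of Turner-style
nearest-neighbor stack free energies (kcal/mol at 37 °C) over consecutive
canonical pairs, plus additive bulge and internal-loop penalties
(bulge 1–6 nt: 3.8/2.8/3.2/3.6/4.0/4.4; internal loops from 1.5;
logarithmic extrapolation beyond tabulated sizes).  Stacks involving one
G·U pair are approximated at −1.3, two G·U at −0.5.  No helix-initiation
term is charged, so the empty duplex is 0 and energy is monotone
non-increasing in the length of a perfect duplex.  The model is a
self-contained approximation of a full secondary-structure folder,
adequate because every downstream use is a threshold or an ordering, and
a pluggable folding backend can replace it.

## Conservation score

Each focal-genome site s in a multiple alignment receives
`score(s) = parsimony_term(s) + tree_term(s)` over the 21-column window
centered on s (k = 10 columns each side; windows truncate at block
edges).  Sites aligned in fewer than 10 of the 17 species score 0.

**Parsimony term.**  Per column, the Fitch parsimony score is computed on
the species tree restricted to leaves with an unambiguous base (gaps and
N excluded; columns with < 2 informative leaves score 0).  The term is
−log₁₀ of the p-value of the windowed sum S under neutral HKY evolution
(default κ = 2.0, uniform base frequencies, rate matrix normalized to one
substitution/site/unit length).  The default null is **exact**: a dynamic
program over (Fitch state set, score) pairs yields the per-column
Fitch-score distribution under HKY on the full tree, and the window null
is its n-fold convolution (columns are independent under the null).  The
p-value uses the **mid-p convention**, P(S' < S) + P(S' = S)/2, the
standard correction that keeps p-values of a discrete statistic
approximately uniform under the null rather than conservative; the term
is capped at 300.  A seeded Monte-Carlo backend (p = (1+#{S′ ≤ S})/(R+1),
R = 1,000 replicates, floored at 1/(R+1)) is available; it is not the
default because its p-value floor caps the term at ~3, far below the
score scale on which the screen's thresholds (75/80/90) are defined.
The null is computed for the full species set; windows with missing
species reuse it (their observed Fitch sums are computed on the reduced
tree), a deliberate approximation at the scale where scores are near
zero anyway.

**Tree term.**  Deviations are measured against the column majority among
informative leaves (ties break toward the focal species' base, then
alphabetically).  With n total leaves, dᵢ deviations in column i, k
window columns, and m the leaf count of the smallest clade containing
every deviating leaf, the term is `w·(Σdᵢ/k)·log₂(n/m)`, and `w·log₂(n)`
for a deviation-free window; the calibration weight w defaults to 10.
The term is large when deviations concentrate in a small subtree (all in
one fish species: m = 1) and zero when they scatter across the whole tree
(m = n).  The published formula image for this term is not recoverable;
this reconstruction honors the stated variables and the stated
qualitative behavior, and w is configurable.

**Scale.**  On the default tree a fully conserved window scores ≈ 94.8
(parsimony ≈ 53.9 + tree ≈ 40.9) and a neutral window ≈ 0.3, matching
the published working range (just above zero to ~110) on which the
cutoff 75 and the 80/90 bits operate.

**Species tree.**  The package ships a 17-taxon vertebrate tree (mouse
focal; rodents, lagomorph, primates, laurasiatherians, atlantogenatans,
opossum, chicken, frog, three fish) with branch lengths in
substitutions/site of realistic magnitude for this clade (total ≈ 6.4).
Any user Newick can replace it.

**Areas and stem conservation.**  A conserved area at threshold c is a
maximal segment containing at least one site ≥ c and bounded on each side
by ≥ 50 consecutive sites < c (track edges also bound).  Stem
conservation is min over the two arms of the maximum site score within
the arm — a stem is only as conserved as its worse arm.

## A-G mismatch calling

ESTs are locally aligned to the genomic mRNA with a BLASTN-like scheme
(match +2, mismatch −3, gap open 5, extend 2, score floor 40; the 2007
BLASTN parameters are not recorded, so these are configurable defaults).
Alignments shorter than 100 nt or with ≥ 20 mismatches are discarded.  A
call is made at every position with genomic A and ≥ 1 EST G (never the
reverse direction); EST support per site is recorded so users can demand
more.  All logic runs in transcript orientation; minus-strand genes are
reverse-complemented at extraction, and SNP alleles are compared in that
orientation (a genomic T/C SNP masks a minus-strand A/G call).  Calls at
genomic-origin A/G SNPs are removed; EST-verified A/G SNPs annotate but
never remove.

## Site scoring

Candidates need stem conservation ≥ 75 (inclusive) before scoring; the
six bits are then: conservation ≥ 80; ≥ 90; the A-G mutation signature
(focal A shared with ≥ 1 near species while some distant clade has all
aligned members G — "permanent G"); A-G calls on both arms; a
non-synonymous A→G codon change (direct translation of the annotated
codon with A and with G, replacing a protein-alignment step by an
equivalent computation); and a downstream G.  Near defaults to the focal
species plus its sister leaves; distant defaults to the first two clades
branching off the root-to-focal path (frog+fish and chicken on the
default tree); both are configurable leaf sets.  The total is the bit
sum (0–6) and candidates with total ≥ 3 are reported, ranked by (total,
conservation) descending.  The information profile I(l) = 2 − H(l) with
H(l) = −Σₙ f(n,l)·log₂ f(n,l) (0·log 0 = 0) over sequences centered on
edited sites documents the neighborhood bias that motivates the
downstream-G bit.

## Enrichment statistics

Stems are binned by conservation (<50, 50–60, 60–70, 70–80, 80–90, ≥90;
half-open intervals).  With background fraction b (the mismatch fraction
of the lowest bin), the excess edited estimate of a bin is
`n_mismatch − b·n_stems`, floored at 0, rounded only in reports.  The
significance of a gap t = |f₂−f₁| between two bins uses the two-sample
Hoeffding bound `exp(−2t²/(1/n₁+1/n₂))`, capped at 1; a log₁₀ form is
provided for values far below floating-point underflow.  The two-sample
two-sided form is one choice among the bound's variants; it is the
package's default and the variant is selectable.

## Editing quantification

Editing frequency is `100·#G/(#A+#G)` — reads calling other bases are
excluded from the denominator, which reproduces published percentages
whose coverages equal #A+#G exactly.  The probability that the observed
G calls are all sequencing errors is Π 10^(−qᵢ/10) over the G-supporting
reads; a site is reported when this falls below 10⁻⁴.  FASTQ qualities
are Sanger-encoded (+33).

## Synthetic data

Generators are pure functions of (config, seed); one global seed fans out
to named independent PCG64 streams (`SeedSequence([seed, crc32(name)])`),
so adding a generator never perturbs existing outputs.  The module
emulates: i.i.d. background sequence (uniform composition by default,
configurable) with planted exact or mutated inverted repeats; HKY
evolution of alignment blocks along the species tree with rate-0
conserved masks, optional pinning of the focal row to the reference
sequence, and clade-restricted substitution injection; EST/read sets
carrying planted A→G edits at per-site frequencies with phred-implied
substitution errors; and SNP tables of either origin.

It deliberately does **not** emulate: indel sequencing errors or 454
homopolymer artifacts, alignment gaps within simulated blocks (rows are
gap-free, so block-level species coverage stands in for per-site
coverage variation), splicing (ESTs are full-length transcript copies),
repeat-derived stems, or genome-scale sequence composition.  Passing
tests therefore demonstrate the machinery's correctness and calibration
on clean planted signal, not performance on real genomes, where
alignment error and compositional structure add noise the screen's
published genome-scale counts reflect.

The end-to-end screen fixture plants one perfect 30-bp stem (loop 60 nt)
in a 400-nt gene: an editable A at a codon third position of arm1 (ATA →
ATG, Ile→Met) followed by a G, a second editable A on arm2, conservation
masks over both arms ±10 nt, a basal-clade (frog+fish) genomic G at the
arm1 edit column, ESTs edited at 50%, and an EST-verified SNP at the
arm2 site.  Problem sizes throughout the tests and the acceptance script
(400-nt genes, ≤ 2-kb genomes, 500–1,000 reads, 500 calibration windows)
are chosen so the full suite runs in seconds while leaving every
statistical check well-powered.

## Numerical and degenerate-input choices

- Coordinates 0-based half-open internally; reports 1-based where
  human-readable.
- Fitch with < 2 informative leaves returns 0; uninformative windows give
  parsimony term 0.
- Majority ties in the tree term break toward the focal base, then
  alphabetically; gap/N leaves never count as deviating.
- `segment_areas` treats track edges as bounding; two high sites with 49
  low sites between them share an area, with 50 they do not.
- Threshold comparisons at 75/80/90, arm length 16, bulge 5/7, glue 10,
  span 5,000 and energy −15.0 are all inclusive on the kept side and
  exact (no epsilon).
- The editing-frequency denominator excludes non-A/G reads; zero
  informative coverage is an error, not 0%.
- Empty duplexes and duplexes with < 2 canonical pairs have energy 0.

## Known limitations

- The nearest-neighbor energy model approximates a full folder; absolute
  ΔG values differ from RNAfold, orderings and thresholds are what the
  screen relies on.
- The exact parsimony null conditions on full species coverage; tracks
  with heavy gap structure lean on an approximation (see above).
- The tree term is a declared reconstruction; its weight w is a
  calibration constant, not a fitted parameter.
- The stem search runs full-matrix DP per gene: appropriate for genes up
  to a few kb, not for chromosome-scale input.
- BLASTN-era alignment parameters and the exact published Hoeffding
  variant are unrecorded upstream; both are exposed as configuration.
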
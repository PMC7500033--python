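# Methods

## Problem and scope

Human mitochondrial DNA (mtDNA) is a 16.6-kb circular genome present in
hundreds to thousands of copies per cell. Acquired deletions produce
shortened circular "deletant" species whose accumulation tracks aging and
mitochondrial disease. This package implements the full desk-side analysis
chain for such data: split-read deletion detection against a circular
reference, conversion of junction read counts into population frequencies
and ablation levels, sequence-context annotation (terminal microhomology),
pattern summaries (binned breakpoint matrices, clustering, PCA, length
spectra, terminus histograms), and Monte Carlo models of
replication-coupled deletion formation fitted to terminus-frequency data.
A synthetic-data generator provides ground-truth populations so that every
stage is testable without sequencing data.

## Coordinates and deletion identity

All coordinates are 1-based and inclusive. A deletion is identified by the
positions of the last missing bases in the light-strand 5' direction
(`ls5`) and heavy-strand 5' direction (`hs5`); the span length is
`hs5 - ls5 + 1` (circularly for spans crossing position 1). Under this
convention the human "common deletion" is (8471, 13447), 4977 bp. Junctions
inside direct repeats have several equivalent representations; all calls
are left-aligned (shifted to the smallest equivalent `ls5`, i.e. while
`base(ls5-1) == base(hs5)`) so each deletant sequence has exactly one key.

The default origin positions are oriL = 5780 and the 7S-DNA 3' terminus =
16,070 — the positions of the terminus ridges that anchor the deletion
"fountains" — and are configurable. The bundled reference FASTA is a
deterministic *synthetic* 16,571-bp genome (the licensed human build is not
redistributed): i.i.d. uniform bases with the 13-bp common-deletion direct
repeat planted at the (8471, 13447) junction and poly-C tracts at the
control-region positions 303 and 16,184. Sequence-dependent results quoted
in the README (e.g. TMH of the common deletion = 13 bp) hold on this
reference by construction, exactly as they do on the real one.

## Split-read detection

Reads are aligned to two tandem copies of the reference so alignments and
junctions crossing the coordinate origin need no special casing. The
aligner is a purpose-built exact-16-mer-seed / ungapped-extension scheme
(≤ 2 mismatches per anchor, anchors ≥ 20 bp): on a 16.6-kb genome nearly
all 16-mers are unique, and the contract that matters for deletion calling
is "two same-strand anchors with a positive reference gap", not general
read-mapping parity. Given the two anchor diagonals, the junction offset
within the read is placed by an optimal-split scan minimizing total
mismatches, with ties going to the leftmost placement; this is robust to
sequencing errors near the junction and to microhomology (naive maximal
extension deterministically shifts junctions across homology runs).
Reverse-complement reads are handled by re-aligning the reverse complement
and reporting on the forward axis.

Mate reconciliation is per pair: a junction reported by one mate is
dropped when the other mate aligns contiguously across the junction locus
(covering `min_anchor` bases on both sides of a deleted terminus — the
margin prevents contiguous alignments that merely extend into the deletion
through junction homology from suppressing true calls). Each surviving
supporting read increments the junction count `x_i` (mates count
separately, matching read-level depth accounting). Spans longer than
15 kbp are kept but flagged `possible_insertion`: on a circular reference
their split reads are indistinguishable from large insertions.

Quality filtering drops a pair when either mate's mean Phred score is
below 20 (pair-level is stricter than read-level and keeps mate logic
simple).

## Frequencies, ablation, geometry

With depth proportional to population fraction and at most one deletion
per molecule, the frequency of deletant *i* with junction count x_i,
mappability factor δ_i, molecule length L_i = L_u − span, mean read length
L_r, and r_t total mapped reads is

    f_i = L_u δ_i x_i / (L_r r_t − Σ_j L_j δ_j x_j + Σ_j L_u δ_j x_j)

with the upper bound f_i ≤ L_u δ_i x_i / (L_r r_t), asserted on every
table. δ_i is the control sample's median depth divided by its mean depth
at the two junction positions (1 when no control is supplied; capped at 10
and flagged when the control has zero depth there, so single reads cannot
dominate ablation).

Raw split-read counts systematically undercount junction-crossing reads:
only read placements leaving ≥ `min_anchor` bases on each side of the
junction are callable, a window widened by the junction's microhomology
(the split may sit anywhere inside the homology run). Counts are therefore
rescaled by `L_r / (L_r − 2·min_anchor + 1 + TMH)` before being treated as
junction depth. Without this correction recovered frequencies are biased
low by ~26% at the default geometry; with it the end-to-end recovery slope
is 1.00 within sampling error.

Background subtraction is per exact left-aligned junction against the mean
control frequency, floored at zero. Ablation at biopsy is
`Σ_i f_i (L_u − L_i)/L_u`, identical (to 1e-9; exactly, in floating point)
to the area above the per-position remaining-fraction curve. Ablation at
symptom onset is the linear projection `a_biopsy · y_onset / y_biopsy`.
Feature ablation sums `f_i` over deletions touching a named feature set;
multiplicative combination treats sets as independent failure modes,
`1 − Π_s (1 − a_s)`.

The multi-fiber boundary chain idealizes a biopsy of mass m and density ρ
as a cube: volume m/ρ, face area (m/ρ)^(2/3), truncated fibers = face
area / mean fiber cross-section (3630 μm²), and the reciprocal fiber count
is the frequency above which a deletion species must span multiple muscle
fibers (≈ 5.1 × 10⁻⁴ for a 20-mg sample).

## Terminal microhomology

TMH is the total length of identical sequence shared between one deletion
terminus and the flank of the other — the direct repeat at the junction —
computed as the sum of exact leftward and rightward extensions with
circular indexing. The sum is invariant under the choice of junction
representation (each homology base is exactly one extra equivalent
representation), so annotating left-aligned calls is lossless. Extensions
are capped at 100 bp (an order of magnitude beyond biological TMH). A
deletion whose TMH reaches its span length removes one unit of a perfect
local repeat (`in_repeat_tract`). Only perfect identity counts; imperfect
homology is deliberately not scored.

## Pattern summaries

Breakpoints are binned into an 80 × 80 matrix (equal 207-bp bins, last bin
absorbing the remainder) after dropping spans < 40 bp and spans inside the
T-shaped artifact region (ls5 ∈ [1, 5700] with hs5 ∈ [15949, 16156], or
ls5 ∈ [3107, 3314] with hs5 ∈ [12000, 16156]); surviving mass is
normalized to 1 and the excluded fraction reported. Junctions may be
weighted by read support (default), equally, or by frequency. Samples are
compared by Euclidean distance with complete-linkage clustering
(scipy) and mean-centered, unscaled PCA (scikit-learn) — inputs are
already normalized fractions on a common scale, so feature scaling would
only amplify empty-bin noise. Sample order is canonicalized by sorted ids
so both analyses are order-independent.

Terminus histograms sum frequencies of LS5' and HS5' termini separately in
250-bp bins, excluding junctions with TMH ≥ 10 (the slippage class would
otherwise punctuate and mask the origin-anchored gradient). On a log scale
these show the "double bowtie" around the two origins.

## Monte Carlo replication/deletion models

Six generation schemata draw a start from one distribution and an end (or
length) from another; shared filters remove candidates shorter than 1 bp or
longer than the reference, anchored models remove candidates impinging on
their own origin, and a selection coefficient `sel ∈ [0, 1]` retains
candidates covering a selected-against origin with probability `sel`.
Clockwise and counterclockwise streams share parameters, so no model
exceeds five adjustable parameters (scale, sel, mu, sigma, shape). The
distribution table is in `repsim`'s module docstring; model 6 — two
unidirectional streams anchored at the 7S-3' terminus and oriL, exponential
start offsets, normal lengths, cross-origin selection — is the
strand-displacement analog that produces the double bowtie.

Fitting minimizes the log-domain least-squares difference between
simulated and observed terminus densities. The pseudo-count is half the
smallest nonzero observed bin; the linear scale is profiled out by total
mass matching; every objective evaluation simulates with the same seed
(common random numbers), making the surface deterministic. Because the
surface has a curved sel–shape ridge, the search is multi-resolution: a
dense seeded scan plus Nelder-Mead at one-fifth the simulation size, then
refinement and fresh-simplex restarts at full size. Self-recovery on
model-6 data at n = 240,000 per direction recovers mu and sigma within a
few percent and sel within 0.1 (sel is the weakest-identified parameter:
it only acts on the minority of candidates crossing the opposite origin).
Model ranking uses n = 24,000 per evaluation, which is sufficient to
separate model 6 from the five alternatives by log-domain R².

## Synthetic data generator

The generator embodies the sampling assumptions behind the frequency math:
molecules (wild type, deletants at specified fractions, optional linear
spike-ins with known junctions), fragments drawn with probability ∝
abundance × molecule length, fragment starts uniform on each circular
molecule, fragment lengths ~ Normal(400, 60) truncated at the read length,
150-bp paired reads from fragment ends, substitution errors at 10⁻³ per
base, constant Q40 qualities. Every junction-crossing read is recorded in
a truth table. The default "strict" profile keeps ±5 bp around a junction
error-free inside junction-spanning reads so pipeline logic is tested in
isolation from error modeling; the "realistic" profile applies errors
everywhere. Not emulated: tagmentation/GC bias, chimeric artifacts,
nuclear mtDNA segments (NUMTs), multi-deletion molecules — so passing
tests demonstrate correctness of the computational chain under the model's
own assumptions, not robustness to every artifact of real libraries.

## Validation problem sizes

The end-to-end frequency-recovery study uses ten deletant species at
log-spaced frequencies 10⁻⁴–10⁻¹ and 20,000× read depth (~1.1 M read
pairs, ~75 s). The depth was fixed by a power analysis: the recovery-slope
check (1 ± 0.05) requires the binomial counting noise of the top junction
counts to be well below the band, which 2,000× does not provide (empirical
slope SD ≈ 0.066 across seeds) while 20,000× does (SD ≈ 0.003). Model-6
self-recovery fits at the full 240,000 deletions per direction; the
six-model ranking fits at 24,000. The three-group pattern-separation study
uses 4,000 accepted deletions per direction per sample.

## Known limitations

- One deletion per molecule is assumed throughout; catalogs from samples
  with frequent compound deletions will misattribute mass.
- Junctions inside perfect repeats longer than the read length are not
  callable by any split-read method; they surface only via the
  repeat-tract flag on shorter representatives.
- The aligner is desk-scale: linear scan per read, no index persistence,
  no BAM output; it is not intended for whole-genome references.
- δ mappability factors require a control depth profile; without one,
  cross-locus mappability differences are uncorrected (δ = 1).
- Deletion classes 1/2/3 are heuristic TMH cuts exposed for convenience;
  the underlying biology defines them qualitatively, not sharply.
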
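# Methods

## Scope and model

`csos2kit` annotates the tripartite repeat architecture of CsoS2-like
carboxysome scaffold proteins and analyses peptide tiling-array binding
data against them. The underlying sequence model: an N-terminal region of
16-residue repeats opening with a basic residue (R/K) followed by an acidic
one (E/D); a middle region of repeat units of ~50 residues (40 for the
short form) that each contain three 3-residue units whose starts are 11
residues apart (3-residue unit + 8-residue gap) and a cysteine signature in
the terminal part of the unit (tandem CC = T, single C = S, none = N); and
a C-terminal region of roughly 170 residues. Detection is rule/score
based — no profile HMMs or de-novo motif discovery.

## Physicochemical computations

* **Molecular weight** sums average (isotope-abundance weighted) residue
  masses plus one water (18.0153 Da), reported in kDa. Average rather than
  monoisotopic masses are used because the values of interest are whole
  protein masses at SDS-PAGE/MALDI scale.
* **Isoelectric point** solves net charge = 0 by bisection on pH ∈ [0, 14]
  to a residual-charge tolerance of 1e-4. Charge contributions: free
  termini (N-terminal pK residue-dependent) plus D, E, C, Y, H, K, R side
  chains with the Bjellqvist pK set used by the Expasy Compute pI/Mw tool;
  the table is spelled out in `physchem.py`. The charge curve is monotone
  in pH, so bisection is deterministic. Note that near the pI the curve can
  be nearly flat (e.g., sequences with few ionisable groups), so a small
  charge tolerance corresponds to a wider pH band; tests therefore compare
  charges, not just pH values.
* **Tryptic digest** cleaves after K or R except before P, with no missed
  cleavages by default (a `max_missed` option enumerates joined adjacent
  fragments). Coverage is the merged-union of peptide spans over the
  parent length, in percent; overlaps count once.
* **Pairwise alignment** is affine-gap global Needleman–Wunsch
  (Biopython's `PairwiseAligner`) with BLOSUM62, gap open 10, gap extend
  0.5; a gap of length L costs open + (L−1)·extend and end gaps are
  penalised like internal ones. Identity and similarity percentages follow
  the EMBOSS convention: denominators include gap columns; a column is
  similar when its substitution score is positive. An exhaustive
  enumeration oracle over all gapped alignments verifies scores on short
  sequences.
* **ΔOD600** and **mean residue ellipticity** are direct evaluations of
  their defining formulas, with zero-volume / zero-path / zero-concentration
  inputs rejected.

## Repeat detection

**M-repeats.** Positions whose 3-mer recurs at +11 and +22 (BLOSUM62 score
of each pair ≥ `min_triad_score`, default 12) anchor a repeat unit. Under a
uniform residue model the probability that a random 3-mer pair scores ≥ 12
is ~2.8e-3, so a chance double recurrence is ~8e-6 per position — well
below one expected false anchor per protein-sized sequence. Competing
anchors closer than 30 residues are resolved toward the higher score
(leftmost on ties). Units extend from anchor − `triad_offset` (default 5)
to 50 residues, or 40 (typed `M_short`) when the next anchor arrives in
fewer than 46 residues; units are truncated rather than allowed to overlap.
The cysteine signature is read from the last 15 residues of each unit:
adjacent CC → T, else any C → S, else N (two non-tandem cysteines therefore
classify as S). An `exact` triad mode is available for noise-free data.

**N-repeats.** Candidate windows are 16-mers starting with R/K and E/D at
position 2. A lone anchored window is not a repeat: acceptance requires at
least two non-overlapping candidates whose pairwise BLOSUM62 score reaches
`n_min_pair_score` (default 40, more than six standard deviations above
the null 16-mer pair score: mean ≈ −17, sd ≈ 8.8). The acidic-second-residue
rule is soft — up to one window per protein lacking it is rescued when it is
similar to an accepted strict window. Overlaps resolve toward the higher
score, leftmost on ties.

**Segmentation.** The N/M boundary is the midpoint between the last
N-repeat end and the first M-repeat start (the transition is gradual in
real proteins, so a midpoint is as defensible as any rule and is exactly
identifiable on synthetic data); the M/C boundary is the last M-repeat end.
Missing either repeat class raises a segmentation error rather than
guessing. The C-region is called intact when it is at least 100 residues.

## Peptide-array analysis

A spot is detectable iff (signal − background mean) > 3·background SD and
spot SD / signal < 0.5, both strict; non-positive signals fail the second
condition outright. The "SD" of the second rule is the per-spot pixel-level
SD from the scanner by default (`sd_mode="spot"`, replicate-level SD
substituted where the value is missing); `sd_mode="replicate"` uses the
replicate-level SD throughout. A peptide is positive iff strictly more
than half of its replicate spots are detectable. The averaged intensity is
the background-subtracted mean over *all* replicates (the alternative,
averaging detectable spots only, is available as `mean_mode="detectable"`).

Hotspots are marked among positives: the ten highest averaged intensities
(ties toward the lower peptide id), plus local maxima inside maximal runs
of step-adjacent positives of length ≥ 6 ("more than five sequential"),
where a local maximum is strictly greater than its run neighbours, run
endpoints compare against their single neighbour, and plateaus are marked
at their leftmost element. A peptide earning both reasons is reported once
as top10. Saturation is the averaged intensity as a percent of the
maximum among positives; the argmax peptide is exactly 100%. Background
statistics are taken from the spot-table header; they are part of the
input, not estimated.

## Synthetic data

The sequence generator plants the geometry above with defaults matching
the family's typical dimensions: region lengths 250/350/170, four
N-repeats, M-signature TTNTTT with the third unit in the 40-residue short
form. Background residues are uniform over the 20 standard amino acids,
except that cysteine is excluded from random draws inside the terminal
signature windows (and from the triad consensus) so the planted signature
remains the ground truth. The last N-repeat and first M-unit are placed
symmetrically around the true N/M boundary, which makes the midpoint
segmentation rule identifiable; substitution noise (a per-residue rate,
default 0) applies inside repeats but never at anchor positions — the
basic/acidic N-repeat opening, the triads and the planted cysteines — so a
"10% noise" sequence stresses the similarity scoring, not the anchors the
rules are defined on.

The array generator draws spot signal = background mean + amplitude·w + ε
with Gaussian ε; w is the peptide's overlap fraction with the hotspot
interval (flat profile) or a linear ramp in the distance of the peptide
centre from the hotspot centre (triangular). Defaults: background mean
100, background SD 10, spot noise SD 10 (equal to the background SD, so
the per-spot null detect rate is the textbook P(Z > 3) ≈ 1.35e-3), four
replicates, hotspot width 23 residues (the width of the prominent
C-region interaction site in this protein family), per-spot SD log-normal
around a CV of 0.1. Negative signal draws are kept — background
subtraction can legitimately go negative and such spots simply fail the 3σ
rule. What the generator does **not** emulate: chip spatial artifacts,
scanner gain, heavy-tailed backgrounds (a log-normal option exists for the
spot SDs only), antibody cross-reactivity, or between-chip normalisation —
so passing tests demonstrate correctness of the calling rules under the
stated noise model, not robustness to real-chip systematics.

## Problem sizes and numerical choices

Simulation-backed checks use 50 seeded replicates for recovery rates
(planted hotspot recovery, repeat recovery under 10% noise), 10,000
peptides × 4 replicates for the null false-positive control, and 100
random pairs of length ≤ 8 for the alignment enumeration oracle — sizes at
which the binomial/closed-form comparisons are already tight. All
randomness flows through explicit integer seeds (NumPy `default_rng`;
independent substreams via `SeedSequence.spawn`). Ties are broken
deterministically everywhere (score, then leftmost coordinate).

## Known limitations

* Repeat counts on real, divergent orthologs may differ from manual
  annotations; thresholds were chosen from null score distributions, not
  fitted to any reference annotation.
* Region boundaries are convention (midpoint rule); real transitions are
  gradual and per-region pI values are sensitive to the exact boundary.
* The tryptic-coverage computation reports coverage given a set of matched
  peptides; it does not model mass-spectral detectability.
* Identity/similarity values depend on the gap-penalty convention; other
  tools that leave end gaps free will differ on length-mismatched pairs.
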
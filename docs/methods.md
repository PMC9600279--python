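# Methods

## Scoring model

The motif model is a per-column product model (positions statistically
independent). Counts from the aligned training sites are regularised with
an additive pseudocount β, shared equally by the four bases:
p(i, b) = (n(i, b) + β) / (N + 4β). β defaults to 0.5; an option allocates
the pseudocount proportionally to the background instead
(p = (n + 4βq(b)) / (N + 4β)), which matters only for strongly skewed
backgrounds. Scores are log2 odds (bits) against the background; the
default background is uniform (q = 0.25), with a genome-composition
background available as a configuration option. The published per-box
scores this pipeline is built around (e.g. the 17.68-bit high-confidence
flag) are printed without units; bits with a uniform background is the
convention adopted here and is the default of the common motif tooling.
Whether those printed values assumed a uniform or genomic background, or a
per-letter pseudocount, cannot be determined from the source text alone;
`cpxscreen.calibration.convention_sweep` exists to settle that empirically
when the original inputs (curated site set, chromosome sequence) are
supplied by the user.

The 16-bp training set is derived from the 15-bp one by duplicating the
middle spacer base (0-based index 7), compensating for the scarcity of
curated sites with a 6-bp spacer. The two matrices are used, calibrated,
and reported independently; overlapping 15/16-bp hits at one locus are
both kept by the scanner and collapsed only by the downstream
distinct-box logic.

### Numerical choices

Window scores are *exactly rounded* sums (`math.fsum`) of the per-position
cells. This makes scores independent of summation order, so the streaming
scanner, the per-window scorer, and reverse-complement scoring agree
bit-for-bit — the scanner-vs-oracle and strand-symmetry tests assert exact
equality, not tolerances. Matrix TSVs store full `repr` precision and
round-trip losslessly. Elsewhere, probability identities are checked at
1e-9 absolute and human-readable output is printed at 6 significant
digits. Consensus ties break by the fixed base order A < C < G < T.

## Genome scan and threshold

Every window of matrix length is scored on the requested strands (both by
default); minus-strand windows are scored on their reverse complement and
reported at the forward coordinate. Windows containing any non-ACGT base
are skipped and counted, never imputed. Circular contigs optionally wrap
across the origin. The adaptive cutoff is τ = μ − σ over the pooled score
population of all scoreable windows, with σ the population SD (divisor n:
the windows are fully enumerated, not sampled), and hits are strictly
above τ.

Because genome-wide window scores are approximately normal, μ − σ retains
on the order of 80 % of all windows — the adaptive rule is a *recall*
device (planted consensus sites always clear it), not a precision device.
For precision-sensitive uses the pipeline supports a fixed cutoff
(`threshold_mode: fixed`), and the threshold population can be restricted
to promoter windows (`threshold_population: promoter`) as a sensitivity
analysis. The end-to-end examples in the tests and README use a fixed
15-bit cutoff for exactly this reason.

## Promoter windows and location groups

Windows span 700 bp upstream through 100 bp downstream of the start
codon, where the start-codon base is the first downstream base; for a
plus-strand gene with start codon at s (0-based) the window is
[s−700, s+100), and for a minus-strand gene the exact mirror image
[s−99, s+701) — width 800 in both cases, clipped at contig ends and
flagged. Assignment requires full containment of the hit interval in the
window; sites are only 15–16 bp, so partial-overlap boundary cases are
excluded to keep counts unambiguous.

"Gene cluster" is operationalised as a maximal run of same-strand
neighbours with intergenic gaps ≤ 50 bp (configurable) — a deliberately
simple operon surrogate; no expression data or TSS evidence is used.
"Distinct boxes" are non-overlapping hit loci; overlapping hits collapse
to the highest-scoring one (ties to the earlier, shorter hit).

Groups are assigned in priority order A > B > C > D, since the multi-box
layouts subsume the single-box descriptions. The group-C divergence test
requires an opposite-strand partner whose window overlaps, with the box
inside the intergenic span between the two gene bodies and inside both
windows; both partners are reported, cross-referenced. A one-exemplar-
per-class synthetic bundle therefore yields *five* candidate genes
(1 A, 1 B, 2 C, 1 D) — an inherent property of the C definition.

## Regulation calls

ΔΔCt with arithmetic means of replicate Ct values before the contrast;
fold = 2^(−ΔΔCt). Per-replicate fold distributions are available
(`per_replicate_folds`) but calls use the mean-Ct fold; at the precision
of the bundled tables the two readings agree. The two-fold rule is
inclusive on both bounds (fold ≥ 2 positive, ≤ 0.5 negative) because
"< 2-fold" defines insignificance; a gene counts for an activation group
when *either* of the group's two condition columns is significant — the
unique reading that reproduces the published 42/64/73 counts from the
transcribed table, which the acceptance script recomputes. When the two
columns of a group disagree in direction, the group verdict follows the
column with the larger |log2 fold|; this choice never affects the counts,
only the sign reported for a handful of genes. No significance testing or
amplification-efficiency correction is applied — calls are
threshold-only, mirroring how the fold-change tables are annotated.

## Synthetic data: what it does and does not emulate

`sample_sites` keeps each flank base with identity probability π and
otherwise substitutes uniformly among the other three bases (the simplest
symmetric variability model); spacer bases are i.i.d. uniform. Because an
aligned collection must share one length, the spacer distribution must be
degenerate — the 16-bp set is meant to be derived by spacer expansion,
exactly as in the real screen. `plant_genome` writes consensus-class
sites into an i.i.d.-background genome (uniform by default; an
*E. coli*-like GC ≈ 0.508 preset is provided) inside promoter windows of
non-overlapping gene units laid out per the requested classes.
`simulate_ct` puts the effect on the cycle scale (Ct = baseline − log2
effect + N(0, σ)), with a constant-in-expectation reference gene.

Passing tests on these inputs demonstrate correctness of the *machinery*
(scoring, thresholding, coordinate arithmetic, classification, calling) —
not performance on real genomes, which have repeats, compositional skew,
operonic correlation, and binding sites that do not follow an independent
per-column model. The generators' defaults mirror the screen's study
conditions: 41 training sites, 15-bp sites around GTAAA-N5-GTAAA, 700/100
windows, 50-kb test genomes (large enough for stable μ, σ while keeping
the suite fast; problem sizes are stated in the tests).

## Known limitations

* No p-value calibration of scores (no dynamic-programming score
  distribution); the mean − σ rule and fixed cutoffs are the only
  threshold semantics.
* No de-novo motif discovery, mixture, or dinucleotide models.
* Operon inference is the adjacency heuristic only.
* Reproducing the original genome-scale hit counts requires the original
  inputs (curated site table and the BW25113 chromosome) plus the
  convention sweep; the package ships neither genome nor curated sites.
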
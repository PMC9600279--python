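# cpxscreen

Genome-wide prediction of genes regulated by the CpxRA two-component
system in *Escherichia coli* — and, more generally, a regulon-prediction
pipeline for any bacterial transcription factor with a curated set of
aligned binding sites.

CpxR, the response regulator of the envelope-stress CpxRA system, binds a
bipartite DNA motif, `GTAAA-N5/6-GTAAA`: two pentamers separated by a 5- or
6-bp spacer. `cpxscreen` turns a collection of known CpxR boxes into a
position-specific scoring matrix (PSSM), scans a genome with it, maps the
resulting putative boxes into promoter windows, classifies candidate genes
by box layout, and calls regulation from qRT-PCR fold-change tables.

## The method

**Scoring model.** From *N* aligned sites of length *L* (15 bp, plus a
16-bp set derived by duplicating the middle spacer base), base counts
*n(i, b)* per column are regularised with a pseudocount β = 0.5 and
converted to log-odds scores in bits against a background *q(b)*
(uniform by default):

    p(i, b) = (n(i, b) + β) / (N + 4β)
    s(i, b) = log2( p(i, b) / q(b) )

A window `w` scores `S(w) = Σᵢ s(i, wᵢ)`; sums are exactly rounded, so
scores are independent of summation order and strand-symmetric to the bit.

**Adaptive threshold.** Every L-bp window of the genome (both strands by
default; windows containing ambiguous bases are skipped) contributes to a
score population with mean μ and population standard deviation σ; windows
scoring strictly above τ = μ − σ are reported as putative boxes. The 15-bp
and 16-bp screens are calibrated independently. A fixed cutoff can be
configured instead.

**Promoter mapping and location groups.** Each gene's promoter window runs
700 bp upstream through 100 bp downstream of its start codon, oriented by
strand. A box belongs to a gene when fully contained in its window; a box
between divergently transcribed genes may belong to both. Candidate genes
are classified A–D (priority A > B > C > D): **A** — ≥ 2 distinct boxes over
a same-strand gene cluster (intergenic gaps ≤ 50 bp); **B** — ≥ 2 distinct
boxes in one gene's window; **C** — one box shared by a divergent pair
through their intergenic region; **D** — one box, one gene.

**Regulation calls.** Relative expression is quantified with the ΔΔCt
method against the constitutive reference gene *rpoD*
(fold = 2^(−ΔΔCt)). A gene is called regulated in an activation group
(cpxA24/ΔcpxA alleles, or NlpE overexpression with and without *cpxR*)
when either condition column shows a ≥ 2-fold change in either direction
(fold ≥ 2 or ≤ 0.5, bounds inclusive). The package bundles the published
fold-change tables of the screen as plain-TSV fixtures.

A seeded synthetic-data module (`cpxscreen.simulate`) generates noisy
binding sites, genomes with boxes planted per the four layout classes plus
matching GFF3 annotations and a truth BED, and Ct tables with known
effects — so the whole pipeline is testable without downloads.

## Worked example

Simulate a bundle with one exemplar of each layout class, build the
matrix, scan, and classify:

```sh
cpxscreen simulate --outdir sim --seed 5
cpxscreen build-matrix sim/training_sites.txt --out pssm15.tsv
# -> wrote pssm15.tsv (15 bp, 41 sites)
cpxscreen scan pssm15.tsv sim/synthetic.fasta --out-prefix hits --threshold 15
# -> 6 hits above 15 bits (99972 windows, 0 skipped)
cpxscreen classify hits.tsv sim/synthetic.gff3 sim/synthetic.fasta --out-prefix cand
# -> 5 candidates {'A': 1, 'B': 1, 'C': 2, 'D': 1}
```

The six planted boxes are recovered as the only hits above 15 bits, and
the five candidate genes get exactly their planted groups — the shared
intergenic box makes *both* divergent genes group-C candidates, with
cross-references in the `shared_with` column:

```
gene   group  n_boxes  best_box_start1  best_box_score  best_box_sequence  shared_with
g001   A      2        571              18.7336         GTAAAGGATAGTAAA
g003   B      2        2691             19.4428         GTAAACGTACGTAAA
g004   C      1        5042             19.6369         GTAAAACCGCGTAAA    g005
```

Calling regulation on the bundled fold-change table of the screen:

```sh
cpxscreen call src/cpxscreen/data/screen_fold_changes.tsv --out calls.tsv
# -> regulated per group: {'cpxA_alleles': 42, 'nlpE_overexpression': 64}; union: 73
```

42 genes respond in the cpxA-allele panel, 64 under NlpE overexpression,
and all 73 genes of the table respond in at least one panel.

`cpxscreen run --config config.yaml` executes the whole screen end to end
and writes BED/TSV tracks, a high-score review list (> 17.68 bits by
default), and a JSON run summary.

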
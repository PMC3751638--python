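# Methods

## Design and coordinate conventions

All genomic intervals are 0-based half-open internally (the BED
convention); GFF3 (1-based closed) is converted only at the I/O boundary.
A gene is reduced to span, strand and TSS — the 5′ end of the span — and
a TSS-centred promoter window of configurable half-width (default
2000 bp, i.e. TSS ± 2 kb). Because the promoter is TSS-centred, "assign
to the nearest promoter" and "assign to the nearest TSS" select the same
gene; the implementation uses the TSS form. Equidistant ties break
toward the smaller TSS coordinate, then the lexicographically smaller
gene id, so assignment is fully deterministic and testable against a
brute-force argmin.

## Synthetic data generator

The generator exists to make every downstream stage testable with known
ground truth; it emulates the structure of a chronic-pretreatment ×
acute-challenge striatal study, not the full complexity of real data.

**Annotation.** `n_genes` TSSs are packed onto equal-length chromosomes
with a guaranteed minimum pairwise spacing (slack construction: sorted
uniform draws over the free length plus fixed offsets), random strands,
and gene lengths uniform in 1–10 kb. Default: 1000 genes on 4 × 2.5 Mb
chromosomes with ≥ 8 kb spacing, so promoter windows never overlap and
planted tags are attributable to a unique gene.

**Expression.** Log2 intensities are Normal per replicate around a
per-gene baseline (mean 8, SD 0.6 across genes), exponentiated so values
are strictly positive and fold-change semantics are exact. Planted
effects: a fraction of genes receive a log2 shift of
±log2(`effect_fold`) in SM (acute drug in naive animals) relative to
SS, and ±`blunting_factor` × log2(`effect_fold`) in MM relative to MS —
the blunted acute response after chronic pretreatment. Defaults plant
6% up / 2.6% down in the acute contrast and 1.8% up / 5.3% down in the
pretreated contrast (at 1000 genes: 60/26 and 18/53), with
`effect_fold` 4, `blunting_factor` 0.5, replicate noise SD 0.25 log2
units, and n = 5 replicates per group (the per-group sample size is a
stand-in; the design the package targets does not fix one).

The baseline spread of 0.6 log2 units deserves a note: the IP simulator
picks genes with probability ∝ exp(slope × log2 expression), so the
expected promoter tag count is exponential in the expression Z score
with curvature slope × SD(log2 expression). The binned readout regresses
tag counts on Z *linearly*; for the planted log-linear coupling to be
recoverable by that readout (slope > 0, R² > 0.8 at coupling slope 1),
the curvature must stay in the near-linear regime, which bounds the
baseline spread at about 0.7. The generator is therefore a planted-signal
testbed with a compressed dynamic range, not a transcriptome emulator —
real log-intensity spreads are 2–4× wider, and on real data the
regression of tag counts on Z is visibly convex.

**Tag libraries.** Each library is exactly `library_size` single
positions (modelling the mapped positions of short sequenced ends;
fragment length defaults to 450 bp, inside the 300–600 bp sonication
range). Input libraries are uniform over the genome. IP libraries mix a
`background_fraction` (default 0.2) of uniform tags with TSS-anchored
tags at Normal(0, `enrichment_sd` = 300 bp) strand-signed offsets. Tag
positions model fragment midpoints, so the quantifier applies no shift;
a 5′-end mode with a ±fragment_length/2 shift is available for realism.
Positions are clipped to chromosome bounds. One seeded numpy Generator
per operation; no global RNG state.

What the generator does **not** emulate: duplicate reads, mappability
and GC bias, copy-number structure, peak-shape asymmetry, probe-level
microarray noise, and correlated replicates. Passing tests show the
pipeline's algebra and statistics are correct on clean planted signal;
they do not certify performance on real libraries.

## Quantification

Normalization is tags-per-million: factor 10⁶/N. The metagene profile
histograms strand-signed distances (upstream negative) of each tag to
its nearest TSS within a flank (default ±2 kb at 100 bp bins), per
million library tags.

The enrichment caller slides windows (default 500 bp at 250 bp steps)
over each chromosome, with the chromosome extent inferred as the maximum
tag position (over IP and input) plus one window. The expected IP count
in a window is the input count scaled by the library-size ratio, floored
at a pseudocount of 0.5; a window is significant when the exact Poisson
upper tail P(X ≥ ip | expected) is below alpha (default 10⁻⁵) **and**
ip/expected ≥ min_fold (default 2). Overlapping or book-ended significant
windows merge into one site keeping the minimum p and recomputed counts.
No multiple-testing correction is applied by default (alpha is
per-window); a Benjamini–Hochberg option exists. This caller is a
deliberately generic stand-in — the analysis it supports only needs a
reasonable site set, and all knobs are exposed.

A known limitation of the plug-in expectation: when the input library is
shallow, the input-derived λ is noisy and the realized per-window false
positive rate exceeds the nominal alpha (we measure ≈ 3× at equal
IP/input depth, alpha 0.01). Calibration tests therefore use an input
10× deeper than the IP, the regime the model assumes; with a shallow
input, alpha should be tightened or the BH option used.

## Expression and integration

Global normalization scales every sample to the grand median.
Differential expression is mean(B)/mean(A) on the linear scale converted
to the signed convention (ratio if ≥ 1 else −1/ratio), with Welch's
unequal-variance t-test on log2 intensities; a gene is called when
|signed FC| ≥ fc_cut (≥, default 1.7) and p < p_cut (strict, default
0.01). Welch's t is a documented stand-in for the unstated test of the
original array software and is swappable. Degenerate zero-variance,
equal-mean genes get p = 1.

Z scores standardise log2 condition-mean expression across genes
(ddof = 1; all-equal input → all zeros). Binning sorts genes ascending
by Z with gene-id tie-breaks, forms consecutive runs of 100, and flags a
trailing remainder bin as partial; partial bins are excluded from the
OLS by default (how the original probe count divided by 100 was handled
is unstated, so the remainder rule is ours). A constant response defines
R² = 0 and slope 0. When a small run yields fewer than three full bins
the pipeline falls back to including the partial bin.

Binding fold change per gene is the input-corrected enrichment ratio
with pseudocount 0.5. Concordance classification labels each called DE
gene: **absent** if not detected on the ChIP platform, **NC** if
|binding fold| < `nc_threshold`, else increased/decreased by sign. The
default `nc_threshold` 1.4 was chosen because the smallest printed
changed magnitude in the packaged tables is 1.49 — it is a package
default, not the (unstated) criterion of the original analysis. In the
packaged fixtures the printed codes are mapped to classifier inputs
('*' → not detected; 'NC' → signed fold +1, below any valid threshold;
numbers → signed fold), so the printed statuses are reproduced through
the generic classification path. Duplicate probe rows for the same
symbol are kept as distinct records.

## Problem sizes

Default end-to-end runs use 1000 genes and 10⁵ tags per library — small
enough to execute in seconds while leaving ≥ 10 full bins for the
regression and stable Venn partitions. The zero-coupling control in the
test suite uses 50 replicates at 2 × 10⁴ tags; null-calibration checks
use 5000 genes. These sizes are the package's choices for a fast,
reproducible demonstration; all of them scale up by config.

## Numerical and degenerate-input conventions

- Signed folds are undefined in (−1, 1); conversion enforces |f| ≥ 1.
- Empty tag libraries cannot be normalized (explicit error); empty
  annotations cannot be assigned against (explicit error).
- BED parsing reports the first offending line number.
- Per-window Poisson p-values of exactly 0 (underflow) print as score
  1000 in BED output (−log10 p clipped).
- The pipeline report excludes the output path from its config hash, so
  the same scientific parameters hash identically wherever written.
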
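# Methods

## Coordinate model and interval algebra

All genomic positions are 0-based, half-open (BED convention); GTF gene
input (1-based closed) is converted at the reader boundary. An
`IntervalSet` is a per-chromosome sorted list of disjoint segments on a
declared `GenomeLayout`; book-ended segments are always fused (a
configurable merge gap exists, default 0 bp, since no gap rule is imposed
on the input LAD calls). Union, intersection, subtraction, complement and
overlap are base-exact; intersection is computed by a two-pointer sweep and
subtraction as intersection with the complement, so all operations reduce
to two audited primitives. Strand is ignored in interval algebra and
carried only on gene/enhancer records. The test suite checks every
operation against a per-base boolean-array oracle on randomized toy
genomes, and against `bedtools intersect` as an independent implementation.

No minimum-size filter is applied to input LAD calls; callers can filter
upstream if their domain caller requires it.

## LAD maps and replicate QC

The final LAD map at a time point is the **union** of the replicate LAD
calls; constitutive LADs (cLADs) are the base-exact intersection of the
maps over all time points; i-LADs are the complement of a time point's
map. Replicate concordance is the Pearson correlation of two lamin B1
log2(ChIP/input) tracks re-binned to 100-kb bins by coverage-weighted mean,
dropping bins where either track lacks data. The within-LAD variant
restricts to bins intersecting the merged LADs by ≥ 1 bp; per-LAD read
counting from alignments is out of scope, so this binned-track restriction
stands in for a read-count-in-LADs correlation (a deliberate, documented
substitution — raw reads never enter the package).

## Change categories and fate classes

Between maps A (earlier) and B (later): common = A∩B; gained bases = B∖A;
lost bases = A∖B. A gained base belongs to a **stand-alone gained LAD**
iff the contiguous LAD of B containing it overlaps A by 0 bp; any ≥ 1 bp
touch makes it a **gained edge** (configurable `min_overlap_bp` threshold,
default 0, for sensitivity analysis). Losses are symmetric, and a B-LAD
bridging two A-LADs contributes its interior to gained edges, which follows
mechanically from the zero-overlap rule. i-LAD is the complement of A∪B;
the six categories provably partition the genome (asserted at run time).
No minimum edge length or flanking-run requirement is imposed.

Fate classes cross the five LAD-related categories with the LAD vs i-LAD
outcome at the final time point. Default granularity is **split**
(base-exact, conserves bp); **majority** assigns each contiguous segment
wholly by overlap fraction ≥ 0.5 (conserves segment counts). Split is the
default because the downstream gene rule (genes spanning > 1 class are
removed) is defined at class-boundary resolution; both modes are exposed
since region-versus-base granularity is a genuine design choice. Class
labels are fixed strings ("Common>LAD" … "Lost edge>i-LAD") for stable
joins.

## Constrained permutation test

Null model: query segments are independently relocated within their own
chromosome, uniformly over every position at which the segment fits
entirely inside a segment of the **background** track. Uniformity over
positions is implemented as segment choice with probability ∝
(segment length − L + 1) followed by a uniform start. Segments that fit in
no background segment fall back to uniform placement on the whole
chromosome and are counted (`n_fallback_segments`), so users can see when
the background is too fragmented for their query; clipping oversize
segments was rejected because it would silently change the statistic.
Permuted segments may overlap each other — forbidding self-overlap would
bias the null for dense queries — and the overlap statistic is computed on
the merged placement.

The background is intended to be "the union of known LAD locations" in the
cells under study. The package builds it as the union of the LAD maps over
the whole time course (plus an external LAD map when one is supplied).
Restricting it to the target time point's map alone would make every
permuted segment a guaranteed full-length hit and collapse the test; the
across-time-course union is the reading that makes the statistic
informative.

p-values are empirical two-sided: p = min(1, 2·min(p≥, p≤)) with the
(k+1)/(n+1) estimator, so p is never 0 and the resolution is 2/(n_perm+1).
Typical n_perm: 50 within a time course, 250 against an external map. The
FDR family is exactly the set of queries passed in one call (e.g. five
categories, or ten classes); q-values are Benjamini–Hochberg
(statsmodels). When expected overlap is 0, O/E is reported as NaN with
p = 1. Fixed seed ⇒ bit-reproducible results; the calibration experiment
(queries drawn from the null placement itself) verifies type-I error at
α = 0.05, mean O/E ≈ 1 and approximately uniform p-values.

## Genes, expression, enhancers

- Gene → class assignment: ≥ 1 bp overlap; overlap with ≥ 2 classes ⇒
  "multi-class (removed)"; no overlap ⇒ i-LAD.
- Expressed gene: normalized count ≥ 15 at ≥ 1 time point (strict ≥).
- z-scores: per gene across time points with population SD; constant genes
  get all-zero z-scores. Replicates are averaged before z-scoring.
- Per-class fold-change of DE genes: log₂((c_to + 1)/(c_from + 1)) —
  pseudocount 1 because a fold-change convention is not otherwise pinned
  down — with a two-sided one-sample t-test vs 0 when the class has ≥ 3 DE
  genes and nonzero variance.
- Enhancer–gene distance: enhancer center (floor midpoint) minus TSS,
  sign-flipped on minus-strand genes so negative is always upstream of the
  gene start; 0 counts as downstream. The gene start is the strand-aware
  TSS (a flag-level alternative of using annotation start regardless of
  strand was considered and rejected: signed upstream/downstream plots
  only make sense strand-aware). Trans (cross-chromosome) pairs error out.
- Enhancer status over a timeline: **vLAD** if it overlaps
  non-constitutive LAD bases at ≥ 1 time point; else **cLAD** if in LADs
  at every time point; else **i-LAD** if in LADs at none; a "mixed" label
  exists for completeness but is unreachable when LAD(t) = cLAD ∪ vLAD(t).
- Fisher's exact test: scipy's exact two-tailed p; odds ratio with the
  Haldane–Anscombe +0.5 correction when a cell is 0. Fisher comparisons of
  genomic coverage are computed on counts of 100-kb coverage units
  (configurable) — raw base-pair counts would treat every base as an
  independent trial and produce meaningless p-values.
- Welch-corrected comparisons: two groups ⇒ Welch t-test (scipy); more ⇒
  Welch's ANOVA (pingouin), cross-checked against the closed form in the
  test suite.

## Signal tracks and profiles

`BinnedTrack` stores one value per fixed-width bin per chromosome with NaN
as the missing-data mask. Region means are coverage-weighted over unmasked
bins; pooling tracks ("all time points confounded") is a per-bin mean with
mask propagation (a bin missing in any input stays missing). TSS
metaprofiles use a ±3 kb window in 50-bp bins by default (the window is a
plotting choice, not a biological constant), are strand-oriented
(minus-strand windows flipped), and drop + count anchors truncated by
chromosome ends. The H3K4me1 sub-domain partition of cLADs intersects the
union of all per-time-point peak footprints with the cLADs at base
resolution; the two parts conserve cLAD bp exactly. A window-tiling
"region" granularity was considered and not provided — base resolution is
the only choice that needs no extra parameter.

## Synthetic study generator

The generator plants, on a 3 × 30-Mb genome (large enough for ~50 elements
while keeping the full pipeline in minutes):

- 18 constitutive LAD cores (log-normal sizes, median 500 kb) and 26
  variable elements (median 150 kb — variable LADs are smaller than common
  ones): 8 gained and 5 lost stand-alone LADs, 8 gained and 5 lost edges
  attached to a host core, all ≥ 10 kb apart so planted labels are
  unambiguous.
- A scripted final-time-point outcome per element (LAD with probability
  0.9 for common elements, 0.5 for variable ones), defining the true
  ten-class labels.
- Replicate LAD calls: truth boundaries + independent Gaussian jitter
  (default SD 5 kb, rounded), inverted segments repaired by swapping, and
  optional whole-LAD dropout (default 0).
- Lamin B1 log2-ratio tracks in 1-kb bins: mean 0.5 in LADs, −0.3 outside,
  a shared latent field (SD 0.2) plus small replicate noise (SD 0.05) so
  replicate correlations are high by construction; H3K9me3 analogous.
  Around each escaper-gene TSS (±5 kb) both means drop by 0.6 — the
  planted low-lamin sub-domain.
- Genes inside elements (mostly silent; an escaper fraction of 0.15 is DE
  and expressed) and 120 i-LAD genes (80% expressed, 30% of those DE);
  two genes deliberately straddle an edge/core boundary to exercise the
  multi-class removal rule. Expression over 8 time points (T00–T24 every
  4 h, then T72) uses negative-binomial counts (dispersion 20; `None`
  gives noise-free rounded means for exact closure tests) with Gaussian
  log2 waves (amplitude 2) peaking at a scripted time point for DE genes.
- Enhancers: 1–5 per DE gene, |distance| exponential with mean 24 kb,
  downstream with probability 0.42, and 70% of LAD-gene enhancers forced
  inside the target's element so they co-partition with it.
- Histone-PTM tracks/peaks (H3K4me1/H3K4me3/H3K27ac) at the three LAD
  time points: noisy baseline plus Gaussian bumps and matching BED peaks
  at escaper promoters, expressed i-LAD promoters and enhancers.

What the generator does **not** emulate: read-level noise and mappability,
domain-caller artifacts beyond boundary jitter/dropout, correlated
replicate structure in expression, GC/length confounders of real enhancer
catalogs, and inter-chromosomal heterogeneity. Passing recovery tests
therefore demonstrates correctness of the classification/statistics logic
under the stated noise model, not robustness to every failure mode of real
ChIP-seq.

The LAD timeline is simulated at T00/T24/T72 only; the intermediate
expression time points carry transcription waves but no additional LAD
maps, matching how the dynamics analysis actually consumes the data.

## Numerical and reproducibility choices

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning (placement, outcome script,
replicates, tracks, expression, enhancers get independent streams), so
every artifact is deterministic given the seed; the pipeline manifest
records parameters and SHA-256 digests of outputs and is byte-identical
across reruns. Degenerate inputs fail loudly: empty replicate lists,
single-time-point cLADs, zero-variance Welch groups, all-zero Fisher
margins, p-values outside (0, 1], regions without signal. Validation
problem sizes — 1,000 oracle genomes, 500 calibration replicates × 200
permutations, 100 power runs × 250 permutations — were chosen so the whole
validation completes in well under a minute each on one CPU while leaving
the binomial confidence bands tight enough to be meaningful.

## Known limitations

- The constrained-placement null treats segments independently; it does
  not preserve inter-segment spacing or GC/length matching (GAT- or
  regioneR-style nulls are out of scope).
- The per-LAD read-count replicate QC is approximated by binned-track
  correlation restricted to LADs (see above).
- The background-track definition is an interpretation (union over the
  time course); alternative readings can be supplied explicitly via the
  `permtest` CLI's `--background`.
- Majority-mode fate assignment reports whole segments and therefore does
  not conserve base pairs across classes; use split mode (default) for
  coverage bookkeeping.
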
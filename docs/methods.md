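# Methods

## Model and procedure

`winscan` computes a principal component analysis independently in rolling
windows along a chromosome and reports, for each sample, its score on the
requested PCs (PC1 and PC2 by default, up to PC10) per window.

**Coordinates and windowing.** All coordinates are 1-based and fully
closed, matching VCF convention; a variant at position *pos* belongs to the
window [start, end] iff start ≤ pos ≤ end. Windows are anchored at position
1 by default and advance by the step size; only full-length windows with
end ≤ span are emitted, so the number of windows on a span L with window w
and step s is ⌊(L−w)/s⌋ + 1. The span defaults to the last variant position
and can be overridden (`--chrom-length`). Whether windows anchor at
position 1 or at the first variant is genuinely underdetermined — both
conventions give the same count on a chromosome with variants near its
ends — so the anchor is a config option (`anchor = one | first_variant`)
with position 1 the default. Windows are processed as a rolling stream, so
memory is bounded by one window's worth of records regardless of
chromosome size.

**Hard-genotype PCA.** Alt-allele dosages g ∈ {0,1,2}; missing calls are
imputed per variant as the mean observed dosage (columns with no observed
call are dropped and counted). Monomorphic columns are dropped, then the
matrix is centered and, by default, Patterson-scaled — divided by
√(p(1−p)), the binomial standard-deviation unit at allele frequency
p = mean dosage / 2. The scaler is exposed (`none | center | patterson`)
because different conventions are in use; Patterson scaling is the default
as the standard choice for genetic eigenanalysis. Scores are
u<sub>k</sub>√λ<sub>k</sub> from a full symmetric eigendecomposition of the
N×N sample covariance XXᵀ. Because columns are mean-centered, the all-ones
vector is in the null space, so scores on every informative PC sum to zero
— asserted throughout the test suite. N (samples) is small relative to M
(variants per window), and the dense LAPACK solve is deterministic, giving
bit-reproducible output with no randomized solver and hence no seed.

**Genotype-likelihood PCA.** Likelihood triplets are normalized to
probabilities (PL: 10^(−PL/10); GL: 10^GL when all values ≤ 0, else
treated as plain probabilities — both dialects occur in the wild, and the
all-nonpositive test separates them unambiguously). The window is then
analyzed iteratively:

0. site frequencies f from mean expected genotypes under a flat prior;
   sites monomorphic under that estimate are dropped;
1. expected genotypes E[g] under a Hardy–Weinberg prior at the current
   frequencies (shared f in round one, per-individual π afterwards);
2. center by column mean, scale by √(f(1−f)), eigendecompose;
3. per-individual allele frequencies π = (X̂ + 2f)/2 from the rank-K
   reconstruction (K = largest requested PC), clamped to
   [1/(2N), 1−1/(2N)] to avoid degenerate priors;
4. repeat 1–3 until the RMS change in expected genotypes falls below `tol`
   (default 1e-4) or `max_iter` (default 100) is reached — non-convergence
   sets a flag on the result rather than raising.

The defaults are desk-scale choices: depth-30 data typically converges in
a handful of rounds, and the tolerance is far below the score differences
that matter for window-to-window interpretation. With certain likelihoods
(one entry = 1) the posterior ignores the prior, the first round already
reproduces the hard-call matrix, and the two pipelines agree exactly.

**Validity.** Windows with fewer usable variants than `min_variants`
(default 20) yield NA scores but are kept in the track, so tracks stay
rectangular and positionally continuous for polarization and plotting.
Fewer than two samples is a hard error.

## Polarization

Each window's eigenvector sign is arbitrary. The polarize step walks the
track in order; the first valid window is kept as-is and seeds the history.
For each later valid window a reference signal is chosen — adaptive mode:
the sample with the largest |score| in the current window (ties broken by
lowest sample index); guided mode: the summed scores of user-specified
guide samples — and the window is negated when the reference's current sign
disagrees with the sign of the mean of its signs over the up-to-`n_prev`
(default 5) most recent polarized valid windows. Edge cases are resolved
as: shorter-than-`n_prev` history uses whatever is available; NA reference
scores are excluded from the sign average; a zero sign average keeps the
current orientation (least surprise); invalid windows are passed through
and consume no history. The rule is greedy and sequential by design — no
global optimization of track polarity is attempted — and is idempotent on
its own output. Signs are recomputed from the stored scores on every
invocation, so an existing run can be re-polarized in place.

`flip` complements this with deterministic manual edits: negate a whole
chromosome (an involution), or negate exactly those windows whose midpoint
falls in user-supplied closed intervals (set semantics — overlapping
intervals never double-flip). The "sign average" weights each history
window equally (±1 per window), not by score magnitude.

## Visualization

`chromplot`/`genomeplot` draw one polyline per sample over window
midpoints (the midpoint is the unbiased x-position within a window); NA
windows break the line rather than being interpolated. Both build a single
backend-neutral figure description that is rendered to self-contained
interactive HTML — hover tooltips carry the sample id plus all metadata
columns, legend entries toggle groups, drag zooms — and to static PDF/SVG/
PNG via matplotlib, so data arrays are identical across formats. Categorical
coloring uses a fixed 12-color colorblind-safe cycle (recycled with a
warning beyond 12 groups); quantitative columns are min–max scaled onto a
continuous spectrum (viridis). Samples are drawn in metadata group order
then input order, so an explicit `group_order` controls z-stacking.
`genomeplot` tiles chromosomes left to right on a shared score axis
(`free_scale` opts out) and aligns samples across tracks by id, not
position. Rendering is read-only with respect to track files.

## Synthetic cohorts

The generator exists so every pipeline stage is testable against known
truth without external downloads. Its defaults are the study conditions
used by the acceptance checks: two populations of 50 samples on a 5 Mbp
chromosome at 1 variant/kb, Balding–Nichols divergence F = 0.2 (a clearly
structured pair of populations), a 2 Mb inversion at 2,000,001–4,000,000
with haplotype frequency q = 0.5, mean depth 30 and per-base error 0.01
(typical modern short-read values).

Per-variant ancestral frequencies are Uniform(0.05, 0.95); population
frequencies are Beta-distributed around them with variance F·p(1−p);
genotypes are Hardy–Weinberg within population. Inside the inversion each
sample draws an inversion genotype at frequency q and its two haplotypes
draw alleles from haplotype-class frequencies diverged at
F_inv = min(0.9, F × divergence_multiplier) (default multiplier 4, so
F_inv = 0.8) — the inversion is encoded as allele-frequency divergence
between haplotype classes, not as coordinate reversal, because PCA sees
only genotype correlation, which is how real inversions manifest in PC
space. Inside the locus the haplotype classes replace population structure
so the inversion dominates local PC1, mirroring how strong inversion
signals override background structure in real scans. Likelihoods come from
Poisson read depth and binomial alt-read counts; missing calls are
sprinkled uniformly at the configured rate (flat triplets on the
likelihood side). One RNG stream seeded once drives everything, and VCF
(GT+PL), BEAGLE and TSV outputs are emitted from the same genotype draw,
so cross-format comparisons see the same cohort; gzip headers are pinned
(no filename, zero mtime) so a fixed seed yields byte-identical files.

What the generator does *not* emulate: linkage disequilibrium and
recombination maps (variants are independent given their frequencies),
multi-chromosome linkage, indels/multiallelic sites, batch effects or
reference bias, and realistic site-frequency spectra. Passing tests
therefore demonstrate the correctness of the windowing, PCA, polarization
and I/O machinery under known structure — not that any particular real
dataset will show a given signal.

## Problem sizes and numerical choices

The test suite and the acceptance script run a 100-sample, 5 Mbp cohort
(41 windows of ~1,000 variants) for the cross-pipeline checks and a
20-sample, 500 kb cohort for format-invariance checks — sizes chosen so the
full suite completes in well under a minute while each window still holds
enough variants (~10× the sample count) for stable eigenstructure. Score
files store 6 significant digits, adequate for plotting and polarity while
keeping tracks compact; NA is written literally. Window counts, interval
membership and flip semantics are all integer arithmetic with no
tolerances. Equality checks between the GL and GT pipelines use 1e-6 per
score; oracle comparisons against an independent dense SVD use 1e-8 with
sign freedom per window.

## Known limitations

* Haploid GT calls are doubled (with a warning) rather than modeled;
  half-calls are treated as missing.
* Multiallelic records are skipped, not split.
* The GL iteration is a simplified expected-genotype/individual-frequency
  scheme; it shares the structure of likelihood-based PCA methods but not
  every option of any particular published implementation.
* Polarization is greedy; pathological tracks (e.g. adjacent flips within
  the history depth, or windows whose top sample changes sign meaning)
  can still need manual `flip` edits — which is why flip exists.
* One chromosome per `pca` invocation; users loop over chromosomes and
  combine with `genomeplot`.
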
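# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions.

## FRAP model and normalization

The kinetic model is a well-mixed two-state exchange: a mobile pool that
re-equilibrates at rate k = ln 2 / τ½ and an immobile pool that stays where
it was bleached. The fully normalized bleach-region curve is

F(t) = b + m(1 − b)(1 − e^(−kt)),

with b the normalized intensity immediately post-bleach (`bleach_depth`),
m = 1 − immobile_fraction, and t = 0 at the first post-bleach frame. The
bleach frame itself belongs to neither phase and is dropped everywhere.

The trace generator works in raw intensities so that the double
normalization is exercised non-trivially. The whole-nucleus channel decays
by `acq_bleach_rate` per acquired frame (acquisition photobleaching) and
drops at the bleach event by the bleached fraction of total signal,
a·(1 − b_raw), where a is the bleach-region area fraction (default 0.1)
and b_raw the raw ROI bleach factor. Because total fluorescence is
conserved apart from these two losses, the raw factor corresponding to a
target normalized depth b is b_raw = b(1 − a)/(1 − ab); with that choice
the double normalization reproduces F(t) exactly (machine precision in the
noise-free test) and — the point of the correction — both τ½ and the
immobile fraction are invariant to the acquisition-bleaching rate.

Noise is multiplicative Gaussian (`noise_sd`, default 0.02 relative),
matching a high-photon confocal regime; a Poisson option was considered
and deferred. The movie generator applies the same model per pixel (the
immobile pool keeps its bleached profile, the mobile density equilibrates
globally) plus stage drift; it exists to exercise registration and the
two-path (movie-trace vs direct-trace) consistency check, not to model
diffusion within the bleach spot. Reaction–diffusion profiles, 3D stacks
and camera noise are out of scope.

Acquisition defaults are 10 pre-bleach and 180 post-bleach frames at 1 s
(250 ms is the fast setting used when τ½ is below ~2 s); normalization
references the last five pre-bleach frames, so at least five are required.

## Kinetic summaries

Two estimators are provided and cross-checked against each other:

* interpolated (default): f0 is the first post-bleach sample; the plateau
  is the mean of the final 10% of post-bleach frames (the qualitative
  "curve has flattened" stopping rule made concrete — 10% is robust and
  testable); τ½ is the linearly interpolated first crossing of
  (f0 + plateau)/2.
* exponential_fit: least squares on F(t) with f0, plateau, k free;
  τ½ = ln 2/k. A non-convergent fit falls back to interpolation with a
  flag.

Mobile fraction = (plateau − f0)/(1 − f0), clipped to [0, 1]. A curve with
plateau ≤ f0 is flagged no-recovery (mobile 0, τ½ undefined) rather than
raised. On noise-free single-exponential input the two estimators agree on
τ½ within one frame interval; over a grid of τ½ ∈ {0.5, 2, 8, 14, 30} s ×
immobile ∈ {0, 0.13, 0.35} with 12 nuclei at 2% noise, both recover the
generating values within 15% (τ½) and 0.05 absolute (immobile fraction).

The headline estimate comes from the ensemble mean curve (mean ± SEM over
6–20 nuclei); per-nucleus fits are also computed and feed the group
comparison. Published FRAP studies rarely name the test behind their
p-values, so `compare_kinetics` uses a seeded percentile bootstrap over
nuclei (default 10⁴ resamples) and records the method in its output.

Registration is translation-only phase correlation against the first
frame, with Fourier-upsampled sub-pixel refinement (factor 10) and
nearest-neighbor resampling — intensities are moved, never blended, so
mask means are unbiased.

## Enrichment scoring

Foci are connected components above mean + k·SD of the DNA channel within
the nucleus (k = 2), discarding components under 5 px. The original
protocol circles one random focus and three nucleoplasmic areas by hand;
here the focus is a seeded random choice among detected foci and the
nucleoplasm is three seeded random disks of the focus radius, redrawn if
they touch any focus (their size/placement is not specified by the manual
protocol; equal-radius disks are this package's choice). Ratios are
scale-invariant by construction. The generator plants a known enrichment
with absolute Gaussian noise; at ≤5% noise the 20-nucleus mean ratio is
within 5% of the planted value for enrichments 1–5. Colocalization
coefficients and 3D foci are out of scope.

## Salt extraction

percent bound = 100·pellet/(pellet + sup) per concentration; a
concentration with both signals zero yields a flagged NaN. Monotonicity in
salt is deliberately not enforced.

## Phylogenetics

p-distance = differing sites / compared sites. Pairwise deletion is the
default gap policy (the common default in distance-phylogenetics GUIs;
complete deletion is available and the choice is recorded in pipeline
output). NJ follows Saitou–Nei with the standard Q criterion; ties are
broken deterministically by the lowest index pair; a negative pendant
length is clipped to zero with the deficit moved to its sister so the pair
sum stays d(i, j) — the standard practical fix that keeps the tree valid
while preserving additivity where it holds. NJ is exact (topology and
branch lengths) on additive matrices, verified against exhaustive
least-squares topology search at n = 5 and path-length reconstruction up
to n = 8, and cross-checked against an independent library implementation.

Bootstrap replicates resample columns with replacement; each replicate's
RNG is keyed to (seed, replicate index), so supports are invariant to
taxon input order. Supports are mapped onto the full-data NJ tree, not a
consensus. Replicates with an incomparable pair under pairwise deletion
are discarded and counted (warning above 1%); supports use valid
replicates as the denominator. Rooting places the root at the midpoint of
the outgroup's pendant edge. Alignment construction and model-corrected
distances are out of scope.

## Sequence features

P-x-V-x-L is scanned with overlaps allowed, 1-based inclusive coordinates.
Composition sets: basic {K, R} (histidine excluded — mostly neutral at
physiological pH; the set is configurable), acidic {D, E}, hydrophobic
{A, V, L, I, M, F, W, C} (no universal definition exists; the set is fixed
and stated here). Acidic tracts are maximal D/E runs ≥ min_len (default
15, below the canonical ~20-residue tract so slightly eroded tracts still
register). Pairwise similarity counts BLOSUM62-positive pairs, identities
included.

The protein generator builds a 553-residue tripartite layout (Glu-rich
NTD of 157, three H1-like globular domains, a pure D/E tract of 20, a
basic CTD at 40% K/R) with exact-count composition per region
(largest-remainder apportionment, then a seeded shuffle), and plants the
PQVKL motif verbatim at position 255 by default. Planted motifs must lie
within a single region. The generator controls composition, not realistic
residue order or secondary structure.

## Genetics

Ratio-to-count reconstruction uses largest-remainder apportionment
(deterministic, sums exactly; the chi-square conclusion is insensitive to
the ±1 rounding involved). The goodness-of-fit is a Pearson chi-square
with df = classes − 1 (expected count ≥ 1 enforced), validated against a
Monte-Carlo multinomial null. Survival deficit is reported raw plus
rounded to the nearest ten for presentation. The sex-ratio test is exact
binomial (small counts make the chi-square approximation inappropriate);
note that counts reconstructed from a rounded printed ratio such as 1:1.6
are approximate by construction — at 76 animals the reconstruction
(29:47) sits at p ≈ 0.0505, just above the nominal 5% line, which is why
raw counts would be needed to reproduce tighter published bounds.

## Expression

The per-gene test is the pooled-variance two-sample t-test on log2 values
(identical to one-way fixed-effects ANOVA with two groups; log2 is
assumed for input matrices and documented here because array suites differ
silently on this). Genes with zero variance in both groups get p = 1 when
the means agree, 0 otherwise. BH q-values come from the standard step-up
implementation and are verified against an explicit min-over-tail
computation. Filtering keeps |fold| ≥ min_fold and q ≤ max_q with signed
folds (down = negative reciprocal). The generator plants uniform
log2-fold shifts (default 271 up, 112 down at 1.6–2.5-fold among 20 000
genes, triplicate groups) with residual log2 sd 0.08 — the low-noise,
high-RIN technical-triplicate regime this filtering stage is designed
for; with biologically realistic noise (sd ≥ 0.2) a 3 + 3 design cannot
resolve 1.4–2-fold effects at q ≤ 0.1, which is a property of the design,
not of the implementation. Array normalization and probe mapping are
upstream and out of scope.

## Problem sizes and determinism

Test and acceptance runs use the stage-native sizes: 12 nuclei × 190
frames for FRAP recovery, 20 nuclei per enrichment group, 5–8 taxa for
tree oracles, 200 bootstrap replicates in oracle-equivalence tests (1000
is the analysis default), 784/130-animal cohorts, and 20 000-gene
matrices. All stochastic paths take an explicit integer seed through
`numpy.random.default_rng`; no global RNG state is used, and identical
(parameters, seed) pairs give byte-identical outputs, including the
pipeline report JSON.

## Known limitations

* The FRAP model is exchange-limited; diffusion within the bleach spot is
  not modeled, so very fast proteins (τ½ ≪ frame interval) are outside
  the model's regime.
* Passing enrichment tests on disk-shaped synthetic foci says nothing
  about segmentation robustness to irregular focus morphology or uneven
  illumination.
* The synthetic protein sequences honor composition but not realistic
  residue order; motif-scan specificity on real sequences is limited only
  by the motif's information content.
* Bootstrap supports on small toy alignments are means to verify the
  resample-and-count machinery, not biologically meaningful supports.
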
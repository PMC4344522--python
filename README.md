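# chromodyn

Quantification tools for the cell-biology workup of a chromatin-binding
nuclear protein — the kind of analysis used to characterize linker-histone
(H1)-family proteins such as HP1BP3: FRAP recovery kinetics, heterochromatin
enrichment scoring, salt-extraction binding profiles, globular-domain
phylogenetics, protein motif/composition features, Mendelian viability
statistics and differential-expression filtering. Every stage ships with a
seeded synthetic-data generator that emulates the statistical structure the
stage assumes, so the whole pipeline is testable end to end without
microscope or array data.

## Who this is for

Researchers quantifying live-cell photobleaching experiments and the
surrounding characterization of a nucleosome-binding protein: image stacks
or intensity traces in, kinetic summaries and statistics out.

## The core model

**FRAP.** A region of a nucleus is photobleached and its fluorescence
recovers as unbleached molecules exchange in. Each raw trace (bleach-region
mean and whole-nucleus mean per frame) is double-normalized:

    F(t) = [ROI(t) / ⟨ROI⟩_pre5] / [N(t) / ⟨N⟩_pre5]

where ⟨·⟩_pre5 is the mean of the last five pre-bleach frames of the
respective channel. Dividing by the whole-nucleus channel N(t) cancels both
acquisition photobleaching and the signal lost at the bleach event. Curves
from 6–20 nuclei are averaged pointwise (mean ± SEM) and the mean curve is
summarized by a two-state recovery model

    F(t) = f0 + (plateau − f0)(1 − e^(−kt)),   τ½ = ln 2 / k,

with the mobile fraction (plateau − f0)/(1 − f0) and the immobile fraction
its complement. τ½ is measured relative to the f0→plateau span — the only
definition consistent with a non-zero immobile pool — either by linear
interpolation of the half-recovery crossing (default) or by the exponential
fit. Group contrasts (fold-change of τ½, difference of immobile fractions)
get two-sided bootstrap p-values.

**Enrichment.** Pericentromeric heterochromatin foci are segmented from the
DNA channel (mean + k·SD threshold, k = 2); enrichment is the mean protein
intensity in one randomly chosen focus divided by the mean over three
sampled nucleoplasmic disks. A homogeneously distributed protein scores
exactly 1.

**Phylogenetics.** Uncorrected p-distances (pairwise- or complete-deletion
gap handling) from a pre-aligned amino-acid FASTA, Saitou–Nei neighbor
joining, bootstrap supports (default 1000 column-resampled replicates)
mapped onto the full-data tree, and outgroup rooting.

**Genetics.** Largest-remainder reconstruction of integer counts from
printed ratios, Pearson chi-square against a 1:2:1 Mendelian expectation,
survival-deficit arithmetic and an exact two-sided binomial sex-ratio test.

**Expression.** Per-gene pooled-variance two-group test on log2 values,
Benjamini–Hochberg q-values, and |fold| ≥ f, q ≤ q* filtering with signed
fold-changes (two-fold down = −2).

## Worked example

Simulate 12 wild-type-like nuclei (τ½ = 14.1 s, immobile fraction 12.8%,
2% noise) and run the full quantification:

```
$ chromodyn simulate-frap --tau-half 14.1 --immobile 0.128 --n-nuclei 12 \
      --seed 1 --out wt_traces.csv
$ chromodyn analyze-frap --traces wt_traces.csv
{
  "n_nuclei": 12,
  "method": "interpolated",
  "tau_half_s": 14.199690873373541,
  "mobile_fraction": 0.8683266692909366,
  "immobile_fraction": 0.1316733307090634,
  "plateau": 0.9070903461489687,
  "f0": 0.29439277224392313
}
```

The pipeline recovers the generating half-time (14.2 s vs 14.1 s) and
immobile fraction (13.2% vs 12.8%) from noisy traces. The plateau of 0.907
below full recovery is exactly what a 13% immobile pool on a 0.29 bleach
depth predicts.

Viability arithmetic from a published-style weaning ratio:

```
$ chromodyn genetics --ratio 3.5:5.8:1 --total 784
{
  "counts": [266, 442, 76],
  "chi2": {"chi2": 104.84693877551021, "df": 2, "p": 1.7091356093594288e-23},
  "ko_deficit": {"deficit_pct": 61.224489795918366,
                 "deficit_pct_rounded10": 60, "surplus_clipped": false}
}
```

A 3.5 : 5.8 : 1 genotype distribution over 784 weanlings is wildly
non-Mendelian (χ² ≈ 104.8, p ≈ 10⁻²³) and implies that ~61% of the
expected homozygous-null animals — presented as a 60% loss — died before
weaning.

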
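# Methods

## Overview

`sweepscan` implements a simulation-trained pipeline for detecting and
classifying selective sweeps in unphased diploid genotype data. A
probabilistic five-class classifier — neutral, hard sweep, soft sweep,
hard-linked, soft-linked — is trained on labeled coalescent simulations,
applied to sliding genomic windows, and followed by three
post-classification inferences: simulation-null false-discovery q-values
for candidate sweeps, a conservative confusion-matrix-corrected estimate
of the fraction of sweeps that are soft, and two permutation enrichment
tests (a focal gene set by score shuffling, and GO terms by circular
chromosome rotation).

## Class geometry and labels

A feature window is divided into k adjacent, equal subwindows (k = 11,
odd, central index (k−1)/2). The classified unit is the central
subwindow. A replicate whose selected site lies in the central subwindow
is a `hard`/`soft` example; in any other subwindow, `hard-linked`/
`soft-linked` (the "soft shoulder" of a sweep); with no selected site,
`neutral`. Labeling is a pure function of sweep type and subwindow index.

## Training simulations

Each replicate draws, from broad priors:

| parameter | distribution | full-scale default |
|---|---|---|
| mutation rate μ (per bp per gen) | uniform | [8.82×10⁻¹⁰, 8.82×10⁻⁹] (mean 4.85×10⁻⁹) |
| recombination rate r (per bp per gen) | exponential, rejected above cap | mean 4.85×10⁻⁹, cap 3× mean |
| selection coefficient s | log-uniform | [0.005, 0.05] over 2.75 Mb |
| fixation time τ (coalescent units of 4N) | uniform | [0, 0.001] |
| standing frequency f₀ (soft classes) | uniform | [0, 0.05] |
| selected-site position | uniform within the class's subwindow | — |

Because the rejection-truncated exponential keeps only draws ≤ 3× the
mean, the realized mean of r lies below the nominal mean parameter.

Windows shorter than the 2.75 Mb full scale use `rescale_for_region`,
which multiplies the s bounds by the length ratio. Since a sweep's
hitchhiking footprint spans ~s/r bp, this keeps the footprint-to-window
ratio — and hence the spatial geometry of the five classes — invariant
across window lengths. The prior stays log-uniform on the rescaled
bounds.

Replicates are simulated with msprime. Sweep classes use the structured-
coalescent sweep model (genic selection): the beneficial allele reaches
fixation τ·4N generations before sampling; soft sweeps start from a
standing variant at frequency f₀ (a near-zero f₀ is floored at 10⁻⁹,
since f₀ = 0 is definitionally a hard sweep). We also evaluated an
explicit standing-phase model (a second, near-neutral sweep phase tracing
the allele from 1/(2N) back to f₀, bounding the swept class's TMRCA by
the allele age); it changed the simulated signatures negligibly —
recombination during the long standing phase dominates — so the simpler
model is used. Haplotypes are paired into unphased diploid dosages and
only biallelic sites are kept.

A limitation of the backward-time sweep machinery: demographic events may
not occur during the sweep phase. Piecewise-constant histories are fully
supported for neutral simulations; sweep simulations require epoch
boundaries older than the sweep's duration, and the packaged scaled
experiment uses a constant size (see below).

Per-replicate seeds are derived from one master seed through a
`numpy.random.SeedSequence`, so any single replicate is reproducible in
isolation and whole corpora are byte-reproducible.

## Summary statistics (unphased conventions)

Twelve statistics per subwindow: π, Watterson's θ, Tajima's D, the number
of distinct multilocus genotypes (MLGs), MLG homozygosity H1, H12, H2/H1,
Kelly's Zns, the maximum of Kim & Nielsen's ω, and the variance, skewness
and kurtosis of the pairwise-difference distribution.

Conventions, each covered by oracle tests:

* "Haplotype" spectrum statistics are computed on MLG strings (the
  unphased convention); MISSING is a distinct fifth symbol.
* π and θ_W adjust per site for the non-missing allele count m (π uses
  the unbiased 2p̂q̂·m/(m−1)); θ_W and D use the modal m as sample size.
* LD statistics use the Rogers–Huff genotype-correlation r², with
  pairwise-complete observations; pairs with fewer than two complete
  observations or zero variance contribute 0.
* ω is maximized over splits l ∈ [3, S−3]; a split with zero cross-block
  LD is skipped (the statistic is undefined there); if no split is valid
  the value is 0.
* Pairwise-difference moments are population moments; kurtosis is not
  excess-corrected; a zero-variance distribution maps to (0, 0, 0).
* Degenerate inputs (empty windows, monomorphic data, S below the
  minimum) return documented zero conventions rather than NaN, so
  feature matrices are always finite.

For very dense windows the quadratic cost of Zns/ω can dominate; the
`max_ld_sites` option computes both on an evenly spaced subsample of
segregating sites (the scaled experiment caps at 300 per subwindow). All
other statistics always use every site.

## Featurization

Each statistic's 11 subwindow values are turned into a spatial profile:
if the row minimum is negative the row is shifted so the minimum is zero
(relevant for Tajima's D and skewness), then the row is divided by its
sum; an all-zero row maps to the uniform profile 1/k. The shift precedes
the division because dividing by a zero or negative row sum is
ill-defined. Row-normalization deliberately discards absolute magnitudes
(robustness to μ, r and demography) and keeps only spatial shape. The
classifier input is the flattened 12 × 11 matrix; the serialized feature
archive names columns `<stat>_<subwindow>`.

## Classifier

A small fully connected network (two hidden layers, 128 and 64 units,
ReLU; softmax output over the five classes) trained with Adam on
categorical cross-entropy, built on scikit-learn's `MLPClassifier` driven
epoch-by-epoch. Ten percent of the training set is held out; after each
epoch the validation cross-entropy is computed, and training stops when
`patience` = 5 consecutive epochs fail to improve the best validation
loss by at least `min_delta` = 0.001 ("improvement" is measured against
the best-so-far loss, not the previous epoch). The weights achieving the
minimum validation loss are restored, so the returned model's validation
loss equals the minimum of the logged trace. Training is exactly
reproducible given `random_state`.

The architecture is deliberately modest: the input is a 132-dimensional
normalized profile, not an image. In side-by-side probes on cached
corpora, the MLP, random forests and gradient boosting all plateaued at
the same held-out AUC, i.e. performance here is limited by the
information in the simulated data, not by model capacity. Softmax
posteriors are taken at face value (no recalibration).

## Genome scan

Feature windows slide along each chromosome in steps of one subwindow;
each window's classification is attributed to its central subwindow. Two
classification-independent filters are applied first:

* zero-recombination: windows whose weighted-average recombination rate
  (overlap-weighted over the map, uncovered bp counting as rate 0) is
  zero over the **central subwindow** are dropped — without recombination
  the spatial LD geometry the classifier relies on does not exist;
* over-masking: windows whose **full feature window** is masked above
  0.85 (strict inequality) are dropped as low-confidence.

The two footprints are configurable; the defaults read "predicted
window" as the classified subwindow for recombination and use the full
featurization footprint for masking.

A window whose argmax class is hard or soft is called a sweep when its
combined sweep probability p_hard + p_soft reaches the threshold
(0.80/0.90/0.95/0.99 are the conventional grid), typed by the larger of
the two sweep posteriors with ties broken toward soft; below the
threshold it is "uncertain". Decisions are monotone in the threshold.
Calls can be intersected across population samples on a shared window
grid into shared and population-specific candidate sets.

## Post-classification inference

**FDR and q-values.** The null distribution is the set of combined sweep
probabilities the trained classifier assigns to truly neutral test
simulations. For threshold t,
FDR(t) = min(1, n_windows · P̂(null ≥ t) / max(1, #real ≥ t)).
Scaling the null exceedance rate by the total number of analyzed windows
assumes every window could be neutral (π₀ = 1), which is conservative.
Each candidate's q-value is the minimum FDR over the observed candidate
thresholds at or below its own probability (the candidate is in the
rejection set of every lower threshold), computed as a running minimum
from the smallest candidate probability upward; q is therefore
nonincreasing in the candidate's probability.

**Corrected soft fraction.** With raw counts (hard, soft) at a threshold
and the q-value at that threshold: FD = q·(hard+soft) expected false
discoveries, all conservatively assumed soft; the true hard count is
estimated as raw_hard / a with a = P(assigned hard | true hard) from the
test-set confusion matrix (over non-omitted assignments), of which a
fraction c = P(assigned soft | true hard) leak into the soft count. The
corrected fraction is max(0, soft − FD − (raw_hard/a)·c) / (hard + soft −
FD), clamped to [0, 1]. Soft-to-hard misclassification is deliberately
ignored, making the estimate a lower bound on softness. The raw_hard/a
inflation is this package's explicit formalization of the "fraction of
hard sweeps misclassified as soft" step.

**Enrichment.** Both tests pad genes by 1 kb on each side, count each
gene at most once, and use the one-sided proportion of permutations with
an overlap count ≥ observed (the `plus_one` option gives the standard
conservative variant; without it, a zero count is floored at 1/n_perm so
p stays in (0, 1]). The gene-set test shuffles the binary sweep-call
vector across window positions. The GO test concatenates the chromosomes
into a ring and rotates the call vector by a uniform non-zero offset,
preserving the spatial autocorrelation of calls (a linkage-aware null);
per-term p-values get Benjamini–Hochberg correction. Permutation counting
is vectorized through a gene × window overlap incidence matrix, so 10⁴
permutations over thousands of windows run in seconds.

Note the permutation p-values are discrete; on fixtures with few
attainable overlap counts their null distribution is a coarse,
conservative step function. The calibration test therefore uses a
randomized-geometry fixture whose counts have wide support.

## Scaled study conditions

The packaged experiment (`run_scaled_experiment`, also used by
`scripts/acceptance.py`) reproduces the full-scale design at desk scale,
chosen once as follows and then frozen:

* window 1.1 Mb = 11 × 100 kb subwindows; priors rescaled by 0.4, so s
  is log-uniform on [2×10⁻³, 2×10⁻²];
* constant effective size Ne = 5×10⁴ — the order of the recent effective
  sizes inferred for bottlenecked *Ae. aegypti* population samples; at
  this size the selection regime spans 2Ns ∈ [200, 2000] and soft sweeps
  start from at most 2N·f₀ = 5,000 founder copies;
* 20 diploid samples (the largest of the study's population samples);
* a balanced corpus of 1,200 replicates per class split 900 train / 300
  test, drawn by the `build_balanced_corpus` sampler, which is
  distributionally equivalent to subsampling the per-subwindow corpus
  design to balanced classes (the test share is larger than the
  full-scale 9:1 split so the held-out rates are estimated on 300
  neutral windows);
* LD statistics capped at 300 segregating sites per subwindow.

Among the affordable configurations (Ne ∈ [5×10⁴, 7.7×10⁵] crossed with
window lengths 275 kb–1.1 Mb, all at the stated rescaled priors), this
one maximizes held-out performance: larger subwindows reduce the
Monte-Carlo noise of per-subwindow statistics (the dominant error source
for the neutral-vs-soft boundary), while the moderate Ne keeps soft
sweeps' founder counts low enough to leave a signature. Raising Ne
toward the organism's real diversity sharpens hard sweeps but makes
standing-variant sweeps start from ~10⁵ founder copies — invisible in a
window — and multiplies simulation cost.

What the scaled conditions do **not** reproduce: the study organism's
full nucleotide diversity. At the estimated mosquito diversity (π/bp ≈
0.015, i.e. Ne near 10⁶ at μ = 4.85×10⁻⁹) a single 550 kb replicate
carries ~3,000 segregating sites per subwindow and costs ~9 s to simulate
and featurize — hundreds of times the per-replicate budget a desk-scale
rerun allows. Statistic precision grows with site density, and held-out
classification accuracy grows with it; the scaled experiment therefore
bounds the full-scale classifier's performance from below. This is the
main caveat when comparing scaled metrics with full-scale ones: passing
tests show the pipeline's machinery is correct and its accuracy at the
stated reduced conditions, not the accuracy attainable on the real data.

## Synthetic genome fixtures

`make_fixture_genome` writes a complete, byte-deterministic scan input:
a diploid VCF assembled from adjacent, independently simulated tiles
(tiles with an implanted sweep place the selected site at the tile
center, so the grid-aligned scan window carries it in its central
subwindow), a mask BED with a configurable over-masked window, a
recombination map with an optional zero-rate interval, evenly spaced
gene annotations with round-robin GO terms, and a truth table of
implanted sweeps. Adjacent tiles are statistically independent — windows
straddling tile boundaries mix unlinked genealogies — which is
acceptable for filter/recovery fixtures but is not a model of real
linked chromosomes.

## Numerical and degenerate-input choices

* Coordinates: 0-based half-open internally; VCF read as 1-based; BED as
  0-based half-open; output tables 1-based inclusive.
* Genotypes with GQ below 20 are masked to MISSING at read time; records
  without a GQ field pass.
* Probabilities are validated to sum to 1 within 10⁻⁶; scan tables print
  8 significant digits, so a written table re-reads to the same
  posteriors within 10⁻⁶.
* FDR values are capped at 1; corrected soft fractions are clamped to
  [0, 1]; all intermediate corrections are floored at 0.
* Sweep-type ties (p_hard = p_soft) break toward soft, the majority type
  in every realistic regime; the tie has probability ~0.

## Known limitations

* At desk-scale site densities the class posteriors of ambiguous windows
  (neutral vs soft-linked vs soft) are nearly flat, so the *argmax*
  assignment of such windows — and with it the fraction of neutral test
  windows whose argmax lands on a sweep class — varies substantially
  between corpus realizations, even though the ROC/PR summaries and the
  thresholded (≥ 0.80) neutral misclassification rate are stable.
  Decisions gated on the combined-probability threshold are the robust
  interface; raw argmax labels on weak data are not.

* Sweep simulations require the demographic history to be constant over
  the sweep's duration (engine restriction, documented above).
* No migration or population structure in training data; no phased-
  haplotype statistics (EHH/iHS) — the pipeline is unphased by design.
* The classifier's posteriors are not calibrated probabilities.
* The mask-transfer mechanism rescales empirical mask coordinates
  proportionally when window lengths differ, which preserves masked
  fraction but not the bp-scale autocorrelation of masks.
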
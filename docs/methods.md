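# Methods

## Statistic and detection rule

All pairwise association is measured by Spearman's rank correlation
coefficient (SCC): the Pearson correlation of average ranks, with ties given
the mean of the ranks they span. Rank correlation is used because miRNA
(RPM) and gene (FPKM) abundances differ by orders of magnitude and miRNA
repression is saturating, both of which compress raw-value Pearson
correlation toward zero on large cohorts; the SCC is invariant under any
strictly increasing transform of either variable.

For a candidate triplet the cohort's samples are sorted in ascending order
of the centered RNA (ties broken lexicographically by sample id, making the
sort deterministic). A window of `w = floor(window_fraction * n)` samples
(default fraction 0.25; 94 samples at n = 376; minimum 3) slides with step 1,
and the SCC of the two non-centered RNAs is computed inside each window,
giving `floor((n - w)/step) + 1` window SCCs. Windows in which either
vector is constant have no defined SCC; they are excluded from the
max/min rather than set to 0, because 0 would fabricate an observation. A
profile with no defined window is reported "unevaluable", never silently
failed.

With `max`, `min` and `ΔCor = max − min` over the defined windows, a
candidate passes when `ΔCor > 0.300` and its class-specific extremum clears
the corresponding whole-cohort screening cutoff: miRNA-centered
`max > 0.520` (lncRNA–mRNA pair), lncRNA-centered `min < −0.311`
(miRNA–mRNA pair), mRNA-centered `min < −0.305` (miRNA–lncRNA pair). The
negative cuts are deliberately crossed between classes: each class watches
the pair *not* containing the centered RNA, so the lncRNA-centered class
applies the miRNA–mRNA threshold and vice versa. All cutoffs are
configuration fields (`CoreConfig`) and can be re-derived from data by the
screening stage.

## Screening

Pairs are screened by whole-cohort SCC with count-based retention:
exactly `floor(retain_fraction * pool_size)` pairs (default fraction 0.001),
the most negative for miRNA–target types and the most positive for
lncRNA–mRNA. Boundary ties are broken by ascending (rna_a, rna_b) id so the
retained set is a deterministic function of the input. The realised
threshold is the SCC of the least extreme retained pair. Pairs with
undefined SCC (constant rows) are excluded before the quantile with a
logged count. A fixed-cutoff mode (−0.305 / −0.311 / +0.520) reproduces the
reference regime on arbitrary data. lncRNA–mRNA candidate pairs are formed
only from lncRNA/mRNA sharing at least one pool miRNA, not the full cross
product, since competition requires a shared miRNA.

## Permutation null and multiplicity

For each passing candidate, `n_permutations = 100` repetitions each draw two
disjoint uniform-random subsets of `subset_size` samples (default = the
window width, so null and observed SCCs share their sample size; drawing
requires `2·subset_size ≤ n`). The null ΔCor is `|SCC₁ − SCC₂|` and
`p = #(null ΔCor > observed ΔCor)/100`; repetitions with an undefined SCC are
redrawn (bounded, then an error). p-values are Bonferroni-corrected over the
*total* number of candidate triplets — everything evaluated, not just what
passed — and adjusted p < 0.01 is called significant. Each candidate's null
stream is seeded by the run seed plus a CRC-32 of its identity, so p-values
do not depend on candidate order or parallel scheduling. `p = 0` is reported
as 0; a `smoothed` flag switches to the (k+1)/(n+1) estimator.

**Calibration caveat.** The null statistic (difference of two random
subsets) and the observed statistic (range over ~n − w overlapping windows)
are not exchangeable: on fully independent data the observed range averages
≈ 0.35 (n = 376, w = 94) while the null differences have 95th percentile
≈ 0.29, so roughly 70% of independent triplets receive p < 0.05. These
p-values are therefore *screening scores*, not calibrated tail
probabilities; false positives are controlled in practice by the threshold
criteria (which independent data pass at < 5% per class, and the
miRNA-centered class essentially never) together with the Bonferroni step.
`PermutationConfig(null_mode="profile")` provides a calibrated alternative —
re-sort the samples by a random permutation and recompute the full window
range — which is exchangeable with the observed statistic by construction;
the two-subset null remains the default because it is the method's defined
behaviour. The acceptance script reports the measured fraction of
independent triplets with p < 0.05 under the default null.

## Expression filters

Rows are kept when (a) value > 0 in strictly more than 75% of samples,
(b) value > 5 in strictly more than 25%, and (c) log2 of the IQR > 0.58
(equivalently IQR > 2^0.58 ≈ 1.494 on the raw scale). "More than" is strict
throughout. Quartiles use the linear-interpolation quantile definition
(numpy's default); IQR = 0 fails (c) by definition (log2 0 = −∞).
An alternative reading of the variation criterion — IQR of log2(x + 1) —
is available via `FilterCriteria(log_iqr_mode="iqr_of_log2")`; log2-of-IQR
is the default. A keep-list hook stands in for annotation-based exclusions
(e.g. mRNAs without 3′-UTR annotation) decided upstream.

## Synthetic cohort

The generator emulates a bulk tumour cohort of n = 376 patients (making the
default window 94), with miRNA medians near 1e3 (RPM regime) and gene
medians near 10 (FPKM regime). Per planted triplet, latent miRNA activity
`A ~ lognormal(0, 1)`; observed miRNA = `1e3 · A ·` lognormal noise
(sd 0.2). Both targets are

```
gene_scale · f(A)^coupling · exp(c) · exp(e),
f(A) = basal + (1 − basal)/(1 + (A/K)^h),  K = median(A)
```

with defaults h = 8, basal = 0.05, coupling = 1, shared co-regulation
`c ~ N(0, 0.18²)` per sample, independent noise `e ~ N(0, 0.30²)`. The basal
floor matters: without it the log-repression keeps a slope of −h at high
miRNA and the window-SCC curve rises monotonically; with it the repression
saturates at *both* extremes, the shared f(A) component varies most where A
crosses K, and the window profile peaks at intermediate miRNA abundance —
the conditional signature the detector looks for. Under these defaults all
planted triplets clear the class-II criteria with ΔCor ≈ 0.6–0.8 and
whole-cohort SCC(miRNA, target) ≈ −0.85; `coupling = 0` together with
`shared_factor_sd = 0` yields exact nulls for negative controls. Null RNAs
are independent lognormals; the interaction pool lists the planted
miRNA→target edges plus random decoy edges among nulls. All draws come from
one seeded generator, so outputs are bitwise reproducible.

What the generator does **not** emulate: count noise (negative binomial
sampling), batch effects, compositionality of RPM/FPKM normalisation,
multi-miRNA regulation of one target, and correlated null structure.
Passing tests on this cohort show the machinery detects the planted
conditional-coupling mechanism at realistic magnitudes and noise — not that
real-tissue false-positive rates equal the synthetic ones.

## Problem sizes and numerical choices

The test-suite and acceptance workloads use the cohort size the method is
designed around (n = 376, w = 94) with 500 independent triplets for the null
study and 50 planted / 200 null triplets for recovery; the end-to-end
pipeline fixtures use n = 120 with 5 planted triplets, sizes chosen to keep
the full suite in the tens of seconds while exercising every stage at
realistic window counts. Window SCCs are computed by ranking each window
slice (`scipy.stats.rankdata`) and taking row-wise Pearson correlations via
einsum; values are clipped to [−1, 1] to absorb floating-point overshoot,
and the kernel agrees with per-slice `scipy.stats.spearmanr` to ~1e−16.
Output tables are written with a fixed `%.10g` float format so identical
runs are byte-identical.

## Known limitations

* The two-subset permutation p-values are anti-conservative as tail
  probabilities (see the calibration caveat); rely on the joint criteria +
  Bonferroni pipeline, or switch to the profile null, when calibrated error
  rates are needed.
* Each triplet is assessed in isolation; a gene pair regulated by several
  miRNAs is handled only through its separate triplets.
* Screening thresholds realised on small pools are noisy; the fixed-cutoff
  mode exists for transferring a reference regime, not for small-sample
  inference.
* The minimum window of 3 samples only guards degenerate configurations;
  windows that small carry almost no rank information.
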
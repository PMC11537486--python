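# Methods

## The problem and the model

Bulk tRNA-seq quantifies mature tRNAs by exploiting their conserved 3'-CCA
end; after mapping, the data are a small count matrix (a few hundred mature
tRNA species × samples).  The scientific question addressed here is whether a
condition (a polymerase III mutant genotype, "KI", versus wild type, "WT")
changes the **size** and **composition** of the cytoplasmic tRNA pool.
Because sequencing depth is arbitrary, a global change in pool size is
invisible unless counts are anchored to something whose per-cell (strictly,
per unit input RNA) abundance is condition-invariant.  Two anchors are used,
separately or jointly ("both", the default): a synthetic spike-in tRNA added
at known mass before library preparation, and the mitochondrially encoded
tRNAs, which are transcribed by the mitochondrial polymerase and are
unaffected in the condition this package models.  The validity of the mito
anchor is an assumption that must be checked per study (e.g. stable
mitochondrial genome content and mito transcript levels); the spike-in
depends only on accurate mass addition.  Agreement between the two anchors
is itself a useful robustness check and both single-anchor modes are
exposed.

## Filtering and size factors

Features with mean raw count across all samples ≤ 10 are removed before any
estimation.  The published threshold ("reads > 10") does not state whether
it applies per sample, per mean or per total; we default to the mean across
samples with `--filter-stat mean|min|total` as alternatives, and we filter
raw counts before size-factor estimation.  Control features are exempt from
removal (a below-threshold control is retained and logged), so the anchor
can never be filtered away.

Two estimators produce per-sample factors from the controls only:

* **sum_of_controls** — `factor_j = Σ_i K_ij` over control features.
  Exactly scale-equivariant: multiplying a sample's column by c multiplies
  its factor by c.
* **median_of_ratios** — the control-gene median-of-ratios estimator:
  each control is divided by its geometric mean across samples (controls
  containing a zero have geometric mean zero and are excluded), and the
  factor is the per-sample median of those ratios, used as-is with no
  rescaling.  The median of an even number of ratios is the mean of the two
  central values.  Scale equivariance holds up to a global constant, because
  scaling one column also moves every control's geometric mean by c^(1/n);
  all *relative* quantities (relative totals, fold changes, pool fractions)
  are exactly invariant, which is what matters downstream.

The total-abundance statistic divides each sample's summed nuclear counts by
its factor and expresses it relative to the WT mean; the group contrast is a
two-sided Welch (unequal-variance) t-test on those relative values — a
robust default for unbalanced groups (the study design is 6 WT vs 4 KI);
the test behind the published group comparison is not stated.

## Differential expression

Counts are modelled per feature as negative binomial,

    K_ij ~ NB(mu_ij, alpha_i),    mu_ij = s_j * exp(beta0 + beta1 * x_j),

with `s_j` the size factor entering as an offset, `x_j` the KI indicator and
`Var = mu + alpha * mu^2`.  The genotype term is tested by a likelihood-ratio
test (2·Δloglik, floored at 0, against χ² with 1 df), with Benjamini–Hochberg
adjustment across features and significance at adjusted p < 0.05.  Decoder-
level analysis sums member isodecoder counts per family — reads are conserved
exactly — and reuses the isodecoder-level size factors rather than
re-estimating them on sums.

**Fitting.**  The GLM is maximized by iteratively reweighted least squares
with weights `mu/(1+alpha*mu)`, started at the factor-weighted group means.
In the Poisson limit, or with equal size factors, those starting values are
already the exact MLE; with overdispersion and unequal factors the IRLS
solution differs slightly because the NB score downweights high-mean
samples.  The linear predictor is clipped at ±30, which turns the
all-zero-group case into a well-behaved boundary fit (flagged, coefficient
at the clip).  No pseudocounts are ever added.

**Dispersion.**  `alpha_i` is estimated per feature by maximizing a
Cox–Reid-adjusted profile likelihood, `ll(alpha) − ½·log det(XᵀWX)`, with the
fitted mean held at the factor-weighted overall mean (the reduced-model MLE),
started from a method-of-moments estimate on normalized counts and clamped
to [1e-8, 10].  Two deliberate choices are embedded here:

* *Reduced-model means.*  Estimating dispersion with means fixed under the
  full (two-group) model uses up the genotype degree of freedom and
  systematically underestimates `alpha` at n ≈ 10, inflating the LRT;
  measured on simulated null data of the study's design the fraction of
  features at p < 0.05 was 0.13 (plain ML) and 0.10 (Cox–Reid, full-design
  means).  Fixing the means under the reduced model folds both the genotype
  sampling variation and residual normalization noise (size factors are
  estimates, and their error is shared across features within a sample but
  unmodeled by the NB) into the dispersion.  This is conservative by
  construction — a truly differential feature gets a slightly inflated
  `alpha` and hence a slightly deflated statistic — and brings null
  calibration to 0.048 at nominal 0.05 in the same simulations.  With ten
  samples and no information sharing across features, we prefer a test that
  errs conservative.
* *No empirical-Bayes shrinkage.*  Dispersion-shrinkage machinery (trend
  fitting, prior degrees of freedom) is deliberately out of scope; the
  estimator is pluggable (`run_de(dispersion_fn=...)`) for users who want to
  substitute one.

One shared `alpha` per feature is used for the full and reduced fits, making
the LRT well-defined.  Per-feature failures (e.g. all-zero features) are
recorded in the output's `note` column without aborting the run.  No
independent filtering or outlier (Cook's distance) handling is applied;
filtering is explicit and up front.

## Decoder profile

Fold change is the ratio of group means of normalized counts (KI/WT), with
log10 mean WT reads carried for MA-style plots; a WT mean of zero leaves the
fold change undefined (flagged, never imputed).  The pool profile expresses
each decoder's normalized reads as a percentage of the sample's total
decoder pool; per-genotype summaries are mean ± SEM (sample SD / √n, n =
biological replicates).  Group-mean percentages sum to exactly 100 within
each genotype.  An ordinary least-squares line with intercept relates mean
KI% to mean WT% across decoders (a through-origin variant is available);
decoders flagged `significant_lower` (decoder-level adjusted p ≤ 0.05 and
fold change < 1) are the profile's headline set.  Z-score heatmap matrices
standardize each feature row to mean 0 / SD 1 (n−1 divisor); zero-variance
rows are dropped with a warning.

Two-tissue comparisons use a paired two-sided t-test on per-decoder log2
fold changes, pairing by decoder family after an inner join (a Welch
unpaired variant is available; which test produced the published tissue
contrast is not stated).  All-zero paired differences return p = 1 by
convention.  DE-set overlaps are plain set arithmetic on the
adjusted-p < threshold sets.

## Decoding capacity

Anticodon position 34 pairs with codon position 3 under wobble rules;
positions 35–36 pair Watson–Crick with codon positions 2–1.  The default
table — A34→{U,C}, G34→{C,U}, C34→{G}, U34→{A,G} — reproduces the published
decoding fractions for the four decoders highlighted in the study (Tyr-GTA
100%, Ser-AGA 41%, Val-AAC 42%) with genome-wide mouse codon usage; Gln-CTG
evaluates to 74.0% where 75% was printed, within rounding of an unspecified
usage source.  An alternate table treating A34 as inosine (reading U, C, A)
is provided; it does not reproduce those fractions and is not the default.
The decoding fraction of a family is Σusage(decoded ∩ synonymous) /
Σusage(synonymous) and is invariant to rescaling of the usage weights.
Special cases: iMet decodes AUG but is reported separately from elongator
Met; the suppressor/selenocysteine family (Sup-TCA) would read the UGA stop,
which has no amino-acid assignment under the standard code, so its fraction
is reported as explicitly undefined rather than a number.  Ile-TAT under the
unmodified default table would also reach AUG; in vivo a U34 modification
restricts it to AUA — since fractions always intersect decoded codons with
the isotype's synonymous set, this leak never mis-assigns usage.  The
packaged usage table is the widely reproduced genome-wide mouse per-1000
frequency table; all usage-dependent outputs record which table was used.

## The simulator: what it emulates and what it does not

`simulate_counts` draws `K_ij ~ NB(s_j · q_i · 2^(x_j·LFC_i), alpha_i)` with:

| parameter | default | meaning |
|---|---|---|
| n_wt / n_ki | 6 / 4 | unbalanced study groups |
| n_nuclear_genes / n_families | 187 / 50 | detectable isodecoders / decoder families |
| n_mito | 22 | mitochondrial tRNAs (condition effect exactly 0) |
| baseline_log10_range | (0.5, 5.5) | log-uniform baselines, ~5 decades |
| spike_log10_abundance | 5.0 | one spike-in, fixed large abundance, effect 0 |
| depth_factor_range | (0.5, 1.5) | per-sample depth multipliers |
| global_lfc | log2 0.75 | global KI effect (~25% reduction) |
| family_lfc_sd / gene_lfc_sd | 0.25 / 0.15 | per-family / per-gene log2 deviations |
| dispersion a0 + a1/q | 0.01 + 2/q | mean-dependent overdispersion trend |

The decoder families are the real (isotype, anticodon) pairs of the mouse
nuclear tRNA set, so registry, profiling and capacity stages all operate on
biologically meaningful names.  The per-gene effect is composed additively
in log2 (global + family deviation + gene deviation); the truth tables
record the realized sums, baselines, dispersions and depth factors exactly
as used.  The deviation SDs are not published quantities; they were chosen
once so that default-simulated decoder fold changes span roughly the
0.5–0.9 range the study reports, and are freely configurable.  Mito
baselines are drawn from the upper half of the abundance range, mimicking
the high abundance of mitochondrial tRNAs in brain total RNA.
`affected_family_fraction` / `affected_family_lfc` (default off) inject a
fixed extra effect into a random subset of families for power studies.

The simulator starts at the count level.  It does not model raw reads,
ligation or RT biases, tRNA modifications that impede reverse transcription,
multimapping between near-identical isodecoders, or correlated biological
replicates.  Passing tests therefore demonstrate the statistical machinery
under the NB design assumptions, not robustness to tRNA-seq's upstream
artifacts.

## Numerical choices

* Dispersion clamp [1e-8, 10]; optimization on log alpha (bounded scalar
  search, xatol 1e-8); the best of {lower clamp, MoM start, optimizer
  solution, upper clamp} by adjusted likelihood is returned, so degenerate
  features (constant counts) land exactly on the clamp.
* IRLS convergence at max |Δbeta| < 1e-10, ≤ 100 iterations;
  non-convergence is reported per feature, never silently ignored.
* LRT statistic floored at 0 (boundary noise can make it ≈ −1e-12).
* Results are deterministic given inputs; permuting samples or features
  permutes outputs correspondingly (verified to ~1e-6, the tolerance set by
  floating-point summation order inside the optimizer).
* Identical-sequence locus collapsing normalizes U→T and merges byte-equal
  sequences; merging sequences annotated with different anticodons is an
  error, and the operation is idempotent.

## Known limitations

* The mito-anchor assumption fails if the condition alters mitochondrial
  genome content or transcription; use spike-only mode in that case.
* Without dispersion shrinkage, power at n = 6+4 is modest for features with
  high dispersion; the conservative dispersion choice trades power for
  type-I control.
* The decoder-level analysis reuses isodecoder-level size factors; whether
  re-estimation on summed counts would be preferable is unresolved and both
  choices are defensible (the difference is a per-sample constant absorbed
  by relative statistics).
* The wobble table is unmodified-anticodon logic; modification-aware
  decoding (e.g. mcm5s2U effects) is out of scope.
* iMet and elongator Met families can be merged via `merge_imet`, but the
  default keeps them distinct.
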
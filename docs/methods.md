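# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would want to know.

## Data model

One LA-ICP-MS ablation line yields a vector of element:Ca ratios
(µmol mol⁻¹ relative to ⁴²Ca) plus metadata (sample, life stage, site,
region, date, collection method, shell portion). Below-LOD cells are carried
as explicit flags; they are excluded from replicate means and never imputed.
An element leaves the analysis only as a whole column, when its below-LOD
fraction among brood records exceeds a threshold (default 0.5) — mirroring
how LOD-bound elements are handled in shell-chemistry studies, where partial
imputation would distort the multivariate signature.

Replicate ablations (10 per brood by default) are arithmetically averaged on
the ratio scale to one signature per brood. All multivariate analyses then
run on natural-log ratios, standardized to mean 0 / variance 1 per element.
Standardization parameters are a first-class object (`TransformParams`) so
held-out samples and settlers are always pushed through the *brood-fitted*
transform — the leakage-free path. By default center/scale are fitted once
on the full brood analysis set; a strict mode refitting within each
cross-validation fold exists but is not the default, because the global fit
is what classical fingerprinting workflows do and the difference on the
packaged data is negligible.

**Outlier rule.** Published workflows typically say only that "outliers were
removed". Here the rule is explicit and logged: on the log scale, within
each group, a sample is removed when any element's robust z-score
(median/MAD, MAD × 1.4826) exceeds 3.5 in magnitude. The rule runs before
standardization, is pluggable, and refuses to remove more than 20% of the
samples (misconfiguration guard). Ordering (outliers judged on log, before
standardization) is a declared choice.

## Synthetic data

Regional signatures are multivariate lognormal: brood truth ~
N(μ_region, Σ) on the log scale, each ablation adds independent log-normal
noise, values are exponentiated. This makes the pipeline's log-normality
assumptions true by construction — deliberately, since the tests are about
the inference machinery, not about distributional robustness. Baseline
magnitudes (Mg:Ca ≈ 2000, Sr:Ca ≈ 1600, P:Ca ≈ 900, Fe:Ca ≈ 200 µmol mol⁻¹,
down to U:Ca ≈ 0.08) are typical shell-carbonate values; log-scale SDs are
0.18–0.6 with a mild common correlation (0.15) between elements.

The packaged dataset mirrors the shape of a regional brood survey: three
regions (CS/NS/Seq) with 49/33/12 broods, 10 ablations each, three
LOD-prone extra columns (Cu, Ga, Pb, flagged ~90% of cells), collection
dates spread over a mid-June–mid-August season. Regional contrasts load on
different elements per region (NS high Fe/Zn, CS high Ba/P, Seq high U with
a Mn contrast); a single separation scalar multiplies all contrasts and was
calibrated once so the optimized regional jackknife accuracy lands in the
70–80% band that regional shell-chemistry discrimination typically
achieves. The 154-settler cohort draws 85% of settlers from an
extra-baseline component displaced ≥ 3 within-region-Mahalanobis units from
every region mean (direction loading on Mn and Fe up, P and Ba down) with
3× inflated covariance, and the remaining 15% evenly from two baseline
regions with 2× dispersion — emulating a settler pool whose natal sources
were mostly not sampled and whose measurement pathway differs from the
brood pathway. A separate 9-brood set (4 anesthetic, 5 lethal) carries a
small anesthetic shift (+0.6 log-SD on Mg:Ca, −0.2 on Sr:Ca), sized to
produce the "statistically detectable, ecologically minor" method effect
(ANOSIM R ≈ 0.1).

What passing tests on these data do **not** show: robustness to
non-lognormal signatures, temporal drift within a season (the generator has
none — dates are decorative), spatial structure below the region level,
instrument drift, or the brood-vs-settler methodological mismatch beyond a
mean shift plus variance inflation.

## Classification

LDA is implemented from its definition. With pooled within-class covariance
`W` (denominator n − g, unbiased) and between-class scatter `B` (group-size
weighted, same denominator), the axes solve the generalized eigenproblem
`B a = λ W a` (via `scipy.linalg.eigh`), giving min(p, g−1) axes normalized
to `aᵀW a = 1`; eigenvalue shares are the proportion-of-trace per canonical
axis. Signs are fixed by orienting each axis so its largest-magnitude
loading is positive (the math leaves signs free; plots and tests need a
convention). Classification uses the shared-covariance Gaussian
discriminant `xᵀW⁻¹μ_k − ½μ_kᵀW⁻¹μ_k + log π_k` with softmax posteriors.
Priors default to group proportions (the conventional default, and the
reason the jackknife on unbalanced groups needs the bootstrap as a
counterweight); uniform priors are a flag away. Ties in the argmax resolve
to the first class in declared (first-appearance) order.

Leave-one-out validation downdates per-class sums and scatters instead of
refitting from scratch, making the exhaustive search over all 511 subsets
of the 9-element panel run in seconds. Ties in the subset search resolve
toward fewer elements, then lexicographically. Subsets with singular fold
covariances are skipped and reported, never silently scored. The 90/10
bootstrap stratifies the split by group (every class stays trainable; an
unstratified mode exists), runs 5,000 replicates by default, and reports
the mean with 2.5/97.5 percentile CIs; classes absent from a replicate's
test split contribute only where they appear.

95% confidence ellipses on 2-D canonical scores use the group mean, sample
covariance (ddof 1) and the χ²₂ 0.95 quantile; membership is boundary-
inclusive. Empirical coverage is verified by simulation (100,000 draws).

## Univariate contrasts

Per-element one-way ANOVA (`scipy.stats.f_oneway`) and Tukey–Kramer HSD
(`scipy.stats.tukey_hsd`, studentized-range adjusted, harmonic handling of
unequal n) run on log-transformed but *unstandardized* ratios — the
contrasts should be in interpretable log-ratio units, and standardization
would not change F anyway.

## Ordination and ANOSIM

Gower dissimilarity is the range-normalized mean absolute difference
(values in [0, 1]); all nine ratios enter, already log-standardized by the
pipeline, though Gower's own range normalization makes the standardization
nearly moot (a configurable choice). ANOSIM uses average ranks of the
condensed dissimilarities, R = (mean between-group rank − mean within-group
rank)/(M/2), and a seeded label-permutation p-value with the +1 correction
(default 999 permutations). NMDS minimizes Kruskal stress-1 by a
monotone-acceptance SMACOF: each iteration refits isotonic disparities
(pool-adjacent-violators on the dissimilarity order; ties averaged) and
applies a Guttman transform, and a step that fails to lower stress-1
terminates the start — so the recorded stress trajectory is non-increasing
by construction. 100 random starts by default (the drivers use 25; the
best-of-starts stress is stable well before that on these n ≤ 40 problems);
the lowest-stress start wins, and configurations are centered (rotation and
reflection remain free, as stress is invariant to them).

The early/late season boundary is a config value (default 2015-07-05).

## Settler assignment

Three diagnostics, all strictly brood-fitted:

1. **Projection**: settlers pass through the frozen brood transform and
   axes; the report counts settlers outside every region's 95% ellipse.
2. **Extra-baseline probability**: per region, a multivariate normal on
   selected log ratios (default Mn:Ca + Sr:Ca — the pair that separates
   regions and shifts in settlers under the generator's mismatch); each
   settler's squared Mahalanobis distance gives a χ²_df tail probability,
   and the outside-probability is 1 − max over regions. Flagged when it
   exceeds the confidence level (default 0.95). Regions need ≥ 5 broods on
   the selected elements. The flagged fraction doubles as a baseline-
   mismatch diagnostic: the pipeline warns (and the assignment drivers say
   so) when it exceeds 0.5, before anyone reads the mixture proportions.
3. **Mixed-stock MLE**: mixture weights over baseline regions by EM with
   the component densities fixed at their baseline fits. Because only the
   weights move, each iteration is a responsibility average, the
   log-likelihood is monotone non-decreasing (asserted), and the whole fit
   is a few matrix operations on the precomputed n × K log-density matrix.
   CIs resample settlers with replacement (default 500 replicates) and
   rerun EM on the resampled density rows; they therefore quantify
   settler-sampling variation under the fixed-baseline model, not baseline
   estimation error — the calibration test draws settlers from the fitted
   densities themselves for exactly this reason.

Both LDA-posterior and MLE assignment are computed even when the mismatch
diagnostic fires; the warning, not a refusal, mirrors how such results
should be read (proportions then describe only the in-baseline share).

## Mixture clustering

A finite Gaussian mixture at fixed K is explored by conjugate Gibbs
sampling: categorical membership draws, Dirichlet(α = 1) weight draws, and
Normal–Inverse-Wishart component draws (prior mean = data mean, κ₀ = 0.01,
ν₀ = p + 2, prior scatter = data covariance — a weak, unit-information-style
prior that keeps empty components proper). Label switching is resolved by
sorting components on the first coordinate of their means in every retained
sweep before averaging. Diagnostics record empty-component persistence
(warned above 50% of sweeps) and split-half log-likelihood means.

Model selection fits K = 1..K_max (default 4, guard ≤ 8), several chains
per K, scores each K by BIC at the posterior-mean parameters of its best
chain, and selects the *smallest* K within 2 BIC units of the optimum — a
small-K preference in the spirit of "not worth more than a bare mention"
evidence thresholds, which protects against spurious extra clusters.
Defaults in the drivers are 1,500 sweeps / 400 burn-in / 3 chains; the
acceptance runs use the same, and chain-length stability (same selected K
at double the sweeps) is asserted in the tests. DIC-from-chain selection is
noted as an alternative but not implemented.

## Problem sizes used in tests and drivers

The suite exercises the chain at the packaged scale (92 broods after
outlier removal, 154 settlers, 511 subsets, 5,000 bootstrap replicates) and
scales simulation-based calibration checks to what they need statistically:
ANOVA type-I error at 10,000 simulations, ellipse coverage at 100,000
draws, mixture-CI coverage at 100 replicates × 300 settlers × 300
bootstrap resamples, K-recovery at 15 seeded replicates per scenario with
300-sweep chains (selection behavior at this scale is already
deterministic enough for a ≥ 90% recovery bound).

## Known limitations

- Subset selection by jackknife and reporting the winner's jackknife
  accuracy shares data between selection and evaluation; the bootstrap
  mitigates but does not remove selection optimism (no nested CV).
- The extra-baseline probability treats baseline parameters as known;
  with 12 broods in the smallest region the χ² tail is mildly
  anticonservative.
- NMDS tie handling averages tied dissimilarities (secondary approach);
  with continuous synthetic ratios, exact ties do not occur.
- The Gibbs sampler is a fixed-K explorer with BIC selection, not a
  trans-dimensional (reversible-jump) or Dirichlet-process sampler.
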
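# Methods

## Model and rationale

Whole-blood expression of gene *g* in donor *i* is treated as a two-lineage
mixture. With myeloid fraction *fᵢ* (lymphoid fraction 1 − *fᵢ*; the two are
strongly anti-correlated in blood, so one degree of freedom suffices), dosage
*Gᵢ* and per-lineage allelic effects *b_m*, *b_l*, the bulk signal is

    Y_gi = fᵢ·(a_m + b_m·Gᵢ) + (1 − fᵢ)·(a_l + b_l·Gᵢ) + ε_gi .

The genotype slope is therefore fᵢ·b_m + (1 − fᵢ)·b_l: constant in *fᵢ* when
the two lineages agree (b_m = b_l, a "generic" eQTL) and linear in *fᵢ*
otherwise. Regressing expression on `[1, G, P, G·P]`, where *P* is a
standardized stand-in for *fᵢ*, turns lineage mediation into the interaction
coefficient β₃ = (b_m − b_l)·sd(f). Two consequences worth keeping in mind:

* β₃ is the per-cell effect *difference* scaled by the population SD of the
  cell fraction (≈ 0.08 for neutrophils). Detectable interactions therefore
  need either large per-cell effects or large samples — the motivation for
  the weighted-Z meta-analysis across cohorts.
* Under b_m = b_l the interaction is exactly zero whatever covariate is used,
  so the type-I error of the test does not depend on proxy quality. Proxy
  quality governs power only.

The proxy is the first principal component of the marker-probe correlation
matrix (probe-space PCA; scores by projection), with markers chosen in a
training cohort for positive Spearman correlation with measured percentages.
Because eigenvector sign is arbitrary, the component is oriented so scores
correlate positively with mean marker expression; markers were selected for
positive correlation with the percentage, so this anchor preserves the
intended direction in cohorts that have no counts at all.

## Pipeline order and normalization choices

Per cohort: quantile normalization to the per-rank median distribution →
PC1-based array QC → log2 (optional) and double centering → covariate
residualization (e.g. genotype MDS components, supplied as a file) →
principal-component correction for the interaction response.

* **Quantile normalization** maps each column through the per-rank median of
  the sorted columns; ties receive the average of the reference values at the
  tied ranks, which makes the map deterministic and exactly idempotent on
  tie-free input.
* **Array QC** computes the first eigenvector of the sample×sample
  correlation matrix, forms the reference profile (expression projected onto
  it), and drops samples correlating below 0.9 with that profile. This runs
  on the *uncentered* quantile-normalized matrix: the shared probe-mean
  profile is what good arrays have in common, and only there does a 0.9 cut
  separate deviating arrays; after probe centering roughly half the samples
  correlate negatively with any reference and the threshold loses its
  meaning.
* **PC correction** removes the strongest components of the sample
  correlation structure (default 40, truncated to the rank bound on small
  matrices) from the interaction response, *except* components under
  detectable genetic control: each component score is regressed on every SNP
  dosage and components with a minimum association p below 5×10⁻⁸
  (configurable; the threshold for calling a component genetic is a package
  choice) are retained. The removed components absorb most of the
  composition-driven expression variance, which deliberately reduces
  collinearity between *P* and *Y* at some cost in interaction signal. The
  report object records both the removed and the skipped component indices,
  so either the "exactly 40" or the "up to 40" reading of the correction is
  auditable.
* The **proxy** is always built from expression *not* PC-corrected (the
  correction would strip exactly the composition signal the proxy needs);
  the interaction response always *is* PC-corrected.

Numerical conventions: PCA components come from correlation matrices with
scores standardized to unit variance and signs anchored to the mean
expression profile; double centering iterates to 1e-8 (≤ 100 sweeps); OLS uses
explicit normal equations with a condition-number guard (> 1e12 → collinear);
marker-selection ties break by probe identifier; LD-pruning ties break by
(p-value, SNP identifier).

## Statistics

* **Meta-analysis:** Z = Σ√nᵢ·Zᵢ / √(Σnᵢ). Pairs testable in fewer than two
  cohorts are dropped by default (configurable to one). Skipped pairs
  (monomorphic SNP, low n, minor genotype group < 3, collinear design,
  missing identifiers) contribute nothing and are logged with reason codes.
* **Effective tests:** n_eff = 0.5 / mean(min p per permutation), with
  permutations shuffling genotype sample labels within cohort — this breaks
  genotype–expression and genotype–proxy linkage while preserving the
  expression–proxy covariance, which is the relevant null. The 0.5 numerator
  is kept exactly as the source method states it even though the mean minimum
  of M independent uniforms is 1/(M+1); the estimator therefore returns
  ≈ (M+1)/2 on independent tests ("about half the number of tests"), and that
  behavior is asserted, not corrected. Default 100 permutations
  (configurable; the original count is not stated).
* **FDR:** candidate thresholds are the observed p-values; FDR(t) =
  t·n_eff / #{p ≤ t}; the call threshold is the largest t with FDR ≤ the
  level. The threshold search is a step function over observed p-values, not
  a continuous grid. Benjamini–Hochberg is deliberately not the primary path.
* **Directions:** significant pairs with Z > 0 are myeloid-mediated, Z < 0
  lymphoid-mediated, the rest generic.
* **Robust SEs:** HC0 and HC3 sandwich estimators are available for the
  interaction term; classical SEs are the default, with the robust variant
  used as a sensitivity check (classical and HC3 Z-scores correlate > 0.95
  under mild heteroscedasticity in the test suite).
* **Enrichment:** greedy LD pruning (keep most significant, discard r² ≥ 0.2
  neighbors, missing r² treated as 0 and counted), then an exact one-tailed
  binomial tail P(X ≥ k) for k mediated among n pruned eQTL SNPs against the
  background proportion. The background defaults to the trait-agnostic
  fraction of mediated SNPs among all tested eQTL SNPs; the original text is
  ambiguous on this set, and this definition keeps the binomial null
  coherent. Traits with ≤ 20 eQTL SNPs after pruning are skipped. When no
  r² table is supplied, r² is the squared dosage correlation in a designated
  reference cohort.
* **Replication:** absolute dosage–expression Pearson correlations, compared
  between mediated and generic groups by a one-tailed Mann–Whitney test
  (exact enumeration when both groups ≤ 10 and tie-free; otherwise the
  normal approximation with tie correction). Absolute values are compared
  because allele coding differs across datasets; the one-tailed direction is
  fixed as mediated > generic.

## Synthetic data: what it emulates and what it does not

The generator produces per-cohort fixtures with: truncated-normal myeloid
fractions (mean 0.60, SD 0.08 — neutrophils are ~60% of leukocytes, and
population neutrophil percentages vary by several points); LD-blocked
Hardy–Weinberg dosages (a per-block latent allele copied with probability
√r, giving within-block dosage correlation r; the allele frequency is drawn
uniformly once per block, since a shared latent allele requires a shared
frequency); marker probes that are noisy copies of *f* (SD 0.02 by default);
eQTL probes following the mixture model above; and background probes with
per-probe baselines (SD 2.0 log-units, shared across cohorts as on a common
platform) plus per-probe composition loadings on *f* (SD 2.0). The loadings
make cell composition a transcriptome-wide factor, as it is in real blood —
without them, PC correction would have nothing composition-related to remove
and the array-QC reference profile would be meaningless. Cell counts
(100·f) are emitted only for cohorts flagged as having them (default: the
first cohort, the training cohort). All randomness flows from one seed
through named substreams, so fixtures are bit-reproducible and adding draws
to one stage never perturbs another.

Not emulated: batch or array artifacts, probe cross-hybridization, more than
two lineages, covariates such as age and sex, realistic LD decay, or
measurement models in which noise scales with intensity. Passing tests
therefore demonstrate the statistical machinery under the stated mixture
model, not robustness to microarray pathology.

## Validation experiments (what the reporting script computes)

* Analytic identities: 0.5/8.15×10⁻⁵ ≈ 6134 effective tests; two-tailed
  p = 0.009 ↔ |Z| = 2.61; a pruned disease table with 49 independent eQTL
  loci of which 11 (22%) are mediated.
* Oracle agreement: interaction coefficients and SEs match an explicit
  (XᵀX)⁻¹Xᵀy computation to better than 1e-8 on 100 random instances
  (statsmodels serves as a second, independent cross-check in the test
  suite).
* Null calibration: 2,000 pairs with b_m = b_l across 3 cohorts × 500
  samples, run through the marker → proxy → scan → meta chain; the
  empirical |Z| > 1.96 rate sits within 0.05 ± 0.015 and the meta-Z variance
  within [0.9, 1.1].
* Proxy recovery: 100 replicates at marker noise 5% of sd(f); Spearman with
  the true fractions ≥ 0.7 in ≥ 95% of replicates.
* Power ordering: equal per-cell effects are planted in the myeloid
  (abundance 0.6) or lymphoid (0.4) lineage. In the additive mixture the
  interaction coefficient is ±(b·sd(f)) with identical sampling variance, so
  a single-stage interaction test has exactly symmetric power; the observed
  myeloid/lymphoid asymmetry arises from the two-stage design, in which
  candidates must first be discovered by the generic single-marker model and
  the bulk main effect scales with lineage abundance (0.6·b vs 0.4·b). The
  experiment therefore screens pairs through a pilot-study generic discovery
  stage (n = 80, |Z| ≥ 4.5) before interaction testing (3 × 300 samples,
  |Z| ≥ 2.61), and counts end-to-end detections per class; the abundant
  lineage is detected at a consistently higher rate (roughly 0.78 vs 0.62
  across seeds at per-cell effects uniform in [0.5, 1.0]).

Problem sizes throughout (hundreds of samples per cohort, tens of SNPs and
hundreds of probes in pipeline fixtures) are chosen so the full suite runs
comfortably on a laptop while keeping every estimate's Monte-Carlo error well
inside its assertion band; where an assertion is statistical, the band is
3σ-or-wider for the simulated sample size.

## Known limitations

* One proxy, two lineages: no simultaneous multi-cell-type deconvolution, and
  a lymphoid "lineage" that is internally heterogeneous in real blood is
  modelled as homogeneous.
* Quantile normalization with few probes (tens) visibly quantizes small
  signals; pipeline fixtures use ≥ 300 probes for that reason. Real arrays
  (tens of thousands of probes) are far past this regime.
* The FDR construction inherits the conservatism/anti-conservatism of the
  0.5-numerator effective-test estimate; at very small candidate panels the
  realized false-discovery proportion is noisy (a rate, not a per-call
  guarantee).
* MDS/population-structure covariates are consumed as a precomputed file;
  computing them from genotypes is out of scope.
* Candidate pairs are supplied explicitly; there is no cis-window discovery
  of new eQTLs and no conditional/secondary-signal analysis.
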
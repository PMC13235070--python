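# Methods

This note documents the statistical models, the simulator, the numerical
choices and the known limitations of `duckgs`.

## Analysis workflow

The package implements the genomic-evaluation workflow of a commercial
discrete-generation poultry nucleus in which every bird is genotyped
(originally for parentage assignment), so pedigree-based BLUP and
marker-based GBLUP can be compared on identical data:

1. **SNP QC** — per-SNP minor allele frequency and exact Hardy–Weinberg
   equilibrium test; markers with MAF < 0.05 or HWE p < 1e−6 are removed.
   Both comparisons are strict, so a marker sitting exactly on a
   threshold is retained. No call-rate or per-individual filters are
   applied. The HWE test is the standard exact conditional test (no
   mid-p): conditioning on the observed allele counts, it sums the
   probabilities of all heterozygote counts no more probable than the
   observed one. Weights are evaluated through log-gamma functions,
   which keeps the test vectorizable and accurate to ~1e−13 relative; a
   tie tolerance of 1e−12 reproduces exact-rational enumeration on all
   tested totals.
2. **Relationship matrices** — pedigree **A** by the tabular method over
   a generation-sorted pedigree (diagonal 1 + F); genomic **G** by
   VanRaden's first method, `G = ZZ′ / (2 Σ p(1−p))`, with missing
   dosages mean-imputed per SNP before centering. Allele frequencies
   default to those observed in the full analysis set (training plus
   validation birds): all birds are genotyped in this design and
   base-generation frequencies are unavailable. No blending of G with A
   and no weighting is used; the only conditioning device is an explicit
   ridge (default 0.01) added to the diagonal when the smallest
   eigenvalue falls below 1e−8, always logged with a warning and
   recorded in `ridge_applied`. Note that with observed frequencies G is
   always singular (Z columns sum to zero), so the ridge fires routinely
   on G; its effect on estimates at ridge = 0.01 is negligible relative
   to sampling error.
3. **Fixed-effect pre-correction** — OLS per trait with treatment
   coding; residuals y* are the adjusted phenotypes. Trait model map:
   early-life and score traits (JW, PRF, GAIT, FPD) and ADG carry
   `sexhatch` (a single combined sex-by-hatch factor) and dam-age class;
   finishing traits (BW, BD) additionally carry feeding pen; BD is
   corrected for BW as a covariate (BW cannot be its own covariate; the
   covariate's scope was ambiguous and is configurable). ADG's pen term
   is likewise configurable; the default carries the early-life terms.
   Pre-correction is fitted on all generations jointly, before masking —
   a deliberate, documented leakage trade-off that mirrors how such
   two-stage analyses are run in practice; its impact is limited to the
   fixed-effect estimates. Ordinal scores (gait, foot-pad) are analysed
   as linear traits, exactly as the two-stage linear workflow does.
4. **REML / BLUP** — single random effect plus residual:
   `y* = 1μ + u + e`, `u ~ N(0, σ²_g K)`. With the eigendecomposition
   `K = U diag(d) U′`, rotating by `U′` makes the covariance diagonal
   and the restricted likelihood a smooth 1-D function of
   h² = σ²_g/(σ²_g + σ²_e) after concentrating out the total variance.
   The profile is maximized by bounded scalar search on
   [1e−4, 0.9999] with tolerance 1e−6; this is exact (no AI/EM
   iterations), costs one O(n³) factorization per kernel — reusable
   across traits sharing a phenotyped set — and is adequate to n in the
   low tens of thousands. Boundary optima are reported with a flag, not
   errored. The h² standard error comes from the numerical curvature of
   the profile log-likelihood at the optimum (observed information on
   the h² scale, central differences with step 1e−3). EBVs are the
   conditional means `σ²_g K[·,t] V_t⁻¹ (y* − 1μ̂)` with μ̂ the GLS
   intercept; this equals the Henderson mixed-model-equation solution
   (verified against an explicit MME solve in the tests) and extends to
   phenotype-masked birds through their K rows.
5. **Forward validation** — phenotypes of the target generation are
   masked; training uses all earlier generations. Reported per trait
   and matrix kind: predictive correlation r of EBV with the masked
   birds' adjusted phenotypes; accuracy r/√h² using the
   training-generation h² of the matching matrix kind; dispersion slope
   b of the whole-data EBV (the "true" EBV, re-estimated with the
   validation phenotypes unmasked, same matrix kind) on the masked-data
   EBV over validation birds only; and the standardized bias
   b̃ = 1 − b (b < 1) or 1/b − 1 (b ≥ 1). The map is continuous at
   b = 1; for b ≤ 0 the first branch exceeds its nominal (−1, 1] range
   and a warning is emitted rather than clipping. The partial/whole
   LR-statistic suite is intentionally not implemented.
6. **Imputation evaluator** — per-SNP Pearson correlation between true
   and imputed dosages over a masked bird set, with per-chromosome and
   genome-wide means; SNPs with a constant true or imputed vector are
   reported as undefined and excluded from means. Only naive baselines
   are shipped (population-mean fill and parent-average fill, the
   Mendelian expectation); a production imputation algorithm is out of
   scope — the evaluator measures whatever imputed matrix it is given.

## The simulator

The generator emulates the structure the analysis assumes, not any
particular flock:

* **Pedigree** — discrete non-overlapping generations (numbered from 1;
  founders have both parents unknown, coded 0); open-pen mating where
  the previous generation is partitioned into pens of `sires_per_pen`
  males (default 5) and `dams_per_pen` females (default 30) and each
  offspring draws its sire and dam uniformly within a random pen,
  creating realistic full- and half-sib family structure; sexes
  balanced. No selection is applied by default (real lines are under
  selection of unstated intensity; selection would mainly shift
  variance-component levels, not the G-vs-A comparisons the tests
  make).
* **Genotypes** — gene dropping on a uniform random genetic map, one
  Morgan per chromosome (1 cM/Mb over a nominal 100 Mb chromosome),
  Haldane (no-interference Poisson) recombination, no mutation, no
  genotyping error, no missingness. Founder allele frequencies draw a
  MAF uniformly on [0.05, 0.5]; two lines drift apart around the shared
  ancestral frequency by a Balding–Nichols Beta draw with Fst = 0.10,
  which reproduces the qualitative two-cluster PCA separation of
  distinct selection lines. How much variance PC1 explains is
  data-dependent and not a target.
* **Traits** — phenotype = mean + fixed effects + TBV + residual. The
  TBV is a dosage-weighted sum of `n_causal` (default 300) causal-SNP
  effects drawn from a zero-mean normal, centered and rescaled so its
  realized variance is exactly `h² · SD²`; the residual SD is
  `SD · √(1 − h²)`. Fixed-effect levels (sexhatch = pedigree sex ×
  random hatch batch of 4, dam-age class of 5 — the class coding is a
  choice, none is prescribed — and 10 feeding pens) default to
  zero-mean normal per-level effects with SD 0.15 × trait SD, so the
  realized phenotypic SD stays within ~3% of the target; explicit
  per-level effect maps can be supplied, and an empty map disables
  fixed effects. Ordinal traits (gait, foot-pad score) are generated as
  Gaussian liabilities and cut into five classes at equiprobable normal
  quantiles; their score-scale mean (≈3) and SD (≈1.4) therefore differ
  from the continuous targets, which is accepted because the analysis
  treats them as linear traits either way. The default seven-trait
  panels carry the means, SDs and pedigree-heritability targets of two
  commercial meat-duck lines (line A and line D).
* **Masking** — the forward split withholds phenotypes of one
  generation; the imputation mask hides off-panel genotypes of selected
  birds. Both are pure views: stored genotypes and phenotypes are never
  altered.

What passing tests on simulated data do **not** show: the simulator has
no linkage disequilibrium beyond map linkage, no selection history, no
genotyping or imputation error, and Gaussian residuals — so real-data
heritabilities, imputation accuracies or PCA eigenvalue spectra are not
reproduced, only the arithmetic of the estimators and the qualitative
marker-vs-pedigree contrasts.

## Numerical and design choices

* Heritability search space [1e−4, 0.9999]; eigenvalues clipped at zero;
  kernels with eigenvalues below −1e−6 are rejected as non-PSD.
* `predict_ebv` refuses numerically singular training covariances
  (Cholesky pivot ratio below 1e−5) instead of returning unstable
  solutions; the remedy is the logged ridge.
* Descriptive statistics use the sample SD (n−1), bias-corrected
  skewness and excess kurtosis, CV = 100·SD/mean and SE = SD/√n. The
  three normality-test columns of the classical descriptive table
  (K-S, CvM, A-D) are not implemented.
* PCA is by default on the centered (not frequency-standardized) dosage
  matrix, matching its visualization use; standardization is available.
  All post-QC SNPs are used.
* Per-line analysis throughout (QC, matrices, evaluation); PCA joins
  lines on the jointly retained SNPs.
* Pipeline randomness is funneled through per-stage generators derived
  from a single integer seed; identical config + seed reproduces every
  TSV byte-for-byte (the JSON manifest carries timestamps and is the
  only non-reproducible artifact).
* Scale used by the shipped verification runs: the acceptance script
  simulates two lines of 1,650 birds × 1,200 SNPs; the heaviest test
  recovers h² at 2,000 birds × 2,000 SNPs over ten seeds. These sizes
  were chosen as the smallest at which the Monte-Carlo checks are
  comfortably stable.

## Known limitations

* Single-trait, single-kernel models only: no multi-trait, no
  dominance/epistasis, no genotype-by-environment, no Bayesian
  whole-genome regression, and no single-step H-matrix (in this design
  every bird is genotyped, so ssGBLUP adds nothing).
* The dense eigendecomposition limits comfortable problem size to a few
  tens of thousands of individuals.
* Ordinal traits are treated as Gaussian at both generation (liability)
  and analysis (linear model) stages; no threshold-model machinery.
* The imputation module evaluates; it does not impute beyond the naive
  pedigree/frequency baselines.
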
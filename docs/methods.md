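# Methods

## Trait model and score test

Traits are generated and analysed under the additive model
`Y = mu + sum_k alpha_k Z_k + sum_j beta_j X_j + eps` with genotypes coded as
minor-allele counts, unrelated individuals, and no gene–gene or
gene–environment interaction.  The error law is normal with standard deviation
`error_sd`; normality is a modelling choice (it matches the chi-square null of
the score test) rather than a requirement of the test itself.

The score test residualises both the test genotype `X_tau` and the trait `Y`
on the design `[1 | Z]` by least squares and forms `u = <X_res, Y_res>`,
`v = s_YY ||X_res||^2`, `chi2 = u^2/v`, with the p-value the upper 1-df
chi-square tail.  `s_YY` uses divisor `N - 1`, computed per trait replicate
from that replicate's residuals.  With intercept-only adjustment this makes
`chi2 = (N-1) r^2` exactly (Pearson `r` of `X` and `Y`), the identity the test
suite uses as an oracle.  The alternative divisor `N - K - 1` would shrink
`chi2` by the factor `(N-K-1)/(N-1)` uniformly; at the reference study size
(`N = 697`, `K ≈ 9`) the difference is ~1.3% and does not move type-I error
outside [0.04, 0.06].

Rare-variant collapsing tests a pseudo-genotype `sum_i w_i X_i` (weights
default to 1) through the identical code path, so the pseudo-SNP is also a
valid test SNP for the power machinery.

## Noncentrality and power

Under the model, `chi2` is noncentral chi-square (1 df) with

`lambda = (N - 1) * (sum_j r_tauj h_j)^2`,

`r_tauj` the covariate-adjusted sample correlation between the test and causal
genotype vectors, `h_j = beta_j sqrt(s_jj / s_yy)` the direct effect, and
`s_{j1,j2} = <res_{j1}, res_{j2}>/(N-1)` the adjusted covariance.  Two
different `s_yy`'s are deliberately in play:

* **Analytic power** uses the model-implied residual variance
  `s_yy = error_sd^2 + beta' S beta` (true effect sizes, cross-causal
  covariances included via the adjusted covariance matrix `S` — no
  independence among causal SNPs is assumed).
* **The score test** uses the empirical `s_YY` of the replicate being tested.

This mirrors a power analysis performed with the true simulation model in
hand while the test itself sees only data.  A small finite-sample wrinkle
follows: the empirical `s_YY` (divisor `N - 1`) estimates
`beta'S beta + error_sd^2 (N-p)/(N-1)`, slightly below the model-implied
value, inflating `chi2` by ~`(N-1)/(N-p)`.  At `N = 697` with ~10 design
columns this is ≤ 1.5% and is absorbed by the Monte-Carlo tolerances; the test
suite asserts the df-corrected expectation exactly.

Analytic power is the upper tail of `ncx2(1, lambda)` beyond the central
`chi2_{1, 1-alpha}` critical value (`alpha` default 0.05); simulated power is
the rejection fraction across replicate traits (default 100 replicates) with
genotypes and covariates held fixed and only the noise redrawn.  On a 500-SNP
LD-block panel with 10 causal SNPs (the scaled-down genome-scan comparison in
the acceptance suite) the analytic values explain ~98% of the variance in the
simulated ones with every SNP inside 3 binomial standard errors.

## Hyper-LD diagnostics

Between independent common SNPs the sample correlation is approximately
`N(0, 1/N)`, so `about 1%` of pairs exceed `z_{0.99}/sqrt(N) ≈ 2.33/sqrt(N)`
by chance (0.088 at `N = 697`).  The correlation scan computes adjusted
correlations blockwise (default 512 target columns per block; results are
independent of block size, tested) and emits pairs above a threshold,
excluding same-chromosome pairs closer than 10 Mb by default; chromosomes
differ ⇒ infinite distance.  Threshold semantics default to **signed**
`r > t` with an absolute-value flag, because minor-allele coding makes the
sign convention-dependent.  The cumulative-effect report applies **no**
distance exclusion: every causal SNP contributes to power wherever it sits.
Whether scan correlations are covariate-adjusted is the caller's choice via
the covariate table; an empty table gives raw correlations.

The null-panel comparison regenerates an independent HWE panel with the
observed panel's MAFs and map, and runs the identical scan/count/histogram
pipeline on both; count excess over the null is attributable to genuine LD.

## Data handling choices

* **Coding ties** (in-sample allele frequency exactly 0.5): the VCF ALT
  allele / the TSV allele coded "1" is treated as minor — deterministic.
* **Missing genotypes**: excluded from MAF; mean-imputed per SNP before
  residualisation in the score test *and* in correlation computations, which
  keeps N constant and the blockwise kernel a single matrix product.
* **HWE QC**: exact conditional test by default (chi-square 1-df optional),
  applied per population with the minimum p-value filtered at `1e-4`;
  monomorphic columns get p = 1 by convention.  The exact test enumerates
  heterozygote counts conditional on allele counts via log-factorials; its
  oracle in the tests is an exact-integer enumeration.
* **Monomorphic / degenerate SNPs** are kept by readers but skipped (logged)
  by scans and power analyses — their adjusted variance is zero.

## Synthetic data

The generators emulate the reference study conditions: `N = 697` unrelated
individuals, covariates Age (uniform integer 20–70), Sex (Bernoulli 0.5),
Smoke (Bernoulli 0.3) and Population (7 equally likely levels → 6 indicator
columns); genotypes either independent Binomial(2, MAF) columns or
haplotype-block draws (two haplotypes per individual per block, blocks
independent).  SNPs are laid out 1 Mb apart, 1,000 per synthetic chromosome,
so the 10 Mb exclusion is exercisable.  "Rare" in configs means a MAF putting
fewer than 30 minor-allele copies in the sample.  All generators are
deterministic given a seed.

What the generators do **not** emulate: population structure/admixture beyond
a categorical Population covariate, relatedness, coalescent LD decay,
genotyping error, and non-normal trait noise.  Passing tests therefore show
the analytics are internally correct under the stated model, not that real
exome panels meet its assumptions — in real data the correlation structure is
richer and the hyper-LD effect correspondingly stronger.

## Numerical choices

Residualisation uses `numpy.linalg.lstsq`; rank deficiency is detected up
front and reported with the names of the collinear columns (pivoted QR).
A residualised genotype with relative squared norm below 1e-12 is degenerate;
a trait whose residual norm is below `1e-10 ×` its raw norm is treated as
fully explained by covariates (`chi2 = 0`, `p = 1`).  `lambda = 0` returns
power exactly `alpha`.  Problem sizes in the test and acceptance suites
(6,000 null pairs, 2,000 replicates for calibration, a 500-SNP panel with 100
replicates for the power comparison) were chosen as the smallest scales at
which the binomial/Monte-Carlo error bands in the checks are meaningful.
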
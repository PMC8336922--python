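# Methods

This note records the statistical model behind each stage, the tunable
parameters and their defaults, what the synthetic generator does and does
not emulate, and the numerical choices made where the design was open.

## Generative model

All estimators assume, within one LD block of `m` SNPs with correlation
matrix `V`:

    z_t = sqrt(n_t) · V · beta_t + eps_t,        eps_t ~ N(0, V)
    Cov(eps_t, eps_t') = c_tt' · V

where `z_t` are a trait's marginal association z-scores, `beta_t` the
standardized per-SNP effects, `n_t = 4/(1/n_cases + 1/n_controls)` the
effective case-control sample size, and `c_tt'` the cross-study score
correlation induced by shared participants (for shared controls,
`c = n_shared · rho_p / sqrt(n_t n_t')` with `rho_p` the phenotypic
correlation among the shared individuals, 1 for identical controls).
Local SNP-heritability is `beta' V beta`; local genetic covariance between
two traits is `beta_1' V beta_2`.

## Harmonization

The canonical marker ID is `chr:pos:minAllele:maxAllele` with alleles
ordered lexicographically *after* strand canonicalization: an allele pair
and its reverse complement name the same variant on opposite strands, and
the lexicographically smaller sorted pair is used everywhere (summary
tables and reference panels alike), making the ID a deterministic,
strand-stable join key. Strand-ambiguous SNPs (A/T, C/G) are removed by
default because their strand cannot be resolved from allele labels. Betas
are sign-flipped and frequencies complemented when a source's effect allele
is the canonical second allele. Multi-allelic positions (more than two
alleles observed across tables, which also covers irreconcilable allele
mismatches) are removed everywhere. "Structural" variants are interpreted
as alleles longer than 50 bp; shorter indels are retained. QC defaults:
imputation quality >= 0.3 (records with no score pass), MAF >= 1%,
|log OR| <= 3, all with strict removal below/above the cutoff.

## LD reference

LD is the Pearson correlation of mean-imputed dosages. A panel-estimated
`R` over `m` SNPs has rank at most `n_panel − 1` and noisy small
eigenvalues, so the quadratic-form estimators use a truncated
pseudo-inverse: the retained rank `q` is the smallest `k` whose top-`k`
eigenvalues reach `var_frac = 0.995` of the total (configurable, optionally
capped by a fixed `q_max`), further capped at `n_panel − 1`, and
`R+ = Σ_top-q v v'/λ`. The truncation rule is reported in output metadata.
BED files on disk are 0-based half-open; every in-memory coordinate is
1-based inclusive.

## Sample-overlap estimation

With both z-vectors dichotomized at zero, `P(same sign) = 1/2 +
asin(rho)/pi` for a bivariate normal pair, so the zero-threshold
tetrachoric estimate `c_hat = sin(pi (p_same − 1/2))` is closed-form and
exact — no 2×2-table maximum likelihood is needed because the thresholds
are exactly zero by construction. To avoid polygenic contamination, SNPs
with association p < 0.1 in either trait of a pair are masked first (the
union mask; recorded in output metadata). A caveat measured in the test
suite: this masking truncates both margins to roughly |z| < 1.64, which
*attenuates* the tetrachoric estimate of a genuine overlap (about half at
c = 0.08). The attenuation is a property of the masking procedure itself;
estimates on unmasked null SNPs are unbiased. Downstream corrections
therefore use slightly conservative (too-small) `c` values when the mask is
active, which matters little at the |c| <= 0.1 scale of realistic control
sharing. The minimum pair count defaults to 1,000 null SNPs; the number of
*effectively independent* null SNPs is what controls precision, and one
dense region cannot supply it — overlap estimation should use genome-wide
data (the generator's `simulate_overlap_study` emulates this with many
independent LD chunks).

## Local genetic correlation

Method-of-moments estimators under the generative model:

    h2_hat  = (z' R+ z − q) / (n − q),    Var ≈ (2q + 4 n h2) / (n − q)^2
    rho_hat = (z1' R+ z2 − q c) / sqrt(n1 n2)
    Var(rho_hat) = (q (1 + c^2) + [n1 h2_1 + n2 h2_2]_+ + 2 c sqrt(n1 n2) rho_hat) / (n1 n2)

Both are unbiased under the model; calibration is asserted by simulation,
not by formula provenance. Two numerical choices in the variance:

* the summed heritability term uses a *positive-part estimator debiased by
  its null expectation* (subtract `sqrt(sd1² + sd2²)/sqrt(2π)` with
  `sd_i = sqrt(2q)·n_i/(n_i − q)`, then floor at zero). The floor keeps the
  plug-in variance from ever falling below the no-signal value
  `q(1 + c²)` — making the far tail of the test conservative — while the
  debiasing keeps the α = 0.05 rejection rate near nominal under a pure
  null (the raw positive-part estimator alone deflates it to ≈ 0.037);
* negative `h2_hat` values are legitimate noise-floor outcomes and are
  reported as-is; `rg` is undefined (with a reason code) when either local
  heritability is non-positive, and clamped with a flag when sampling noise
  pushes |rg| past 1.

Significance in a scan of `B` blocks uses the Bonferroni threshold
`alpha/B` (0.05/1703 = 2.94e-5 for the standard genome partition). The
genome-wide polygenic-leakage adjustment present in some local-heritability
tools is omitted: the synthetic genome concentrates heritability locally,
and the block-scan simulation verifies the omission is negligible there
(cross-block leakage through panel-sampling LD scales as `1/n_panel` and is
controlled by using an adequately large panel).

## Conditional analysis

Works entirely in z-space with one effective sample size per trait:

    z_cond_j = (z_j − r_jS' R_SS^-1 z_S) / sqrt(1 − r_jS' R_SS^-1 r_Sj)

which is exact for standardized genotypes and equal per-SNP `n`, and is
validated against an individual-level OLS residual-regression oracle
(agreement within 0.05 absolute at panel size 10,000). SNPs whose
projection on the lead set exceeds `collinearity_max = 0.9` are flagged and
reported missing rather than unstably inverted; a later lead perfectly
correlated with an earlier one is dropped with a warning. Stepwise forward
selection adds the smallest-conditional-p SNP while that p < 5e-8, with
ties broken by larger |z| then lower position.

## Two-sided subset meta-analysis

For each SNP the search enumerates all assignments of the `K` available
traits to {positive, negative, excluded} — `(3^K − 1)/2` sign classes after
identifying an assignment with its global flip — and maximizes
`|v'z|/sqrt(v'Cv)` with `v_k = ±sqrt(n_eff,k)` and `C` the overlap matrix.
Exhaustive search is vectorized and bounded at K <= 12. Ties are broken by
smaller subset size, then lexicographic subsets. SNPs missing in some
traits are searched over the observed subset with `K` reduced.

The maximum over correlated subset tests needs a multiplicity adjustment.
The published discrete-local-maxima approximation is not reimplemented;
instead a seeded Monte-Carlo calibration draws `z ~ N(0, C)` (default
100,000 draws), computes the null maxima, and fits an effective number of
independent tests `m_eff` to the empirical 5%, 1% and 0.1% upper quantiles:
each anchor's tail mass is inflated by two binomial standard errors (so the
fit is conservative under the calibration's own Monte-Carlo noise), `m_eff`
is the maximum of the buffered per-anchor ratios (never less than the
log-scale least-squares fit), capped by the Bonferroni bound — the number
of sign classes. Then `p_adj = min(1, m_eff · 2Φ(−T))`. This is
conservative by construction, reproducible given the seed, and extrapolates
through the normal tail to genome-wide levels that direct simulation cannot
reach; the cost is ~20–30% conservatism in the extreme tail, a negligible
power loss at the 5e-8 stopping rule. `K = 1` is the identity adjustment
(`m_eff = 1` exactly).

## The iterative loop

Starting from marginal statistics: condition every trait on the accumulated
leads (a trait skips leads absent from its own data), run the subset
meta-analysis over SNPs observed in at least two traits, harvest the
arg-min SNP if `p_adj < 5e-8`, else stop and record the best remaining
candidate. Calibrations are cached per trait-availability pattern. A
`max_iter = 25` safety cap fails loudly on non-convergence. Fine-mapping
trait lists per signal are the union of the harvested positive/negative
subsets with any trait whose unadjusted marginal p at the lead is below
5e-8 (the manual-addition rule).

## Fine-mapping, annotation priors, colocalization

Under the one-causal assumption, with per-trait z conditioned on the other
leads, the likelihood reduces to a product over traits of single-SNP
Wakefield-style approximate Bayes factors on the standardized scale:

    log ABF = ½ log(1 − r) + z² r / 2,    r = w_prior / (w_prior + 1/n_eff)

with `w_prior = 0.04` (log-odds sd 0.2, the conventional case-control
choice; configurable per trait). The full LD-aware multivariate likelihood
is not needed because the statistics are conditional and one causal variant
is assumed; the credible-set coverage simulation is the arbiter (empirical
coverage of nominal-95% sets exceeds 93%, in practice near 100% at the
planted |z| in [5, 9] — single-causal Bayesian sets over-cover when the
model is correct and signals are strong). 95% credible sets are the
shortest prefix of the PP-sorted SNP list reaching 0.95.

Annotation priors: `prior_j ∝ exp(Σ_t gamma_t a_jt)` normalized over the
region's SNPs. The baseline `gamma0` cancels in the normalization and is
fixed at 0; `gamma = 0` recovers the uniform prior. Enrichment coefficients
are fitted by EM across signals (E-step: per-signal posteriors; M-step: a
concave softmax-regression solved by BFGS with analytic gradient;
convergence when the log-likelihood improves by < 1e-6 per signal).
Annotations constant across SNPs are non-identifiable and pinned at 0 with
a warning. Annotation indicators honor BED's 0-based half-open convention.

Colocalization uses the standard five-hypothesis decomposition over per-SNP
log ABFs (none / trait 1 only / trait 2 only / two distinct / one shared)
with conventional priors `p1 = p2 = 1e-4`, `p12 = 1e-5`. Because the ABFs
are on the standardized scale, per-SNP allele frequencies do not enter; the
`maf` argument is accepted for interface compatibility only.

## The synthetic generator

Haplotypes come from an AR(1) latent Gaussian thresholded at
frequency-specific cutoffs. The chain parameter is the *target adjacent
dosage correlation*: the latent correlation is found per adjacent pair by
inverting the thresholded-binary correlation (a tetrachoric inversion via
a closed-form bivariate-normal CDF and vectorized bisection), so planted LD
levels survive discretization. Allele frequencies follow a slow reflected
random walk (sd 0.02 per step, range [0.1, 0.9]) because tightly linked
variants in real data have similar frequencies; without this, high LD
targets would be unattainable at discordant frequencies (targets beyond the
Fréchet bound are clipped, with a warning when the deficit exceeds 0.02).
Summary statistics are drawn exactly from the generative model above using
the panel's empirical `V` through its low-rank factor (`Cov(X'g/√n) = V`),
so no m×m decomposition is formed. Emitted allele pairs are restricted to
strand-canonical representations (A/C, A/G) so simulated marker IDs survive
harmonization unchanged.

What the generator does **not** emulate: coalescent haplotype structure,
allele-frequency/LD coupling beyond the random walk, imputation error and
INFO heterogeneity, per-SNP sample-size variation, population stratification
and polygenic background outside the simulated blocks. Passing tests
therefore demonstrate correctness *under the model the estimators assume*
plus robustness to panel sampling noise — not robustness to LD mismatch
between panel and study populations, which the real-data workflow flags as
its main caveat.

Flagship defaults: m = 3,000 SNPs per region (the scale of the dense
pleiotropic block the workflow targets), K = 8 traits with case/control
counts spanning consortium-scale studies (n_eff ≈ 16,500–137,000), panel
n = 5,000, adjacent-LD target 0.9, three planted causal variants with
per-trait |z| ≈ 8–12 including one opposite-direction configuration, and
shared controls planting a 0.05 score correlation between the breast and
ovarian studies. Monte-Carlo experiment sizes (500 replicates for
recovery/coverage, 1,000 null blocks for type-I error, 50,000–100,000
calibration draws, 100 replicates for pipeline recovery) were chosen so
every check resolves its tolerance comfortably at interactive cost.

## Known limitations

* Overlap estimates from masked SNPs are attenuated (see above).
* The subset-meta p-value is method-compatible with, not numerically
  identical to, the published tool's discrete-local-maxima approximation.
* Local `rg` magnitudes depend on the truncation rank and are reported
  alongside raw `rho`; with weak local heritability the ratio is unstable
  and flagged undefined rather than extrapolated.
* Fine-mapping assumes exactly one causal variant per conditioned signal;
  residual secondary signals bias posteriors toward bridging proxies.
* The conditional step ignores per-SNP sample-size heterogeneity.
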
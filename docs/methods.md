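# Methods

## Scope and model

`grsgxe` tests whether an exposure modifies the aggregate effect of a
candidate gene's common variants on a trait, and names the direction of the
modification.  The genetic unit is a set of L SNPs (dosages 0/1/2 counting
the minor allele, additive coding); the trait is continuous
(identity link) or binary (logit link); the exposure may be binary or
continuous.  Covariates enter both stages as ordinary fixed effects —
ancestry principal components are treated as covariates like any other, and
their computation is out of scope, as are relatedness pruning, rare
variants, and multi-gene scores.

### Two-stage GRS test

Stage one removes covariate signal by regressing Y on X alone and keeping
response-scale residuals; for binary traits the residual is
Y − expit(α̂₀+α̂'X), which lies in (−1, 1).  SNP weights are then estimated
by penalized least squares of those residuals on all L dosages jointly —
squared-error loss for both trait families, matching the score's role as a
linear aggregation device rather than a full likelihood model.  The
objective is kept on the *total* residual-sum-of-squares scale,

    RSS + λ·P(β),  P = Σβ² (ridge), Σ|β| (lasso),
                   Σ[(1−α)β²/2 + α|β|] (elastic net, α = 0.5),

with an unpenalized intercept.  scikit-learn's coordinate descent is used
for lasso/elastic net with its per-observation penalty mapped back
(α_sklearn = λ/2n); the ridge path is solved in closed form from one
eigendecomposition of the Gram matrix per cross-validation fold.  All
reported λ values are on the RSS scale.

λ is the minimizer of 10-fold cross-validated MSE over 100 log-spaced
values.  λ_max is the smallest penalty nulling every slope (2·max|G_c'ε_c|,
divided by α for the elastic net); ridge, which never reaches exact zeros,
uses a data-scaled cap of 1000× that value.  The grid floor is λ_max·1e-4.
Folds are a seeded random permutation split as evenly as possible; held-out
MSE is pooled over all n predictions.  The minimum-MSE rule (not the
one-standard-error rule) is deliberate: a single gene explains little
phenotypic variance, and the 1-SE rule routinely selects zero SNPs, which
destroys the score.

The raw score Σβ̂ⱼG_ij is standardized to mean 0, SD 1 (denominator n−1).
Stage two fits the interaction GLM with the standardized score and
Wald-tests γ_Int (two-sided; t-reference for gaussian, normal for
binomial).  No positivity constraint is placed on γ_G.  Direction is
reported only when p < α, with the sign of γ̂_Int.

**Degenerate scores.**  When every lasso/elastic-net weight is shrunk to
exactly zero, no score exists.  The pipeline reports p = 1, direction
"none", and a machine-readable flag instead of raising, so replicated
studies keep running.  This matters at moderate sample sizes: at n = 2,000
with per-SNP effects of 0.04–0.08 trait SD, roughly a fifth of null
replicates are degenerate, which makes the lasso/enet tests conservative
(empirical size ≈ 0.03 at α = 0.05) even though they are exactly nominal by
n = 8,000.  Ridge never degenerates and holds nominal size at n = 2,000.

**Why same-sample weighting is valid.**  The weights are functions of (Y, G)
only; under the null of no SNP-by-exposure interaction the weight estimates
and the interaction estimate are asymptotically independent, so filtering/
weighting by marginal association does not inflate size.  This is verified
empirically by the type-I studies in the test suite rather than assumed.

### Comparators

*SBERIA.*  Stage one fits L separate covariate-adjusted single-SNP models;
weights are I(pⱼ < 0.1)·sign(β̂ⱼ) + ν with ν = 1e-4, so the score is defined
even when nothing passes.  Stage two keeps all L SNP main effects alongside
the standardized score × exposure term; exactly aliased SNP columns are
dropped by QR with column pivoting before fitting.  For SEN/PPV accounting
the "selected" set is the p < 0.1 indicator alone — the ν offset does not
count as selection.

*Variance-component score test (iSKAT-style).*  Null model: intercept,
covariates, exposure unpenalized, all SNP main effects under a ridge
penalty chosen by 10-fold CV.  The statistic is Q = ‖S'r‖² with r the null
residuals and S the column-centered matrix of Gⱼ∘E products; its null law
is a weighted sum of χ²₁ variables with weights σ̂²·eig(C'C), where
C = (I−H)'S accounts for both the fixed-effect projection and the ridge
smoother.  Tail probabilities use Imhof's inversion integral (adaptive
quadrature) with the Liu moment-matching approximation as fallback.  The
null-model ridge grid is capped at the lasso-scale λ_max: the penalty only
needs to stabilize LD-induced near-singularity, and heavier shrinkage leaks
genetic main-effect signal into r, inflating the test (size ≈ 0.07 with a
1000× cap vs ≈ 0.056 with the lasso-scale cap, 800 null replicates at
n = 2,000).  For binary traits the null model is fit by penalized IRLS and
the kernel uses the working-weight projection.

*ADABF.*  Each SNP's interaction Wald summary (z, se) from its own
single-SNP model yields an approximate Bayes factor
√(se²/(se²+ψ))·exp(z²ψ/(2(se²+ψ))) with prior variance ψ = 0.04 (prior SD
0.2 on the interaction coefficient; configurable).  The statistic is the
minimum over k = 1..L of the resampling p-value of T_k = sum of the k
largest log-BFs; null z-vectors are drawn from a multivariate normal whose
correlation is estimated from the interaction columns residualized on each
SNP's remaining design.  Overall significance is read from the same null
pool (rank-based per-k p-values), with sequential early stopping once 50
exceedances accumulate; p̂ = (r+1)/(B+1), default budget 1,000 resamples.
When zero exceedances survive the budget the result is flagged as a floor
value p = 1/(B+1).

The variance-component and ADABF results deliberately expose no direction
field.

## Synthetic data

*Genotypes.*  A Gaussian copula: latent MVN vectors with AR(1) correlation
ρ inside blocks and independence across blocks, thresholded at the
standard-normal quantiles of (1−m)² and (1−m)²+2m(1−m) for each SNP's
sampled MAF m — Hardy–Weinberg marginals with tunable local LD.  Defaults:
genes of 48/95/242 SNPs split into blocks of ~12, ρ = 0.8, MAF uniform on
[0.05, 0.5].  These defaults reproduce the two features the methods care
about — common-variant marginals and strong local correlation that makes
G'G near-singular.  What they do *not* reproduce: real genes' irregular
block boundaries, long-range LD, MAF-dependent LD strength, or any
population structure.  Passing tests therefore demonstrate behavior under
idealized LD, not on any particular human gene.

*Phenotypes.*  Continuous traits: Y = Σβ_Gd G_d + β_E E + Σβ_Intd G_d E + ε,
ε standard normal, with exactly four causal SNPs drawn uniformly per
replicate.  Binary traits: the logistic analogue, sampled marginally per
subject (cohort-style; no case-control ascertainment), intercept
log(p/(1−p)) for prevalence p (0.1 or 0.4 typical).  Effect magnitudes:
|β_G|, |β_Int| ~ U(0.04, 0.08) for continuous traits, U(log 1.05, log 1.15)
on the log-odds scale for binary; |β_E| = 0.3 or log(1.3); interaction
magnitudes sampled independently of main-effect magnitudes.  Exposures:
Bernoulli(0.2 or 0.5) or Normal(0, 0.5²).  Sign patterns follow fourteen
canonical scenarios (exacerbation / attenuation / cross-over, with two or
four interacting SNPs, exposures raising or lowering the trait); structural
zeros are exact zeros.  Simulated cohorts carry no covariates — covariates
exist for real-data mode only.

## Study harness and problem sizes

Studies are pure functions of their configuration: every replicate's
streams derive from (master_seed, scenario, replicate) via numpy
SeedSequence, so results are bit-reproducible.  Power for the directional
tests counts a success only when the interaction is significant *and* its
sign matches the scenario's truth; for the non-directional tests (and for
cross-over scenarios, where no true aggregate sign exists) power is the
rejection rate.  Sign misspecification is wrong-signed rejections over all
rejections, undefined (NaN) for cross-over scenarios or when nothing
rejects.  All rates carry Wilson 95% intervals.

Default problem sizes are chosen for a desk, not a cluster: n = 2,000
subjects and 2,000 replicates for size studies (the acceptance script's
scale), 300 replicates at n = 1,500–2,000 for the power-ordering and
sign-misspecification suites, with inflated (2×) effect magnitudes where a
single-dataset ordering is being demonstrated.  The claims checked at this
scale are rates and *orderings*, which are robust to the reduction; exact
power values at full scale (tens of thousands of subjects, 1,000–10,000
replicates) are not asserted anywhere.

## Numerical choices and edge cases

- Hardy–Weinberg: plain exact test (full enumeration of the conditional
  heterozygote distribution), no mid-p.
- QC filters apply sequentially — call rate, then HWE, then MAF — each
  counted against the survivors of the previous step; `qc_filter` is
  idempotent.
- Region windows are 1-based and inclusive at both flanked ends.
- Missing genotypes are preserved by I/O and mean-imputed per SNP before
  any regression.
- Dosages are always re-oriented so 2 counts the minor allele in the
  analyzed sample; the interaction p-value is invariant to allele-coding
  flips (weights are refit on the flipped column and change sign).
- Constant adjusted phenotype → all slopes zero with a warning; constant
  exposure or constant score → explicit inestimable-interaction errors;
  exact collinearity in OLS weighting → explicit singularity error.
- Imhof p-values falling outside [0, 1e-10..1] trigger the Liu fallback;
  results are clipped to [1e-300, 1].

## Known limitations

- The binary-trait variance-component branch uses an IRLS ridge fit with a
  working-weight kernel; its calibration is checked only at unit-test
  scale, not with a dedicated large replicate study.
- ADABF's prior variance and resampling scheme follow this package's own
  defaults; other implementations of the same idea will differ in detail.
- Marginal logistic scans loop over per-SNP GLM fits and are markedly
  slower than the vectorized gaussian scans.
- The LD simulator does not emulate real genes' LD maps; results on real
  data depend on LD structure the simulator idealizes.
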
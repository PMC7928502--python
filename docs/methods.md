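# Methods

## Model

For a gene with p rare variants observed in N individuals, the
case/control phenotype y_i ∈ {0,1} follows a Bernoulli likelihood with
logit link,

    logit P(y_i = 1) = x_i'α + g_i'β,      β_j = z_j'ω + δ_j,

where x_i (length m, intercept first) are individual covariates,
g_i ∈ {0,1,2}^p the minor-allele dosages, and z_j (length q) the
characteristics of variant j — one indicator per observed
exonic-function category (missense, LoF, indel, …; no reference level
and no variant-level intercept) plus one column per numeric
deleteriousness score (CADD by default, entered per unit and
untransformed). ω captures the shared effect of each characteristic;
δ_j ~ N(0, τ) absorbs variant-specific heterogeneity. Substituting
gives the mixed-model predictor η = Xα + (GZ)ω + Gδ with latent field
u = (α, ω, δ) of dimension m+q+p.

Priors: α and ω components are N(0, 1/c) with c = 0.001 by default;
the random-effect precision 1/τ has a Gamma(shape 1, rate 5e-5)
hyperprior. Both are configurable; they are diffuse latent-Gaussian
defaults of the kind INLA-style software ships, and the proper priors
double as regularisation under quasi-separation (frequent with rare
variants), so no separation special-casing is needed.

## Inference

Inference follows the integrated-nested-Laplace recipe specialised to
a one-dimensional hyperparameter, on the log-precision scale
ψ = −log τ:

1. **Conditional mode.** For fixed ψ, the mode u*(ψ) of
   p(u | ψ, y) is found by Newton iterations with step-halving;
   convergence when the penalised log-posterior improves by less than
   1e-8 (max 100 iterations, error with iteration trace otherwise).
   H(ψ) is the negative Hessian at the mode.
2. **Hyperparameter marginal.** The Laplace identity gives
   log p̃(ψ|y) = log p(y, u*, ψ) + log p(ψ) − ½log|H| + (m+q+p)/2·log 2π,
   with all constants kept so that data-free Gaussian blocks cancel
   exactly (a variant nobody carries changes nothing). The ψ mode is
   located by a coarse scan (step 2 over [−3, 16]) plus golden-section
   refinement; the grid is mode-centred with step 0.5σ (σ from a
   finite-difference curvature), extended each way until the
   log-density drops 6 units, capped at 35 points, and normalised.
3. **Latent marginals.** Each fixed-effect coefficient's posterior is
   the grid-weight mixture of its per-point Gaussian conditionals
   (mixture mean, sd, and 2.5%/97.5% quantiles by bisection on the
   mixture CDF). This is the Gaussian mixing strategy, a deliberate
   simplification of full nested-Laplace marginals; the quadrature
   oracle tests show it is accurate to <0.02 on means at these sample
   sizes.
4. **DIC.** DIC = D̄ + pD with D̄ the posterior-mean deviance and
   pD = D̄ − D(ū). Two estimators: a seeded Monte-Carlo average over
   M = 200 mixture draws (default; probabilities clamped to
   [1e-12, 1−1e-12] with a warning if a draw degenerates), and a
   deterministic plug-in variant, D̄ ≈ Σ_k w_k [D(u*_k) + (m+q+p −
   tr(P H_k⁻¹))], the second-order Taylor expansion of the expected
   deviance per grid component. The plug-in form is used in
   permutation scans, where S×K×2 fits must stay cheap and exact
   reproducibility is convenient.

The null model (covariates only) is a single Laplace fit with no
hyperparameter. A full fit on a gene left with zero qualifying
variants returns the null fit flagged degenerate.

## Association and calibration

ΔDIC = DIC(H0) − DIC(H1); positive values favour the genetic model.
Significance thresholds are calibrated by permutation: case/control
labels are shuffled S times preserving group sizes (S=10 by default;
the desk-scale experiments use S=3), all genes re-tested per shuffle,
and the level-a threshold taken as the ΔDIC at descending rank
ceil(K·a) among the K tested genes (per shuffle), then the median
across shuffles. A gene is called significant when its ΔDIC *strictly*
exceeds the median threshold. Genes with no qualifying variants are
excluded from both K and the ranking. The covariates-only null fit is
shared across genes within a scan (it does not depend on the gene),
and the variant filter mask is computed once from the observed labels
rather than per shuffle — at AF ≤ 0.01 the control-frequency criterion
is nearly label-invariant.

## Synthetic cohorts

The generator produces a WES-like background cohort: per-gene variant
counts Poisson with gene-specific means LogNormal(log 25, 0.5); MAF
density ∝ 1/x truncated to [1/(2N), 0.05]; exonic categories
synonymous/missense/LoF/indel with probabilities 0.45/0.45/0.04/0.06
and CADD-like scores N(5,3)/N(18,6)/N(32,5)/N(22,6) truncated at 0;
genotypes Binomial(2, MAF) under Hardy–Weinberg equilibrium; 1%
missing calls; optional population structure via Balding–Nichols
Beta-perturbed per-population frequencies (divergence 0.01 by
default). Case fraction 0.5 (1:1) or 1/3 (1:2). Everything is
seed-deterministic.

Risk architectures: a pool of rare risk variants (MAF log-uniform on
[1e-4, 0.01]) carries relative risks whose log is normal with sd 0.3
and median decaying from 8 at MAF→0 to 1.5 at MAF = 0.01, truncated at
RR ≥ 1.1 (so the realised median at the common end sits near 1.59).
Per-variant variance explained uses the liability-threshold model:
HWE genotype frequencies, multiplicative genotype risks (λ1 = RR,
λ2 = RR²), baseline penetrance scaled so population risk equals the
prevalence (0.0066 by default, a 5-year breast-cancer figure),
liability shifts μ_g = Φ⁻¹(1−K) − Φ⁻¹(1−f_g), and
VE = Var(μ_g)/(Var(μ_g)+1). Variants are added (without replacement,
optionally restricted to missense-only or LoF-only) until the additive
cumulative VE reaches the target (0.02/0.01/0.005); draws implying
penetrance > 1 are skipped as unusable. Spiking inserts each selected
variant into Binomial(n_eligible_cases, min(2·MAF·RR, 1)) randomly
chosen cases as heterozygous calls, at most one spiked variant per
case; in the stratified scenario only cases of the variant's
population are eligible; controls are never touched.

What the generator does *not* emulate: linkage disequilibrium and
haplotype structure, capture-kit coverage geometry, genotyping error
and allele-balance artefacts, relatedness, and the site-frequency
correlations of real panels. Passing calibration/power checks on
these cohorts therefore demonstrates the statistical machinery under
the assumed sampling model, not robustness to those real-data
complications.

## Experiment sizes

The calibration experiments use 600 samples × 2,000 null genes (5%
TIER) and 400 samples × 8,000 null genes (0.1% TIER), each with S=3
shuffles and an independently seeded second null cohort for the
empirical error rate; the power experiment uses 1,000 samples (500
cases), a 300-gene background, a 400-variant risk pool, and 50
replicates of a VE = 2% architecture tested at the calibrated 5%
threshold. These sizes were chosen so each experiment is a faithful
scaled-down analog of the exome-wide design while remaining a
single-CPU desk run.

## Numerical choices and edge cases

- Missing genotypes are imputed as homozygous reference by default
  (variants are rare and a call-rate filter precedes testing);
  mean-dosage imputation is available.
- Ti/Tv with zero transversions is reported as undefined rather than
  infinite.
- Genotype PCA uses variants with MAF ≥ 0.01 only, mean-imputes
  missing calls, and unit-scales columns; a constant matrix yields
  zero scores and zero explained variance.
- Outlier flags use |z| > 3 on variant count and Ti/Tv and |z| > 6 on
  PC1/PC2 — thresholds are conventions, configurable.
- Filter boundary semantics: AF ≤ 0.01 kept, CADD ≥ 10 kept,
  synonymous dropped; call rate strictly > 0.85 in the simulation
  setting, ≥ 0.95 in the application setting.
- Ties at the threshold rank resolve to the larger ΔDIC value
  (conservative), and a gene exactly at the threshold is not
  significant.

## Limitations

- The variant-level covariance Q is fixed to the identity; dependency
  structure across variants is out of scope.
- Only binary phenotypes are supported.
- Latent marginals use the Gaussian mixture approximation, not the
  full nested-Laplace correction; skewness in small-sample posteriors
  is not captured.
- The permutation calibration assumes exchangeability of labels under
  the null; strong uncorrected stratification violates it (PCs should
  be included as covariates, as the QC module supports).
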
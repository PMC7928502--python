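# bati

Bayesian rare-variant association testing for case-control sequencing
studies, with a synthetic cohort simulator and the QC/filtering stages
needed to run a full gene-wise benchmark end to end.

## The problem and the model

Rare variants (MAF ≤ 1%) are individually far too scarce to test one
at a time, so rare-variant association studies (RVAS) aggregate them
per gene. Burden-style tests lose power when damaging, neutral and
protective variants coexist in one gene; variance-component tests
ignore what we know about each variant. This package implements a
hierarchical Bayesian test that keeps per-variant heterogeneity *and*
exploits variant characteristics (functional category, deleteriousness
scores) as covariates.

For individual i with phenotype Y_i ∈ {0,1}, covariates X_i and
dosages G_i over the gene's p rare variants:

    logit P(Y_i = 1) = X_i'α + G_i'β,      β_j = Z_j'ω + δ_j,
    δ ~ N(0, τI),

where Z is the p×q matrix of variant characteristics (category
indicators + CADD), ω the shared characteristic effects and δ
variant-specific random effects. The model is fitted by Laplace
approximation with grid integration over the random-effect precision
(an INLA-style scheme specialised to this model), yielding posterior
marginals for every fixed effect and the Deviance Information
Criterion. Genes are ranked by

    ΔDIC = DIC(H0: covariates only) − DIC(H1: full model),

and significance thresholds for a desired type-I error rate (TIER) are
calibrated empirically by permuting case/control labels, ranking the
null ΔDIC values, and taking the median order-statistic threshold
across shuffles. See `docs/methods.md` for the full specification.

## Worked example

```python
import numpy as np
from bati import (BackgroundCohortSpec, ModelConfig, simulate_background,
                  simulate_risk_pool, build_architecture, spike_cases,
                  test_gene, estimate_tier_thresholds)
from bati.qc import apply_standard_filters

# synthetic background cohort: 600 samples (300/300), 200 genes
cohort = simulate_background(BackgroundCohortSpec(n_samples=600,
                                                  n_genes=200, seed=7))

# spike one gene with rare risk variants explaining ~2% of liability
rng = np.random.default_rng(7)
pool = simulate_risk_pool(300, rng)
arch = build_architecture(pool, "G00000", target_ve=0.02, mode="any",
                          prevalence=0.0066, rng=rng)
spiked = spike_cases(cohort, arch, rng)

# QC filter, permutation thresholds, then test the spiked gene
cfg = ModelConfig(dic_method="plugin")
mask = apply_standard_filters(spiked)
th = estimate_tier_thresholds(spiked, spiked.gene_ids, levels=(0.05,),
                              S=3, seed=1, config=cfg, variant_mask=mask)
idx = spiked.gene_columns("G00000")
res = test_gene(spiked, "G00000", cfg, variant_idx=idx[mask[idx]])
print(f"threshold(5% TIER) = {th.medians[0.05]:.3f}")
print(f"DeltaDIC           = {res.delta_dic:.3f}")
print(res.effects.round(3).to_string(index=False))
```

prints

```
threshold(5% TIER) = 3.333
DeltaDIC           = 67.097
     name      kind   mean    sd   q025   q975
intercept covariate -0.232 0.089 -0.405 -0.058
      LoF  category 14.123 8.600 -2.733 30.980
    indel  category 13.968 8.676 -3.037 30.974
 missense  category  5.513 1.907  1.776  9.250
     cadd     score -0.213 0.090 -0.390 -0.036
```

The spiked gene's ΔDIC (67.1) far exceeds the permutation threshold
(3.33), so it is called significant at the 5% TIER. The effect table
is the per-characteristic report: the architecture drawn here is
dominated by missense risk variants, and correspondingly the missense
category shows a positive mean effect whose 95% credible interval
excludes 0; LoF and indel rest on very few carriers, hence the wide
intervals. The per-unit CADD effect is small — with no variant-level
reference category, score and category columns are partially aliased,
so the per-category effects absorb most of the signal.

A command-line interface wraps the same machinery
(`bati simulate/qc/test/thresholds/power`, YAML-configured); run
`bati --help`.

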
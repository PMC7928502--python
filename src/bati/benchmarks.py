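"""Desk-scale calibration and power experiments.

These drivers reproduce, on fully synthetic cohorts, the two study
designs used to characterise the test: (i) type-I-error calibration —
estimate permutation DeltaDIC thresholds on one null cohort and
measure the exceedance rate on an independent null cohort; (ii) power
— spike a VE-targeted risk architecture into cases and measure how
often the gene clears the calibrated threshold across replicates.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every experiment is exactly
reproducible.  Permutation scans and calibration runs use the
deterministic plug-in DIC estimator; the Monte-Carlo estimator is
exercised by the unit suite.
"""

from __future__ import annotations

import numpy as np

from .association import estimate_tier_thresholds, scan_delta_dics, test_gene
from .cohort import Cohort
from .design import ModelConfig
from .qc import apply_standard_filters
from .simulate import (
    DEFAULT_PREVALENCE,
    BackgroundCohortSpec,
    build_architecture,
    simulate_background,
    simulate_risk_pool,
    spike_cases,
)


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic 31-bit child seed."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def fast_config(seed: int) -> ModelConfig:
    return ModelConfig(dic_method="plugin", seed=seed)


def null_cohort(n_samples: int, n_genes: int, seed: int) -> Cohort:
    spec = BackgroundCohortSpec(
        n_samples=n_samples, n_genes=n_genes, case_fraction=0.5, seed=seed
    )
    return simulate_background(spec)


def cohort_null_deltas(
    cohort: Cohort, config: ModelConfig
) -> np.ndarray:
    """Per-gene DeltaDIC under the cohort's own (null) labels."""
    mask = apply_standard_filters(cohort)
    deltas = scan_delta_dics(
        cohort, cohort.gene_ids, config, variant_mask=mask
    ).to_numpy()
    return deltas[np.isfinite(deltas)]


def tier_calibration_experiment(
    seed: int,
    *,
    n_samples: int,
    n_genes: int,
    level: float,
    S: int = 3,
) -> dict:
    """Threshold on cohort A by permutation; exceedance rate on cohort B.

    Both cohorts are null (no spiked risk variants).  Returns the
    estimated threshold, the empirical type-I-error rate on the
    independent replicate, and the gene counts involved.
    """
    config = fast_config(_child_seed(seed, 0))
    cohort_a = null_cohort(n_samples, n_genes, _child_seed(seed, 1))
    mask_a = apply_standard_filters(cohort_a)
    thresholds = estimate_tier_thresholds(
        cohort_a, cohort_a.gene_ids, levels=(level,), S=S,
        seed=_child_seed(seed, 2), config=config, variant_mask=mask_a,
    )
    thr = thresholds.medians[level]

    cohort_b = null_cohort(n_samples, n_genes, _child_seed(seed, 3))
    deltas_b = cohort_null_deltas(cohort_b, config)
    rate = float(np.mean(deltas_b > thr))
    return {
        "level": level,
        "threshold": thr,
        "per_shuffle": thresholds.per_shuffle[:, 0].tolist(),
        "empirical_rate": rate,
        "n_genes_calibration": len(cohort_a.gene_ids),
        "n_genes_test": int(len(deltas_b)),
        "n_exceed": int(np.sum(deltas_b > thr)),
    }


def power_experiment(
    seed: int,
    *,
    n_samples: int = 1000,
    n_genes: int = 300,
    n_replicates: int = 50,
    target_ve: float = 0.02,
    level: float = 0.05,
    S: int = 3,
    prevalence: float = DEFAULT_PREVALENCE,
    pool_size: int = 400,
) -> dict:
    """Power of the test at a calibrated TIER threshold.

    One background cohort is simulated; the DeltaDIC threshold at
    ``level`` is calibrated by S label shuffles on the un-spiked
    cohort.  Then, per replicate, case/control labels are
    re-randomised, a fresh architecture targeting ``target_ve`` is
    built from the risk pool and spiked into cases (at most one
    variant per case), and the spiked gene is tested against the
    threshold.  Returns power as a percentage of replicates.
    """
    config = fast_config(_child_seed(seed, 0))
    background = null_cohort(n_samples, n_genes, _child_seed(seed, 1))
    mask = apply_standard_filters(background)
    thresholds = estimate_tier_thresholds(
        background, background.gene_ids, levels=(level,), S=S,
        seed=_child_seed(seed, 2), config=config, variant_mask=mask,
    )
    thr = thresholds.medians[level]

    pool_rng = np.random.default_rng(_child_seed(seed, 3))
    pool = simulate_risk_pool(pool_size, pool_rng)
    target_gene = background.gene_ids[0]
    n_cases = int(np.sum(background.status == 1))

    hits = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(_child_seed(seed, 4, r))
        status = np.zeros(n_samples, dtype=np.int8)
        status[rng.choice(n_samples, n_cases, replace=False)] = 1
        base = background.with_status(status)
        arch = build_architecture(
            pool, target_gene, target_ve, "any", prevalence, rng
        )
        spiked = spike_cases(base, arch, rng)
        rep_mask = apply_standard_filters(spiked)
        idx = spiked.gene_columns(target_gene)
        idx = idx[rep_mask[idx]]
        res = test_gene(spiked, target_gene, config, variant_idx=idx)
        if res.status == "ok" and res.delta_dic > thr:
            hits += 1
    return {
        "level": level,
        "threshold": thr,
        "target_ve": target_ve,
        "n_replicates": n_replicates,
        "power_percent": 100.0 * hits / n_replicates,
    }
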
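"""End-to-end runners: QC + genome-wide testing, power scoring, burden baseline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import qc
from .association import (
    DEFAULT_LEVELS,
    TierThresholds,
    estimate_tier_thresholds,
    scan_delta_dics,
    test_gene,
)
from .cohort import Cohort
from .design import GeneDesign, ModelConfig


@dataclass
class RunConfig:
    """Settings for a genome-wide run."""

    model: ModelConfig = field(default_factory=ModelConfig)
    levels: tuple[float, ...] = DEFAULT_LEVELS
    n_shuffles: int = 10
    af_max: float = 0.01
    score_min: float = 10.0
    drop_synonymous: bool = True
    min_call_rate: float = 0.85
    inclusive_call_rate: bool = False
    n_pca_covariates: int = 0
    score_cols: tuple[str, ...] = ("cadd",)
    covariate_cols: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < a < 1 for a in self.levels):
            raise ValueError("TIER levels must lie in (0, 1)")


def _prepare(cohort: Cohort, config: RunConfig):
    """Apply filters, attach PCA covariates; returns (cohort, mask, cov_cols)."""
    mask = qc.apply_standard_filters(
        cohort,
        af_max=config.af_max,
        score_min=config.score_min,
        drop_synonymous=config.drop_synonymous,
        min_call_rate=config.min_call_rate,
        inclusive_call_rate=config.inclusive_call_rate,
    )
    cov_cols = list(config.covariate_cols)
    if config.n_pca_covariates > 0:
        scores, _ = qc.genotype_pca(
            cohort.genotypes, n_components=config.n_pca_covariates
        )
        samples = cohort.samples.copy()
        for k in range(config.n_pca_covariates):
            samples[f"PC{k + 1}"] = scores[:, k]
        cohort = Cohort(samples=samples, variants=cohort.variants,
                        genotypes=cohort.genotypes)
        cov_cols += [f"PC{k + 1}" for k in range(config.n_pca_covariates)]
    return cohort, mask, cov_cols


def run_rvas(cohort: Cohort, config: RunConfig) -> tuple[pd.DataFrame, TierThresholds]:
    """Filter, calibrate TIER thresholds, test every gene, rank by DeltaDIC.

    Returns the per-gene results table (sorted by DeltaDIC, skipped
    genes unranked at the bottom) and the permutation thresholds.
    """
    cohort, mask, cov_cols = _prepare(cohort, config)
    genes = cohort.gene_ids
    testable = [g for g in genes if mask[cohort.gene_columns(g)].any()]
    if not testable:
        raise ValueError("no testable genes after filtering")

    fast = dataclasses.replace(config.model, dic_method="plugin")
    thresholds = estimate_tier_thresholds(
        cohort, testable, levels=config.levels, S=config.n_shuffles,
        seed=config.seed, config=fast, variant_mask=mask,
        covariate_cols=cov_cols, score_cols=config.score_cols,
    )

    rows = []
    for gene in genes:
        idx = cohort.gene_columns(gene)
        idx = idx[mask[idx]]
        res = test_gene(
            cohort, gene, config.model, variant_idx=idx,
            covariate_cols=cov_cols, score_cols=config.score_cols,
        )
        row = {
            "gene": gene,
            "n_variants": res.n_variants,
            "n_lof": res.n_per_category.get("LoF", 0),
            "n_missense": res.n_per_category.get("missense", 0),
            "delta_dic": res.delta_dic,
            "status": res.status,
        }
        for a in config.levels:
            row[f"sig_{a:g}"] = (
                res.status == "ok" and res.delta_dic > thresholds.medians[a]
            )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "delta_dic", ascending=False, na_position="last"
    )
    ok = table["status"] == "ok"
    table["rank"] = np.nan
    table.loc[ok, "rank"] = np.arange(1, ok.sum() + 1)
    return table.reset_index(drop=True), thresholds


def estimate_power(
    replicate_results: list[dict],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Power per (gene, target VE, TIER level) across replicates.

    ``replicate_results`` entries need ``gene``, ``target_ve`` and a
    ``significant`` dict mapping level -> bool (one entry per
    replicate, as produced by the benchmark driver).
    """
    if not replicate_results:
        raise ValueError("no replicate results")
    df = pd.DataFrame(replicate_results)
    rows = []
    for (gene, ve), grp in df.groupby(["gene", "target_ve"]):
        for a in levels:
            calls = [bool(s.get(a, False)) for s in grp["significant"]]
            rows.append(
                {
                    "gene": gene,
                    "target_ve": ve,
                    "level": a,
                    "power": float(np.mean(calls)),
                    "n_replicates": len(calls),
                }
            )
    return pd.DataFrame(rows)


def burden_baseline(design: GeneDesign) -> tuple[float, bool]:
    """Logistic likelihood-ratio burden test; plumbing sanity baseline.

    Regresses phenotype on the per-sample minor-allele count plus the
    design's covariates and compares against the covariate-only model.
    Returns (p_value, degenerate).  A constant burden (e.g. no
    carriers) is degenerate with p = 1.
    """
    import statsmodels.api as sm

    burden = design.G.sum(axis=1)
    if np.ptp(burden) == 0:
        return 1.0, True
    y = design.y
    X0 = design.X
    X1 = np.column_stack([X0, burden])
    try:
        fit0 = sm.Logit(y, X0).fit(disp=0)
        fit1 = sm.Logit(y, X1).fit(disp=0)
        lr = 2.0 * (fit1.llf - fit0.llf)
    except Exception:
        return 1.0, True
    if not np.isfinite(lr):
        return 1.0, True
    return float(chi2.sf(max(lr, 0.0), df=1)), False
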
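"""Gene-level association via DIC model comparison.

For each gene the covariates-only null model H0 and the genetic model
H1 are fitted and compared through

    DeltaDIC = DIC(H0) - DIC(H1),

so positive values favour the genetic model.  Because DeltaDIC has no
analytic null distribution, genome-wide significance thresholds are
calibrated empirically: case/control labels are permuted S times
(preserving group sizes), every gene is re-tested, and for a type-I
error level a the threshold is the DeltaDIC order statistic at the
top ceil(K*a) descending rank among the K tested genes; the final
threshold per level is the median over the S shuffles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .design import ModelConfig, assemble_design
from .inference import ConvergenceError, FitResult, fit_model

DEFAULT_LEVELS = (0.05, 0.001, 1e-4)


@dataclass
class GeneResult:
    gene_id: str
    delta_dic: float = np.nan
    n_variants: int = 0
    n_per_category: dict = field(default_factory=dict)
    effects: pd.DataFrame | None = None
    status: str = "ok"  # ok / degenerate / skipped
    message: str = ""

    def __post_init__(self) -> None:
        if self.status == "ok" and not np.isfinite(self.delta_dic):
            raise ValueError("DeltaDIC must be finite when status is ok")


@dataclass
class TierThresholds:
    """Permutation-calibrated DeltaDIC significance thresholds."""

    levels: tuple[float, ...]
    per_shuffle: np.ndarray  # shape (S, n_levels)
    medians: dict[float, float]
    S: int
    seed: int

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        per = np.atleast_2d(self.per_shuffle)
        for j, level in enumerate(self.levels):
            med = self.medians[level]
            if not (per[:, j].min() - 1e-9 <= med <= per[:, j].max() + 1e-9):
                raise ValueError("median threshold outside per-shuffle range")
        meds = [self.medians[a] for a in sorted(self.levels, reverse=True)]
        if any(b < a - 1e-9 for a, b in zip(meds, meds[1:])) and len(meds) > 1:
            # stricter levels (smaller a) must not have smaller thresholds
            raise ValueError("thresholds must be non-decreasing with strictness")


def delta_dic(fit_null: FitResult, fit_full: FitResult) -> float:
    """DIC(H0) - DIC(H1); positive values favour the genetic model."""
    if fit_null.status != "ok" or fit_full.status != "ok":
        return float("nan")
    return float(fit_null.dic - fit_full.dic)


def test_gene(
    cohort: Cohort,
    gene_id: str,
    config: ModelConfig,
    *,
    status: np.ndarray | None = None,
    fit_null: FitResult | None = None,
    variant_idx: np.ndarray | None = None,
    **assemble_kwargs,
) -> GeneResult:
    """Fit H0 and H1 for one gene and return its DeltaDIC report.

    ``fit_null`` may be supplied to share a single covariates-only fit
    across genes (the null model does not depend on the gene).
    """
    design = assemble_design(
        cohort, gene_id, variant_idx=variant_idx, status=status, **assemble_kwargs
    )
    if design.p == 0:
        return GeneResult(gene_id=gene_id, status="skipped",
                          message="no qualifying variants")
    try:
        if fit_null is None:
            fit_null = fit_model(design, config, "null")
        fit_full = fit_model(design, config, "full")
    except ConvergenceError as exc:
        return GeneResult(gene_id=gene_id, status="degenerate", message=str(exc))

    cats = design.z_names[: len([k for k in design.z_kinds if k == "category"])]
    cat_counts = {
        c: int(design.Z[:, j].sum())
        for j, c in enumerate(cats)
    }
    return GeneResult(
        gene_id=gene_id,
        delta_dic=delta_dic(fit_null, fit_full),
        n_variants=design.p,
        n_per_category=cat_counts,
        effects=fit_full.effects,
    )


def threshold_from_deltas(deltas: np.ndarray, level: float) -> float:
    """DeltaDIC at descending rank ceil(K * level); ties take the larger value.

    This is the empirical upper-tail order statistic used by the
    permutation calibration: with K null genes ranked by DeltaDIC, the
    gene at the top ``level`` position defines the threshold.
    """
    deltas = np.asarray(deltas, dtype=float)
    deltas = deltas[np.isfinite(deltas)]
    K = len(deltas)
    if K == 0:
        raise ValueError("no finite DeltaDIC values")
    rank = max(1, math.ceil(K * level))
    return float(np.sort(deltas)[::-1][rank - 1])


def build_gene_designs(
    cohort: Cohort,
    gene_ids: list[str],
    *,
    variant_mask: np.ndarray | None = None,
    **assemble_kwargs,
) -> dict:
    """Assemble designs for many genes once (genes with p=0 omitted)."""
    designs = {}
    for gene in gene_ids:
        idx = cohort.gene_columns(gene)
        if variant_mask is not None:
            idx = idx[variant_mask[idx]]
        if idx.size == 0:
            continue
        designs[gene] = assemble_design(
            cohort, gene, variant_idx=idx, **assemble_kwargs
        )
    return designs


def _scan_designs(
    designs: dict,
    y: np.ndarray,
    config: ModelConfig,
) -> dict[str, float]:
    """DeltaDIC per pre-assembled design for one phenotype assignment.

    The covariates-only null fit depends only on y, so it is computed
    once and shared by every gene in the scan.
    """
    fit_null = None
    out = {}
    for gene, design in designs.items():
        d = design.with_y(y)
        if fit_null is None:
            fit_null = fit_model(d, config, "null", compute_effects=False)
        try:
            fit_full = fit_model(d, config, "full", compute_effects=False)
        except ConvergenceError:
            out[gene] = np.nan
            continue
        out[gene] = delta_dic(fit_null, fit_full)
    return out


def scan_delta_dics(
    cohort: Cohort,
    gene_ids: list[str],
    config: ModelConfig,
    *,
    status: np.ndarray | None = None,
    variant_mask: np.ndarray | None = None,
    **assemble_kwargs,
) -> pd.Series:
    """DeltaDIC for every gene under one phenotype assignment.

    Genes left with zero qualifying variants are returned as NaN.
    """
    y = cohort.status if status is None else np.asarray(status)
    designs = build_gene_designs(
        cohort, gene_ids, variant_mask=variant_mask, **assemble_kwargs
    )
    scanned = _scan_designs(designs, y, config)
    return pd.Series(
        {g: scanned.get(g, np.nan) for g in gene_ids}, name="delta_dic"
    )


def estimate_tier_thresholds(
    cohort: Cohort,
    gene_ids: list[str],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    S: int = 10,
    seed: int = 0,
    config: ModelConfig | None = None,
    *,
    variant_mask: np.ndarray | None = None,
    **assemble_kwargs,
) -> TierThresholds:
    """Permutation-calibrated significance thresholds per TIER level.

    For each of ``S`` shuffles the case/control labels are permuted
    (preserving the original group sizes), every gene is re-tested,
    and per-level order-statistic thresholds are extracted; the final
    threshold is the per-level median over shuffles.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    config = config or ModelConfig()
    K = len(gene_ids)
    if K < 1 / min(levels):
        import warnings

        warnings.warn(
            f"only {K} genes for a minimum level of {min(levels)}; "
            "thresholds will be coarse",
            RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    base = cohort.status
    designs = build_gene_designs(
        cohort, gene_ids, variant_mask=variant_mask, **assemble_kwargs
    )
    per_shuffle = np.empty((S, len(levels)))
    for s in range(S):
        y_perm = rng.permutation(base)
        deltas = np.array(list(_scan_designs(designs, y_perm, config).values()))
        if not np.isfinite(deltas).any():
            raise ValueError("all genes skipped in permutation scan")
        for j, a in enumerate(levels):
            per_shuffle[s, j] = threshold_from_deltas(deltas, a)
    medians = {
        a: float(np.median(per_shuffle[:, j])) for j, a in enumerate(levels)
    }
    return TierThresholds(
        levels=tuple(levels), per_shuffle=per_shuffle, medians=medians,
        S=S, seed=seed,
    )


def classify_genes(
    results: list[GeneResult] | pd.Series,
    thresholds: TierThresholds,
    level: float,
) -> set[str]:
    """Genes whose DeltaDIC strictly exceeds the median threshold."""
    if level not in thresholds.medians:
        raise KeyError(f"level {level} not in thresholds")
    thr = thresholds.medians[level]
    if isinstance(results, pd.Series):
        items = results.items()
        return {g for g, d in items if np.isfinite(d) and d > thr}
    return {
        r.gene_id
        for r in results
        if r.status == "ok" and np.isfinite(r.delta_dic) and r.delta_dic > thr
    }
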
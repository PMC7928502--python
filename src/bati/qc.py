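"""Variant- and sample-level quality control.

Implements the filtering stages that precede association testing:
common-variant / benign-variant removal (allele frequency, CADD,
synonymous), a call-rate gate, per-sample transition/transversion
ratios, outlier flagging on summary statistics, and genotype PCA for
population-stratification covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import MISSING, Cohort

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = {"A", "C", "G", "T"}


def filter_variants(
    records: pd.DataFrame,
    af_max: float = 0.01,
    score_min: float = 10.0,
    drop_synonymous: bool = True,
    *,
    control_af: np.ndarray | None = None,
    af_cols: tuple[str, ...] = ("af_public",),
    score_col: str = "cadd",
    category_col: str = "exonic_function",
) -> np.ndarray:
    """Boolean keep-mask for the rare/damaging variant filter.

    A variant is kept iff every available allele frequency (public
    panels and, when provided, the randomized control group) is
    <= ``af_max``, its score is >= ``score_min``, and (optionally) it
    is not synonymous.
    """
    for col in (*af_cols, score_col, category_col):
        if col not in records.columns:
            raise KeyError(f"annotation column '{col}' missing")
        bad = records.index[records[col].isna()]
        if len(bad):
            raise ValueError(f"missing '{col}' for variant row(s) {list(bad)[:5]}")
    keep = np.ones(len(records), dtype=bool)
    for col in af_cols:
        keep &= records[col].to_numpy(dtype=float) <= af_max
    if control_af is not None:
        keep &= np.asarray(control_af, dtype=float) <= af_max
    keep &= records[score_col].to_numpy(dtype=float) >= score_min
    if drop_synonymous:
        keep &= records[category_col].to_numpy() != "synonymous"
    return keep


def call_rate_filter(
    call_rates: np.ndarray, min_rate: float, inclusive: bool = False
) -> np.ndarray:
    """Keep-mask on per-variant call rate.

    The simulation-cohort rule is strictly greater than the threshold
    (default); the application rule (``inclusive=True``) keeps
    variants at or above it.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    cr = np.asarray(call_rates, dtype=float)
    return cr >= min_rate if inclusive else cr > min_rate


def classify_titv(ref: str, alt: str) -> str | None:
    """'ti', 'tv', or None for non-SNVs."""
    if ref in _BASES and alt in _BASES and ref != alt:
        return "ti" if (ref, alt) in _TRANSITIONS else "tv"
    return None


def compute_titv(records: pd.DataFrame) -> tuple[float, bool]:
    """Ti/Tv ratio over a set of variant records (indels excluded).

    Returns (ratio, defined); with zero transversions the ratio is
    undefined and NaN is returned with ``defined=False``.
    """
    n_ti = n_tv = 0
    for ref, alt in zip(records["ref"], records["alt"]):
        kind = classify_titv(str(ref), str(alt))
        if kind == "ti":
            n_ti += 1
        elif kind == "tv":
            n_tv += 1
    if n_tv == 0:
        return float("nan"), False
    return n_ti / n_tv, True


def sample_statistics(cohort: Cohort) -> pd.DataFrame:
    """Per-sample variant counts and Ti/Tv ratios (over carried SNVs)."""
    refs = cohort.variants["ref"].astype(str).to_numpy()
    alts = cohort.variants["alt"].astype(str).to_numpy()
    kinds = np.array([classify_titv(r, a) for r, a in zip(refs, alts)], dtype=object)
    is_ti = kinds == "ti"
    is_tv = kinds == "tv"
    carried = cohort.genotypes > 0
    n_var = carried.sum(axis=1)
    n_ti = carried[:, is_ti].sum(axis=1)
    n_tv = carried[:, is_tv].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        titv = np.where(n_tv > 0, n_ti / np.maximum(n_tv, 1), np.nan)
    return pd.DataFrame(
        {"n_variants": n_var, "titv": titv}, index=cohort.samples.index
    )


def detect_sample_outliers(
    sample_stats: pd.DataFrame,
    k_sd: float = 3.0,
    pc_sd: float = 6.0,
) -> pd.DataFrame:
    """Flag samples deviating on variant count, Ti/Tv or PC1/PC2.

    A sample is flagged when its z-score exceeds ``k_sd`` standard
    deviations on the variant count or Ti/Tv ratio, or ``pc_sd`` on
    either of the first two principal components (when present).
    Returns the stats table with ``outlier`` and ``reasons`` columns.
    """
    if len(sample_stats) < 3:
        raise ValueError("need at least 3 samples to define outliers")

    def zscores(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ok = np.isfinite(x)
        mu, sd = x[ok].mean(), x[ok].std()
        if sd == 0 or not np.isfinite(sd):
            return np.zeros(len(x))
        z = np.zeros(len(x))
        z[ok] = (x[ok] - mu) / sd
        return z

    checks = {"n_variants": k_sd, "titv": k_sd, "PC1": pc_sd, "PC2": pc_sd}
    reasons = [[] for _ in range(len(sample_stats))]
    for col, thr in checks.items():
        if col not in sample_stats.columns:
            continue
        z = zscores(sample_stats[col].to_numpy())
        for i in np.flatnonzero(np.abs(z) > thr):
            reasons[i].append(col)
    out = sample_stats.copy()
    out["outlier"] = [len(r) > 0 for r in reasons]
    out["reasons"] = [",".join(r) for r in reasons]
    return out


def genotype_pca(
    genotypes: np.ndarray,
    n_components: int = 10,
    maf_min: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the genotype matrix.

    Restricts to variants with MAF >= ``maf_min`` (rare variants carry
    no stable axes), mean-imputes missing calls, centres and
    unit-scales columns, and returns (scores, explained-variance
    fractions).
    """
    G = np.asarray(genotypes, dtype=float)
    N = G.shape[0]
    if N < n_components:
        raise ValueError("need at least n_components samples")
    miss = G == MISSING
    Gn = np.where(miss, np.nan, G)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(Gn, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    usable = np.isfinite(maf) & (maf >= maf_min)
    if not usable.any():
        raise ValueError("no variants with MAF >= maf_min for PCA")
    Gn = Gn[:, usable]
    col_mean = np.nanmean(Gn, axis=0)
    inds = np.where(np.isnan(Gn))
    Gn[inds] = np.take(col_mean, inds[1])
    Gn -= col_mean
    sd = Gn.std(axis=0)
    sd[sd == 0] = 1.0
    Gn /= sd
    if not Gn.any():
        return np.zeros((N, n_components)), np.zeros(n_components)
    k = min(n_components, min(Gn.shape) - 1) or 1
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Gn)
    if k < n_components:
        scores = np.pad(scores, ((0, 0), (0, n_components - k)))
        evr = np.pad(pca.explained_variance_ratio_, (0, n_components - k))
    else:
        evr = pca.explained_variance_ratio_
    return scores, evr


def apply_standard_filters(
    cohort: Cohort,
    *,
    af_max: float = 0.01,
    score_min: float = 10.0,
    drop_synonymous: bool = True,
    min_call_rate: float = 0.85,
    inclusive_call_rate: bool = False,
    status: np.ndarray | None = None,
) -> np.ndarray:
    """Composite keep-mask: rare/damaging filter + call-rate gate.

    Uses the public allele frequencies from the annotation table plus
    the control-group allele frequency computed from the (possibly
    permuted) labels.
    """
    control_af = cohort.control_allele_frequency(status)
    keep = filter_variants(
        cohort.variants,
        af_max=af_max,
        score_min=score_min,
        drop_synonymous=drop_synonymous,
        control_af=control_af,
    )
    keep &= call_rate_filter(cohort.call_rate(), min_call_rate, inclusive_call_rate)
    return keep
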
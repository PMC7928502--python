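"""Model configuration and per-gene design assembly.

The association model for one gene is a hierarchical logistic
regression.  For individual i with phenotype y_i,

    logit P(y_i = 1) = x_i' alpha + g_i' beta,
    beta_j = z_j' omega + delta_j,        delta_j ~ N(0, tau),

where x_i are individual covariates (intercept first), g_i the dosage
vector over the gene's rare variants, z_j the characteristics of
variant j (exonic-function indicators plus numeric scores such as
CADD), omega the shared characteristic effects and delta_j a
variant-specific random deviation.  Substituting gives the mixed-model
linear predictor

    eta_i = x_i' alpha + (g_i' Z) omega + g_i' delta.

:func:`assemble_design` builds the (y, X, G, Z) blocks from cohort
tables; :class:`ModelConfig` holds priors and numerical settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort


@dataclass(frozen=True)
class ModelConfig:
    """Priors and numerical controls for the gene-level fit.

    The outcome likelihood is fixed to Bernoulli with logit link.
    Fixed effects (alpha, omega) carry independent N(0, 1/c) priors
    with precision ``fixed_effect_prior_precision``; the random-effect
    precision 1/tau carries a Gamma(shape, rate) hyperprior.  Grid
    integration over the hyperparameter works on the log-precision
    scale psi = -log(tau).
    """

    fixed_effect_prior_precision: float = 0.001
    hyperprior_shape: float = 1.0
    hyperprior_rate: float = 5e-5
    grid_max_points: int = 35
    grid_log_drop: float = 6.0
    grid_step_factor: float = 0.5
    psi_bounds: tuple[float, float] = (-3.0, 16.0)
    newton_tol: float = 1e-8
    newton_max_iter: int = 100
    dic_samples: int = 200
    dic_method: str = "mc"  # "mc" or "plugin"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fixed_effect_prior_precision", "hyperprior_shape",
                     "hyperprior_rate", "newton_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dic_samples < 1:
            raise ValueError("dic_samples must be >= 1")
        if self.grid_max_points < 1:
            raise ValueError("grid_max_points must be >= 1")
        if self.dic_method not in ("mc", "plugin"):
            raise ValueError("dic_method must be 'mc' or 'plugin'")


@dataclass
class GeneDesign:
    """Ready-to-fit data blocks for one gene.

    Attributes
    ----------
    y : (N,) 0/1 phenotype
    X : (N, m) individual covariates, intercept in column 0
    G : (N, p) genotype dosages in {0, 1, 2} (missing already imputed)
    Z : (p, q) variant characteristics: one indicator column per
        observed exonic-function category plus one column per numeric
        score
    """

    gene_id: str
    y: np.ndarray
    X: np.ndarray
    G: np.ndarray
    Z: np.ndarray
    variant_ids: list[str] = field(default_factory=list)
    x_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)
    z_kinds: list[str] = field(default_factory=list)  # "category" / "score"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.G = np.asarray(self.G, dtype=float).reshape(len(self.y), -1)
        Z = np.asarray(self.Z, dtype=float)
        p = self.G.shape[1]
        self.Z = Z.reshape(p, -1) if Z.size else Z.reshape(p, 0)
        n = len(self.y)
        if self.X.shape[0] != n or self.G.shape[0] != n:
            raise ValueError("y, X and G must have the same number of rows")
        if not np.isin(self.y, [0.0, 1.0]).all():
            raise ValueError("phenotype must be binary 0/1")
        if self.G.size and not np.isin(np.unique(self.G), [0.0, 1.0, 2.0]).all():
            # mean imputation can give fractional dosages; only reject
            # values outside the [0, 2] dosage range
            if (self.G < 0).any() or (self.G > 2).any():
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return self.G.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def n_latent(self) -> int:
        """Length of the latent field u = (alpha, omega, delta)."""
        return self.m + self.q + self.p

    def blocks(self) -> dict[str, slice]:
        """Index map partitioning u into its alpha/omega/delta blocks."""
        return {
            "alpha": slice(0, self.m),
            "omega": slice(self.m, self.m + self.q),
            "delta": slice(self.m + self.q, self.n_latent),
        }

    def predictor_matrix(self) -> np.ndarray:
        """N x (m+q+p) matrix A with eta = A @ u."""
        if self.p == 0:
            return self.X
        return np.hstack([self.X, self.G @ self.Z, self.G])

    def fixed_effect_names(self) -> list[str]:
        return list(self.x_names) + list(self.z_names)

    def with_y(self, y: np.ndarray) -> "GeneDesign":
        """Cheap copy with a replacement phenotype (permutation scans)."""
        import copy

        new = copy.copy(self)
        new.y = np.asarray(y, dtype=float)
        if len(new.y) != len(self.y):
            raise ValueError("replacement phenotype has wrong length")
        return new

    def drop_variants(self) -> "GeneDesign":
        """Null-model reduction: covariates only."""
        return GeneDesign(
            gene_id=self.gene_id,
            y=self.y,
            X=self.X,
            G=np.empty((self.n, 0)),
            Z=np.empty((0, 0)),
            x_names=list(self.x_names),
        )


def assemble_design(
    cohort: Cohort,
    gene_id: str,
    *,
    covariate_cols: list[str] | None = None,
    score_cols: tuple[str, ...] = ("cadd",),
    category_col: str = "exonic_function",
    impute: str = "zero",
    variant_idx: np.ndarray | None = None,
    status: np.ndarray | None = None,
    center_scores: bool = False,
) -> GeneDesign:
    """Build the per-gene design from cohort tables.

    Parameters
    ----------
    variant_idx
        Optional pre-filtered cohort column indices for the gene
        (e.g. after QC filtering); defaults to every variant annotated
        to the gene.
    status
        Optional replacement phenotype vector (used by the permutation
        machinery); defaults to the cohort's case/control labels.
    impute
        Missing-genotype policy: ``"zero"`` codes missing calls as
        homozygous reference, ``"mean"`` uses the variant's mean
        observed dosage.
    """
    if cohort.n_samples == 0:
        raise ValueError("cohort has no samples")
    y = cohort.status if status is None else np.asarray(status, dtype=np.int8)
    if len(y) != cohort.n_samples:
        raise ValueError("status vector length does not match cohort")

    covariate_cols = list(covariate_cols or [])
    missing_cov = [c for c in covariate_cols if c not in cohort.samples.columns]
    if missing_cov:
        raise KeyError(f"covariate columns not in sample table: {missing_cov}")
    X = np.column_stack(
        [np.ones(cohort.n_samples)]
        + [cohort.samples[c].to_numpy(dtype=float) for c in covariate_cols]
    )
    x_names = ["intercept"] + covariate_cols

    idx = cohort.gene_columns(gene_id) if variant_idx is None else np.asarray(variant_idx)
    if idx.size == 0:
        return GeneDesign(
            gene_id=gene_id,
            y=y,
            X=X,
            G=np.empty((cohort.n_samples, 0)),
            Z=np.empty((0, 0)),
            x_names=x_names,
        )

    ann = cohort.variants.iloc[idx]
    for col in (category_col, *score_cols):
        if col not in ann.columns:
            raise KeyError(f"annotation column '{col}' missing")
        bad = ann.index[ann[col].isna()]
        if len(bad):
            raise ValueError(
                f"gene {gene_id}: missing '{col}' annotation for variant row(s) {list(bad)}"
            )

    G = cohort.genotypes[:, idx].astype(float)
    miss = G == MISSING
    if miss.any():
        if impute == "zero":
            G[miss] = 0.0
        elif impute == "mean":
            col_mean = np.where(~miss, G, np.nan)
            means = np.nanmean(col_mean, axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            G[miss] = np.broadcast_to(means, G.shape)[miss]
        else:
            raise ValueError(f"unknown imputation mode '{impute}'")

    cats = ann[category_col].astype(str).to_numpy()
    observed = sorted(pd.unique(cats))
    z_cols, z_names, z_kinds = [], [], []
    for c in observed:
        z_cols.append((cats == c).astype(float))
        z_names.append(c)
        z_kinds.append("category")
    for s in score_cols:
        v = ann[s].to_numpy(dtype=float)
        if center_scores:
            v = v - v.mean()
        z_cols.append(v)
        z_names.append(s)
        z_kinds.append("score")
    Z = np.column_stack(z_cols) if z_cols else np.empty((len(idx), 0))

    key_cols = ["chrom", "pos", "ref", "alt"]
    if all(c in ann.columns for c in key_cols):
        vids = [
            f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}" for r in ann[key_cols].itertuples()
        ]
    else:
        vids = [str(i) for i in idx]

    return GeneDesign(
        gene_id=gene_id,
        y=y,
        X=X,
        G=G,
        Z=Z,
        variant_ids=vids,
        x_names=x_names,
        z_names=z_names,
        z_kinds=z_kinds,
    )
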
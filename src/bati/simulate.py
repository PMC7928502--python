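"""Synthetic case-control cohort and risk-architecture generator.

Two layers are generated:

* a *background* whole-exome-like cohort — per-gene rare-variant
  counts, a rare-skewed allele-frequency spectrum, exonic-function
  categories with category-specific deleteriousness scores,
  Hardy-Weinberg genotypes (optionally perturbed per population by a
  Balding-Nichols model), and per-entry missingness;
* *risk architectures* — pools of rare risk variants with
  MAF-dependent relative risks, accumulated one variant at a time
  until a target fraction of liability-scale phenotypic variance (VE)
  is explained, then spiked into case genotypes (at most one spiked
  variant per case, heterozygous).

The defaults mimic a filtered WES cohort qualitatively: ~25 variants
per gene, MAF density proportional to 1/x, category mix dominated by
synonymous and missense variants, and CADD-like scores that rise from
synonymous through missense/indel to loss-of-function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .cohort import MISSING, Cohort

#: category -> (probability, score mean, score sd)
DEFAULT_CATEGORIES = {
    "synonymous": (0.45, 5.0, 3.0),
    "missense": (0.45, 18.0, 6.0),
    "LoF": (0.04, 32.0, 5.0),
    "indel": (0.06, 22.0, 6.0),
}

DEFAULT_PREVALENCE = 0.0066  # 5-year breast-cancer prevalence used throughout


@dataclass
class BackgroundCohortSpec:
    """Parameters of the synthetic background cohort."""

    n_samples: int = 600
    case_fraction: float = 0.5  # 1:1 design; 1/3 gives the 1:2 design
    n_genes: int = 200
    gene_mean_log_variants: float = float(np.log(25.0))
    gene_sd_log_variants: float = 0.5
    maf_min: float | None = None  # default 1/(2N)
    maf_max: float = 0.05
    categories: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    populations: dict = field(default_factory=lambda: {"POP1": 1.0})
    divergence: float = 0.0  # Balding-Nichols Fst-like parameter
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        for name, probs in (("categories", [v[0] for v in self.categories.values()]),
                            ("populations", list(self.populations.values()))):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")


@dataclass
class RiskVariantPool:
    """Candidate risk variants: rare MAF, MAF-dependent RR, annotation."""

    maf: np.ndarray
    rr: np.ndarray
    category: np.ndarray
    score: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        if ((self.maf <= 0) | (self.maf > 0.01)).any():
            raise ValueError("risk-variant MAF must lie in (0, 0.01]")
        if (self.rr < 1.0).any():
            raise ValueError("relative risks must be >= 1")

    def __len__(self) -> int:
        return len(self.maf)

    def subset(self, idx: np.ndarray) -> "RiskVariantPool":
        return RiskVariantPool(
            maf=self.maf[idx], rr=self.rr[idx], category=self.category[idx],
            score=self.score[idx], population=self.population[idx],
        )


@dataclass
class ArchitectureSpec:
    """A VE-targeted selection of risk variants for one gene."""

    gene: str
    target_ve: float
    mode: str  # "missense-only" / "lof-only" / "any"
    prevalence: float
    variants: pd.DataFrame  # maf, rr, category, score, population, ve
    cumulative_ve: float

    def __post_init__(self) -> None:
        if self.target_ve > 0:
            if self.cumulative_ve < self.target_ve - 1e-12:
                raise ValueError("cumulative VE below target")
            if len(self.variants) > 1:
                without_last = self.cumulative_ve - self.variants["ve"].iloc[-1]
                if without_last >= self.target_ve:
                    raise ValueError("stopping rule violated: last variant redundant")


# ----------------------------------------------------------------------
# background cohort
# ----------------------------------------------------------------------

def _truncated_normal(mean, sd, low, rng, size):
    a = (low - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _reciprocal_maf(n, lo, hi, rng):
    """Sample from density proportional to 1/x on [lo, hi]."""
    u = rng.random(n)
    return lo * (hi / lo) ** u


def simulate_background(spec: BackgroundCohortSpec) -> Cohort:
    """Generate the background cohort (no risk variants).

    Genotypes are Binomial(2, MAF) per sample under Hardy-Weinberg
    equilibrium; with more than one population and a positive
    divergence parameter, per-population allele frequencies are drawn
    from the Balding-Nichols Beta distribution around the ancestral
    MAF.  Identical specs (including seed) give byte-identical
    cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_samples

    # samples ---------------------------------------------------------
    n_cases = int(round(spec.case_fraction * N))
    status = np.zeros(N, dtype=np.int8)
    status[rng.choice(N, size=n_cases, replace=False)] = 1
    pop_names = list(spec.populations)
    pop_probs = np.array([spec.populations[k] for k in pop_names])
    sample_pop = rng.choice(len(pop_names), size=N, p=pop_probs)
    samples = pd.DataFrame(
        {
            "status": status,
            "population": [pop_names[i] for i in sample_pop],
        },
        index=pd.Index([f"S{i:05d}" for i in range(N)], name="sample"),
    )

    # variants --------------------------------------------------------
    gene_means = np.exp(
        rng.normal(spec.gene_mean_log_variants, spec.gene_sd_log_variants, spec.n_genes)
    )
    counts = rng.poisson(gene_means)
    counts = np.maximum(counts, 1)
    P = int(counts.sum())
    gene_ids = np.repeat([f"G{i:05d}" for i in range(spec.n_genes)], counts)

    lo = spec.maf_min if spec.maf_min is not None else 1.0 / (2 * N)
    maf = _reciprocal_maf(P, lo, spec.maf_max, rng)

    cat_names = list(spec.categories)
    cat_probs = np.array([spec.categories[c][0] for c in cat_names])
    cat_idx = rng.choice(len(cat_names), size=P, p=cat_probs)
    category = np.array(cat_names, dtype=object)[cat_idx]
    score = np.empty(P)
    for ci, c in enumerate(cat_names):
        mask = cat_idx == ci
        if mask.any():
            _, mu, sd = spec.categories[c]
            score[mask] = _truncated_normal(mu, sd, 0.0, rng, int(mask.sum()))

    # per-population allele frequencies (Balding-Nichols)
    n_pops = len(pop_names)
    if n_pops > 1 and spec.divergence > 0:
        F = spec.divergence
        a = maf * (1 - F) / F
        b = (1 - maf) * (1 - F) / F
        pop_af = np.stack(
            [np.clip(rng.beta(a, b), 1e-6, 0.5) for _ in range(n_pops)], axis=1
        )
    else:
        pop_af = np.tile(maf[:, None], (1, n_pops))

    # genotypes, chunked over variants to bound memory ----------------
    G = np.empty((N, P), dtype=np.int8)
    chunk = max(1, int(4e6 // max(N, 1)))
    for start in range(0, P, chunk):
        end = min(start + chunk, P)
        probs = pop_af[start:end, :][:, sample_pop].T  # N x chunk
        G[:, start:end] = rng.binomial(2, probs).astype(np.int8)
    if spec.missing_rate > 0:
        miss = rng.random((N, P)) < spec.missing_rate
        G[miss] = MISSING

    pos = np.arange(1, P + 1) * 100
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "gene": gene_ids,
            "exonic_function": category,
            "cadd": score,
            "af_public": maf,
        }
    )
    for k, name in enumerate(pop_names):
        variants[f"population_af_{name}"] = pop_af[:, k]
    return Cohort(samples=samples, variants=variants, genotypes=G)


# ----------------------------------------------------------------------
# risk variants
# ----------------------------------------------------------------------

def sample_rr(maf: np.ndarray | float, rng: np.random.Generator) -> np.ndarray:
    """Relative risks negatively correlated with MAF.

    log RR is normal with sd 0.3 and a median that decays linearly in
    MAF from RR = 8 at MAF -> 0 down to RR = 1.5 at MAF = 0.01; draws
    are truncated below at RR = 1.1.
    """
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    if ((maf <= 0) | (maf > 0.01)).any():
        raise ValueError("MAF must lie in (0, 0.01]")
    mu = np.log(8.0) + (np.log(1.5) - np.log(8.0)) * (maf / 0.01)
    sd = 0.3
    a = (np.log(1.1) - mu) / sd
    log_rr = truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng)
    return np.exp(log_rr)


def variance_explained(prevalence: float, maf: float, rr: float) -> float:
    """Liability-scale variance explained by one biallelic risk variant.

    Under Hardy-Weinberg genotype frequencies and multiplicative
    genotype relative risks (lambda_1 = RR, lambda_2 = RR^2), the
    baseline penetrance is scaled so the population risk equals the
    prevalence K.  Each genotype g then corresponds to a mean liability
    shift mu_g = PHI^-1(1-K) - PHI^-1(1-f_g) on the standard-normal
    liability scale, and

        VE = Var_g(mu_g) / (Var_g(mu_g) + 1).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must be in (0, 1)")
    if rr < 1.0:
        raise ValueError("rr must be >= 1")
    p = maf
    freqs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    lam = np.array([1.0, rr, rr**2])
    baseline = prevalence / float(freqs @ lam)
    penetrance = baseline * lam
    if (penetrance > 1.0).any():
        raise ValueError("implied penetrance exceeds 1; rr too large for prevalence")
    threshold = norm.ppf(1.0 - prevalence)
    mu = threshold - norm.ppf(1.0 - penetrance)
    mean_mu = float(freqs @ mu)
    var_mu = float(freqs @ (mu - mean_mu) ** 2)
    return var_mu / (var_mu + 1.0)


def simulate_risk_pool(
    n_variants: int,
    rng: np.random.Generator,
    *,
    maf_range: tuple[float, float] = (1e-4, 0.01),
    category_probs: dict | None = None,
    populations: list[str] | None = None,
) -> RiskVariantPool:
    """Generate a ClinVar/HGMD-like pool of rare risk variants.

    Scores are drawn from the same per-category distributions as the
    background but truncated at 10, reflecting that curated disease
    variants are almost always predicted damaging.
    """
    category_probs = category_probs or {"missense": 0.6, "LoF": 0.3, "indel": 0.1}
    names = list(category_probs)
    probs = np.array([category_probs[c] for c in names])
    maf = _reciprocal_maf(n_variants, maf_range[0], maf_range[1], rng)
    rr = sample_rr(maf, rng)
    cat_idx = rng.choice(len(names), size=n_variants, p=probs)
    category = np.array(names, dtype=object)[cat_idx]
    score = np.empty(n_variants)
    for ci, c in enumerate(names):
        mask = cat_idx == ci
        if mask.any():
            _, mu, sd = DEFAULT_CATEGORIES.get(c, (0, 25.0, 5.0))
            score[mask] = _truncated_normal(mu, sd, 10.0, rng, int(mask.sum()))
    pops = populations or ["POP1"]
    population = np.array([pops[i] for i in rng.integers(0, len(pops), n_variants)],
                          dtype=object)
    return RiskVariantPool(maf=maf, rr=rr, category=category, score=score,
                           population=population)


def assign_populations(
    pool: RiskVariantPool,
    population_afs: pd.DataFrame | None,
    populations: list[str],
    rng: np.random.Generator,
) -> RiskVariantPool:
    """Label each risk variant with a population.

    Variants with reference-panel frequencies take the population of
    their largest observed allele frequency; variants absent from the
    panel (all-NaN rows) are assigned uniformly at random.  With a
    single population everything is labelled homogeneously.
    """
    if not populations:
        raise ValueError("populations must be non-empty")
    n = len(pool)
    if len(populations) == 1 or population_afs is None:
        if len(populations) == 1:
            labels = np.array([populations[0]] * n, dtype=object)
        else:
            labels = np.array(
                [populations[i] for i in rng.integers(0, len(populations), n)],
                dtype=object,
            )
    else:
        afs = population_afs[populations].to_numpy(dtype=float)
        labels = np.empty(n, dtype=object)
        observed = ~np.isnan(afs).all(axis=1)
        arg = np.nanargmax(np.where(np.isnan(afs), -np.inf, afs), axis=1)
        labels[observed] = [populations[i] for i in arg[observed]]
        n_missing = int((~observed).sum())
        labels[~observed] = [
            populations[i] for i in rng.integers(0, len(populations), n_missing)
        ]
    return RiskVariantPool(
        maf=pool.maf, rr=pool.rr, category=pool.category, score=pool.score,
        population=labels,
    )


_MODE_FILTER = {
    "missense-only": lambda c: c == "missense",
    "lof-only": lambda c: c == "LoF",
    "any": lambda c: np.ones(len(c), dtype=bool),
}


def build_architecture(
    pool: RiskVariantPool,
    gene: str,
    target_ve: float,
    mode: str,
    prevalence: float,
    rng: np.random.Generator,
) -> ArchitectureSpec:
    """Accumulate risk variants until the target VE is reached.

    Variants are drawn without replacement (respecting ``mode``); the
    per-variant VE from the liability-threshold model is summed
    additively, treating rare variants as independent, until the
    cumulative VE first meets the target.
    """
    if mode not in _MODE_FILTER:
        raise ValueError(f"unknown mode '{mode}'")
    eligible = np.flatnonzero(_MODE_FILTER[mode](pool.category))
    if target_ve > 0 and eligible.size == 0:
        raise ValueError(f"pool has no variants for mode '{mode}'")
    order = rng.permutation(eligible)
    rows, cum = [], 0.0
    for i in order:
        if cum >= target_ve:
            break
        try:
            ve = variance_explained(
                prevalence, float(pool.maf[i]), float(pool.rr[i])
            )
        except ValueError:
            # extreme RR draws can imply homozygote penetrance > 1 at this
            # prevalence; such variants are not usable in the architecture
            continue
        rows.append(
            (float(pool.maf[i]), float(pool.rr[i]), pool.category[i],
             float(pool.score[i]), pool.population[i], ve)
        )
        cum += ve
    if cum < target_ve:
        raise ValueError(
            f"pool exhausted at cumulative VE {cum:.4f} < target {target_ve}"
        )
    variants = pd.DataFrame(
        rows, columns=["maf", "rr", "category", "score", "population", "ve"]
    )
    return ArchitectureSpec(
        gene=gene, target_ve=target_ve, mode=mode, prevalence=prevalence,
        variants=variants, cumulative_ve=cum,
    )


# ----------------------------------------------------------------------
# spiking
# ----------------------------------------------------------------------

def spike_cases(
    cohort: Cohort,
    architecture: ArchitectureSpec,
    rng: np.random.Generator,
    *,
    stratified: bool = False,
) -> Cohort:
    """Insert the architecture's risk variants into case genotypes.

    For each selected variant the number of case carriers is drawn
    Binomial(n_eligible_cases, min(2*MAF*RR, 1)) — the rare-variant
    approximation to the case allele frequency — capped by the number
    of still-unspiked eligible cases.  Carriers become heterozygous
    and each case receives at most one spiked variant.  Controls are
    never modified.  In the stratified scenario only cases of the
    variant's population are eligible.
    """
    status = cohort.status
    case_idx = np.flatnonzero(status == 1)
    if case_idx.size == 0:
        raise ValueError("cohort has no cases to spike")

    spiked = np.zeros(cohort.n_samples, dtype=bool)
    new_cols, new_rows = [], []
    pos0 = int(cohort.variants["pos"].max()) + 1000 if len(cohort.variants) else 1000
    for k, row in architecture.variants.iterrows():
        if stratified:
            eligible = case_idx[
                (cohort.samples["population"].to_numpy()[case_idx] == row["population"])
                & ~spiked[case_idx]
            ]
        else:
            eligible = case_idx[~spiked[case_idx]]
        if eligible.size == 0 and not spiked[case_idx].any():
            raise ValueError("no eligible cases for spiking")
        p_carrier = min(2.0 * row["maf"] * row["rr"], 1.0)
        n_carriers = min(int(rng.binomial(len(eligible), p_carrier)), len(eligible))
        col = np.zeros(cohort.n_samples, dtype=np.int8)
        if n_carriers > 0:
            carriers = rng.choice(eligible, size=n_carriers, replace=False)
            col[carriers] = 1
            spiked[carriers] = True
        new_cols.append(col)
        new_rows.append(
            {
                "chrom": "1",
                "pos": pos0 + 100 * k,
                "ref": "A",
                "alt": "T",
                "gene": architecture.gene,
                "exonic_function": row["category"],
                "cadd": row["score"],
                "af_public": row["maf"],
            }
        )

    variants = pd.concat(
        [cohort.variants, pd.DataFrame(new_rows)], ignore_index=True
    )
    G = np.concatenate([cohort.genotypes, np.array(new_cols).T], axis=1)
    return Cohort(samples=cohort.samples, variants=variants, genotypes=G)


# ----------------------------------------------------------------------
# benchmark bundles
# ----------------------------------------------------------------------

def generate_benchmark_dataset(
    background_spec: BackgroundCohortSpec,
    architecture_requests: list[dict],
    n_replicates: int,
    seed: int,
    out_dir=None,
    pool_size: int = 300,
):
    """Replicate bundle: fresh labels + fresh spiking per replicate.

    ``architecture_requests`` is a list of dicts with keys ``gene``,
    ``target_ve`` and ``mode``.  Per replicate, case/control labels
    are re-randomised (randomising the background noise) and each
    requested architecture is rebuilt from the risk pool and spiked.
    Returns a manifest (list of dicts, one per replicate x
    architecture) with the spiked-variant truth; cohorts are included
    in memory and written to ``out_dir`` when given.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from . import io as _io

    master = np.random.SeedSequence(seed)
    background = simulate_background(background_spec)
    pool_rng = np.random.default_rng(master.spawn(1)[0])
    pool = simulate_risk_pool(pool_size, pool_rng,
                              populations=list(background_spec.populations))
    manifest = []
    n_cases = int(round(background_spec.case_fraction * background_spec.n_samples))
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r + 1]))
        status = np.zeros(background_spec.n_samples, dtype=np.int8)
        status[rng.choice(background_spec.n_samples, n_cases, replace=False)] = 1
        base = background.with_status(status)
        for req in architecture_requests:
            arch = build_architecture(
                pool, req["gene"], req["target_ve"], req.get("mode", "any"),
                req.get("prevalence", DEFAULT_PREVALENCE), rng,
            )
            spiked = spike_cases(base, arch, rng,
                                 stratified=req.get("stratified", False))
            entry = {
                "replicate": r,
                "gene": req["gene"],
                "target_ve": req["target_ve"],
                "mode": req.get("mode", "any"),
                "achieved_ve": arch.cumulative_ve,
                "variants": arch.variants.to_dict("records"),
                "cohort": spiked,
            }
            if out_dir is not None:
                import json
                from pathlib import Path

                d = Path(out_dir) / f"rep{r:03d}_{req['gene']}_{req['target_ve']}"
                d.mkdir(parents=True, exist_ok=True)
                _io.write_cohort(spiked, d)
                truth = {k: v for k, v in entry.items() if k != "cohort"}
                (d / "manifest.json").write_text(json.dumps(truth, indent=1))
                entry["path"] = str(d)
            manifest.append(entry)
    return manifest
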
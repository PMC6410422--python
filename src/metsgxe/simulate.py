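"""Synthetic cohort / genotype / annotation generator.

The restricted Korean cohort behind this analysis cannot be redistributed,
so every downstream stage is exercised on synthetic data that reproduces
the statistical structure the method assumes:

* a cohort of women aged 40-69 whose AAM category proportions and
  covariate scales match the published descriptive table, with a planted
  additive early-menarche effect on triglycerides;
* Hardy-Weinberg genotypes at configurable MAF, independent across SNPs
  (the scan models no LD), with optional random missingness;
* per-SNP main and G x E interaction effects planted on the TG column;
* a gene/pathway annotation tiled over the SNP grid, optionally with one
  pathway whose genes carry all planted SNPs (an enriched pathway).

A single seed drives four documented RNG substreams in fixed order
(cohort, genotypes, missingness, annotation), so every artifact is
byte-reproducible from the configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import constants as C
from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "AnnotationBundle",
    "simulate_cohort",
    "simulate_genotypes",
    "plant_gxe_effects",
    "simulate_annotation",
    "simulate_binary_outcome",
    "interaction_beta_for_z",
]

# AAM category proportions of the 3,180-woman reference table.
_DEFAULT_AAM_PROBS = tuple(
    C.KARE_CATEGORY_COUNTS[c] / C.KARE_TOTAL_N for c in C.AAM_CATEGORIES
)

# Years each category pools over (uniform within-category assignment).
_CATEGORY_YEARS = {
    "<=12": (11, 12),
    "13": (13,),
    "14": (14,),
    "15": (15,),
    "16": (16,),
    ">=17": (17, 18),
}


@dataclass
class SimulationConfig:
    """All knobs of the generator. Defaults emulate the reference cohort."""

    n_subjects: int = 2000
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    aam_category_probs: tuple[float, ...] = _DEFAULT_AAM_PROBS
    tg_baseline_mean: float = 130.0   # mg/dl
    tg_baseline_sd: float = 80.0      # mg/dl
    early_menarche_tg_effect: float = 37.83  # mg/dl, planted on AAM <= 12
    planted_snps: tuple[tuple[int, float, float], ...] = ()
    enriched_pathway_id: str | None = None
    missing_genotype_rate: float = 0.002
    seed: int = 0
    # Annotation sizing (genes tiled over consecutive SNPs).
    snps_per_gene: int = 3
    n_pathways: int = 25
    pathway_size_range: tuple[int, int] = (20, 60)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        probs = np.asarray(self.aam_category_probs, dtype=float)
        if probs.shape != (6,) or (probs < 0).any():
            raise ValueError("aam_category_probs must be 6 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"aam_category_probs must sum to 1, got {probs.sum()!r}")
        if not (0.0 <= self.missing_genotype_rate < 1.0):
            raise ValueError("missing_genotype_rate must be in [0, 1)")
        for idx, _, _ in self.planted_snps:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"planted SNP index {idx} out of range [0, {self.n_snps})")
        if self.snps_per_gene < 1:
            raise ValueError("snps_per_gene must be >= 1")

    def substreams(self) -> list[np.random.Generator]:
        """Four independent generators: cohort, genotypes, missingness, annotation."""
        seqs = np.random.SeedSequence(self.seed).spawn(4)
        return [np.random.default_rng(s) for s in seqs]


@dataclass
class AnnotationBundle:
    """Gene intervals (1-based inclusive) plus pathway membership."""

    gene_intervals: pd.DataFrame  # columns gene_id, chrom, start, end
    pathways: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gi = self.gene_intervals
        if (gi["start"] > gi["end"]).any():
            raise ValueError("gene interval with start > end")
        known = set(gi["gene_id"])
        for pid, genes in self.pathways.items():
            unknown = set(genes) - known
            if unknown:
                raise ValueError(f"pathway {pid} references unknown genes: {sorted(unknown)[:5]}")


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table (one row per woman).

    AAM categories follow ``aam_category_probs`` with uniform integer-year
    assignment inside the pooled bins; enrolment age is Normal(56.07, 8.88)
    truncated to [40, 69]; TG is baseline + planted early-menarche shift +
    Gaussian noise; the remaining MetS component traits and covariates are
    drawn from fixed plausible marginals independent of AAM.
    """
    rng = config.substreams()[0]
    n = config.n_subjects
    probs = np.asarray(config.aam_category_probs, dtype=float)
    probs = probs / probs.sum()

    cat_idx = rng.choice(6, size=n, p=probs)
    aam = np.empty(n, dtype=int)
    for k, cat in enumerate(C.AAM_CATEGORIES):
        years = _CATEGORY_YEARS[cat]
        sel = cat_idx == k
        aam[sel] = rng.choice(years, size=sel.sum())
    early = (aam <= 12).astype(int)

    a, b = (40 - 56.07) / 8.88, (69 - 56.07) / 8.88
    age = stats.truncnorm.rvs(a, b, loc=56.07, scale=8.88, size=n, random_state=rng)

    tg = (
        config.tg_baseline_mean
        + config.early_menarche_tg_effect * early
        + rng.normal(0.0, config.tg_baseline_sd, size=n)
    )

    # CRP lognormal moment-matched to mean 1.41, SD 1.30 mg/dl.
    crp_sigma = np.sqrt(np.log(1.0 + (1.30 / 1.41) ** 2))
    crp_mu = np.log(1.41) - crp_sigma**2 / 2.0

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "aam": aam,
            "sbp": np.clip(rng.normal(118.0, 16.0, n), 70, None),
            "dbp": np.clip(rng.normal(73.0, 10.0, n), 40, None),
            "fg": np.clip(rng.normal(92.0, 16.0, n), 40, None),
            "fi": np.clip(rng.normal(9.0, 4.0, n), 0.5, None),
            "wc": np.clip(rng.normal(80.0, 9.0, n), 50, None),
            "tg": tg,
            "hdl": np.clip(rng.normal(52.0, 11.0, n), 10, None),
            "antihypertensive_med": rng.binomial(1, 0.12, n),
            "antidiabetic_med": rng.binomial(1, 0.05, n),
            "age": age,
            "area": rng.binomial(1, 1481 / 3180, n),  # 1 = urban
            "income": rng.choice(3, size=n, p=(0.402, 0.227, 0.371)),
            "education": rng.choice(3, size=n, p=(0.17, 0.50, 0.33)),
            "crp": rng.lognormal(crp_mu, crp_sigma, n),
            "smoking": rng.binomial(1, 0.018, n),
            "alcohol": rng.exponential(1.44, n),
            "obs_score": np.clip(rng.normal(9.10, 2.51, n), 0, None),
        }
    )
    return df


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """HWE genotypes: per-SNP MAF ~ Uniform(maf_range), dosage ~ Binomial(2, MAF).

    Missing calls are applied independently at ``missing_genotype_rate``
    from a dedicated substream. SNPs are laid on a regular positional grid
    over 22 autosome labels.
    """
    rngs = config.substreams()
    rng_geno, rng_miss = rngs[1], rngs[2]
    n, m = config.n_subjects, config.n_snps
    lo, hi = config.maf_range
    maf = rng_geno.uniform(lo, hi, size=m)
    dosages = rng_geno.binomial(2, maf, size=(n, m)).astype(float)
    if config.missing_genotype_rate > 0:
        mask = rng_miss.random((n, m)) < config.missing_genotype_rate
        dosages[mask] = np.nan

    per_chrom = int(np.ceil(m / 22))
    chrom = np.array([str(1 + i // per_chrom) for i in range(m)])
    pos = np.array([10_000 + 5_000 * (i % per_chrom) for i in range(m)], dtype=int)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"snp{i:06d}" for i in range(m)]),
        chromosomes=chrom,
        positions=pos,
        ref=np.array(["A"] * m),
        alt=np.array(["G"] * m),
        subject_ids=np.array([f"S{i:06d}" for i in range(n)]),
    )


def plant_gxe_effects(
    cohort: pd.DataFrame, genotypes: GenotypeMatrix, config: SimulationConfig
) -> pd.DataFrame:
    """Add per-SNP main and interaction effects to the TG column.

    For each (snp_index, beta_main, beta_int) the TG of subject i gains
    ``beta_main * G_i + beta_int * G_i * E_i`` where E is the binary
    early-menarche indicator. Masked (missing) dosages contribute zero.
    Returns a new table; the input is unmodified.
    """
    out = cohort.copy()
    if not config.planted_snps:
        return out
    early = (pd.to_numeric(out["aam"]) <= 12).to_numpy(dtype=float)
    tg = out["tg"].to_numpy(dtype=float).copy()
    for idx, bmain, bint in config.planted_snps:
        if not (0 <= idx < genotypes.n_snps):
            raise IndexError(f"planted SNP index {idx} out of range")
        g = np.nan_to_num(genotypes.dosages[:, idx], nan=0.0)
        tg += bmain * g + bint * g * early
    out["tg"] = tg
    return out


def simulate_annotation(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> AnnotationBundle:
    """Tile genes over the SNP grid and build pathway gene sets.

    Consecutive same-chromosome SNPs are grouped into genes of
    ``snps_per_gene`` markers, so every gene contains at least one SNP.
    Pathways draw random gene subsets with sizes in ``pathway_size_range``;
    when ``enriched_pathway_id`` is set, that pathway is guaranteed to
    contain every gene hosting a planted SNP.
    """
    rng = config.substreams()[3]
    m = genotypes.n_snps
    spg = config.snps_per_gene

    gene_rows = []
    snp_gene = np.empty(m, dtype=int)
    gid = 0
    i = 0
    while i < m:
        j = i
        while j < m and j - i < spg and genotypes.chromosomes[j] == genotypes.chromosomes[i]:
            j += 1
        gene_rows.append(
            {
                "gene_id": f"GENE{gid:05d}",
                "chrom": genotypes.chromosomes[i],
                "start": int(genotypes.positions[i:j].min()),
                "end": int(genotypes.positions[i:j].max()),
            }
        )
        snp_gene[i:j] = gid
        gid += 1
        i = j
    genes = pd.DataFrame(gene_rows)
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)

    lo, hi = config.pathway_size_range
    lo = min(lo, n_genes)
    if lo < 1:
        raise ValueError("cannot place any pathway: no genes available")

    pathways: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}

    planted_gene_ids: list[str] = []
    if config.enriched_pathway_id is not None:
        planted_gene_idx = sorted({int(snp_gene[idx]) for idx, _, _ in config.planted_snps})
        planted_gene_ids = [gene_ids[k] for k in planted_gene_idx]
        size = max(lo, len(planted_gene_ids))
        if size > n_genes:
            raise ValueError("enriched pathway needs more genes than available")
        fill = [g for g in gene_ids if g not in set(planted_gene_ids)]
        extra = rng.choice(fill, size=size - len(planted_gene_ids), replace=False)
        members = planted_gene_ids + list(extra)
        pathways[config.enriched_pathway_id] = members
        descriptions[config.enriched_pathway_id] = "synthetic enriched pathway (carries planted GxE SNPs)"

    for k in range(config.n_pathways):
        pid = f"PW{k:04d}"
        if pid in pathways:
            continue
        size = int(rng.integers(lo, min(hi, n_genes) + 1))
        members = list(rng.choice(gene_ids, size=size, replace=False))
        pathways[pid] = members
        descriptions[pid] = f"synthetic null pathway {k}"

    return AnnotationBundle(gene_intervals=genes, pathways=pathways, descriptions=descriptions)


def simulate_binary_outcome(
    cohort: pd.DataFrame,
    early_log_odds: float,
    intercept: float = -1.0,
    seed: int = 0,
) -> pd.Series:
    """Bernoulli outcome from a logistic model on the early indicator.

    Used to plant a known odds ratio (exp(early_log_odds)) for recovery
    checks of the categorical logistic models.
    """
    rng = np.random.default_rng(seed)
    early = (pd.to_numeric(cohort["aam"]) <= 12).to_numpy(dtype=float)
    logit = intercept + early_log_odds * early
    p = 1.0 / (1.0 + np.exp(-logit))
    return pd.Series(rng.binomial(1, p), index=cohort.index, name="outcome")


def interaction_beta_for_z(
    z: float,
    n_subjects: int,
    maf: float,
    early_prevalence: float,
    noise_sd: float,
    n_planted: int = 1,
) -> float:
    """Interaction effect size giving an expected Wald z of about ``z``.

    Uses the large-sample variance of the interaction estimator in the
    linear model Y ~ E + G + G.E with independent G (HWE, variance
    2*maf*(1-maf)) and binary E: Var(beta_int) ~ sigma^2 * (1/n1 + 1/n0)
    / Var(G), with n1 = n*p_E exposed and n0 unexposed subjects.

    When ``n_planted`` SNPs all carry the same interaction effect on one
    trait, each SNP's fit absorbs only its own term; the other n-1
    planted terms add ``p_E*(n_planted-1)*beta^2*Var(G)`` to the
    residual variance. The returned beta solves that self-consistently,
    so the realized z stays near ``z`` instead of being deflated by the
    stacked variance.
    """
    var_g = 2.0 * maf * (1.0 - maf)
    n1 = n_subjects * early_prevalence
    n0 = n_subjects * (1.0 - early_prevalence)
    c = (1.0 / n1 + 1.0 / n0) / var_g
    shrink = 1.0 - z**2 * c * early_prevalence * (n_planted - 1) * var_g
    if shrink <= 0:
        raise ValueError(
            "no effect size attains the requested z: the planted SNPs' "
            "combined variance outgrows the signal; lower z, n_planted or "
            "the exposure prevalence"
        )
    beta_sq = z**2 * c * noise_sd**2 / shrink
    return float(np.sqrt(beta_sq))
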
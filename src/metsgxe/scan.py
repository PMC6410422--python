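"""Genome-wide SNP x AAM interaction scan.

Per SNP the model is

    Y_i            = b0 + b1*E_i + b_main*G_i + b_int*G_i*E_i + covariates
    logit P(Y_i=1) = ...                                      (binary trait)

with E the exposure (by default the binary early-menarche indicator,
AAM <= 12) and G the additive ALT-allele dosage. Two Wald tests are
reported per SNP:

* interaction, 1 df: H0 b_int = 0, statistic (b_int / se_int)^2;
* joint, 2 df: H0 b_main = b_int = 0, statistic b' V^{-1} b on the
  (b_main, b_int) block of the coefficient covariance.

Genome-wide diagnostics include the genomic-control inflation factor
lambda (median observed statistic over the null chi-square median, for
the stated df) for both tests. When a quantitative trait shows
interaction inflation above a trigger (default 1.05), the scan re-runs
on the rank-based inverse-normal transformed trait, covariates retained
in the model, and reports both sets of lambdas; dividing the statistics
by lambda is offered as an alternative.

SNP QC precedes the scan: SNPs with missing-call proportion above 0.5%
or MAF <= 0.05 are removed (both thresholds configurable; the MAF rule
is inclusive at the boundary). Missing dosages are handled by per-SNP
complete-case deletion; the n used is recorded per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeMatrix
from . import constants as C

__all__ = [
    "ScanConfig",
    "ScanResultRow",
    "ScanOutput",
    "QCReport",
    "qc_filter",
    "fit_gxe_snp",
    "wald_tests",
    "genomic_lambda",
    "inverse_normal_transform",
    "run_scan",
    "bonferroni_threshold",
    "bh_fdr",
    "qq_table",
]

# Medians of the chi-square distribution used by genomic control.
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...
CHI2_MEDIAN_2DF = float(stats.chi2.ppf(0.5, 2))  # 2*ln 2


@dataclass
class ScanConfig:
    trait: str = "tg"
    family: str = "linear"  # or "logistic"
    exposure_coding: str = "early_binary"  # or "aam_continuous"
    covariates: tuple[str, ...] = C.DEFAULT_COVARIATES
    maf_threshold: float = 0.05
    missing_threshold: float = 0.005
    lambda_gc_trigger: float = 1.05
    alpha: float = 0.05
    gc_action: str = "int"  # "int" (re-run on INT trait) or "divide"

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "missing_threshold", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.exposure_coding not in ("early_binary", "aam_continuous"):
            raise ValueError(f"unknown exposure coding {self.exposure_coding!r}")
        if self.gc_action not in ("int", "divide"):
            raise ValueError(f"unknown gc_action {self.gc_action!r}")


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_removed_total: int
    n_kept: int


@dataclass
class ScanResultRow:
    snp_id: str
    beta_main: float = np.nan
    beta_int: float = np.nan
    se_main: float = np.nan
    se_int: float = np.nan
    cov_main_int: float = np.nan
    wald_int: float = np.nan
    wald_joint: float = np.nan
    p_int: float = np.nan
    p_joint: float = np.nan
    n_used: int = 0
    status: str = "ok"  # ok | degenerate | singular | nonconverged


@dataclass
class ScanOutput:
    results: pd.DataFrame
    lambda_int: float
    lambda_joint: float
    int_applied: bool = False
    lambda_int_raw: float | None = None
    lambda_joint_raw: float | None = None
    results_raw: pd.DataFrame | None = None
    qq_int: pd.DataFrame | None = None
    qq_joint: pd.DataFrame | None = None


def qc_filter(genotypes: GenotypeMatrix, config: ScanConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs failing missingness (> threshold) or MAF (<= threshold) QC."""
    if genotypes.n_snps == 0:
        raise ValueError("empty genotype matrix")
    miss = genotypes.missing_rate()
    maf = genotypes.maf()
    bad_miss = miss > config.missing_threshold
    bad_maf = maf <= config.maf_threshold
    bad = bad_miss | bad_maf
    report = QCReport(
        n_input=genotypes.n_snps,
        n_removed_missing=int(bad_miss.sum()),
        n_removed_maf=int(bad_maf.sum()),
        n_removed_total=int(bad.sum()),
        n_kept=int((~bad).sum()),
    )
    if report.n_kept == 0:
        raise ValueError("QC removed every SNP")
    return genotypes.subset_snps(~bad), report


def wald_tests(
    beta_main: float, beta_int: float, cov: np.ndarray
) -> tuple[float, float, float, float]:
    """1-df interaction and 2-df joint Wald statistics with p-values.

    ``cov`` is the 2x2 covariance of (beta_main, beta_int). Returns
    (wald_int, p_int, wald_joint, p_joint); NaNs if ``cov`` is singular.
    """
    cov = np.asarray(cov, dtype=float)
    var_int = cov[1, 1]
    if not np.isfinite(var_int) or var_int <= 0:
        return np.nan, np.nan, np.nan, np.nan
    w_int = beta_int**2 / var_int
    p_int = float(stats.chi2.sf(w_int, 1))
    b = np.array([beta_main, beta_int])
    try:
        w_joint = float(b @ np.linalg.solve(cov, b))
    except np.linalg.LinAlgError:
        return float(w_int), p_int, np.nan, np.nan
    if w_joint < 0:  # numerically non-PSD covariance
        return float(w_int), p_int, np.nan, np.nan
    p_joint = float(stats.chi2.sf(w_joint, 2))
    return float(w_int), p_int, float(w_joint), p_joint


def _irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, maxiter: int = 100):
    """Newton/IRLS logistic fit; returns (beta, cov, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    cov = None
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        if not np.all(np.isfinite(w)) or w.max() < 1e-12:
            return beta, None, False
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return beta, None, False
            return beta, cov, True
    return beta, None, False


def fit_gxe_snp(
    y: np.ndarray,
    dosage: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "linear",
    snp_id: str = "",
) -> ScanResultRow:
    """Fit Y ~ 1 + E + G + G.E (+ covariates) for one SNP.

    Complete-case deletion over all inputs; identity link for a
    quantitative trait, logit link for a binary one. Degenerate designs
    (constant G or G.E after subsetting, too few rows, singular normal
    equations) are flagged rather than raised.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosage, dtype=float)
    e = np.asarray(exposure, dtype=float)
    if covariates is None:
        covariates = np.empty((len(y), 0))
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]

    mask = np.isfinite(y) & np.isfinite(g) & np.isfinite(e)
    if Z.shape[1]:
        mask &= np.isfinite(Z).all(axis=1)
    y, g, e, Z = y[mask], g[mask], e[mask], Z[mask]
    n = len(y)
    p = 4 + Z.shape[1]
    row = ScanResultRow(snp_id=snp_id, n_used=n)

    if n < p + 2:
        row.status = "degenerate"
        return row
    ge = g * e
    if np.ptp(g) == 0 or np.ptp(ge) == 0:
        row.status = "degenerate"
        return row

    X = np.column_stack([np.ones(n), e, Z, g, ge])
    i_main, i_int = p - 2, p - 1

    if family == "linear":
        XtX = X.T @ X
        try:
            beta = np.linalg.solve(XtX, X.T @ y)
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            row.status = "singular"
            return row
        resid = y - X @ beta
        dof = n - p
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * XtX_inv
    elif family == "logistic":
        beta, cov, converged = _irls_logistic(X, y)
        if not converged or cov is None:
            row.status = "nonconverged"
            return row
    else:
        raise ValueError(f"unknown family {family!r}")

    block = cov[np.ix_([i_main, i_int], [i_main, i_int])]
    row.beta_main = float(beta[i_main])
    row.beta_int = float(beta[i_int])
    row.se_main = float(np.sqrt(block[0, 0]))
    row.se_int = float(np.sqrt(block[1, 1]))
    row.cov_main_int = float(block[0, 1])
    row.wald_int, row.p_int, row.wald_joint, row.p_joint = wald_tests(
        row.beta_main, row.beta_int, block
    )
    if not np.isfinite(row.wald_joint):
        row.status = "singular"
    return row


def genomic_lambda(statistics, df: int = 1, min_count: int = 100) -> float:
    """Genomic-control inflation factor: median statistic / chi2 median.

    ``df`` selects the null median (0.4549 for 1 df, 2 ln 2 for 2 df).
    Requires at least ``min_count`` finite statistics.
    """
    arr = np.asarray(list(statistics), dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < min_count:
        raise ValueError(f"need >= {min_count} finite statistics, got {len(arr)}")
    if df == 1:
        divisor = CHI2_MEDIAN_1DF
    elif df == 2:
        divisor = CHI2_MEDIAN_2DF
    else:
        divisor = float(stats.chi2.ppf(0.5, df))
    return float(np.median(arr) / divisor)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4)) over non-missing values,
    average ranks for ties; missing entries stay missing. Requires at
    least 3 non-missing values with some variation.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need >= 3 non-missing values")
    sub = x[mask]
    if np.ptp(sub) == 0:
        raise ValueError("all values identical; no rank information")
    r = stats.rankdata(sub, method="average")
    out[mask] = ndtri((r - 0.375) / (n + 0.25))
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise critical p-value alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order, NaNs preserved."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def qq_table(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[np.isfinite(p)]
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, None))
    return pd.DataFrame({"expected": expected, "observed": observed})


def _exposure_vector(cohort: pd.DataFrame, coding: str) -> np.ndarray:
    if coding == "early_binary":
        if "early" in cohort.columns:
            return cohort["early"].to_numpy(dtype=float)
        return (pd.to_numeric(cohort["aam"]) <= 12).to_numpy(dtype=float)
    return pd.to_numeric(cohort["aam"]).to_numpy(dtype=float)


def _scan_once(y, E, Z, genotypes: GenotypeMatrix, family: str) -> pd.DataFrame:
    rows = [
        fit_gxe_snp(y, genotypes.dosages[:, j], E, Z, family=family,
                    snp_id=str(genotypes.snp_ids[j]))
        for j in range(genotypes.n_snps)
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.insert(1, "chrom", genotypes.chromosomes)
    df.insert(2, "pos", genotypes.positions.astype(int))
    return df


def run_scan(
    cohort: pd.DataFrame, genotypes: GenotypeMatrix, config: ScanConfig
) -> ScanOutput:
    """Fit every SNP, compute inflation diagnostics, apply genomic control.

    The cohort must already be phenotyped (exclusions applied). Subjects
    are aligned on ``subject_id``; a mismatch is an error that names the
    offenders. For a quantitative trait with interaction lambda above
    ``lambda_gc_trigger`` the scan is repeated on the inverse-normal
    transformed trait (``gc_action='int'``, the default) or the
    statistics are divided by lambda (``gc_action='divide'``); both
    lambda sets are reported.
    """
    cohort_ids = cohort["subject_id"].astype(str).to_numpy()
    geno_ids = genotypes.subject_ids.astype(str)
    if list(cohort_ids) != list(geno_ids):
        extra_c = sorted(set(cohort_ids) - set(geno_ids))[:5]
        extra_g = sorted(set(geno_ids) - set(cohort_ids))[:5]
        if extra_c or extra_g:
            raise ValueError(
                f"subject mismatch between phenotype and genotype files; "
                f"phenotype-only: {extra_c}, genotype-only: {extra_g}"
            )
        order = {s: i for i, s in enumerate(geno_ids)}
        idx = np.array([order[s] for s in cohort_ids])
        genotypes = GenotypeMatrix(
            dosages=genotypes.dosages[idx],
            snp_ids=genotypes.snp_ids,
            chromosomes=genotypes.chromosomes,
            positions=genotypes.positions,
            ref=genotypes.ref,
            alt=genotypes.alt,
            subject_ids=geno_ids[idx],
        )

    y = pd.to_numeric(cohort[config.trait]).to_numpy(dtype=float)
    E = _exposure_vector(cohort, config.exposure_coding)
    Z = cohort.loc[:, list(config.covariates)].apply(pd.to_numeric).to_numpy(dtype=float)

    results = _scan_once(y, E, Z, genotypes, config.family)

    def _lam(stats_col, df):
        # lambda is meaningless on very small scans; report NaN there
        try:
            return genomic_lambda(stats_col, df=df)
        except ValueError:
            return np.nan

    lam_int = _lam(results["wald_int"], 1)
    lam_joint = _lam(results["wald_joint"], 2)

    out = ScanOutput(results=results, lambda_int=lam_int, lambda_joint=lam_joint)
    if config.family == "linear" and np.isfinite(lam_int) and lam_int > config.lambda_gc_trigger:
        out.lambda_int_raw, out.lambda_joint_raw = lam_int, lam_joint
        out.results_raw = results
        if config.gc_action == "int":
            y_t = inverse_normal_transform(y)
            corrected = _scan_once(y_t, E, Z, genotypes, config.family)
        else:  # divide statistics by the inflation factors
            corrected = results.copy()
            corrected["wald_int"] = corrected["wald_int"] / lam_int
            corrected["wald_joint"] = corrected["wald_joint"] / lam_joint
            corrected["p_int"] = stats.chi2.sf(corrected["wald_int"], 1)
            corrected["p_joint"] = stats.chi2.sf(corrected["wald_joint"], 2)
        out.results = corrected
        out.lambda_int = _lam(corrected["wald_int"], 1)
        out.lambda_joint = _lam(corrected["wald_joint"], 2)
        out.int_applied = True
    out.qq_int = qq_table(out.results["p_int"])
    out.qq_joint = qq_table(out.results["p_joint"])
    return out
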
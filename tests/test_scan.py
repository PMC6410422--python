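"""Per-SNP G x E fits, Wald tests, genomic control, INT, multiplicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metsgxe.genotypes import GenotypeMatrix
from metsgxe.phenotyping import phenotype_cohort
from metsgxe.scan import (
    CHI2_MEDIAN_1DF,
    ScanConfig,
    bh_fdr,
    bonferroni_threshold,
    fit_gxe_snp,
    genomic_lambda,
    inverse_normal_transform,
    qc_filter,
    run_scan,
    wald_tests,
)
from metsgxe.simulate import SimulationConfig, plant_gxe_effects, simulate_cohort, simulate_genotypes
from .conftest import BALANCED_AAM_PROBS


def _matrix(dosages, positions=None):
    d = np.asarray(dosages, dtype=float)
    m = d.shape[1]
    return GenotypeMatrix(
        dosages=d,
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        chromosomes=np.array(["1"] * m),
        positions=np.asarray(positions) if positions is not None else np.arange(1, m + 1) * 100,
        ref=np.array(["A"] * m),
        alt=np.array(["G"] * m),
    )


class TestQC:
    def test_maf_boundary_inclusive(self):
        # MAF exactly at the threshold is removed (<= is inclusive)
        n = 1000
        rng = np.random.default_rng(0)
        at = rng.binomial(2, 0.05, n)
        while abs(at.mean() / 2 - 0.05) > 1e-12:
            at = rng.binomial(2, 0.05, n)
        good = rng.binomial(2, 0.3, n)
        gm = _matrix(np.column_stack([at, good]))
        kept, report = qc_filter(gm, ScanConfig())
        assert list(kept.snp_ids) == ["s1"]
        assert report.n_removed_maf == 1

    def test_clean_snp_kept(self):
        rng = np.random.default_rng(1)
        gm = _matrix(rng.binomial(2, 0.3, (500, 3)))
        kept, report = qc_filter(gm, ScanConfig())
        assert kept.n_snps == 3 and report.n_removed_total == 0

    def test_planted_failures_counted_exactly(self):
        rng = np.random.default_rng(2)
        n, m = 2000, 100
        d = rng.binomial(2, 0.3, (n, m)).astype(float)
        low_maf = rng.choice(m, 10, replace=False)
        d[:, low_maf] = rng.binomial(2, 0.01, (n, 10))
        gm = _matrix(d)
        kept, report = qc_filter(gm, ScanConfig())
        assert report.n_removed_total == 10 and kept.n_snps == 90

    def test_missingness_rule(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, (1000, 2)).astype(float)
        d[:20, 0] = np.nan  # 2% missing > 0.5%
        kept, report = qc_filter(_matrix(d), ScanConfig())
        assert report.n_removed_missing == 1 and list(kept.snp_ids) == ["s1"]

    def test_all_removed_is_error(self):
        d = np.zeros((100, 2))
        with pytest.raises(ValueError, match="every SNP"):
            qc_filter(_matrix(d), ScanConfig())


class TestFit:
    def _fixture(self, n=50, seed=4):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.4, n).astype(float)
        e = rng.binomial(1, 0.5, n).astype(float)
        z = rng.normal(0, 1, (n, 2))
        y = 1.0 + 0.5 * e + 0.8 * g + 1.2 * g * e + z @ [0.3, -0.2] + rng.normal(0, 1, n)
        return y, g, e, z

    def test_matches_normal_equations_oracle(self):
        y, g, e, z = self._fixture()
        row = fit_gxe_snp(y, g, e, z, family="linear")
        X = np.column_stack([np.ones(len(y)), e, z, g, g * e])
        beta = np.linalg.pinv(X.T @ X) @ X.T @ y
        assert row.beta_main == pytest.approx(beta[-2], abs=1e-8)
        assert row.beta_int == pytest.approx(beta[-1], abs=1e-8)

    def test_matches_statsmodels_linear(self):
        import statsmodels.api as sm
        y, g, e, z = self._fixture(seed=5)
        row = fit_gxe_snp(y, g, e, z, family="linear")
        X = np.column_stack([np.ones(len(y)), e, z, g, g * e])
        fit = sm.OLS(y, X).fit()
        assert row.beta_int == pytest.approx(fit.params[-1], rel=1e-8)
        assert row.se_int == pytest.approx(fit.bse[-1], rel=1e-8)

    def test_matches_statsmodels_logistic(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        n = 400
        g = rng.binomial(2, 0.4, n).astype(float)
        e = rng.binomial(1, 0.5, n).astype(float)
        eta = -0.5 + 0.3 * e + 0.4 * g + 0.5 * g * e
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        row = fit_gxe_snp(y, g, e, None, family="logistic")
        X = np.column_stack([np.ones(n), e, g, g * e])
        fit = sm.Logit(y, X).fit(disp=0)
        assert row.beta_int == pytest.approx(fit.params[-1], abs=1e-6)
        assert row.se_int == pytest.approx(fit.bse[-1], rel=1e-4)

    def test_complete_case_deletion(self):
        y, g, e, z = self._fixture(n=80, seed=7)
        g_miss = g.copy()
        g_miss[:10] = np.nan
        row = fit_gxe_snp(y, g_miss, e, z, family="linear")
        row_sub = fit_gxe_snp(y[10:], g[10:], e[10:], z[10:], family="linear")
        assert row.n_used == 70
        assert row.beta_int == pytest.approx(row_sub.beta_int, abs=1e-12)

    def test_degenerate_exposure_flagged(self):
        y, g, _, z = self._fixture()
        row = fit_gxe_snp(y, g, np.zeros(len(y)), z, family="linear")
        assert row.status == "degenerate"
        assert np.isnan(row.p_int)

    def test_constant_dosage_flagged(self):
        y, _, e, z = self._fixture()
        row = fit_gxe_snp(y, np.ones(len(y)), e, z, family="linear")
        assert row.status == "degenerate"

    def test_interaction_coverage(self):
        # planted beta_int inside its 95% CI in >= 90% of 50 replicates
        beta_true = 25.0
        cover = 0
        for rep in range(50):
            cfg = SimulationConfig(
                n_subjects=2000, n_snps=1, maf_range=(0.3, 0.3),
                planted_snps=((0, 0.0, beta_true),), seed=1000 + rep,
                missing_genotype_rate=0.0,
            )
            coh = simulate_cohort(cfg)
            gm = simulate_genotypes(cfg)
            coh = plant_gxe_effects(coh, gm, cfg)
            ph, _ = phenotype_cohort(coh)
            row = fit_gxe_snp(ph["tg"].to_numpy(), gm.dosages[:, 0],
                              ph["early"].to_numpy(float),
                              ph[["age", "crp"]].to_numpy(float))
            lo = row.beta_int - 1.959964 * row.se_int
            hi = row.beta_int + 1.959964 * row.se_int
            cover += lo <= beta_true <= hi
        assert cover >= 45


class TestWald:
    def test_zero_betas(self):
        w_int, p_int, w_joint, p_joint = wald_tests(0.0, 0.0, np.eye(2))
        assert (w_int, w_joint) == (0.0, 0.0)
        assert (p_int, p_joint) == (1.0, 1.0)

    def test_one_df_at_z_1_96(self):
        # z = 1.96 -> chi2(1) = 3.8416 -> p ~ 0.0500
        se = 0.5
        _, p_int, _, _ = wald_tests(0.0, 1.96 * se, np.diag([1.0, se**2]))
        assert p_int == pytest.approx(0.05, abs=5e-4)

    def test_two_df_closed_form(self):
        # both z-scores 1.96, diagonal V: joint = 7.6832, p = exp(-7.6832/2)
        v = np.diag([0.25, 0.25])
        b = 1.96 * 0.5
        w_int, _, w_joint, p_joint = wald_tests(b, b, v)
        assert w_joint == pytest.approx(7.6832, abs=1e-10)
        assert p_joint == pytest.approx(np.exp(-7.6832 / 2), rel=1e-10)
        assert w_int == pytest.approx(3.8416, abs=1e-10)

    def test_singular_covariance_flagged(self):
        v = np.array([[1.0, 1.0], [1.0, 1.0]])
        _, _, w_joint, p_joint = wald_tests(0.5, 0.5, v)
        assert np.isnan(w_joint) or np.isinf(w_joint)


class TestGenomicLambda:
    def test_definitional_unity(self):
        stats_in = [CHI2_MEDIAN_1DF] * 200
        assert genomic_lambda(stats_in, df=1) == pytest.approx(1.0, abs=1e-12)

    def test_scaling_property(self):
        rng = np.random.default_rng(9)
        draws = rng.chisquare(1, 100_000)
        assert genomic_lambda(2 * draws, df=1) == pytest.approx(2.0, abs=0.05)

    def test_two_df_divisor(self):
        stats_in = [2 * np.log(2)] * 200
        assert genomic_lambda(stats_in, df=2) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_statistics(self):
        with pytest.raises(ValueError):
            genomic_lambda([1.0] * 50)


class TestINT:
    def test_middle_of_three_is_zero(self):
        out = inverse_normal_transform([5.0, 1.0, 9.0])
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_smallest_of_three_blom(self):
        # Phi^-1((1 - 3/8) / (3 + 1/4)) = Phi^-1(0.1923077) ~ -0.8694
        out = inverse_normal_transform([5.0, 1.0, 9.0])
        assert out[1] == pytest.approx(-0.8694, abs=1e-4)
        assert out[2] == pytest.approx(+0.8694, abs=1e-4)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.lognormal(0, 1, 200)
        np.testing.assert_allclose(
            inverse_normal_transform(x), inverse_normal_transform(np.log(x)), atol=1e-12
        )

    def test_missing_preserved(self):
        out = inverse_normal_transform([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_ties_get_average_rank(self):
        out = inverse_normal_transform([1.0, 2.0, 2.0, 3.0])
        assert out[1] == pytest.approx(out[2], abs=1e-15)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([2.0, 2.0, 2.0])

    def test_near_zero_mean(self):
        rng = np.random.default_rng(11)
        out = inverse_normal_transform(rng.normal(0, 1, 999))
        assert abs(out.mean()) < 1e-3


class TestMultiplicity:
    def test_bonferroni_reference_scan(self):
        # 0.05 over the reference 344,396-SNP scan: 1.45e-7 at 3 sig figs
        thr = bonferroni_threshold(0.05, 344_396)
        assert f"{thr:.3g}" == "1.45e-07"

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 100, 5e-4), (0.05, 1, 0.05)])
    def test_bonferroni_simple(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_bonferroni_m_zero(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_bh_stepup_hand_run(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_bh_single_and_degenerate(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_bh_monotone_in_sorted_order(self, pvals):
        q = bh_fdr(sorted(pvals))
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all((q >= np.sort(np.asarray(pvals))) | np.isclose(q, np.sort(pvals)))


class TestRunScan:
    def _dataset(self, seed=20, n=600, m=150, planted=(), probs=BALANCED_AAM_PROBS):
        cfg = SimulationConfig(n_subjects=n, n_snps=m, seed=seed,
                               planted_snps=planted, missing_genotype_rate=0.0,
                               aam_category_probs=probs)
        coh = simulate_cohort(cfg)
        gm = simulate_genotypes(cfg)
        coh = plant_gxe_effects(coh, gm, cfg)
        ph, _ = phenotype_cohort(coh)
        return ph, gm

    def test_subject_mismatch_names_offenders(self):
        ph, gm = self._dataset()
        ph = ph.iloc[:-1]
        with pytest.raises(ValueError, match="S000599"):
            run_scan(ph, gm, ScanConfig())

    def test_planted_snp_attains_smallest_p_joint(self):
        # one enormous interaction (z ~ 8) must win the joint test
        ph, gm = self._dataset(planted=((7, 0.0, 60.0),), n=1000)
        out = run_scan(ph, gm, ScanConfig())
        best = out.results.loc[out.results["p_joint"].idxmin()]
        assert best.snp_id == "snp000007"

    def test_exposure_coding_switch(self):
        # a purely main-effect SNP stays null for the interaction test
        # under both exposure codings
        ph, gm = self._dataset(planted=((3, 30.0, 0.0),), n=1000, seed=21)
        for coding in ("early_binary", "aam_continuous"):
            out = run_scan(ph, gm, ScanConfig(exposure_coding=coding))
            row = out.results.loc[out.results.snp_id == "snp000003"].iloc[0]
            assert row.p_joint < 1e-4     # main effect drives the joint test
            assert row.p_int > 1e-3       # interaction stays unremarkable

    def test_results_carry_position_metadata(self):
        ph, gm = self._dataset()
        out = run_scan(ph, gm, ScanConfig())
        assert {"chrom", "pos", "n_used"} <= set(out.results.columns)
        assert (out.results["n_used"] == len(ph)).all()
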
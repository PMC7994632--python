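"""Mixed-model GWAS: QC boundaries, GRM arithmetic, REML recovery and the
OLS-reduction oracle."""

import numpy as np
import pytest

from ricemr.gwas_lmm import (
    GrmEigen,
    VarianceComponents,
    compute_grm,
    fit_null_lmm,
    mlma_scan,
    qc_filter,
)
from ricemr.io_formats import ValidationError
from ricemr.synthetic_data import default_truth, simulate_genotypes, simulate_study

from conftest import toy_matrix


class TestQcFilter:
    def test_boundaries_are_strict(self):
        # MAF exactly at the floor and missingness exactly at the cap are
        # both removed (the filters are "MAF > x" and "missing < y")
        d = np.zeros((10, 3))
        d[0, 0] = 1.0  # freq 0.05 -> MAF == 0.05
        d[:4, 1] = 1.0  # MAF 0.2, no missing: survives
        d[:2, 2] = np.nan  # 20% missing
        d[2:6, 2] = 1.0
        g = toy_matrix(d)
        kept = qc_filter(g, maf_min=0.05, missing_max=0.20)
        assert kept.snp_ids == [g.snps[1].snp_id]

    def test_hand_enumerated_survivors(self):
        rng = np.random.default_rng(0)
        freqs = [0.01, 0.03, 0.08, 0.20, 0.35, 0.5, 0.02, 0.45, 0.06, 0.04]
        d = rng.binomial(2, freqs, size=(400, 10)).astype(float)
        g = toy_matrix(d)
        maf = g.maf()
        expect = [s.snp_id for s, m in zip(g.snps, maf) if m > 0.05]
        assert qc_filter(g, 0.05, 0.2).snp_ids == expect

    def test_removing_everything_warns_not_raises(self):
        g = toy_matrix(np.zeros((4, 2)) + [[0, 2], [0, 2], [0, 2], [0, 2]][0])
        with pytest.warns(UserWarning, match="empty"):
            out = qc_filter(g, maf_min=0.49, missing_max=1.0)
        assert out.n_snps == 0


class TestGrm:
    def test_identical_lines_share_diagonal_value(self):
        g = toy_matrix([[0, 1, 2], [0, 1, 2], [2, 1, 0], [1, 2, 0]])
        grm = compute_grm(g)
        assert grm[0, 1] == pytest.approx(grm[0, 0])
        assert np.allclose(grm, grm.T)

    def test_matches_hand_standardized_arithmetic(self):
        d = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        g = toy_matrix(d)
        f = d.mean(axis=0) / 2
        Z = (d - 2 * f) / np.sqrt(2 * f * (1 - f))
        assert np.allclose(compute_grm(g), Z @ Z.T / 2)

    def test_mean_diagonal_near_one_for_random_panel(self):
        g = simulate_genotypes(2000, 300, seed=12)
        grm = compute_grm(g)
        assert abs(np.mean(np.diag(grm)) - 1.0) < 0.05

    def test_monomorphic_snp_named_in_error(self):
        g = toy_matrix([[0, 1], [0, 2], [0, 1]])
        with pytest.raises(ValidationError, match="chr01_1000"):
            compute_grm(g)


class TestNullLmm:
    def test_pure_noise_estimates_near_zero_h2(self):
        g = simulate_genotypes(1000, 400, seed=1)
        grm = compute_grm(g)
        y = np.random.default_rng(2).standard_normal(1000)
        vc = fit_null_lmm(y, grm)
        assert vc.h2 < 0.1

    def test_recovers_planted_heritability(self):
        truth = default_truth(n_snps=2000, seed=21, heritability=0.5)
        study = simulate_study(truth, {"P1": 1000}, n_snps=2000)
        g = study.genotypes["P1:E1"]
        y = study.phenotypes.values_for("P1:E1", "GPP", g.line_ids)
        vc = fit_null_lmm(y, compute_grm(g))
        assert 0.4 <= vc.h2 <= 0.6

    def test_identity_grm_flat_likelihood_convention(self):
        y = np.random.default_rng(5).standard_normal(200)
        with pytest.warns(UserWarning, match="flat"):
            vc = fit_null_lmm(y, np.eye(200))
        assert vc.h2 == 0.0

    def test_non_psd_grm_rejected(self):
        bad = np.diag([1.0, 1.0, -0.5])
        with pytest.raises(ValidationError, match="positive semi-definite"):
            GrmEigen.from_grm(bad)


class TestMlmaScan:
    def test_reduces_to_ols_when_genetic_variance_zero(self):
        rng = np.random.default_rng(7)
        g = simulate_genotypes(300, 40, seed=8)
        y = rng.standard_normal(300) + 0.3 * g.dosage[:, 0]
        grm = compute_grm(g)
        vc = VarianceComponents(sigma_g2=0.0, sigma_e2=1.0)
        stats = mlma_scan(g, y, vc, grm)
        X = np.column_stack([np.ones(300), g.dosage[:, 0]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        xtx_inv = np.linalg.inv(X.T @ X)
        # EMMAX holds the residual variance fixed at the null estimate
        se = np.sqrt(xtx_inv[1, 1] * vc.sigma_e2)
        assert stats[0].beta == pytest.approx(coef[1], rel=1e-8)
        assert stats[0].se == pytest.approx(se, rel=1e-8)

    def test_strong_causal_snp_reaches_genome_wide_significance(self):
        truth = default_truth(n_snps=1500, seed=31, n_causal_per_trait=4,
                              heritability=0.5)
        study = simulate_study(truth, {"P1": 1000}, n_snps=1500)
        g = study.genotypes["P1:E1"]
        y = study.phenotypes.values_for("P1:E1", "GPP", g.line_ids)
        grm = GrmEigen.from_grm(compute_grm(g))
        vc = fit_null_lmm(y, grm)
        stats = mlma_scan(g, y, vc, grm)
        lut = {s.snp.snp_id: s for s in stats}
        for i in truth.causal_indices("GPP"):
            assert lut[g.snps[i].snp_id].p < 1e-6

    def test_null_type_i_error_near_nominal(self):
        g = simulate_genotypes(1000, 1000, seed=13)
        y = np.random.default_rng(14).standard_normal(1000)
        grm = GrmEigen.from_grm(compute_grm(g))
        vc = fit_null_lmm(y, grm)
        stats = mlma_scan(g, y, vc, grm)
        frac = np.mean([s.p < 0.05 for s in stats])
        assert 0.03 <= frac <= 0.07

    def test_null_p_values_are_uniform(self):
        from scipy import stats as sps

        g = simulate_genotypes(800, 1000, seed=15)
        y = np.random.default_rng(16).standard_normal(800)
        grm = GrmEigen.from_grm(compute_grm(g))
        vc = fit_null_lmm(y, grm)
        pvals = [s.p for s in mlma_scan(g, y, vc, grm)]
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks < 0.05

    def test_estimates_invariant_under_line_reordering(self):
        g = simulate_genotypes(200, 30, seed=17)
        y = np.random.default_rng(18).standard_normal(200) + 0.5 * g.dosage[:, 3]
        grm = compute_grm(g)
        vc = fit_null_lmm(y, grm)
        stats = mlma_scan(g, y, vc, grm)
        perm = np.random.default_rng(19).permutation(200)
        g2 = toy_matrix(g.dosage[perm])
        stats2 = mlma_scan(g2, y[perm], vc, compute_grm(g2))
        for a, b in zip(stats, stats2):
            assert a.beta == pytest.approx(b.beta, rel=1e-9, abs=1e-12)
            assert a.se == pytest.approx(b.se, rel=1e-9)

    def test_zero_variance_snp_skipped(self):
        d = np.array([[0.0, 1], [0, 2], [0, 0], [0, 1]])
        g = toy_matrix(d)
        y = np.array([1.0, 2.0, 0.5, 1.5])
        vc = VarianceComponents(0.0, 1.0)
        stats = mlma_scan(g, y, vc, np.eye(4))
        assert [s.snp.snp_id for s in stats] == [g.snps[1].snp_id]
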
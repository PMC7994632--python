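"""Generator checks: LD structure, determinism, heritability and the
yield-composition channel."""

import numpy as np
import pytest

from ricemr.synthetic_data import (
    COMPONENTS,
    ParameterError,
    TruthRecord,
    default_truth,
    expected_adjacent_r2,
    simulate_genotypes,
    simulate_study,
)


def _adjacent_r2(g):
    d = g.dosage
    out = []
    for j in range(d.shape[1] - 1):
        r = np.corrcoef(d[:, j], d[:, j + 1])[0, 1]
        out.append(r * r)
    return np.array(out)


class TestSimulateGenotypes:
    def test_no_copying_gives_independent_adjacent_snps(self):
        g = simulate_genotypes(2000, 30, ld_rho=0.0, seed=3)
        assert _adjacent_r2(g).mean() < 0.05

    def test_adjacent_r2_matches_haplotype_frequency_oracle(self):
        # the oracle enumerates the 2x2 haplotype table of the copying process
        rho = 0.9
        g = simulate_genotypes(2000, 40, maf_range=(0.2, 0.4), ld_rho=rho, seed=4)
        f = g.alt_freq()
        expected = np.array(
            [expected_adjacent_r2(f[j], f[j + 1], rho) for j in range(g.n_snps - 1)]
        )
        observed = _adjacent_r2(g)
        assert abs(observed.mean() - expected.mean()) < 0.1

    def test_same_seed_is_bit_identical(self):
        a = simulate_genotypes(50, 20, seed=9)
        b = simulate_genotypes(50, 20, seed=9)
        assert np.array_equal(a.dosage, b.dosage)
        assert a.line_ids == b.line_ids and a.snps == b.snps

    def test_degenerate_maf_range_rejected(self):
        with pytest.raises(ParameterError, match="maf_range"):
            simulate_genotypes(10, 5, maf_range=(0.3, 0.1))


def _flat_truth(**over):
    base = dict(
        component_effects={},
        yield_weights=(0.25, 1.5, 3.75),
        direct_yield_effects=[],
        heritability={t: 0.0 for t in COMPONENTS},
        seed=0,
        polygenic_fraction=0.0,
        base_noise_sd={t: 0.0 for t in COMPONENTS},
        yield_noise_sd=0.0,
    )
    base.update(over)
    return TruthRecord(**base)


class TestSimulateStudy:
    def test_degenerate_generator_returns_intercepts(self):
        truth = _flat_truth()
        study = simulate_study(truth, {"P1": 10}, n_snps=20)
        for t in COMPONENTS:
            v = study.phenotypes.values_for("P1:E1", t, study.genotypes["P1:E1"].line_ids)
            assert np.allclose(v, truth.intercepts[t])

    def test_pure_gpp_channel_makes_yield_equal_gpp(self):
        truth = _flat_truth(
            yield_weights=(1.0, 0.0, 0.0),
            component_effects={"GPP": [(0, 5.0)]},
            heritability={"GPP": 1.0, "KGW": 0.0, "TP": 0.0},
            intercepts={"GPP": 100.0, "KGW": 25.0, "TP": 10.0, "YD": 0.0},
        )
        study = simulate_study(truth, {"P1": 50}, n_snps=20)
        ids = study.genotypes["P1:E1"].line_ids
        gpp = study.phenotypes.values_for("P1:E1", "GPP", ids)
        yd = study.phenotypes.values_for("P1:E1", "YD", ids)
        assert np.allclose(yd, gpp)

    def test_yield_regression_recovers_weights(self):
        # ordinary-least-squares oracle on the simulated table
        truth = default_truth(n_snps=5000, seed=5, n_causal_per_trait=8)
        study = simulate_study(truth, {"P1": 1000, "P2": 1000}, n_snps=5000)
        ids = [l for ds in study.genotypes for l in study.genotypes[ds].line_ids]
        cols = []
        for t in COMPONENTS:
            v = np.concatenate(
                [
                    study.phenotypes.values_for(ds, t, study.genotypes[ds].line_ids)
                    for ds in study.genotypes
                ]
            )
            cols.append(v)
        yd = np.concatenate(
            [
                study.phenotypes.values_for(ds, "YD", study.genotypes[ds].line_ids)
                for ds in study.genotypes
            ]
        )
        X = np.column_stack([np.ones(len(yd))] + cols)
        coef, *_ = np.linalg.lstsq(X, yd, rcond=None)
        resid = yd - X @ coef
        cov = np.linalg.inv(X.T @ X) * resid.var(ddof=4)
        se = np.sqrt(np.diag(cov))
        for w, b, s in zip(truth.yield_weights, coef[1:], se[1:]):
            assert abs(b - w) < 2 * s + 1e-9

    def test_realized_heritability_close_to_target(self):
        truth = default_truth(n_snps=3000, seed=7, heritability=0.5)
        study = simulate_study(truth, {"P1": 1500}, n_snps=3000)
        g = study.genotypes["P1:E1"]
        Dc = g.dosage - g.dosage.mean(axis=0)
        for t in COMPONENTS:
            beta = np.zeros(g.n_snps)
            for i, e in truth.component_effects[t]:
                beta[i] = e
            # genetic part = major effects (polygenic part is folded into the
            # same realized variance by construction, so bound from the
            # major share alone): compare total trait variance decomposition
            y = study.phenotypes.values_for("P1:E1", t, g.line_ids)
            g_major = Dc @ beta
            var_major = g_major.var()
            # major loci carry (1 - polygenic_fraction) of genetic variance
            var_g = var_major / (1 - truth.polygenic_fraction)
            h2_hat = var_g / y.var()
            assert abs(h2_hat - 0.5) < 0.05

    def test_overlapping_causal_sets_rejected_in_exclusivity_mode(self):
        truth = _flat_truth(
            component_effects={"GPP": [(3, 1.0)], "KGW": [(3, 0.5)]},
            heritability={"GPP": 0.5, "KGW": 0.5, "TP": 0.0},
        )
        with pytest.raises(ParameterError, match="disjoint"):
            simulate_study(truth, {"P1": 10}, n_snps=20, exclusivity="disjoint")

    def test_h2_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError, match="h2"):
            _flat_truth(heritability={"GPP": 1.2, "KGW": 0.0, "TP": 0.0})

    def test_strict_mode_zeroes_in_sample_cross_trait_association(self):
        truth = default_truth(n_snps=500, seed=3, n_causal_per_trait=4)
        study = simulate_study(
            truth, {"P1": 400}, n_snps=500, exclusivity="strict"
        )
        g = study.genotypes["P1:E1"]
        kgw = study.phenotypes.values_for("P1:E1", "KGW", g.line_ids)
        for i in truth.causal_indices("GPP"):
            x = g.dosage[:, i]
            r = np.corrcoef(x, kgw)[0, 1]
            assert abs(r) < 1e-10
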
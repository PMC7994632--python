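"""MR estimators against the published worked example and their algebraic
invariants."""

import numpy as np
import pytest

from ricemr.instruments import Instrument, InstrumentSet, derive_se
from ricemr.io_formats import SnpRecord, ValidationError
from ricemr.mr_core import (
    heterogeneity,
    ivw,
    mr_egger,
    split_by_ratio_sign,
    wald_ratios,
    weighted_median,
)


def make_set(rows, exposure="X"):
    ins = []
    for i, (bx, sx, by, sy) in enumerate(rows):
        snp = SnpRecord.from_id(f"chr{(i % 12) + 1:02d}_{1000 * (i + 1)}")
        ins.append(Instrument(snp, bx, sx, 1e-8, by, sy, 0.5))
    return InstrumentSet(exposure, "YD", ins)


class TestWaldRatios:
    def test_reference_tiller_instrument_ratio(self, reference_sets):
        wr = {w.snp_id: w for w in wald_ratios(reference_sets["TP"])}
        assert wr["chr06_1578700"].ratio == pytest.approx(-1.691 / -0.639, abs=1e-3)
        assert wr["chr06_1578700"].ratio == pytest.approx(2.646, abs=2e-3)

    def test_zero_outcome_effect_gives_zero_ratio(self):
        s = make_set([(2.0, 0.1, 0.0, 0.3)])
        (w,) = wald_ratios(s)
        assert w.ratio == 0.0 and np.isfinite(w.se_ratio)

    def test_exposure_scaling_homogeneity(self):
        s1 = make_set([(2.0, 0.1, 1.0, 0.3)])
        s2 = make_set([(6.0, 0.3, 1.0, 0.3)])
        (a,), (b,) = wald_ratios(s1), wald_ratios(s2)
        assert b.ratio == pytest.approx(a.ratio / 3)
        assert b.weight == pytest.approx(a.weight * 9)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValidationError, match="beta_x"):
            wald_ratios(make_set([(0.0, 0.1, 1.0, 0.3)]))


class TestIvw:
    def test_reproduces_published_grain_number_effect(self, reference_sets):
        res = ivw(reference_sets["GPP"])
        assert res.estimate == pytest.approx(0.086, abs=2e-3)
        assert res.ci_low == pytest.approx(0.030, abs=5e-3)
        assert res.ci_high == pytest.approx(0.141, abs=5e-3)
        assert res.p == pytest.approx(0.003, abs=2e-3)

    def test_reproduces_published_tiller_effect(self, reference_sets):
        res = ivw(reference_sets["TP"])
        assert res.estimate == pytest.approx(1.865, abs=2e-3)
        assert res.ci_low == pytest.approx(1.035, abs=5e-3)
        assert res.ci_high == pytest.approx(2.694, abs=5e-3)
        assert res.p < 1e-4

    def test_single_instrument_reduces_to_wald_ratio(self):
        s = make_set([(2.0, 0.1, 1.0, 0.4)])
        res = ivw(s)
        (w,) = wald_ratios(s)
        assert res.estimate == pytest.approx(w.ratio)
        assert res.se == pytest.approx(w.se_ratio)
        assert res.scale_factor == 1.0

    def test_estimate_within_ratio_envelope_and_sign_equivariant(self):
        rng = np.random.default_rng(2)
        rows = [(rng.uniform(0.5, 2), 0.1, rng.normal(), rng.uniform(0.1, 1))
                for _ in range(6)]
        s = make_set(rows)
        res = ivw(s)
        ratios = [w.ratio for w in wald_ratios(s)]
        assert min(ratios) <= res.estimate <= max(ratios)
        flipped = make_set([(bx, sx, -by, sy) for bx, sx, by, sy in rows])
        assert ivw(flipped).estimate == pytest.approx(-res.estimate)

    def test_exposure_unit_rescaling(self):
        rows = [(1.0, 0.1, 0.5, 0.2), (2.0, 0.2, 1.5, 0.3), (0.7, 0.1, 0.2, 0.25)]
        s1 = make_set(rows)
        c = 4.0
        s2 = make_set([(c * bx, c * sx, by, sy) for bx, sx, by, sy in rows])
        r1, r2 = ivw(s1), ivw(s2)
        assert r2.estimate == pytest.approx(r1.estimate / c)
        assert r2.p == pytest.approx(r1.p)


class TestWeightedMedian:
    def test_reproduces_published_grain_number_median(self, reference_sets):
        res = weighted_median(reference_sets["GPP"], n_boot=5000, seed=0)
        assert res.estimate == pytest.approx(0.081, abs=2e-3)

    def test_reproduces_published_tiller_median(self, reference_sets):
        res = weighted_median(reference_sets["TP"], n_boot=5000, seed=0)
        assert res.estimate == pytest.approx(1.540, abs=2e-3)

    def test_degenerate_identical_ratios(self):
        rows = [(1.0, 0.1, 2.0, 0.2), (2.0, 0.1, 4.0, 0.4), (0.5, 0.1, 1.0, 0.1)]
        res = weighted_median(make_set(rows), n_boot=2000, seed=1)
        assert res.estimate == pytest.approx(2.0)
        assert 0 < res.se < 1.0  # bootstrap spread stays on the per-ratio scale

    def test_requires_three_instruments(self):
        with pytest.raises(ValidationError, match="k >= 3"):
            weighted_median(make_set([(1, 0.1, 1, 0.1), (1, 0.1, 1, 0.1)]))

    def test_bootstrap_seed_reproducible(self, reference_sets):
        a = weighted_median(reference_sets["TP"], n_boot=1000, seed=7)
        b = weighted_median(reference_sets["TP"], n_boot=1000, seed=7)
        assert a.se == b.se


class TestMrEgger:
    def test_reproduces_published_grain_number_regression(self, reference_sets):
        res = mr_egger(reference_sets["GPP"])
        assert res.estimate == pytest.approx(-0.029, abs=2e-3)
        assert res.intercept == pytest.approx(1.387, abs=3e-3)
        assert res.intercept_p == pytest.approx(0.061, abs=5e-3)

    def test_reproduces_published_tiller_regression(self, reference_sets):
        res = mr_egger(reference_sets["TP"])
        assert res.estimate == pytest.approx(1.797, abs=2e-3)
        assert res.intercept == pytest.approx(0.046, abs=2e-3)
        assert res.intercept_p == pytest.approx(0.968, abs=5e-3)

    def test_exact_line_through_origin(self):
        c = 1.7
        rows = [(bx, 0.1, c * bx, 0.2) for bx in (0.5, 1.0, 1.5, -2.0)]
        res = mr_egger(make_set(rows))
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.estimate == pytest.approx(c, abs=1e-9)

    def test_singular_design_rejected(self):
        rows = [(1.0, 0.1, 0.5, 0.2), (-1.0, 0.1, 0.1, 0.2), (1.0, 0.1, 0.3, 0.2)]
        with pytest.raises(ValidationError, match="singular"):
            mr_egger(make_set(rows))

    def test_outcome_sign_equivariance(self):
        rows = [(1.0, 0.1, 0.5, 0.2), (2.0, 0.2, 1.5, 0.3), (0.7, 0.1, 0.2, 0.25)]
        a = mr_egger(make_set(rows))
        b = mr_egger(make_set([(bx, sx, -by, sy) for bx, sx, by, sy in rows]))
        assert b.estimate == pytest.approx(-a.estimate)
        assert b.intercept == pytest.approx(-a.intercept)


class TestHeterogeneity:
    def test_published_grain_number_q_test(self, reference_sets):
        Q, df, p, i2 = heterogeneity(reference_sets["GPP"])
        assert p == pytest.approx(0.38, abs=0.01)
        assert i2 == pytest.approx(0.05, abs=0.02)

    def test_published_tiller_q_test(self, reference_sets):
        Q, df, p, i2 = heterogeneity(reference_sets["TP"])
        assert p == pytest.approx(0.43, abs=0.01)
        assert i2 == 0.0

    def test_duplicated_instruments_have_zero_q(self):
        rows = [(1.0, 0.1, 0.5, 0.2)] * 3
        s = InstrumentSet("X", "YD", [
            Instrument(SnpRecord.from_id(f"chr01_{i + 1}000"), *r[:2], 1e-8, *r[2:], 0.5)
            for i, r in enumerate(rows)
        ])
        Q, _, p, i2 = heterogeneity(s)
        assert Q == pytest.approx(0.0, abs=1e-20) and i2 == 0.0


class TestSplitBySign:
    def test_published_grain_weight_split_is_seven_four(self, reference_sets):
        pos, neg = split_by_ratio_sign(reference_sets["KGW"])
        assert pos.k == 7 and neg.k == 4

    def test_published_negative_subgroup_ivw(self, reference_sets):
        _, neg = split_by_ratio_sign(reference_sets["KGW"])
        assert ivw(neg).estimate == pytest.approx(-0.233, abs=3e-3)

    def test_all_concordant_gives_empty_negative_subset(self):
        rows = [(1.0, 0.1, 0.5, 0.2), (-2.0, 0.2, -1.5, 0.3)]
        pos, neg = split_by_ratio_sign(make_set(rows))
        assert pos.k == 2 and neg.k == 0
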
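"""Group statistics: t tests, effect sizes, 2x2 ANOVA, Bayes factors."""

import math

import numpy as np
import pingouin as pg
import pytest
from scipy import stats as sps

from facebody.stats import (
    DegenerateVarianceError,
    bf_robustness,
    bonferroni,
    hedges_correction,
    jzs_bf01_directional,
    one_sample_test,
    paired_contrast,
    pearson_with_bf,
    rm_anova_2x2,
)


class TestPairedContrast:
    def test_identical_inputs_carry_no_evidence(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        res = paired_contrast(a, a)
        assert (res.statistic, res.effect_size, res.p_value) == (0.0, 0.0, 1.0)

    def test_hand_arithmetic_oracle(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_contrast(d, np.zeros(5))
        sd = d.std(ddof=1)
        assert res.statistic == pytest.approx(3.0 / (sd / math.sqrt(5)), rel=1e-12)
        assert res.statistic == pytest.approx(4.2426, abs=1e-4)
        assert res.effect_size == pytest.approx((3.0 / sd) * hedges_correction(5), rel=1e-12)

    def test_matches_scipy_t_and_p(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=15), rng.normal(size=15)
        res = paired_contrast(a, b)
        t_sp, p_sp = sps.ttest_rel(a, b)
        assert res.statistic == pytest.approx(t_sp, rel=1e-12)
        assert res.p_value == pytest.approx(p_sp, rel=1e-12)
        # effect size uses the difference-score SD convention
        d = a - b
        assert res.effect_size == pytest.approx(
            d.mean() / d.std(ddof=1) * hedges_correction(15), rel=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_contrast([1.0], [0.0])

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            paired_contrast([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestOneSample:
    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            one_sample_test(np.zeros(5))

    def test_hand_arithmetic_oracle(self):
        x = np.array([0.1, 0.1, 0.1, 0.3])
        res = one_sample_test(x, 0.0)
        se = x.std(ddof=1) / 2.0
        assert res.statistic == pytest.approx(x.mean() / se, rel=1e-12)
        assert res.effect_size == pytest.approx(
            x.mean() / x.std(ddof=1) * hedges_correction(4), rel=1e-12)

    def test_symmetric_sample_gives_zero_t(self):
        res = one_sample_test(np.array([-0.2, -0.1, 0.1, 0.2]), 0.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_hedges_correction_properties(self):
        js = np.array([hedges_correction(n) for n in range(3, 200)])
        assert np.all(js < 1)
        assert np.all(np.diff(js) > 0)
        assert hedges_correction(10_000) == pytest.approx(1.0, abs=1e-4)


class TestAnova2x2:
    def test_identical_cells_give_zero_f(self):
        cells = np.tile(np.array([[0.3]]), (6, 4))
        res = rm_anova_2x2(cells)
        assert all(r.statistic == 0.0 and r.p_value == 1.0 for r in res.values())

    def test_additive_construction_has_null_interaction(self):
        rng = np.random.default_rng(8)
        n = 12
        base = rng.normal(size=(n, 1))
        a_eff = rng.normal(size=(n, 1))
        b_eff = rng.normal(size=(n, 1))
        cells = np.hstack([base + a_eff + b_eff, base + a_eff,
                           base + b_eff, base])
        res = rm_anova_2x2(cells)
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-10)

    def test_f_equals_t_squared_and_matches_pingouin(self):
        rng = np.random.default_rng(21)
        cells = rng.normal(size=(10, 4))
        res = rm_anova_2x2(cells)
        t_a = one_sample_test(cells @ np.array([1, 1, -1, -1]) / 2)
        assert res["factor_a"].statistic == pytest.approx(t_a.statistic ** 2, abs=1e-8)
        # independent route: pingouin's repeated-measures ANOVA
        import pandas as pd
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(10), 4),
            "A": np.tile(["p", "p", "a", "a"], 10),
            "B": np.tile(["d", "g", "d", "g"], 10),
            "y": cells.ravel(),
        })
        aov = pg.rm_anova(data=long, dv="y", within=["A", "B"], subject="subj",
                          detailed=True)
        f_by_source = dict(zip(aov["Source"], aov["F"]))
        assert res["factor_a"].statistic == pytest.approx(f_by_source["A"], rel=1e-6)
        assert res["factor_b"].statistic == pytest.approx(f_by_source["B"], rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(f_by_source["A * B"], rel=1e-6)

    def test_incomplete_cells_rejected(self):
        cells = np.ones((5, 4))
        cells[2, 3] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_2x2(cells)


def grid_jzs_bf01(t, n, scale, direction=1, n_grid=40_000):
    """Fixed-grid quadrature oracle for the directional JZS Bayes factor.

    The half-Cauchy integral is evaluated on an arctan-transformed grid;
    the far tail (noncentrality beyond ~1e6) contributes nothing and is
    clipped to keep the noncentral-t density evaluable.
    """
    t = t * direction
    u = np.linspace(1e-9, math.atan(1e6 / scale), n_grid)
    delta = scale * np.tan(u)
    dens = np.nan_to_num(sps.nct.pdf(t, n - 1, delta * math.sqrt(n)))
    m1 = (2 / math.pi) * np.trapezoid(dens, u)
    return sps.t.pdf(t, n - 1) / m1


class TestJzsBayesFactor:
    def test_null_favoured_at_t_zero(self):
        assert jzs_bf01_directional(0.0, 21, 0.707) > 1.0

    def test_matches_fixed_grid_quadrature_oracle(self):
        assert jzs_bf01_directional(1.2, 20, 0.707) == pytest.approx(
            grid_jzs_bf01(1.2, 20, 0.707), rel=1e-4)

    def test_vanishing_prior_scale_limits_to_one(self):
        assert jzs_bf01_directional(1.7, 25, 1e-7) == pytest.approx(1.0, abs=1e-4)

    def test_directional_halves_average_to_pingouin_two_sided(self):
        t, n = 1.4, 18
        bf10 = 0.5 * (1 / jzs_bf01_directional(t, n, direction=1)
                      + 1 / jzs_bf01_directional(t, n, direction=-1))
        assert bf10 == pytest.approx(
            float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-6)

    def test_wrong_direction_strengthens_null(self):
        assert jzs_bf01_directional(2.0, 20, direction=-1) \
            > jzs_bf01_directional(2.0, 20, direction=1)


class TestRobustness:
    def test_monotone_at_t_zero_and_min_scale(self):
        scales = [0.1, 0.2, 0.5, 0.707, 1.0]
        res = bf_robustness(0.0, 21, scales)
        bfs = [bf for _, bf in res.robustness_curve]
        assert np.all(np.diff(bfs) > 0)
        substantial = [s for s, bf in res.robustness_curve if bf >= 3.0]
        assert res.min_scale_substantial == min(substantial)

    def test_curve_matches_pointwise_oracle(self):
        res = bf_robustness(1.1, 22, [0.3, 0.707])
        for s, bf in res.robustness_curve:
            assert bf == pytest.approx(grid_jzs_bf01(1.1, 22, s), rel=1e-4)

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            bf_robustness(0.0, 21, [])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(8.0)
        r, p, _ = pearson_with_bf(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_null_data_favour_null(self):
        rng = np.random.default_rng(12)
        wins = 0
        for _ in range(10):
            x = rng.normal(size=40)
            y = rng.permutation(x)
            r, p, bf01 = pearson_with_bf(x, y)
            wins += bf01 > 1
        assert wins >= 8

    def test_bf_matches_pingouin_exact_formula(self):
        rng = np.random.default_rng(4)
        for n in (10, 20, 35):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p, bf01 = pearson_with_bf(x, y)
            assert 1 / bf01 == pytest.approx(float(pg.bayesfactor_pearson(r, n)),
                                             rel=1e-4)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            pearson_with_bf(np.ones(5), np.arange(5.0))


class TestTypeIRate:
    def test_paired_contrast_nominal_alpha(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            d = rng.normal(0, 0.05, size=21)
            rejections += paired_contrast(d, np.zeros(21)).p_value < 0.05
        assert 0.035 <= rejections / n_rep <= 0.065


def test_bonferroni_caps_at_one():
    assert np.allclose(bonferroni([0.01, 0.4], 3), [0.03, 1.0])
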
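"""The NB differential-expression engine against independent oracles:
hand-computed size factors, statsmodels GLM fits, brute-force BH."""

import numpy as np
import pytest

from ernakit.diffexpr import (
    ALPHA_MIN,
    DEResult,
    bh_adjust,
    classify_regulated,
    estimate_dispersion,
    estimate_size_factors,
    nb_wald_test,
    run_de,
)
from ernakit.quantify import CountMatrix


def make_cm(counts, condition=None, lib_sizes=None):
    counts = np.asarray(counts, dtype=np.int64)
    n_feat, n_samp = counts.shape
    return CountMatrix(
        feature_ids=[f"f{i}" for i in range(n_feat)],
        sample_ids=[f"s{j}" for j in range(n_samp)],
        counts=counts,
        condition=condition or [],
        lib_sizes=lib_sizes,
    )


def nb_counts(rng, mean, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)


class TestSizeFactors:
    def test_hand_computed_two_by_two(self):
        sf = estimate_size_factors(make_cm([[10, 20], [30, 60]]))
        assert sf == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_identical_columns_give_unit_factors(self):
        sf = estimate_size_factors(make_cm([[5, 5], [80, 80], [13, 13]]))
        assert sf == pytest.approx([1.0, 1.0])

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 2000, size=(100, 4))
        sf = estimate_size_factors(make_cm(counts))
        # direct median-of-ratios, written independently
        geo = np.exp(np.mean(np.log(counts), axis=1))
        expected = [np.median(counts[:, j] / geo) for j in range(4)]
        assert sf == pytest.approx(expected)

    def test_no_all_positive_feature_errors(self):
        with pytest.raises(ValueError, match="pseudocount"):
            estimate_size_factors(make_cm([[0, 5], [5, 0]]))


class TestDispersion:
    GROUPS = ["vehicle"] * 3 + ["treated"] * 3

    def test_constant_counts_hit_the_floor(self):
        cm = make_cm([[50] * 6], condition=self.GROUPS)
        disp = estimate_dispersion(cm, np.ones(6), method="per_feature")
        assert disp[0] == ALPHA_MIN

    def test_poisson_counts_mostly_floored(self):
        rng = np.random.default_rng(9)
        cm = make_cm(rng.poisson(200, size=(300, 6)), condition=self.GROUPS)
        disp = estimate_dispersion(cm, np.ones(6), method="per_feature")
        # Poisson data: moment alpha <= ~0 for most features
        assert np.mean(disp <= 0.01) >= 0.5
        assert np.median(disp) < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(10)
        groups = ["vehicle"] * 5 + ["treated"] * 5
        cm = make_cm(nb_counts(rng, 500.0, 0.1, (2000, 10)), condition=groups)
        disp = estimate_dispersion(cm, np.ones(10), method="per_feature")
        assert 0.05 <= np.median(disp) <= 0.2

    def test_single_sample_groups_unidentifiable(self):
        cm = make_cm([[5, 9]], condition=["vehicle", "treated"])
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(cm, np.ones(2))


class TestWaldTest:
    def test_equal_group_means_give_null_result(self):
        cm = make_cm([[50, 50, 50, 50]],
                     condition=["vehicle", "vehicle", "treated", "treated"])
        (r,) = nb_wald_test(cm, np.ones(4), np.array([0.05]))
        assert r.log2fc == pytest.approx(0.0, abs=1e-9)
        assert r.p_value == pytest.approx(1.0)

    def test_all_zero_feature_flagged_not_error(self):
        cm = make_cm([[0, 0, 0, 0], [10, 10, 40, 40]],
                     condition=["vehicle", "vehicle", "treated", "treated"])
        r0, _ = nb_wald_test(cm, np.ones(4), np.array([0.05, 0.05]))
        assert r0.all_zero and r0.p_value == 1.0 and r0.log2fc == 0.0

    def test_poisson_limit_matches_statsmodels_poisson_glm(self):
        import statsmodels.api as sm

        tables = [
            [12, 20, 15, 31, 28, 25],
            [200, 180, 210, 340, 310, 355],
            [3, 1, 4, 9, 6, 11],
        ]
        condition = ["vehicle"] * 3 + ["treated"] * 3
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        X = np.column_stack([np.ones(6), x])
        for y in tables:
            cm = make_cm(np.array([y]), condition=condition)
            (r,) = nb_wald_test(cm, np.ones(6), np.array([ALPHA_MIN]))
            fit = sm.GLM(np.array(y, float), X,
                         family=sm.families.Poisson()).fit()
            z = fit.params[1] / fit.bse[1]
            from scipy import stats
            p_ref = 2 * stats.norm.sf(abs(z))
            assert r.p_value == pytest.approx(p_ref, abs=1e-6)
            assert r.log2fc == pytest.approx(fit.params[1] / np.log(2), abs=1e-6)

    def test_nb_table_matches_statsmodels_nb_glm(self):
        import statsmodels.api as sm

        y = np.array([120, 95, 143, 510, 470, 602], dtype=float)
        alpha = 0.08
        sf = np.array([0.9, 1.0, 1.1, 0.95, 1.05, 1.0])
        condition = ["vehicle"] * 3 + ["treated"] * 3
        cm = make_cm(np.array([y], dtype=np.int64), condition=condition)
        (r,) = nb_wald_test(cm, sf, np.array([alpha]))
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                     offset=np.log(sf)).fit()
        from scipy import stats
        z = fit.params[1] / fit.bse[1]
        assert r.log2fc == pytest.approx(fit.params[1] / np.log(2), abs=1e-6)
        assert r.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-6)

    def test_swapping_group_labels_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(11)
        counts = nb_counts(rng, 300.0, 0.05, (50, 6))
        a = make_cm(counts, condition=["vehicle"] * 3 + ["treated"] * 3)
        b = make_cm(counts, condition=["treated"] * 3 + ["vehicle"] * 3)
        disp = np.full(50, 0.05)
        ra = nb_wald_test(a, np.ones(6), disp)
        rb = nb_wald_test(b, np.ones(6), disp)
        for x, y in zip(ra, rb):
            assert x.log2fc == pytest.approx(-y.log2fc, abs=1e-6)
            assert x.p_value == pytest.approx(y.p_value, rel=1e-6)

    def test_joint_count_and_lib_scaling_leaves_calls_unchanged(self):
        rng = np.random.default_rng(12)
        counts = nb_counts(rng, 400.0, 0.05, (100, 4))
        counts[:10, 2:] *= 8
        condition = ["vehicle", "vehicle", "treated", "treated"]
        base = run_de(make_cm(counts, condition=condition))
        scaled = counts.copy()
        scaled[:, 0] *= 10  # one sample deeper by 10x; size factors absorb it
        res = run_de(make_cm(scaled, condition=condition))
        assert [r.call for r in res] == [r.call for r in base]


class TestBHAndCalls:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_is_its_own_fdr(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.random(1000)
        assert bh_adjust(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1]
        )

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize(
        "log2fc,fdr,call",
        [
            (1.5, 0.01, "up"),
            (1.0, 0.001, "ns"),   # strict > 1
            (-2.0, 0.04, "down"),
            (2.0, 0.05, "ns"),    # strict < 0.05
            (0.2, 0.001, "ns"),
        ],
    )
    def test_call_boundaries_are_strict(self, log2fc, fdr, call):
        r = DEResult("f", 10.0, log2fc, 0.1, 1.0, 0.01, fdr=fdr)
        classify_regulated([r])
        assert r.call == call


class TestNullCalibration:
    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(100)
        condition = ["vehicle"] * 3 + ["treated"] * 3
        cm = make_cm(nb_counts(rng, 200.0, 0.1, (2000, 6)), condition=condition)
        res = run_de(cm)
        frac = np.mean([r.p_value < 0.05 for r in res])
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_eightfold_change(self):
        rng = np.random.default_rng(101)
        mu = np.full((200, 4), 500.0)
        mu[:100, 2:] *= 8.0
        r_ = 1.0 / 0.05
        counts = rng.negative_binomial(r_, r_ / (r_ + mu))
        cm = make_cm(counts, condition=["vehicle", "vehicle", "treated", "treated"])
        res = run_de(cm)
        called = np.mean([r.call == "up" for r in res[:100]])
        assert called >= 0.9
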
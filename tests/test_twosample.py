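"""Harmonization and the summary-data MR estimator suite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cvhmr.containers import SUMMARY_COLUMNS
from cvhmr.twosample import (
    HarmonizedPairs,
    bh_fdr,
    cochrans_q,
    harmonize,
    ivw,
    mr_egger,
    mr_presso,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)


def stats_table(rows):
    df = pd.DataFrame(rows, columns=["snp", "a1", "a2", "eaf", "beta", "se"])
    df["p"] = 2 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    df["p"] = df["p"].clip(lower=1e-300)
    df["n"] = 10_000
    return df[SUMMARY_COLUMNS]


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = stats_table([("rs1", "A", "G", 0.3, 0.1, 0.02)])
        out = stats_table([("rs1", "G", "A", 0.7, 0.05, 0.02)])
        h = harmonize(exp, out)
        assert list(h.actions["action"]) == ["flipped"]
        assert h.table.loc[0, "by"] == pytest.approx(-0.05)
        assert h.table.loc[0, "eaf_y"] == pytest.approx(0.3)

    def test_palindromic_informative_eaf_kept(self):
        exp = stats_table([("rs1", "A", "T", 0.10, 0.1, 0.02)])
        out = stats_table([("rs1", "A", "T", 0.12, 0.07, 0.02)])
        h = harmonize(exp, out)
        assert list(h.actions["action"]) == ["kept"]
        assert h.table.loc[0, "by"] == pytest.approx(0.07)

    def test_palindromic_opposite_side_eaf_flipped(self):
        exp = stats_table([("rs1", "C", "G", 0.10, 0.1, 0.02)])
        out = stats_table([("rs1", "C", "G", 0.88, 0.07, 0.02)])
        h = harmonize(exp, out)
        assert list(h.actions["action"]) == ["flipped"]
        assert h.table.loc[0, "by"] == pytest.approx(-0.07)

    def test_palindromic_ambiguous_eaf_dropped(self):
        exp = stats_table([("rs1", "C", "G", 0.30, 0.1, 0.02)])
        out = stats_table([("rs1", "C", "G", 0.48, 0.07, 0.02)])
        h = harmonize(exp, out)
        assert list(h.actions["action"]) == ["dropped_palindromic"]
        assert len(h) == 0

    def test_strand_complement_alignment(self):
        exp = stats_table([("rs1", "A", "G", 0.3, 0.1, 0.02)])
        out = stats_table([("rs1", "T", "C", 0.3, 0.05, 0.02)])
        h = harmonize(exp, out)
        assert list(h.actions["action"]) == ["kept"]
        assert h.table.loc[0, "by"] == pytest.approx(0.05)

    def test_incompatible_alleles_dropped(self):
        exp = stats_table([("rs1", "A", "G", 0.3, 0.1, 0.02),
                           ("rs2", "A", "G", 0.3, 0.1, 0.02)])
        out = stats_table([("rs1", "A", "C", 0.3, 0.05, 0.02),
                           ("rs2", "A", "G", 0.3, 0.05, 0.02)])
        h = harmonize(exp, out)
        assert dict(zip(h.actions["snp"], h.actions["action"])) == {
            "rs1": "dropped_incompatible", "rs2": "kept",
        }

    def test_every_intersected_snp_accounted_for(self, clean_pairs):
        counts = clean_pairs.actions["action"].value_counts()
        assert counts.sum() == 30
        assert counts.get("kept", 0) + counts.get("flipped", 0) == len(clean_pairs)

    def test_empty_intersection_is_error(self):
        exp = stats_table([("rs1", "A", "G", 0.3, 0.1, 0.02)])
        out = stats_table([("rs9", "A", "G", 0.3, 0.1, 0.02)])
        with pytest.raises(ValueError, match="shared"):
            harmonize(exp, out)


class TestWaldRatio:
    def test_ratio_and_delta_se(self):
        ratio, se = wald_ratio(0.2, 0.01, 0.4, 0.1)
        assert ratio == pytest.approx(2.0)
        assert se == pytest.approx(0.5)

    def test_double_sign_flip_invariance(self):
        assert wald_ratio(0.2, 0.01, 0.4, 0.1)[0] == pytest.approx(
            wald_ratio(-0.2, 0.01, -0.4, 0.1)[0]
        )

    def test_zero_bx_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.4, 0.1)


def wls_through_origin_oracle(bx, by, w):
    """Independent normal-equations WLS solve (no intercept)."""
    X = bx[:, None]
    beta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (by * w))
    se = np.sqrt(np.linalg.inv(X.T @ (X * w[:, None]))[0, 0])
    return float(beta[0]), float(se)


class TestIvw:
    def test_exact_fit_recovers_slope_with_zero_q(self):
        pairs = HarmonizedPairs.from_arrays([1.0, 2.0], [0.01] * 2,
                                            [1.0, 2.0], [0.05] * 2)
        res = ivw(pairs)
        assert res.beta == pytest.approx(1.0, abs=1e-12)
        assert res.diagnostics["Q"] == pytest.approx(0.0, abs=1e-12)

    def test_single_snp_equals_wald_ratio(self):
        pairs = HarmonizedPairs.from_arrays([0.2], [0.01], [0.4], [0.1])
        res = ivw(pairs)
        ratio, se = wald_ratio(0.2, 0.01, 0.4, 0.1)
        assert res.beta == pytest.approx(ratio, abs=1e-12)
        assert res.se == pytest.approx(se, abs=1e-12)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            bx = rng.uniform(0.05, 0.3, 50) * rng.choice([-1, 1], 50)
            se_y = rng.uniform(0.02, 0.1, 50)
            by = -0.5 * bx + rng.normal(0, se_y)
            pairs = HarmonizedPairs.from_arrays(bx, 0.01, by, se_y)
            res = ivw(pairs, mode="fixed")
            beta_o, se_o = wls_through_origin_oracle(bx, by, se_y**-2)
            assert res.beta == pytest.approx(beta_o, abs=1e-10)
            assert res.se == pytest.approx(se_o, abs=1e-10)

    def test_recovers_theta_within_three_se(self, clean_pairs):
        res = ivw(clean_pairs)
        assert abs(res.beta - (-0.5)) < 3 * res.se

    def test_row_order_invariance(self, clean_pairs):
        shuffled = HarmonizedPairs(
            table=clean_pairs.table.sample(frac=1, random_state=5).reset_index(drop=True)
        )
        assert ivw(shuffled).beta == pytest.approx(ivw(clean_pairs).beta, abs=1e-12)


class TestCochransQ:
    def test_identical_ratios_give_zero(self):
        pairs = HarmonizedPairs.from_arrays([0.1, 0.2, 0.3], [0.01] * 3,
                                            [0.2, 0.4, 0.6], [0.05] * 3)
        q, df, p = cochrans_q(pairs, 2.0)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_snp_value(self):
        """Ratios 1 and 2 with unit ratio-SE: Q = 0.5 at the weighted mean."""
        pairs = HarmonizedPairs.from_arrays([1.0, 1.0], [0.01] * 2,
                                            [1.0, 2.0], [1.0, 1.0])
        beta = ivw(pairs, mode="fixed").beta
        assert beta == pytest.approx(1.5)
        q, df, _ = cochrans_q(pairs, beta)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert df == 1


class TestWeightedMedian:
    def test_middle_value_with_equal_weights(self):
        assert weighted_median_point([1.0, 2.0, 3.0], [1, 1, 1]) == pytest.approx(2.0)

    def test_two_ratio_interpolation(self):
        assert weighted_median_point([1.0, 3.0], [1, 1]) == pytest.approx(2.0)

    def test_fewer_than_three_snps_rejected(self):
        pairs = HarmonizedPairs.from_arrays([0.1, 0.2], [0.01] * 2,
                                            [0.1, 0.2], [0.05] * 2)
        with pytest.raises(ValueError):
            weighted_median(pairs)

    def test_bootstrap_se_deterministic_under_seed(self, clean_pairs):
        a = weighted_median(clean_pairs, n_boot=200, seed=9)
        b = weighted_median(clean_pairs, n_boot=200, seed=9)
        assert a.se == b.se

    def test_robust_to_minority_directional_pleiotropy(self):
        """With 40% pleiotropic SNPs the median beats IVW most of the time."""
        wins = 0
        reps = 100
        rng = np.random.default_rng(31)
        for _ in range(reps):
            bx = rng.uniform(0.1, 0.2, 30)
            se_y = np.full(30, 0.05)
            alpha = np.zeros(30)
            alpha[:12] = 0.3  # strong one-directional direct effects
            by = 1.0 * bx + alpha + rng.normal(0, se_y)
            pairs = HarmonizedPairs.from_arrays(bx, 0.01, by, se_y)
            err_ivw = abs(ivw(pairs, mode="fixed").beta - 1.0)
            err_wm = abs(weighted_median(pairs, n_boot=50,
                                         seed=int(rng.integers(2**31))).beta - 1.0)
            wins += err_wm < err_ivw
        assert wins / reps >= 0.9


class TestMrEgger:
    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.5 + 1.5 * bx
        pairs = HarmonizedPairs.from_arrays(bx, 0.01, by, np.full(4, 0.05))
        res, intercept = mr_egger(pairs)
        assert res.beta == pytest.approx(1.5, abs=1e-10)
        assert intercept["estimate"] == pytest.approx(0.5, abs=1e-10)

    def test_invariant_to_pair_sign_flips(self, clean_pairs):
        res_a, icpt_a = mr_egger(clean_pairs)
        flipped = clean_pairs.table.copy()
        flipped.loc[0, ["bx", "by"]] *= -1
        res_b, icpt_b = mr_egger(HarmonizedPairs(table=flipped))
        assert res_a.beta == pytest.approx(res_b.beta, abs=1e-12)
        assert icpt_a["estimate"] == pytest.approx(icpt_b["estimate"], abs=1e-12)

    def test_no_leverage_rejected(self):
        pairs = HarmonizedPairs.from_arrays([0.1, 0.1, 0.1], [0.01] * 3,
                                            [0.1, 0.2, 0.15], [0.05] * 3)
        with pytest.raises(ValueError, match="leverage"):
            mr_egger(pairs)


class TestMrPresso:
    def _pairs(self, seed, outlier=None):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.2, 25)
        se_y = np.full(25, 0.05)
        by = -0.5 * bx + rng.normal(0, se_y)
        if outlier is not None:
            by[outlier] += 20 * se_y[outlier]
        return HarmonizedPairs.from_arrays(bx, 0.01, by, se_y)

    def test_planted_outlier_flagged_and_corrected(self):
        pairs = self._pairs(3, outlier=7)
        res = mr_presso(pairs, n_sim=500, seed=11)
        assert 7 in res.outliers
        full = ivw(pairs, mode="fixed").beta
        assert abs(res.corrected.beta - (-0.5)) < abs(full - (-0.5))

    def test_null_rarely_flags(self):
        flagged = 0
        for seed in range(30):
            res = mr_presso(self._pairs(seed), n_sim=300, seed=seed)
            flagged += bool(res.outliers)
        assert flagged <= 4

    def test_seed_determinism(self):
        pairs = self._pairs(5)
        a = mr_presso(pairs, n_sim=300, seed=2)
        b = mr_presso(pairs, n_sim=300, seed=2)
        assert a.global_p == b.global_p

    def test_low_n_sim_rejected(self):
        with pytest.raises(ValueError, match="n_sim"):
            mr_presso(self._pairs(1), n_sim=50)


class TestBhFdr:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(2, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])


class TestExactFitCollapse:
    def test_all_estimators_agree_on_exact_proportionality(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        theta = -0.8
        pairs = HarmonizedPairs.from_arrays(bx, 0.01, theta * bx, np.full(5, 0.05))
        res_ivw = ivw(pairs)
        res_wm = weighted_median(pairs, n_boot=100, seed=0)
        res_egger, intercept = mr_egger(pairs)
        assert res_ivw.beta == pytest.approx(theta, abs=1e-10)
        assert res_wm.beta == pytest.approx(theta, abs=1e-10)
        assert res_egger.beta == pytest.approx(theta, abs=1e-10)
        assert intercept["estimate"] == pytest.approx(0.0, abs=1e-10)
        assert res_ivw.diagnostics["Q"] == pytest.approx(0.0, abs=1e-12)
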
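"""MR estimators against independent closed-form and brute-force oracles."""

import numpy as np
import pytest

from mrscreen import (
    ConfigurationError,
    InsufficientInstrumentsError,
    egger,
    heterogeneity,
    instrument_strength,
    ivw_fixed_effects,
    ivw_random_effects,
    presso,
    relative_bias,
    steiger,
    wald_ratio,
    weighted_median,
)
from mrscreen.estimators import estimates_from_frame, estimates_to_frame
from mrscreen.simulate import SyntheticTruth, ProteinTruth, simulate_step1_panel
from mrscreen import harmonize

from conftest import make_instruments


# ---------------------------------------------------------------- oracles

def wls_origin_oracle(bx, by, w):
    """Weighted least squares through the origin by normal equations."""
    X = np.asarray(bx, float).reshape(-1, 1)
    W = np.diag(np.asarray(w, float))
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ np.asarray(by, float))
    se = np.sqrt(np.linalg.inv(X.T @ W @ X)[0, 0])
    return float(beta[0]), float(se)


def wls_intercept_oracle(bx, by, w):
    """Weighted least squares with intercept by normal equations.

    Returns (intercept, slope, se_intercept, se_slope) with the
    covariance scaled by max(1, RSS_w/(k-2)).
    """
    bx, by, w = map(np.asarray, (bx, by, w))
    X = np.column_stack([np.ones_like(bx), bx])
    W = np.diag(w)
    XtWX = X.T @ W @ X
    coef = np.linalg.solve(XtWX, X.T @ W @ by)
    resid = by - X @ coef
    sigma2 = max(1.0, float(resid @ (w * resid)) / (len(bx) - 2))
    cov = sigma2 * np.linalg.inv(XtWX)
    return coef[0], coef[1], np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])


def weighted_median_scan_oracle(ratios, weights):
    """Exhaustive scan of the weighted CDF over all interpolation intervals."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= p[0]:
        return r[0]
    for j in range(1, len(r)):
        if p[j - 1] < 0.5 <= p[j]:
            frac = (0.5 - p[j - 1]) / (p[j] - p[j - 1])
            return r[j - 1] + frac * (r[j] - r[j - 1])
    return r[-1]


# ------------------------------------------------------------- wald ratio

class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,sx,by,sy,beta,se",
        [
            (0.1, 0.01, 0.05, 0.02, 0.5, 0.2),
            (1.0, 0.1, 0.0, 0.05, 0.0, 0.05),
            (-0.1, 0.01, 0.05, 0.02, -0.5, 0.2),
        ],
    )
    def test_direct_formula(self, bx, sx, by, sy, beta, se):
        est = wald_ratio(bx, sx, by, sy)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)
        assert est.ci_low <= est.beta <= est.ci_high

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ConfigurationError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


# -------------------------------------------------------------------- IVW

class TestIVW:
    def test_symmetric_two_instrument_average(self):
        inst = make_instruments([0.1, 0.1], 0.01, [0.04, 0.06], 0.01)
        assert ivw_random_effects(inst).beta == pytest.approx(0.5)

    def test_single_instrument_directs_to_wald_ratio(self):
        inst = make_instruments([0.1], 0.01, [0.05], 0.01)
        with pytest.raises(InsufficientInstrumentsError, match="wald_ratio"):
            ivw_random_effects(inst)

    def test_matches_wls_oracle_to_1e10(self, rng):
        for _ in range(10):
            k = 5
            bx = rng.normal(0.1, 0.03, k)
            by = rng.normal(0.05, 0.03, k)
            sy = rng.uniform(0.005, 0.05, k)
            inst = make_instruments(bx, 0.01, by, sy)
            beta_o, se_o = wls_origin_oracle(bx, by, 1.0 / sy**2)
            est = ivw_fixed_effects(inst)
            assert est.beta == pytest.approx(beta_o, abs=1e-10)
            assert est.se == pytest.approx(se_o, abs=1e-10)
            # random-effects beta identical; se only ever inflated
            re = ivw_random_effects(inst)
            assert re.beta == pytest.approx(beta_o, abs=1e-10)
            assert re.se >= se_o - 1e-12

    def test_vanishing_weight_degenerates_to_other_wald_ratio(self):
        # as one instrument's outcome SE explodes, IVW converges to the
        # remaining instrument's ratio
        target = wald_ratio(0.1, 0.01, 0.07, 0.01).beta
        for big_se in (1.0, 10.0, 1000.0):
            inst = make_instruments([0.1, 0.2], 0.01, [0.07, 0.5],
                                    [0.01, big_se])
            drift = abs(ivw_random_effects(inst).beta - target)
            assert drift < 0.2 / big_se**2 * 10 + 1e-6

    def test_sign_equivariance_and_order_invariance(self, rng):
        k = 6
        bx = rng.normal(0.1, 0.03, k)
        by = rng.normal(0.05, 0.02, k)
        sy = rng.uniform(0.01, 0.03, k)
        inst = make_instruments(bx, 0.01, by, sy)
        flipped = make_instruments(-bx, 0.01, by, sy)
        assert ivw_random_effects(flipped).beta == pytest.approx(
            -ivw_random_effects(inst).beta
        )
        perm = rng.permutation(k)
        shuffled = make_instruments(bx[perm], 0.01, by[perm], sy[perm])
        assert ivw_random_effects(shuffled).beta == pytest.approx(
            ivw_random_effects(inst).beta
        )


# ------------------------------------------------------------------ Egger

class TestEgger:
    def test_exact_line_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        inst = make_instruments(bx, 0.01, 0.5 * bx, 0.01)
        est = egger(inst)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_recovers_intercept(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        inst = make_instruments(bx, 0.01, 0.1 + 0.5 * bx, 0.01)
        est = egger(inst)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert est.beta == pytest.approx(0.5, abs=1e-10)

    def test_matches_wls_intercept_oracle_to_1e10(self, rng):
        for _ in range(10):
            k = 6
            bx = np.abs(rng.normal(0.1, 0.03, k))
            by = rng.normal(0.05, 0.03, k)
            sy = rng.uniform(0.005, 0.05, k)
            inst = make_instruments(bx, 0.01, by, sy)
            ic, sl, se_ic, se_sl = wls_intercept_oracle(bx, by, 1.0 / sy**2)
            est = egger(inst)
            assert est.beta == pytest.approx(sl, abs=1e-10)
            assert est.egger_intercept == pytest.approx(ic, abs=1e-10)
            assert est.se == pytest.approx(se_sl, abs=1e-10)
            assert est.egger_intercept_se == pytest.approx(se_ic, abs=1e-10)

    def test_orientation_makes_fit_invariant_to_exposure_sign(self, rng):
        k = 5
        bx = np.abs(rng.normal(0.1, 0.03, k))
        by = rng.normal(0.05, 0.02, k)
        inst = make_instruments(bx, 0.01, by, 0.01)
        signs = rng.choice([-1.0, 1.0], k)
        mixed = make_instruments(bx * signs, 0.01, by * signs, 0.01)
        assert egger(mixed).beta == pytest.approx(egger(inst).beta)
        assert egger(mixed).egger_intercept == pytest.approx(
            egger(inst).egger_intercept
        )

    def test_origin_constrained_fit_is_fixed_effect_ivw(self, rng):
        # dropping the intercept column reproduces fixed-effect IVW
        k = 6
        bx = np.abs(rng.normal(0.1, 0.03, k))
        by = rng.normal(0.05, 0.03, k)
        sy = rng.uniform(0.005, 0.05, k)
        inst = make_instruments(bx, 0.01, by, sy)
        beta_o, _ = wls_origin_oracle(bx, by, 1.0 / sy**2)
        assert ivw_fixed_effects(inst).beta == pytest.approx(beta_o, abs=1e-10)

    def test_too_few_instruments(self):
        inst = make_instruments([0.1, 0.2], 0.01, [0.05, 0.1], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            egger(inst)


# -------------------------------------------------------- weighted median

class TestWeightedMedian:
    def test_symmetric_ratios_give_middle(self):
        inst = make_instruments([1.0, 1.0, 1.0], 0.01, [0.4, 0.5, 0.6], 0.01)
        assert weighted_median(inst, n_boot=50, seed=0).beta == pytest.approx(0.5)

    def test_dominant_weight_returns_that_ratio(self):
        # middle ratio carries 60% of total weight, flanked symmetrically
        sy = np.array([0.02, 0.02 / np.sqrt(3), 0.02])  # weights 1:3:1
        inst = make_instruments([1.0, 1.0, 1.0], 0.01, [0.2, 0.5, 0.9], sy)
        assert weighted_median(inst, n_boot=50, seed=0).beta == pytest.approx(0.5)

    def test_matches_exhaustive_cdf_scan_oracle(self, rng):
        for _ in range(25):
            k = int(rng.integers(3, 8))
            bx = rng.normal(0.1, 0.03, k)
            bx[np.abs(bx) < 0.01] = 0.05
            by = rng.normal(0.05, 0.05, k)
            sy = rng.uniform(0.005, 0.05, k)
            inst = make_instruments(bx, 0.01, by, sy)
            ratios = by / bx
            weights = (bx / sy) ** 2
            expected = weighted_median_scan_oracle(ratios, weights)
            got = weighted_median(inst, n_boot=10, seed=1).beta
            assert got == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_se_is_seed_reproducible(self, random_instruments):
        a = weighted_median(random_instruments, n_boot=200, seed=42)
        b = weighted_median(random_instruments, n_boot=200, seed=42)
        assert a.se == b.se


# ---------------------------------------------------------- heterogeneity

class TestHeterogeneity:
    def test_identical_ratios_give_zero(self):
        bx = np.array([0.05, 0.1, 0.2])
        inst = make_instruments(bx, 0.01, 0.5 * bx, 0.01)
        Q, i2 = heterogeneity(inst)
        assert Q == pytest.approx(0.0, abs=1e-20)
        assert i2 == 0.0

    def test_hand_arithmetic_two_instruments(self):
        # ratios 0 and 1 with unit ratio-weights: fixed IVW = 0.5,
        # Q = 1*(0-0.5)^2 + 1*(1-0.5)^2 = 0.5; Q < k-1 so I2 = 0
        inst = make_instruments([1.0, 1.0], 0.01, [0.0, 1.0], 1.0)
        Q, i2 = heterogeneity(inst)
        assert Q == pytest.approx(0.5)
        assert i2 == 0.0

    def test_strong_pleiotropy_inflates_i2_in_most_replicates(self):
        hits = 0
        for s in range(30):
            truth = SyntheticTruth(
                seed=s, n_instruments=60, balanced_pleio_sd=0.02,
                proteins=[ProteinTruth("P", 0.3, 0.0, "balanced")],
            )
            exposure, _, panel = simulate_step1_panel(truth)
            inst = harmonize(exposure, panel[0], list(exposure.df.index))
            _, i2 = heterogeneity(inst)
            hits += i2 > 50.0
        assert hits > 15


# ---------------------------------------------------------------- PRESSO

class TestPresso:
    def test_planted_outlier_flagged_and_corrected(self, rng):
        k = 20
        bx = rng.normal(0.1, 0.02, k)
        sy = np.full(k, 0.005)
        by = 0.3 * bx + rng.normal(0, 0.005, k)
        by[7] += 10 * np.sqrt(0.005**2 + (0.3 * 0.0) ** 2) * 2  # gross outlier
        inst = make_instruments(bx, 0.01, by, sy)
        global_p, flags, corrected = presso(inst, n_sim=500, seed=3)
        assert flags[7]
        assert corrected is not None
        assert corrected.method == "presso_corrected"
        assert global_p < 0.05

    def test_clean_data_reports_no_outliers_and_no_corrected(self, rng):
        k = 20
        bx = rng.normal(0.1, 0.02, k)
        by = 0.3 * bx + rng.normal(0, 0.005, k)
        inst = make_instruments(bx, 0.01, by, 0.005)
        global_p, flags, corrected = presso(inst, n_sim=500, seed=4)
        assert not flags.any()
        assert corrected is None

    def test_global_p_uniform_under_null(self, rng):
        # KS test over repeated null simulations should not reject
        from scipy import stats

        pvals = []
        for s in range(200):
            r = np.random.default_rng(s + 10_000)
            k = 15
            bx = r.normal(0.1, 0.02, k)
            by = 0.3 * bx + r.normal(0, 0.005, k)
            inst = make_instruments(bx, 0.01, by, 0.005)
            gp, _, _ = presso(inst, n_sim=500, seed=s)
            pvals.append(gp)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_instruments(self):
        inst = make_instruments([0.1] * 3, 0.01, [0.05] * 3, 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            presso(inst)


# ---------------------------------------------------------------- Steiger

class TestSteiger:
    def test_exposure_explains_more_variance(self):
        inst = make_instruments([0.5], 0.05, [0.05], 0.05)
        res = steiger(inst, 10_000, 10_000)
        assert res.correct_direction
        assert res.r2_exposure > res.r2_outcome

    def test_equal_r2_boundary(self):
        inst = make_instruments([0.1], 0.01, [0.1], 0.01)
        res = steiger(inst, 5000, 5000)
        assert not res.correct_direction
        assert res.steiger_pval == pytest.approx(1.0)

    def test_small_sample_sizes_rejected(self):
        inst = make_instruments([0.1], 0.01, [0.05], 0.01)
        with pytest.raises(ConfigurationError):
            steiger(inst, 3, 100)


# ----------------------------------------------------- instrument strength

class TestStrength:
    def test_f_and_relative_bias_formulas(self):
        inst = make_instruments([0.1] * 4, 0.01, [0.05] * 4, 0.01)
        res = instrument_strength(inst, phi=1.0)
        assert res.f_statistic == pytest.approx(100.0)
        assert res.relative_bias == pytest.approx(0.01)

    def test_zero_overlap_means_zero_bias(self):
        inst = make_instruments([0.02] * 4, 0.01, [0.05] * 4, 0.01)
        assert instrument_strength(inst, phi=0.0).relative_bias == 0.0

    def test_printed_formula_arithmetic(self):
        assert relative_bias(1.0, 10.0) == pytest.approx(0.1)
        assert relative_bias(0.0, 10.0) == 0.0
        assert relative_bias(0.3, 30.0) == pytest.approx(0.01)

    def test_phi_out_of_range(self):
        with pytest.raises(ConfigurationError):
            relative_bias(1.5, 10.0)


def test_estimate_table_round_trip(random_instruments):
    records = [
        ("bmi", "P1", ivw_random_effects(random_instruments)),
        ("bmi", "P1", egger(random_instruments)),
    ]
    df = estimates_to_frame(records)
    back = estimates_from_frame(df)
    np.testing.assert_equal(back[0][2].to_dict(), records[0][2].to_dict())
    assert back[1][2].egger_intercept == pytest.approx(
        records[1][2].egger_intercept
    )
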
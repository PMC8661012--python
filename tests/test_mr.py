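"""MR estimators: oracle agreement, invariances, calibration, transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bidirmr.errors import (
    HarmonizationError,
    InsufficientInstrumentsError,
    InvalidInputError,
    UnitError,
)
from bidirmr.mr import (
    Z95,
    HarmonizedInstruments,
    harmonize,
    ivw,
    mr_egger,
    ratio_estimates,
    run_all_methods,
    simple_median,
    to_odds_ratio,
    two_stage_least_squares,
    weighted_median,
)

from conftest import make_harmonized
from oracles import weighted_median_walk, wls_through_origin, wls_with_intercept


def table(bx, sx, by, sy):
    return pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(len(bx))],
            "beta_exposure": bx,
            "se_exposure": sx,
            "beta_outcome": by,
            "se_outcome": sy,
        }
    )


def H(bx, sx, by, sy, **kw):
    return HarmonizedInstruments(table(bx, sx, by, sy), **kw)


class TestHarmonize:
    def _instruments(self):
        return pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "beta_exposure": [0.4, -0.3],
                "se_exposure": [0.05, 0.04],
                "effect_allele": ["A", "C"],
            }
        )

    def _outcome(self, alleles=("A", "C")):
        return pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "beta": [0.08, -0.06],
                "se": [0.02, 0.02],
                "effect_allele": alleles,
                "testable": [True, True],
            }
        )

    def test_orientation_flips_pairs_and_preserves_ratios(self):
        h = harmonize(self._instruments(), self._outcome())
        assert (h.table["beta_exposure"] >= 0).all()
        ratios, _ = ratio_estimates(h)
        np.testing.assert_allclose(ratios, [0.2, 0.2], atol=1e-12)

    def test_aligned_input_unchanged(self):
        instr = self._instruments()
        instr.loc[1, "beta_exposure"] = 0.3
        h = harmonize(instr, self._outcome())
        np.testing.assert_allclose(h.table["beta_exposure"], [0.4, 0.3])
        np.testing.assert_allclose(h.table["beta_outcome"], [0.08, -0.06])

    def test_missing_snp_and_allele_mismatch_named(self):
        with pytest.raises(HarmonizationError, match="b"):
            harmonize(self._instruments(), self._outcome().iloc[:1])
        with pytest.raises(HarmonizationError, match="b"):
            harmonize(self._instruments(), self._outcome(alleles=("A", "G")))


class TestRatioEstimates:
    def test_elementwise_quotient_and_delta_se(self):
        h = H([0.5], [0.05], [0.1], [0.02])
        ratios, ses = ratio_estimates(h)
        assert ratios[0] == pytest.approx(0.2, abs=1e-15)
        assert ses[0] == pytest.approx(0.02 / 0.5, abs=1e-15)

    def test_zero_outcome_gives_zero_ratio(self):
        ratios, _ = ratio_estimates(H([0.5], [0.05], [0.0], [0.02]))
        assert ratios[0] == 0.0


class TestIVW:
    def test_single_instrument_collapses_to_ratio(self):
        r = ivw(H([0.5], [0.05], [0.1], [0.02]))
        assert r.estimate == pytest.approx(0.2, abs=1e-15)
        assert r.se == pytest.approx(0.02 / 0.5, abs=1e-15)

    def test_equal_weight_mean(self):
        r = ivw(H([1.0, 1.0], [0.1, 0.1], [0.2, 0.4], [0.05, 0.05]))
        assert r.estimate == pytest.approx(0.3, abs=1e-15)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(25):
            h = make_harmonized(rng, n_instruments=int(rng.integers(2, 9)))
            bx, _, by, sy = h.arrays()
            slope, se = wls_through_origin(bx, by, sy**-2)
            r = ivw(h)
            assert r.estimate == pytest.approx(slope, abs=1e-10)
            assert r.se == pytest.approx(se, abs=1e-10)
            assert r.ci_low == pytest.approx(r.estimate - Z95 * r.se, abs=1e-9)

    def test_random_effects_never_shrinks_se(self, rng):
        h = make_harmonized(rng, n_instruments=8, noise=0.2)
        assert ivw(h, "multiplicative_random").se >= ivw(h).se

    def test_random_effects_single_instrument_falls_back(self):
        with pytest.warns(UserWarning):
            r = ivw(H([0.5], [0.05], [0.1], [0.02]), "multiplicative_random")
        assert r.se == pytest.approx(0.04, abs=1e-12)


class TestMREgger:
    def test_exact_line_recovered_with_floored_se(self):
        bx = np.array([0.2, 0.5, 0.8, 1.1])
        by = 0.1 + 0.3 * bx
        r = mr_egger(H(bx, np.full(4, 0.05), by, np.full(4, 0.02)))
        assert r.intercept == pytest.approx(0.1, abs=1e-12)
        assert r.estimate == pytest.approx(0.3, abs=1e-12)
        # residual variance factor floored at 1: SEs at the fixed-effect level
        _, ses, phi_raw = wls_with_intercept(bx, by, np.full(4, 0.02) ** -2.0)
        assert phi_raw == pytest.approx(0.0, abs=1e-20)
        assert r.se == pytest.approx(ses[1], abs=1e-12)

    def test_through_origin_data_equal_weights_matches_ivw(self, rng):
        bx = rng.uniform(0.2, 1.0, 6)
        by = 0.25 * bx
        sy = np.full(6, 0.03)
        r_egger = mr_egger(H(bx, np.full(6, 0.05), by, sy))
        r_ivw = ivw(H(bx, np.full(6, 0.05), by, sy))
        assert r_egger.intercept == pytest.approx(0.0, abs=1e-12)
        assert r_egger.estimate == pytest.approx(r_ivw.estimate, abs=1e-9)

    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(25):
            h = make_harmonized(rng, n_instruments=6, noise=0.05)
            bx, _, by, sy = h.arrays()
            coef, ses, _ = wls_with_intercept(bx, by, sy**-2)
            r = mr_egger(h)
            assert r.intercept == pytest.approx(coef[0], abs=1e-10)
            assert r.estimate == pytest.approx(coef[1], abs=1e-10)
            assert r.intercept_se == pytest.approx(ses[0], abs=1e-10)
            assert r.se == pytest.approx(ses[1], abs=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(H([0.5, 0.6], [0.05, 0.05], [0.1, 0.1], [0.02, 0.02]))

    def test_null_calibration_under_balanced_pleiotropy_inside(self):
        """Summary-level balanced pleiotropy with InSIDE: the intercept test
        rejects at ~nominal 5% over 2,000 replicates."""
        rng = np.random.default_rng(4242)
        J, theta = 20, 0.2
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            bx_true = rng.uniform(0.2, 1.0, J)
            alpha = rng.normal(0.0, 0.08, J)  # balanced, independent of bx
            sy = np.full(J, 0.03)
            sx = np.full(J, 0.02)
            bx = rng.normal(bx_true, sx)
            by = rng.normal(alpha + theta * bx_true, sy)
            r = mr_egger(H(bx, sx, by, sy))
            rejections += r.intercept_p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08


class TestMedians:
    def test_simple_median_interpolation_example(self):
        # equal weights, ratios {0.1, 0.2, 0.9}: cumulative weights hit 0.5
        # exactly at the middle ratio
        h = H([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.9], [0.05] * 3)
        r = simple_median(h, n_boot=100, seed=0)
        assert r.estimate == pytest.approx(0.2, abs=1e-12)
        assert r.estimate == pytest.approx(
            weighted_median_walk([0.1, 0.2, 0.9], np.ones(3)), abs=1e-12
        )

    def test_degenerate_equal_ratios(self):
        h = H([0.5, 0.8, 1.1], [0.001] * 3, [0.15, 0.24, 0.33], [0.001] * 3)
        r = simple_median(h, n_boot=500, seed=1)
        assert r.estimate == pytest.approx(0.3, abs=1e-12)
        assert r.se < 0.01  # se -> 0 with vanishing summary-statistic noise

    def test_bootstrap_seed_determinism(self, rng):
        h = make_harmonized(rng, n_instruments=5)
        a = weighted_median(h, n_boot=300, seed=77)
        b = weighted_median(h, n_boot=300, seed=77)
        c = weighted_median(h, n_boot=300, seed=78)
        assert a.se == b.se
        assert a.se != c.se

    def test_equal_weights_reduce_weighted_to_simple(self):
        bx = np.full(5, 0.8)
        sy = np.full(5, 0.04)
        h = H(bx, np.full(5, 0.01), np.array([0.1, 0.3, 0.2, 0.25, 0.18]), sy)
        ws = weighted_median(h, n_boot=10, seed=0)
        ss = simple_median(h, n_boot=10, seed=0)
        assert ws.estimate == pytest.approx(ss.estimate, abs=1e-12)

    def test_weighted_median_hand_walk_with_dominant_outlier(self):
        bx = np.array([1.0, 1.0, 1.0, 2.0])
        sy = np.array([0.05, 0.05, 0.05, 0.02])  # last SNP carries most weight
        by = np.array([0.20, 0.21, 0.19, 1.0])   # outlying ratio 0.5
        h = H(bx, np.full(4, 0.01), by, sy)
        r = weighted_median(h, n_boot=10, seed=0)
        expected = weighted_median_walk(by / bx, bx**2 / sy**2)
        assert r.estimate == pytest.approx(expected, abs=1e-12)
        # pulled toward, but bounded by, the neighbouring order statistics
        assert 0.21 <= r.estimate <= 0.5

    def test_breakdown_two_of_five_invalid(self, rng):
        """With <50% invalid weight the weighted median tracks the valid
        consensus while IVW is displaced."""
        bx = np.full(5, 1.0)
        sy = np.full(5, 0.02)
        by = np.array([0.2, 0.2, 0.2, 0.8, 0.9])  # 2 pleiotropic offsets
        h = H(bx, np.full(5, 0.01), by, sy)
        wm = weighted_median(h, n_boot=400, seed=3)
        iv = ivw(h)
        assert abs(wm.estimate - 0.2) < 3 * wm.se
        assert abs(iv.estimate - 0.2) > abs(wm.estimate - 0.2)


class TestInvariances:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_equivariance(self, seed):
        """Multiplying all exposure effects by c divides every estimate by c."""
        rng = np.random.default_rng(seed)
        h = make_harmonized(rng, n_instruments=6)
        c = float(rng.uniform(0.5, 4.0))
        t = h.table.copy()
        t["beta_exposure"] *= c
        t["se_exposure"] *= c
        h2 = HarmonizedInstruments(t)
        assert ivw(h2).estimate * c == pytest.approx(ivw(h).estimate, rel=1e-12)
        assert mr_egger(h2).estimate * c == pytest.approx(
            mr_egger(h).estimate, rel=1e-12
        )
        wm1 = weighted_median(h, n_boot=50, seed=1).estimate
        wm2 = weighted_median(h2, n_boot=50, seed=1).estimate
        assert wm2 * c == pytest.approx(wm1, rel=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_orientation_invariance(self, seed):
        """Flipping the sign of any (bX, bY) pair changes nothing."""
        rng = np.random.default_rng(seed)
        h = make_harmonized(rng, n_instruments=6)
        t = h.table.copy()
        j = int(rng.integers(6))
        t.loc[j, ["beta_exposure", "beta_outcome"]] *= -1
        h2 = HarmonizedInstruments(t)
        assert ivw(h2).estimate == pytest.approx(ivw(h).estimate, rel=1e-12)
        assert mr_egger(h2).estimate == pytest.approx(
            mr_egger(h).estimate, rel=1e-12
        )
        assert simple_median(h2, 50, seed=2).estimate == pytest.approx(
            simple_median(h, 50, seed=2).estimate, rel=1e-12
        )


class TestOddsRatioAndRunAll:
    def test_zero_maps_to_unit_or(self):
        h = H([1.0], [0.1], [0.0], [0.05], outcome_binary=True)
        or_, (lo, hi) = to_odds_ratio(ivw(h))
        assert or_ == pytest.approx(1.0, abs=1e-12)
        assert lo < 1.0 < hi

    def test_log_odds_exponentiation(self):
        r = ivw(H([1.0], [0.01], [0.134], [0.009], outcome_binary=True))
        or_, (lo, hi) = to_odds_ratio(r)
        assert or_ == pytest.approx(np.exp(0.134), abs=1e-9)
        assert lo == pytest.approx(np.exp(0.134 - Z95 * 0.009), abs=1e-9)
        assert hi == pytest.approx(np.exp(0.134 + Z95 * 0.009), abs=1e-9)
        assert lo < hi

    def test_continuous_outcome_rejected(self):
        r = ivw(H([1.0], [0.1], [0.1], [0.05], outcome_binary=False))
        with pytest.raises(UnitError):
            to_odds_ratio(r)

    def test_run_all_methods_consistent_on_clean_fixture(self, rng):
        h = make_harmonized(rng, n_instruments=8, theta=0.3, noise=0.005)
        out = run_all_methods(h, seed=5, n_boot=300)
        estimates = [out[m].estimate for m in ("ivw", "simple_median", "weighted_median", "mr_egger")]
        assert np.ptp(estimates) < 0.05
        assert out["mr_egger"].intercept_p > 0.05

    def test_run_all_methods_deterministic_and_partial(self, rng):
        h = make_harmonized(rng, n_instruments=6)
        a = run_all_methods(h, seed=9, n_boot=200)
        b = run_all_methods(h, seed=9, n_boot=200)
        assert a["weighted_median"].se == b["weighted_median"].se
        small = HarmonizedInstruments(h.table.iloc[:2])
        out = run_all_methods(small, seed=9, n_boot=50)
        assert out["ivw"] is not None
        assert out["mr_egger"] is None
        assert "needs >= 3" in out["mr_egger_error"] or "instruments" in out["mr_egger_error"]

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            run_all_methods(make_harmonized(rng), methods=("ivw", "mode"))


class TestTwoStageLeastSquares:
    def test_recovers_effect_with_confounding(self, rng):
        n = 20_000
        g = rng.binomial(2, 0.3, (n, 3)).astype(float)
        u = rng.normal(size=n)
        x = g @ [0.5, 0.4, 0.6] + u + rng.normal(size=n)
        y = 0.25 * x + 1.5 * u + rng.normal(size=n)
        est, se = two_stage_least_squares(g, x, y)
        assert est == pytest.approx(0.25, abs=3.5 * se)
        # OLS, by contrast, is confounded upward
        ols = np.cov(x, y)[0, 1] / np.var(x)
        assert ols - 0.25 > 5 * se
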
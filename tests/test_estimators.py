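"""The five MR estimators, Wald ratios and odds-ratio conversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from twostepmr import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    InverseVarianceWeighted,
    egger,
    ivw,
    mode_estimator,
    run_all_methods,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from conftest import make_harmonized


class TestWaldRatio:
    @pytest.mark.parametrize(
        "b_x, s_x, b_y, s_y, beta, se",
        [
            (0.10, 0.01, 0.05, 0.01, 0.5, 0.1),
            (0.10, 0.01, 0.0, 0.01, 0.0, 0.1),
            (-0.20, 0.01, 0.06, 0.02, -0.3, 0.1),
        ],
    )
    def test_ratio_and_first_order_se(self, b_x, s_x, b_y, s_y, beta, se):
        est = wald_ratio(b_x, s_x, b_y, s_y)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_beta_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIVW:
    def test_consensus_ratios(self, consensus_h):
        assert ivw(consensus_h).beta == pytest.approx(0.5)

    def test_closed_form_weighted_least_squares(self):
        # sum(w bx by) = 60 + 40, sum(w bx^2) = 100 + 100 -> beta = 0.5
        h = make_harmonized([0.1, 0.2], [0.06, 0.08], [0.01, 0.02])
        est = ivw(h, effects_model="fixed")
        assert est.beta == pytest.approx(100.0 / 200.0)
        assert est.se == pytest.approx(1.0 / np.sqrt(200.0))

    def test_single_snp_falls_back_to_wald(self):
        h = make_harmonized([0.1], [0.05], [0.01])
        est = ivw(h)
        ref = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_matches_weighted_mean_of_ratios(self):
        """Algebraic identity: fixed-effects IVW equals the weighted mean of
        Wald ratios with weights b_x^2/s_y^2."""
        rng = np.random.default_rng(1)
        bx = rng.normal(0.2, 0.05, 10)
        by = rng.normal(0.06, 0.02, 10)
        sy = rng.uniform(0.01, 0.03, 10)
        h = make_harmonized(bx, by, sy)
        w = bx**2 / sy**2
        expected = np.sum(w * by / bx) / np.sum(w)
        assert ivw(h, effects_model="fixed").beta == pytest.approx(expected)

    def test_random_effects_inflate_se_only_when_overdispersed(self, consensus_h):
        assert ivw(consensus_h).se == pytest.approx(
            ivw(consensus_h, effects_model="fixed").se
        )
        noisy = make_harmonized([0.1, 0.2, 0.3], [0.09, 0.02, 0.21], [0.005, 0.005, 0.005])
        assert ivw(noisy).se > ivw(noisy, effects_model="fixed").se


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.01 + 0.2 * bx, np.full(4, 0.05))
        est = egger(h)
        assert est.beta == pytest.approx(0.2)
        assert est.intercept == pytest.approx(0.01)

    def test_zero_outcomes_give_zero_fit(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [0.01, 0.01, 0.01])
        est = egger(h)
        assert est.beta == pytest.approx(0.0)
        assert est.intercept == pytest.approx(0.0)

    def test_orientation_invariant_to_exposure_sign(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.3 * bx
        h1 = make_harmonized(bx, by, np.full(4, 0.02))
        h2 = make_harmonized(np.abs(bx), 0.3 * np.abs(bx), np.full(4, 0.02))
        assert egger(h1).beta == pytest.approx(egger(h2).beta)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_intercept_unbiased_without_pleiotropy(self):
        """Zero-intercept generating model: the mean estimated intercept over
        replicates stays within 3 Monte-Carlo SEs of zero."""
        rng = np.random.default_rng(11)
        intercepts = []
        for _ in range(300):
            bx = rng.normal(0.2, 0.05, 20)
            sy = np.full(20, 0.01)
            by = 0.3 * bx + rng.normal(0, sy)
            intercepts.append(egger(make_harmonized(bx, by, sy)).intercept)
        intercepts = np.array(intercepts)
        mcse = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(intercepts.mean()) < 3 * mcse


class TestWeightedMedian:
    def test_equal_weight_median(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.05, 0.05, 0.05])
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.2)

    def test_dominant_weight_wins(self):
        # middle ratio carries 90% of the weight: crossing lands exactly there
        h = make_harmonized(
            [1.0, 1.0, 1.0], [0.1, 0.5, 0.9], [np.sqrt(1 / 0.05), np.sqrt(1 / 0.9), np.sqrt(1 / 0.05)]
        )
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.5)

    def test_interpolated_crossing_matches_enumeration(self):
        """Hand-enumerated cumulative weights: ratios (.1,.2,.3,.4) with
        weights (1,2,3,4) cross 0.5 between .3 and .4 at 0.3142857..."""
        sy = 1.0 / np.sqrt([1.0, 2.0, 3.0, 4.0])
        h = make_harmonized([1.0] * 4, [0.1, 0.2, 0.3, 0.4], sy)
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.3 + 0.1 * (0.05 / 0.35))

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_harmonized([0.1], [0.05], [0.01]))

    def test_bootstrap_se_deterministic_given_seed(self, consensus_h):
        a = weighted_median(consensus_h, n_boot=200, seed=5)
        b = weighted_median(consensus_h, n_boot=200, seed=5)
        assert a.se == b.se


class TestModeBased:
    def test_dominant_cluster_simple_mode(self):
        h = make_harmonized([1.0] * 4, [0.2, 0.2, 0.2, 0.9], [0.05] * 4)
        assert mode_estimator(h, variant="simple", n_boot=10, seed=0).beta == pytest.approx(0.2)

    def test_identical_ratios_zero_bootstrap_se(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.3, 0.3, 0.3], [0.0, 0.0, 0.0],
                            sx=[0.0, 0.0, 0.0])
        est = mode_estimator(h, variant="simple", n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.0)

    def test_weighted_mode_tracks_heavier_cluster(self):
        """Bimodal ratios: the heavier-weighted cluster near 0.4 wins; the
        point estimate agrees with a fine-grid density-maximization oracle."""
        ratios = np.array([0.38, 0.40, 0.42, 0.9, 0.92])
        sy = np.array([0.02, 0.02, 0.02, 0.2, 0.2])  # ratio SEs (bx = 1)
        h = make_harmonized([1.0] * 5, ratios, sy)
        est = mode_estimator(h, variant="weighted", n_boot=10, seed=0)
        assert 0.35 < est.beta < 0.45

        # independent oracle: brute-force weighted KDE over a dense grid
        from scipy.stats import median_abs_deviation

        w = 1.0 / sy**2
        bw = 0.9 * min(np.std(ratios, ddof=1), median_abs_deviation(ratios, scale="normal"))
        bw *= len(ratios) ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 20001)
        dens = np.zeros_like(grid)
        for r, wi in zip(ratios, w):
            dens += wi * np.exp(-0.5 * ((grid - r) / bw) ** 2)
        oracle = grid[np.argmax(dens)]
        assert est.beta == pytest.approx(oracle, abs=2 * (grid[-1] - grid[0]) / 511)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mode_estimator(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


class TestOddsRatio:
    def test_zero_beta_is_unit_or(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.0)
        assert (or_, lo, hi) == (1.0, 1.0, 1.0)

    def test_published_conversions(self):
        # printed IVW beta 0.152 vs OR 1.1646 (rounding of the printed beta)
        assert to_odds_ratio(0.152, 0.0)[0] == pytest.approx(1.1646, rel=5e-4)
        # printed total-effect OR 0.9053 back from its log
        assert to_odds_ratio(-0.0995, 0.0)[0] == pytest.approx(0.9053, rel=5e-4)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, -0.01)


class TestRunAllMethods:
    def test_consensus_all_five_agree(self, consensus_h):
        bundle = run_all_methods(consensus_h)
        assert bundle.complete
        for est in bundle.estimates.values():
            assert est.beta == pytest.approx(0.5)

    def test_outlier_robustness_ordering(self):
        """A single gross outlier pulls IVW further from the clean ratio than
        the median and mode estimates."""
        bx = np.linspace(0.15, 0.33, 10)
        by = 0.5 * bx
        by[0] = 0.5 * bx[0] + 0.5  # one contaminated instrument
        h = make_harmonized(bx, by, np.full(10, 0.01))
        bundle = run_all_methods(h)
        err = {k: abs(v.beta - 0.5) for k, v in bundle.estimates.items()}
        assert err["weighted_median"] < err["ivw"]
        assert err["weighted_mode"] < err["ivw"]
        assert err["simple_mode"] < err["ivw"]

    def test_two_snps_degrade_to_ivw_only(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        bundle = run_all_methods(h)
        assert bundle.ivw is not None
        assert bundle.egger is None and bundle.weighted_median is None
        assert not bundle.complete
        assert bundle.notes

    def test_results_table_columns(self, consensus_h):
        df = run_all_methods(consensus_h).to_frame()
        assert list(df.columns) == [
            "method", "n_snp", "beta", "se", "ci_low", "ci_high",
            "pval", "or_", "or_low", "or_high",
        ]
        assert len(df) == 5


class TestScaleEquivariance:
    @given(c=hst.floats(0.2, 5.0))
    def test_rescaling_exposure_rescales_estimates(self, c):
        bx = np.array([0.1, 0.15, 0.2, 0.3, 0.25])
        by = np.array([0.06, 0.05, 0.11, 0.14, 0.12])
        sy = np.array([0.01, 0.02, 0.01, 0.02, 0.015])
        h1 = make_harmonized(bx, by, sy)
        h2 = make_harmonized(c * bx, by, sy)
        assert ivw(h2).beta == pytest.approx(ivw(h1).beta / c)
        assert egger(h2).beta == pytest.approx(egger(h1).beta / c)
        m1 = weighted_median(h1, n_boot=2, seed=0).beta
        m2 = weighted_median(h2, n_boot=2, seed=0).beta
        assert m2 == pytest.approx(m1 / c)

    def test_sklearn_estimator_interface(self, consensus_h):
        est = InverseVarianceWeighted(effects_model="fixed")
        assert est.get_params() == {"effects_model": "fixed"}
        est.set_params(effects_model="multiplicative_random")
        est.fit(consensus_h)
        assert est.beta_ == pytest.approx(0.5)
        assert est.n_snp_ == 5
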
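"""Summary-data MR estimators: exact oracles, robustness properties,
pleiotropy diagnostics, meta-analysis, bidirectional analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecgmr
from ecgmr import summary_mr

from _oracles import ivw_via_normal_equations, weighted_median_walk
from conftest import make_pair


class TestWaldRatio:
    def test_arithmetic(self):
        est = ecgmr.wald_ratio(make_pair(beta_x=2.0, beta_y=1.0, se_y=0.2))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        assert ecgmr.wald_ratio(make_pair(beta_y=0.0)).beta == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            ecgmr.wald_ratio(make_pair(beta_x=0.0))


class TestIVW:
    def test_duplicated_pair_collapses_to_wald_ratio(self):
        pair = make_pair(beta_x=1.5, beta_y=0.3, se_y=0.1)
        pairs = [make_pair(vid=f"v{i}", beta_x=1.5, beta_y=0.3, se_y=0.1) for i in range(6)]
        est = ecgmr.ivw(pairs)
        assert est.beta == pytest.approx(ecgmr.wald_ratio(pair).beta, abs=1e-14)

    def test_matches_normal_equations_on_toy_pairs(self):
        bx, by, sy = [1.0, 2.0, 0.5], [0.05, 0.12, 0.02], [0.02, 0.05, 0.01]
        pairs = [make_pair(vid=f"v{i}", beta_x=x, beta_y=y, se_y=s)
                 for i, (x, y, s) in enumerate(zip(bx, by, sy))]
        est = ecgmr.ivw(pairs)
        beta_o, se_o = ivw_via_normal_equations(bx, by, sy)
        assert est.beta == pytest.approx(beta_o, abs=1e-14)
        assert est.se == pytest.approx(se_o, abs=1e-14)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(71)
        for trial in range(20):
            J = int(rng.integers(3, 30))
            pairs = [
                make_pair(vid=f"v{j}", beta_x=float(rng.uniform(0.5, 2)),
                          beta_y=float(rng.normal(0, 0.2)),
                          se_y=float(rng.uniform(0.01, 0.1)))
                for j in range(J)
            ]
            fixed = ecgmr.ivw(pairs, "fixed")
            random = ecgmr.ivw(pairs, "random")
            assert random.se >= fixed.se
            assert random.beta == pytest.approx(fixed.beta)
            assert fixed.q_df == J - 1

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            ecgmr.ivw([make_pair()])


class TestEgger:
    def test_exact_interpolation_of_linear_configuration(self):
        b0, b1 = 0.02, -0.01
        pairs = [
            make_pair(vid=f"v{j}", beta_x=x, beta_y=b0 + b1 * x, se_y=0.05)
            for j, x in enumerate([0.5, 1.0, 1.5, 2.0])
        ]
        slope, intercept = ecgmr.mr_egger(pairs)
        assert slope.beta == pytest.approx(b1, abs=1e-12)
        assert intercept.beta == pytest.approx(b0, abs=1e-12)

    def test_zero_intercept_regression_reproduces_ivw(self):
        """Weighted through-origin fit equals fixed-effects IVW exactly."""
        rng = np.random.default_rng(72)
        pairs = [
            make_pair(vid=f"v{j}", beta_x=float(rng.uniform(0.5, 2)),
                      beta_y=float(rng.normal(-0.05, 0.1)),
                      se_y=float(rng.uniform(0.02, 0.1)))
            for j in range(12)
        ]
        bx = np.array([p.beta_exposure for p in pairs])
        by = np.array([p.beta_outcome for p in pairs])
        w = np.array([1 / p.se_outcome**2 for p in pairs])
        # constrained (zero-intercept) weighted LS solved directly
        beta_constrained = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert ecgmr.ivw(pairs).beta == pytest.approx(beta_constrained, abs=1e-14)

    def test_directional_pleiotropy_recovered(self):
        """Intercept estimates the common direct effect, slope the causal one."""
        causal, direct = -0.012, 0.02
        reps, intercepts, slopes = 60, [], []
        for r in range(reps):
            pairs = ecgmr.simulate_summary_pairs(
                n_variants=30, causal_beta=causal, seed=500 + r,
                pleiotropy=np.full(30, direct),
            )
            s, i = ecgmr.mr_egger(pairs)
            slopes.append(s.beta)
            intercepts.append(i.beta)
        mc_se_i = np.std(intercepts) / np.sqrt(reps)
        mc_se_s = np.std(slopes) / np.sqrt(reps)
        assert np.mean(intercepts) == pytest.approx(direct, abs=2 * mc_se_i)
        assert np.mean(slopes) == pytest.approx(causal, abs=2 * mc_se_s)

    def test_no_spread_in_exposure_rejected(self):
        pairs = [make_pair(vid=f"v{j}", beta_x=1.0) for j in range(4)]
        with pytest.raises(ValueError, match="spread"):
            ecgmr.mr_egger(pairs)

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            ecgmr.mr_egger([make_pair(vid="a"), make_pair(vid="b")])


class TestWeightedMedian:
    def test_equal_ratios_return_that_value(self):
        pairs = [make_pair(vid=f"v{j}", beta_x=x, beta_y=0.25 * x, se_y=0.1)
                 for j, x in enumerate([0.5, 1.0, 2.0])]
        est = ecgmr.weighted_median(pairs, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.25)

    def test_matches_cumulative_weight_walk(self):
        rng = np.random.default_rng(73)
        for trial in range(30):
            J = int(rng.integers(2, 11))
            bx = rng.uniform(0.5, 2.0, J)
            by = rng.normal(0, 0.3, J)
            sy = rng.uniform(0.02, 0.2, J)
            pairs = [make_pair(vid=f"v{j}", beta_x=float(bx[j]),
                               beta_y=float(by[j]), se_y=float(sy[j]))
                     for j in range(J)]
            est = ecgmr.weighted_median(pairs, n_boot=100, seed=trial)
            oracle = weighted_median_walk(by / bx, bx**2 / sy**2)
            assert est.beta == pytest.approx(oracle, abs=1e-12)

    def test_robust_to_forty_percent_invalid_instruments(self):
        """Median stays near truth while IVW is dragged by invalid variants.

        With 40% of variants carrying a large positive direct effect the
        weighted median keeps a small residual offset (it sits at an upper
        quantile of the valid cluster, an offset proportional to the ratio
        noise) while fixed-effects IVW absorbs the pleiotropy directly, so
        the IVW bias must dominate the median bias by an order of magnitude.
        """
        causal = -0.012
        J, n_bad = 20, 8
        delta = np.zeros(J)
        delta[:n_bad] = 0.08  # large positive direct effects
        med, ivw_est = [], []
        for r in range(60):
            # near-equal instrument strengths keep the invalid weight share at ~40%
            pairs = ecgmr.simulate_summary_pairs(
                n_variants=J, causal_beta=causal, seed=900 + r, pleiotropy=delta,
                mean_beta_x=1.0, sd_beta_x=0.05, se_y=0.005,
            )
            med.append(ecgmr.weighted_median(pairs, n_boot=100, seed=r).beta)
            ivw_est.append(ecgmr.ivw(pairs).beta)
        med_bias = np.mean(med) - causal
        ivw_bias = np.mean(ivw_est) - causal
        assert ivw_bias > 0.02  # pulled far toward the planted positive pleiotropy
        assert abs(med_bias) < 0.005
        assert abs(med_bias) < abs(ivw_bias) / 4


class TestWeightedMode:
    def test_tight_cluster_returns_center(self):
        pairs = [make_pair(vid=f"v{j}", beta_x=1.0, beta_y=0.1 + 1e-4 * j, se_y=0.05)
                 for j in range(5)]
        est = ecgmr.weighted_mode(pairs, n_boot=100, seed=2)
        assert est.beta == pytest.approx(0.1, abs=0.01)

    def test_bimodal_majority_cluster_wins(self):
        """60% of weight at ratio 0.1, 40% at 0.5: the mode sits near 0.1."""
        rng = np.random.default_rng(74)
        pairs = []
        for j in range(12):
            ratio = 0.1 if j < 7 else 0.5
            pairs.append(make_pair(
                vid=f"v{j}", beta_x=1.0,
                beta_y=float(ratio + rng.normal(0, 0.005)), se_y=0.05,
            ))
        est = ecgmr.weighted_mode(pairs, n_boot=100, seed=3)
        assert est.beta == pytest.approx(0.1, abs=0.05)

    def test_bandwidth_sweep_reported(self):
        pairs = [make_pair(vid=f"v{j}", beta_x=1.0 + 0.1 * j,
                           beta_y=0.02 * j, se_y=0.05) for j in range(6)]
        est = ecgmr.weighted_mode(pairs, n_boot=100, seed=4)
        sweep = est.notes["bandwidth_sweep"]
        assert set(sweep) == {"bandwidth_factor=0.5", "bandwidth_factor=1",
                              "bandwidth_factor=2"}

    def test_invalid_bandwidth_rejected(self):
        pairs = [make_pair(vid="a"), make_pair(vid="b", beta_y=0.6)]
        with pytest.raises(ValueError):
            ecgmr.weighted_mode(pairs, bandwidth_factor=0.0)


class TestRangeInvariants:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_median_and_mode_lie_within_ratio_range(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(3, 15))
        pairs = [
            make_pair(vid=f"v{j}", beta_x=float(rng.uniform(0.3, 2.5)),
                      beta_y=float(rng.normal(0, 0.3)),
                      se_y=float(rng.uniform(0.02, 0.2)))
            for j in range(J)
        ]
        ratios = [p.beta_outcome / p.beta_exposure for p in pairs]
        med = ecgmr.weighted_median(pairs, n_boot=100, seed=seed).beta
        mode = ecgmr.weighted_mode(pairs, n_boot=100, seed=seed).beta
        lo, hi = min(ratios), max(ratios)
        assert lo - 1e-9 <= med <= hi + 1e-9
        span = hi - lo
        assert lo - span <= mode <= hi + span  # kernel may peak slightly outside


class TestPresso:
    def _pairs_with_outlier(self, seed, J=20, direct=0.2):
        delta = np.zeros(J)
        delta[0] = direct  # one planted pleiotropic outlier
        return ecgmr.simulate_summary_pairs(
            n_variants=J, causal_beta=-0.012, seed=seed, pleiotropy=delta,
        )

    def test_planted_outlier_flagged_and_estimate_corrected(self):
        """The positive-pleiotropy variant is flagged; exclusion shifts the
        estimate downward and the corrected value recovers the truth."""
        flagged, shifts, errors = 0, [], []
        for r in range(10):
            rep = ecgmr.mr_presso(self._pairs_with_outlier(80 + r), n_sim=1000, seed=r)
            flagged += bool(rep.outlier_flags[0])
            assert rep.global_p < 0.05
            assert rep.corrected is not None
            assert rep.distortion_p is not None
            shifts.append(rep.corrected.beta - rep.original.beta)
            errors.append(rep.corrected.beta + 0.012)
        assert flagged >= 9
        assert np.mean(shifts) < 0  # removing upward pleiotropy lowers the estimate
        assert abs(np.mean(errors)) < 3 * np.std(errors) / np.sqrt(10) + 0.003

    def test_clean_data_rarely_rejects(self):
        rejections = 0
        for r in range(40):
            pairs = ecgmr.simulate_summary_pairs(n_variants=15, causal_beta=-0.012,
                                                 seed=2000 + r)
            rep = ecgmr.mr_presso(pairs, n_sim=500, seed=r)
            rejections += rep.global_p < 0.05
        assert rejections <= 8  # ~5% nominal; generous binomial bound at 40 reps

    def test_bit_reproducible_under_fixed_seed(self):
        pairs = self._pairs_with_outlier(82)
        a = ecgmr.mr_presso(pairs, n_sim=500, seed=9)
        b = ecgmr.mr_presso(pairs, n_sim=500, seed=9)
        assert a.global_p == b.global_p
        assert np.array_equal(a.outlier_p, b.outlier_p)
        assert a.distortion_p == b.distortion_p

    def test_too_few_variants_rejected(self):
        pairs = [make_pair(vid=f"v{j}") for j in range(3)]
        with pytest.raises(ValueError):
            ecgmr.mr_presso(pairs)


class TestMeta:
    def _est(self, b, s, scale="per-ms"):
        return summary_mr._wrap("ivw_fixed", b, s, 5, scale=scale)

    def test_identical_inputs_pool_to_se_over_sqrt_two(self):
        pooled = ecgmr.meta_fixed([self._est(0.1, 0.02), self._est(0.1, 0.02)])
        assert pooled.beta == pytest.approx(0.1)
        assert pooled.se == pytest.approx(0.02 / np.sqrt(2))

    def test_direct_inverse_variance_arithmetic(self):
        pooled = ecgmr.meta_fixed([self._est(-0.06, 0.01), self._est(-0.05, 0.02)])
        assert pooled.beta == pytest.approx(-0.058, abs=5e-4)
        assert pooled.se == pytest.approx(0.00894, abs=5e-5)

    @settings(max_examples=40, deadline=None)
    @given(
        b1=st.floats(-1, 1), b2=st.floats(-1, 1),
        s1=st.floats(0.01, 1), s2=st.floats(0.01, 1),
    )
    def test_pooled_estimate_between_inputs(self, b1, b2, s1, s2):
        pooled = ecgmr.meta_fixed([self._est(b1, s1), self._est(b2, s2)])
        assert min(b1, b2) - 1e-12 <= pooled.beta <= max(b1, b2) + 1e-12

    def test_mixed_scales_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            ecgmr.meta_fixed([self._est(0.1, 0.02), self._est(0.5, 0.1, "per-5ms")])


class TestBidirectional:
    def test_null_reverse_direction_estimates_zero(self):
        estimates = []
        for r in range(40):
            pairs = ecgmr.simulate_summary_pairs(
                n_variants=20, causal_beta=0.0, seed=3000 + r,
                mean_beta_x=0.1, sd_beta_x=0.03, se_x=0.005, se_y=0.05,
            )
            estimates.append(ecgmr.bidirectional_mr(pairs).beta)
        mc_se = np.std(estimates) / np.sqrt(len(estimates))
        assert np.mean(estimates) == pytest.approx(0.0, abs=2 * mc_se + 1e-4)

    def test_both_directions_recovered_and_ratio_reported(self):
        forward = summary_mr._wrap("ivw_fixed", -0.012, 0.002, 50)
        reverse_truth = -0.012 / 50  # a reverse effect 1/50th of the forward one
        estimates = []
        for r in range(40):
            pairs = ecgmr.simulate_summary_pairs(
                n_variants=25, causal_beta=reverse_truth, seed=4000 + r,
                mean_beta_x=1.0, sd_beta_x=0.3, se_x=0.01, se_y=0.002,
            )
            est = ecgmr.bidirectional_mr(pairs, forward_estimate=forward)
            estimates.append(est.beta)
        mc_se = np.std(estimates) / np.sqrt(len(estimates))
        assert np.mean(estimates) == pytest.approx(reverse_truth, abs=2 * mc_se)
        assert "reverse_to_forward_ratio" in est.notes


def test_funnel_table_fields(pr_pairs):
    table = ecgmr.funnel_table(pr_pairs)
    assert set(table.dtype.names) == {"variant_id", "ratio", "precision"}
    assert (table["precision"] > 0).all()
    assert len(table) == len(pr_pairs)


def test_scale_mr_per_5ms_roundtrip():
    est = summary_mr._wrap("ivw_fixed", np.log(0.94) / 5.0, 0.001, 10)
    scaled = ecgmr.scale_mr_per_5ms(est)
    assert scaled.odds_ratio == pytest.approx(0.94)
    with pytest.raises(ValueError):
        ecgmr.scale_mr_per_5ms(scaled)
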
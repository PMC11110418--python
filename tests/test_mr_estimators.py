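import itertools
import math

import numpy as np
import pytest
import statsmodels.api as sm
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from mrtriage.instruments import harmonize
from mrtriage.mr_estimators import (
    InsufficientInstrumentsError, MREstimate,
    beta_to_or, bh_fdr, choose_estimate, egger, ivw, mr_presso, mr_raps,
    wald_ratio, weighted_median, _wmedian_point,
)
from mrtriage.synthetic_data import SimulationConfig, simulate_instruments

from conftest import make_instruments


class TestWaldRatio:
    def test_arithmetic(self):
        inst = make_instruments([0.5], [0.25], [0.05])[0]
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_identity_instrument(self):
        inst = make_instruments([1.0], [0.37], [0.05])[0]
        assert wald_ratio(inst).beta == pytest.approx(0.37)

    def test_zero_bx_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(make_instruments([0.0], [0.1], [0.05])[0])

    def test_first_vs_second_order_se_close_for_strong_instruments(self, rng):
        # when sx/|bx| < 0.1 the two delta-method orders agree within 10%
        for _ in range(50):
            bx = rng.uniform(0.5, 1.0)
            sx = rng.uniform(0.0, 0.05) * bx
            by, sy = 0.3 * bx, rng.uniform(0.05, 0.1)
            inst = make_instruments([bx], [by], [sy], sx=[sx])[0]
            s1 = wald_ratio(inst).se
            s2 = wald_ratio(inst, second_order=True).se
            assert abs(s2 - s1) / s1 < 0.10


class TestIvw:
    def test_hand_computed_two_instrument_case(self):
        instr = make_instruments([1.0, 1.0], [0.4, 0.6], [0.1, 0.1])
        est = ivw(instr)
        assert est.beta == pytest.approx(0.5)
        assert est.q_stat == pytest.approx(2.0)
        # overdispersion scaling: (1/sqrt(200)) * sqrt(Q/1)
        assert est.se == pytest.approx(0.1)
        assert ivw(instr, scale_overdispersion=False).se == pytest.approx(1 / math.sqrt(200))

    def test_identical_instruments_zero_q(self):
        instr = make_instruments([1.0] * 3, [0.5] * 3, [0.1] * 3)
        est = ivw(instr)
        assert est.beta == pytest.approx(0.5)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_single_instrument_policy_falls_back_to_wald(self):
        instr = make_instruments([0.5], [0.25], [0.05])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(instr)
        est = choose_estimate({"wald_ratio": wald_ratio(instr[0])})
        assert est.beta == pytest.approx(0.5)
        assert est.selection_reason == "single_instrument_wald"


class TestEgger:
    def test_collinear_points(self):
        instr = make_instruments([1, 2, 3], [1, 2, 3], [0.1] * 3)
        est = egger(instr)
        assert est.beta == pytest.approx(1.0)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_against_statsmodels_wls(self, rng):
        bx = rng.uniform(0.2, 2.0, 5)
        by = rng.normal(0.4 * bx + 0.03, 0.05)
        sy = rng.uniform(0.03, 0.2, 5)
        est = egger(make_instruments(bx, by, sy))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], rel=1e-10)

    def test_orientation_invariance(self, rng):
        # flipping (bx, by) of any instrument leaves the fit unchanged
        bx = rng.uniform(0.2, 2.0, 6)
        by = rng.normal(0.4 * bx, 0.05)
        sy = rng.uniform(0.03, 0.2, 6)
        e1 = egger(make_instruments(bx, by, sy))
        bx[2], by[2] = -bx[2], -by[2]
        e2 = egger(make_instruments(bx, by, sy))
        assert e1.beta == pytest.approx(e2.beta)
        assert e1.egger_intercept == pytest.approx(e2.egger_intercept)

    def test_slope_equals_ivw_with_intercept_constrained(self, rng):
        bx = rng.uniform(0.2, 2.0, 6)
        by = rng.normal(0.4 * bx, 0.05)
        sy = rng.uniform(0.03, 0.2, 6)
        instr = make_instruments(bx, by, sy)
        fit0 = sm.WLS(by, bx, weights=1 / sy**2).fit()  # intercept fixed at 0
        assert ivw(instr).beta == pytest.approx(fit0.params[0], rel=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_instruments([1, 2], [1, 2], [0.1, 0.1]))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        instr = make_instruments([1, 1, 1], [0.1, 0.2, 0.3], [0.1] * 3)
        est = weighted_median(instr, n_boot=0)
        assert est.beta == pytest.approx(0.2)

    def test_bootstrap_se_is_deterministic_per_seed(self):
        instr = make_instruments([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.25],
                                 [0.1] * 4, sx=[0.01] * 4)
        a = weighted_median(instr, n_boot=200, seed=42)
        b = weighted_median(instr, n_boot=200, seed=42)
        c = weighted_median(instr, n_boot=200, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_duplication_with_half_weight_stays_within_ratio_gap(self, rng):
        # splitting an instrument into two half-weight copies moves the
        # interpolated median by less than one adjacent-ratio gap
        for _ in range(50):
            bx = rng.uniform(0.5, 2.0, 7)
            by = rng.normal(0.5 * bx, 0.1)
            sy = rng.uniform(0.05, 0.2, 7)
            m0 = _wmedian_point(bx, by, sy)
            j = rng.integers(0, 7)
            bx2, by2, sy2 = (np.append(a, a[j]) for a in (bx, by, sy))
            sy2[j] *= math.sqrt(2)
            sy2[-1] *= math.sqrt(2)
            m1 = _wmedian_point(bx2, by2, sy2)
            gap = np.max(np.diff(np.sort(by / bx)))
            assert abs(m0 - m1) <= gap


class TestMrPresso:
    def _shifted(self, seed=0, shift=10.0):
        exp, out, _ = simulate_instruments(SimulationConfig(
            theta=0.3, n_instruments=20, seed=seed))
        harm, _ = harmonize(exp, out)
        harm = list(harm)
        harm[0] = replace(harm[0], by=harm[0].by + shift * harm[0].sy)
        return harm

    def test_outlier_flagged_and_corrected(self):
        harm = self._shifted(seed=11)
        est = mr_presso(harm, n_sim=1000, seed=11)
        assert harm[0].variant_id in est.outlier_ids
        assert est.presso_global_p < 0.05
        assert abs(est.beta - 0.3) < abs(ivw(harm).beta - 0.3)

    def test_zero_simulations_rejected(self):
        with pytest.raises(ValueError):
            mr_presso(self._shifted(), n_sim=0)

    def test_seeded_reproducibility(self):
        harm = self._shifted(seed=3)
        a = mr_presso(harm, n_sim=500, seed=9)
        b = mr_presso(harm, n_sim=500, seed=9)
        assert a.presso_global_p == b.presso_global_p


class TestMrRaps:
    def test_no_exposure_error_limit_equals_fixed_ivw(self, rng):
        bx = rng.uniform(0.2, 2.0, 8)
        by = rng.normal(0.4 * bx, 0.05)
        sy = rng.uniform(0.03, 0.2, 8)
        instr = make_instruments(bx, by, sy)  # sx = 0
        r = mr_raps(instr)
        f = ivw(instr, scale_overdispersion=False)
        assert r.beta == pytest.approx(f.beta, abs=1e-8)
        assert r.se == pytest.approx(f.se, abs=1e-8)

    def test_identical_instruments_recover_ratio(self):
        instr = make_instruments([0.5, 0.5], [0.2, 0.2], [0.05, 0.05],
                                 sx=[0.01, 0.01])
        assert mr_raps(instr).beta == pytest.approx(0.4, abs=1e-9)

    def test_weak_instruments_less_biased_than_ivw(self):
        # dilution from exposure noise biases IVW toward zero; the profile
        # score corrects for it
        diffs = []
        for s in range(100):
            cfg = SimulationConfig(theta=0.4, n_instruments=40, n_exposure=800,
                                   target_z=3.0, gamma_sd=0.02, seed=s)
            exp, out, _ = simulate_instruments(cfg)
            harm, _ = harmonize(exp, out)
            diffs.append((abs(ivw(harm).beta - 0.4), abs(mr_raps(harm).beta - 0.4)))
        ivw_bias = np.mean([d[0] for d in diffs])
        raps_bias = np.mean([d[1] for d in diffs])
        assert raps_bias < ivw_bias


class TestPolicy:
    @staticmethod
    def _cands(intercept_p, global_p, outliers=("rs1",)):
        mk = lambda m, **kw: MREstimate(method=m, beta=0.1, se=0.05,
                                        pvalue=0.04, n_snp=10, **kw)
        return {
            "ivw": mk("ivw"),
            "egger": mk("egger", egger_intercept=0.01,
                        egger_intercept_se=0.005, egger_intercept_p=intercept_p),
            "mr_presso": mk("mr_presso", presso_global_p=global_p,
                            outlier_ids=outliers),
        }

    def test_default_prefers_ivw(self):
        est = choose_estimate(self._cands(0.30, 0.40))
        assert est.method == "ivw"

    def test_pleiotropy_switches_to_egger(self):
        est = choose_estimate(self._cands(0.01, 0.40))
        assert est.method == "egger"

    def test_presso_outliers_take_priority(self):
        est = choose_estimate(self._cands(0.01, 0.001))
        assert est.method == "mr_presso"

    def test_presso_without_outliers_does_not_fire(self):
        est = choose_estimate(self._cands(0.30, 0.001, outliers=()))
        assert est.method == "ivw"


class TestBhFdr:
    def test_known_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=8))
    def test_matches_definition_on_small_sets(self, ps):
        # independent step-up computation from the definition
        m = len(ps)
        order = np.argsort(ps)
        q_sorted = [m * ps[order[i]] / (i + 1) for i in range(m)]
        for i in range(m - 2, -1, -1):
            q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
        expect = np.empty(m)
        expect[order] = np.minimum(q_sorted, 1.0)
        assert bh_fdr(ps) == pytest.approx(expect)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=20))
    def test_bounded_and_order_preserving(self, ps):
        q = bh_fdr(ps)
        assert np.max(q) <= 1.0
        idx = np.argsort(ps)
        assert np.all(np.diff(q[idx]) >= -1e-15)


class TestBetaToOr:
    def test_null_and_doubling(self):
        assert beta_to_or(MREstimate("ivw", 0.0, 0.1, 1.0, 2))[0] == pytest.approx(1.0)
        assert beta_to_or(MREstimate("ivw", math.log(2), 0.1, 0.01, 2))[0] == pytest.approx(2.0)

    def test_consistent_with_ci_conversion(self):
        from mrtriage.summary_io import ci_from_beta
        est = MREstimate("ivw", 0.3, 0.07, 1e-5, 4)
        assert beta_to_or(est) == pytest.approx(ci_from_beta(0.3, 0.07))
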
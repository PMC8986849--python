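"""Rate decomposition (R_obs = R_0 + R_p, R_inner = R_p - R_os) and diagnostics."""

import math

import pytest

from prenmr import synthetic, workflow
from prenmr.exceptions import InconsistentRatesError, MismatchedConditionsError
from prenmr.pre_rates import (
    PRERates,
    RateRecord,
    compute_Rp,
    correct_outer_sphere,
    diagnose_regime,
    exchange_evidence,
)


def rec(cond, r1, r2, T=298.15, fld=500.0, e1=0.0, e2=0.0, guest=5e-3):
    return RateRecord(condition=cond, R1_obs=r1, R2_obs=r2, temperature=T,
                      field=fld, stderr_R1=e1, stderr_R2=e2, guest_total=guest)


class TestComputeRp:
    def test_zero_control_passes_observed_rate_through(self):
        rp = compute_Rp(rec("paramagnetic", 11.94, 10.02), rec("diamagnetic", 0, 0))
        assert rp.R1_p == pytest.approx(11.94)
        assert rp.R2_p == pytest.approx(10.02)

    def test_equal_rates_give_zero(self):
        rp = compute_Rp(rec("paramagnetic", 3.0, 4.0), rec("diamagnetic", 3.0, 4.0))
        assert rp.R1_p == 0.0 and rp.R2_p == 0.0

    def test_quadrature_uncertainty(self):
        rp = compute_Rp(rec("paramagnetic", 5.0, 5.0, e1=0.1, e2=0.1),
                        rec("diamagnetic", 1.0, 1.0, e1=0.1, e2=0.1))
        assert rp.R1_p == pytest.approx(4.0)
        assert rp.stderr_R1_p == pytest.approx(math.hypot(0.1, 0.1), rel=1e-9)

    def test_mismatched_temperature_rejected(self):
        with pytest.raises(MismatchedConditionsError):
            compute_Rp(rec("paramagnetic", 5, 5, T=298.15),
                       rec("diamagnetic", 1, 1, T=300.0))

    def test_negative_beyond_noise_rejected_but_within_noise_clamped(self):
        with pytest.raises(InconsistentRatesError):
            compute_Rp(rec("paramagnetic", 1.0, 1.0, e1=0.01, e2=0.01),
                       rec("diamagnetic", 2.0, 2.0, e1=0.01, e2=0.01))
        rp = compute_Rp(rec("paramagnetic", 1.0, 1.0, e1=0.2, e2=0.2),
                        rec("diamagnetic", 1.2, 1.2, e1=0.2, e2=0.2))
        assert rp.R1_p == 0.0 and any("clamped" in f for f in rp.flags)


class TestOuterSphere:
    def test_arithmetic_matches_hand_computation(self):
        rp = compute_Rp(rec("paramagnetic", 10.91, 10.91), rec("diamagnetic", 0, 0))
        out = correct_outer_sphere(rp, rec("blocked_rotaxane", 1.03, 1.38),
                                   rec("diamagnetic", 0, 0))
        assert out.R1_inner == pytest.approx(10.91 - 1.03)
        assert out.R2_inner == pytest.approx(10.91 - 1.38)

    def test_zero_outer_sphere_is_identity(self):
        rp = compute_Rp(rec("paramagnetic", 8.0, 8.0), rec("diamagnetic", 0, 0))
        out = correct_outer_sphere(rp, rec("blocked_rotaxane", 0.0, 0.0),
                                   rec("diamagnetic", 0, 0))
        assert out.R1_inner == rp.R1_p

    def test_additivity_single_shot(self):
        # compute_Rp then correct == R_obs - R_0 - R_os to machine precision
        rp = compute_Rp(rec("paramagnetic", 12.5, 11.0), rec("diamagnetic", 0.4, 0.6))
        out = correct_outer_sphere(rp, rec("blocked_rotaxane", 1.43, 1.98),
                                   rec("diamagnetic", 0.4, 0.6))
        assert out.R1_inner == pytest.approx(12.5 - 0.4 - (1.43 - 0.4), abs=1e-14)
        assert out.R2_inner == pytest.approx(11.0 - 0.6 - (1.98 - 0.6), abs=1e-14)

    def test_mismatched_rotaxane_conditions_rejected(self):
        rp = compute_Rp(rec("paramagnetic", 8.0, 8.0), rec("diamagnetic", 0, 0))
        with pytest.raises(MismatchedConditionsError):
            correct_outer_sphere(rp, rec("blocked_rotaxane", 1.0, 1.0, fld=300.0),
                                 rec("diamagnetic", 0, 0, fld=300.0))

    def test_synthetic_split_recovered_exactly(self, gt_noiseless):
        records = synthetic.simulate_rates(gt_noiseless, rate_noise=0.0)
        prer = workflow._pair_records(records)
        for p in prer:
            r1os, _ = gt_noiseless.R_os_at(p.temperature)
            cond = gt_noiseless.conditions(temperature=p.temperature)
            r1p_true, _ = synthetic.simulate_rp_general(gt_noiseless, cond,
                                                        p.temperature)
            assert p.R1_inner == pytest.approx(r1p_true - r1os, rel=1e-12)


def _prer_series(points):
    return [PRERates(R1_p=r1, R2_p=r2, stderr_R1_p=0, stderr_R2_p=0,
                     temperature=T, field=f) for T, f, r1, r2 in points]


class TestDiagnostics:
    def test_tau_m_dominated_series_passes(self):
        pts = [(T, f, 2.0 * math.exp(0.02 * (T - 298)), 2.0 * math.exp(0.02 * (T - 298)))
               for T in (288.15, 298.15, 308.15) for f in (300.0, 500.0)]
        d = diagnose_regime(_prer_series(pts))
        assert d.verdict == "tau_M_dominated"
        assert d.dRp_dT_positive and d.field_independent and d.ratio_in_band

    def test_ratio_1_5_flags_outer_sphere_contamination(self):
        pts = [(263.15, 500.0, 10.0, 15.0), (283.15, 500.0, 20.0, 24.0),
               (303.15, 500.0, 40.0, 42.0)]
        d = diagnose_regime(_prer_series(pts))
        assert d.verdict == "outer_sphere_contaminated"
        assert max(d.ratio_R2p_R1p.values()) == pytest.approx(1.5)

    def test_decreasing_rp_suspects_fast_exchange(self):
        pts = [(T, 500.0, 30.0 * math.exp(-0.01 * (T - 263)),
                30.0 * math.exp(-0.01 * (T - 263)))
               for T in (263.15, 283.15, 303.15)]
        d = diagnose_regime(_prer_series(pts))
        assert d.verdict == "fast_exchange_suspected"

    def test_verdict_invariant_under_rescaling(self):
        pts = [(T, 500.0, 2.0 * math.exp(0.02 * (T - 298)),
                2.1 * math.exp(0.02 * (T - 298)))
               for T in (288.15, 298.15, 308.15)]
        d1 = diagnose_regime(_prer_series(pts))
        d2 = diagnose_regime(_prer_series(
            [(T, f, 17.3 * r1, 17.3 * r2) for T, f, r1, r2 in pts]))
        assert d1.verdict == d2.verdict

    def test_single_field_skips_field_check(self):
        pts = [(T, 500.0, 2.0 * math.exp(0.02 * (T - 298)),
                2.0 * math.exp(0.02 * (T - 298)))
               for T in (288.15, 298.15, 308.15)]
        d = diagnose_regime(_prer_series(pts))
        assert d.field_independent is None
        assert any("skipped" in n for n in d.notes)

    def test_simulator_slow_regime_with_small_ros_passes(self):
        gt = synthetic.default_ground_truth(T1M=1e-5, T2M=1e-5,
                                            R1_os=0.05, R2_os=0.05)
        prer = workflow._pair_records(
            [r for r in synthetic.simulate_rates(gt, rate_noise=0.0)
             if r.condition != "blocked_rotaxane"])
        assert diagnose_regime(prer).verdict == "tau_M_dominated"

    def test_nonpositive_rp_rejected(self):
        with pytest.raises(ValueError):
            diagnose_regime(_prer_series([(288.15, 500.0, 0.0, 1.0),
                                          (298.15, 500.0, 1.0, 1.0),
                                          (308.15, 500.0, 2.0, 2.0)]))


class TestExchangeEvidence:
    def test_printed_rate_ratios(self):
        ev = exchange_evidence(rec("paramagnetic", 11.94, 10.02),
                               rec("blocked_rotaxane", 1.03, 1.38))
        assert ev.ratio_R1 == pytest.approx(11.94 / 1.03, rel=1e-9)
        assert ev.ratio_R2 == pytest.approx(10.02 / 1.38, rel=1e-9)
        assert ev.threading

    def test_equal_rates_no_threading(self):
        ev = exchange_evidence(rec("paramagnetic", 1.5, 1.5),
                               rec("blocked_rotaxane", 1.5, 1.5))
        assert ev.ratio_R1 == 1.0 and not ev.threading

    def test_binding_disabled_simulator_ratio_near_one(self, gt_noiseless):
        # the rotaxane sample itself has f = 0: comparing it against itself
        records = synthetic.simulate_rates(gt_noiseless, rate_noise=0.0,
                                           temperatures=(298.15,), fields=(500.0,))
        rot = next(r for r in records if r.condition == "blocked_rotaxane")
        obs = RateRecord(condition="paramagnetic", R1_obs=rot.R1_obs,
                         R2_obs=rot.R2_obs, temperature=rot.temperature,
                         field=rot.field, guest_total=rot.guest_total)
        ev = exchange_evidence(obs, rot)
        assert ev.ratio_R1 == pytest.approx(1.0) and not ev.threading

    def test_zero_outer_sphere_rejected(self):
        with pytest.raises(ValueError):
            exchange_evidence(rec("paramagnetic", 5, 5),
                              rec("blocked_rotaxane", 0.0, 1.0))
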
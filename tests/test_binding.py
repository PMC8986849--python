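"""1:1 binding: mass-action quadratic, reporter model, titration fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from prenmr import synthetic
from prenmr.binding import (
    TitrationPoint,
    bound_host_fraction,
    dG_to_ka,
    fit_titration,
    ka_to_dG,
    predict_reporter_rate,
)
from prenmr.exceptions import UnidentifiableFitError


def brute_force_theta(ka, h, g):
    """Independent oracle: root-find the mass-action equilibrium directly."""
    if ka == 0 or h == 0 or g == 0:
        return 0.0

    def balance(c):
        return ka * (h - c) * (g - c) - c

    c = brentq(balance, 0.0, min(h, g), xtol=1e-18, rtol=1e-15)
    return c / h


class TestBoundHostFraction:
    def test_matches_brute_force_over_1000_random_triples(self):
        rng = np.random.default_rng(2024)
        ka = 10.0 ** rng.uniform(-1, 9, 1000)
        h = 10.0 ** rng.uniform(-6, -2, 1000)
        g = 10.0 ** rng.uniform(-6, -1, 1000)
        for ka_i, h_i, g_i in zip(ka, h, g):
            assert bound_host_fraction(ka_i, h_i, g_i) == pytest.approx(
                brute_force_theta(ka_i, h_i, g_i), abs=1e-10)

    def test_saturation_limit(self):
        assert bound_host_fraction(1e12, 5e-4, 5e-3) == pytest.approx(1.0, abs=1e-6)

    def test_zero_affinity(self):
        assert bound_host_fraction(0.0, 5e-4, 5e-3) == 0.0

    def test_strong_binding_example(self):
        theta = bound_host_fraction(4796.0, 5e-4, 5e-3)
        assert theta == pytest.approx(0.956, abs=5e-4)
        assert theta * 5e-4 == pytest.approx(4.78e-4, rel=1e-3)


class TestReporterModel:
    def test_endpoints(self):
        assert predict_reporter_rate(1e4, 2.0, 0.3, 5e-4, 0.0) == 2.0
        assert predict_reporter_rate(1e4, 2.0, 0.3, 5e-4, 10.0) == pytest.approx(
            0.3, abs=1e-4)

    def test_linearity_at_half_occupancy(self):
        # pick G so that theta = 0.5, then R must be the midpoint
        ka, h = 1e4, 5e-4

        def theta(g):
            return bound_host_fraction(ka, h, g)

        from scipy.optimize import brentq
        g_half = brentq(lambda g: theta(g) - 0.5, 1e-9, 1.0)
        r = predict_reporter_rate(ka, 2.0, 0.3, h, g_half)
        assert r == pytest.approx((2.0 + 0.3) / 2, rel=1e-9)

    @given(st.lists(st.floats(min_value=0, max_value=0.1), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_monotonically_nonincreasing_in_guest(self, guests):
        guests = sorted(guests)
        rates = [predict_reporter_rate(3000.0, 2.0, 0.3, 5e-4, g) for g in guests]
        assert all(b <= a + 1e-12 for a, b in zip(rates, rates[1:]))


class TestFreeEnergy:
    @pytest.mark.parametrize("logka, dg", [(3.68, -5.02), (7.29, -9.95)])
    def test_table_values(self, logka, dg):
        assert ka_to_dG(logka, 298.15) == pytest.approx(dg, abs=0.005)

    def test_zero(self):
        assert ka_to_dG(0.0) == 0.0

    @given(st.floats(min_value=-12, max_value=12))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, logka):
        assert dG_to_ka(ka_to_dG(logka, 310.0), 310.0) == pytest.approx(
            logka, abs=1e-12)


class TestFitTitration:
    def test_noiseless_exact_recovery(self, gt_noiseless):
        pts = synthetic.simulate_titration(gt_noiseless)
        fit = fit_titration(pts, mc_draws=0)
        assert fit.logKa == pytest.approx(3.68, abs=1e-6)
        assert fit.R_empty == pytest.approx(2.0, abs=1e-6)
        assert fit.R_sat == pytest.approx(0.30, abs=1e-6)
        assert fit.dG == pytest.approx(ka_to_dG(3.68), abs=1e-5)

    def test_noisy_recovery_within_tenth_of_log_unit(self):
        gt = synthetic.default_ground_truth(seed=11, noise_sigma=0.01)
        fit = fit_titration(synthetic.simulate_titration(gt), mc_draws=200, seed=1)
        assert fit.logKa == pytest.approx(3.68, abs=0.1)
        assert fit.mc_stderr_logKa is not None and fit.mc_stderr_logKa > 0

    def test_median_recovery_error_over_100_seeds(self):
        errs = []
        for seed in range(100):
            gt = synthetic.default_ground_truth(seed=seed, noise_sigma=0.02)
            fit = fit_titration(synthetic.simulate_titration(gt), mc_draws=0)
            errs.append(abs(fit.logKa - 3.68))
        assert np.median(errs) <= 0.1

    def test_flat_series_unidentifiable(self):
        pts = [TitrationPoint(guest_total=g, host_total=5e-4, reporter_R1_obs=1.5)
               for g in np.linspace(0, 5e-2, 8)]
        with pytest.raises(UnidentifiableFitError):
            fit_titration(pts, mc_draws=0)

    def test_no_curvature_unidentifiable(self):
        # occupancy stays pinned near 1 over the measured range: Ka unidentifiable
        gt = synthetic.default_ground_truth(Ka=1e9, noise_sigma=0.0)
        grid = tuple(np.linspace(5e-3, 5e-2, 8))
        pts = synthetic.simulate_titration(gt, guest_grid=grid)
        with pytest.raises(UnidentifiableFitError):
            fit_titration(pts, mc_draws=0)
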
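"""Mono-exponential T1/T2 fitting: exact recovery, noise behavior, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prenmr.exceptions import DegenerateDataError
from prenmr.relaxometry import (
    DecaySeries,
    fit_cpmg_decay,
    fit_inversion_recovery,
    rate_from_time_constant,
    read_decays_csv,
    write_decays_csv,
)


def ir_series(t1=1.0, i_inf=1.0, b=2.0, n=8, sigma=0.0, seed=0, **kw):
    t = np.geomspace(0.01 * t1, 5 * t1, n)
    y = i_inf * (1 - b * np.exp(-t / t1))
    if sigma:
        y = y + np.random.default_rng(seed).normal(0, sigma * i_inf, n)
    return DecaySeries("s", "inversion_recovery", tuple(t), tuple(y),
                       temperature=kw.get("temperature", 298.15),
                       field=kw.get("field", 500.0))


def cpmg_series(t2=0.25, i0=1.0, n=10, sigma=0.0, seed=0):
    t = np.geomspace(0.02 * t2, 3 * t2, n)
    y = i0 * np.exp(-t / t2)
    if sigma:
        y = y + np.random.default_rng(seed).normal(0, sigma * i0, n)
    return DecaySeries("s", "cpmg", tuple(t), tuple(y), 298.15, 500.0)


def grid_search_t1(series, t1_grid, iinf_grid, b_grid):
    """Independent brute-force oracle: minimise SSE over a parameter grid."""
    t = np.array(series.delays)
    y = np.array(series.intensities)
    best, best_sse = None, np.inf
    for t1, i_inf, b in itertools.product(t1_grid, iinf_grid, b_grid):
        sse = np.sum((i_inf * (1 - b * np.exp(-t / t1)) - y) ** 2)
        if sse < best_sse:
            best, best_sse = t1, sse
    return best


class TestInversionRecovery:
    def test_noiseless_exact_recovery(self):
        fit = fit_inversion_recovery(ir_series(t1=1.0))
        assert fit.converged
        assert fit.time_constant == pytest.approx(1.0, rel=1e-8)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-8)
        assert fit.inversion_factor == pytest.approx(2.0, rel=1e-8)
        assert fit.rate * fit.time_constant == pytest.approx(1.0, rel=1e-12)

    def test_noisy_recovery_matches_grid_oracle(self):
        s = ir_series(t1=1.0, sigma=0.01, seed=4)
        fit = fit_inversion_recovery(s)
        assert fit.converged
        assert abs(fit.time_constant - 1.0) <= 3 * fit.stderr_time_constant
        t1_oracle = grid_search_t1(
            s, np.linspace(0.8, 1.2, 401), np.linspace(0.95, 1.05, 41),
            np.linspace(1.9, 2.1, 41))
        # grid resolution is 1e-3 in T1; the optimizer must land on the same basin
        assert fit.time_constant == pytest.approx(t1_oracle, abs=2e-3)

    def test_constant_series_refused(self):
        s = DecaySeries("s", "inversion_recovery", (0.1, 0.2, 0.4, 0.8),
                        (1.0, 1.0, 1.0, 1.0), 298.15, 500.0)
        fit = fit_inversion_recovery(s)
        assert not fit.converged

    def test_wrong_experiment_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_inversion_recovery(cpmg_series())


class TestCpmg:
    def test_noiseless_rate_exact(self):
        fit = fit_cpmg_decay(cpmg_series(t2=0.25))
        assert fit.rate == pytest.approx(4.0, rel=1e-8)

    def test_noisy_within_stderr_and_loglinear_agrees(self):
        fit = fit_cpmg_decay(cpmg_series(t2=0.25, sigma=0.02, seed=1))
        assert abs(fit.rate - 4.0) <= 3 * fit.stderr_rate
        assert fit.loglinear_rate == pytest.approx(fit.rate, rel=0.02)

    def test_rate_ratio_16_6_recovered(self):
        # mirrors a 16.6x transverse-relaxation enhancement contrast
        slow = fit_cpmg_decay(cpmg_series(t2=1.0))
        fast = fit_cpmg_decay(cpmg_series(t2=1.0 / 16.6))
        assert fast.rate / slow.rate == pytest.approx(16.6, rel=0.01)

    def test_too_few_positive_points_error(self):
        s = DecaySeries("s", "cpmg", (0.1, 0.2, 0.3, 0.4, 0.5),
                        (1.0, 0.5, -0.1, -0.2, -0.3), 298.15, 500.0)
        with pytest.raises(DegenerateDataError):
            fit_cpmg_decay(s)


class TestInvariants:
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        base = cpmg_series(t2=0.5, sigma=0.02, seed=7)
        scaled = DecaySeries("s", "cpmg", base.delays,
                             tuple(i * scale for i in base.intensities),
                             298.15, 500.0)
        f1, f2 = fit_cpmg_decay(base), fit_cpmg_decay(scaled)
        assert f2.rate == pytest.approx(f1.rate, rel=1e-6)

    def test_joint_permutation_then_resort_identical(self, rng):
        s = ir_series(t1=0.7, sigma=0.01, seed=3)
        order = rng.permutation(len(s.delays))
        pairs = sorted(zip(np.array(s.delays)[order],
                           np.array(s.intensities)[order]))
        s2 = DecaySeries("s", "inversion_recovery",
                         tuple(t for t, _ in pairs), tuple(y for _, y in pairs),
                         s.temperature, s.field)
        f1, f2 = fit_inversion_recovery(s), fit_inversion_recovery(s2)
        assert f1.time_constant == f2.time_constant

    def test_csv_roundtrip_with_shuffled_rows(self, tmp_path):
        s = ir_series(t1=0.7, sigma=0.01, seed=3)
        path = tmp_path / "decays.csv"
        write_decays_csv([s], path)
        import pandas as pd
        df = pd.read_csv(path).sample(frac=1.0, random_state=0)
        df.to_csv(path, index=False)
        (s2,) = read_decays_csv(path)  # reader re-sorts by delay
        f1, f2 = fit_inversion_recovery(s), fit_inversion_recovery(s2)
        assert f2.time_constant == pytest.approx(f1.time_constant, rel=1e-9)


@pytest.mark.parametrize("t, expected", [(0.5, 2.0), (1.0, 1.0), (0.0125, 80.0)])
def test_rate_from_time_constant(t, expected):
    assert rate_from_time_constant(t) == pytest.approx(expected, rel=1e-12)


def test_rate_from_nonpositive_time_constant_error():
    with pytest.raises(ValueError):
        rate_from_time_constant(0.0)


def test_series_validation():
    with pytest.raises(ValueError):
        DecaySeries("s", "inversion_recovery", (0.2, 0.1, 0.3, 0.4),
                    (1, 2, 3, 4), 298.15, 500.0)  # not increasing
    with pytest.raises(ValueError):
        DecaySeries("s", "cpmg", (0.1, 0.2, 0.3), (1, 2, 3), 298.15, 500.0)  # <4
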
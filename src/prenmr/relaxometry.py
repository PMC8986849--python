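"""Mono-exponential relaxometry: inversion-recovery T1 and CPMG-type T2 fits.

The pipeline starts from integrated signal intensities (delay, intensity)
pairs; no FID processing happens here.  Longitudinal recovery is modelled as

    I(t) = I_inf * (1 - B * exp(-t / T1))

with a free inversion factor B (B = 2 for a perfect 180-degree inversion,
B = 1 for saturation recovery), and transverse decay as

    I(t) = I0 * exp(-t / T2)  [+ offset, optional]

fitted by nonlinear least squares on the raw intensity scale.  A log-linear
slope estimate is reported alongside the CPMG fit as a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DegenerateDataError

ExperimentKind = Literal["inversion_recovery", "cpmg"]

#: minimum signal span, in units of the point-noise estimate, required to fit
MIN_SPAN_OVER_NOISE = 5.0


@dataclass(frozen=True)
class DecaySeries:
    """One relaxation experiment on one signal under one condition."""

    sample_id: str
    experiment: ExperimentKind
    delays: tuple[float, ...]
    intensities: tuple[float, ...]
    temperature: float  # K
    field: float  # spectrometer 1H frequency, MHz
    signal_label: str = ""

    def __post_init__(self) -> None:
        delays = tuple(float(t) for t in self.delays)
        intensities = tuple(float(i) for i in self.intensities)
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "intensities", intensities)
        if self.experiment not in ("inversion_recovery", "cpmg"):
            raise ValueError(f"unknown experiment kind {self.experiment!r}")
        if len(delays) != len(intensities):
            raise ValueError("delays and intensities must have equal length")
        if len(delays) < 4:
            raise ValueError("need at least 4 points per decay series")
        if min(delays) < 0:
            raise ValueError("delays must be non-negative")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ValueError("delays must be strictly increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")


@dataclass
class RelaxationFitResult:
    """Parameters of a mono-exponential fit with Jacobian-based uncertainties."""

    time_constant: float  # T1 or T2, s
    rate: float  # 1/time_constant, s^-1
    amplitude: float  # I_inf (IR) or I0 (CPMG)
    inversion_factor: float | None  # B, inversion-recovery only
    offset: float | None  # baseline, CPMG with offset only
    stderr_rate: float
    stderr_time_constant: float
    rms_residual: float
    converged: bool
    experiment: ExperimentKind
    loglinear_rate: float | None = None  # CPMG cross-check estimate
    warnings: list[str] = field(default_factory=list)


def rate_from_time_constant(t: float) -> float:
    """Convert a relaxation time constant (s) to a rate (s^-1)."""
    if t <= 0:
        raise ValueError(f"time constant must be positive, got {t}")
    return 1.0 / t


def _noise_estimate(y: np.ndarray) -> float:
    # second-difference estimator: robust to the smooth exponential trend
    if len(y) < 3:
        return 0.0
    return float(np.std(np.diff(y, n=2)) / math.sqrt(6.0))


def _half_crossing_time(t: np.ndarray, y: np.ndarray) -> float:
    """Delay at which |y - y_end| first falls below half its initial value.

    For a mono-exponential approach to y_end this happens at T*ln(2).
    """
    dev = np.abs(y - y[-1])
    if dev[0] <= 0:
        return float(t[-1]) / 2.0 if t[-1] > 0 else 1.0
    below = np.nonzero(dev <= dev[0] / 2.0)[0]
    idx = below[0] if len(below) else len(t) - 1
    t_half = float(t[idx]) if t[idx] > 0 else float(t[-1]) / 2.0
    return max(t_half / math.log(2.0), 1e-12)


def _failed_result(experiment: ExperimentKind, msg: str) -> RelaxationFitResult:
    return RelaxationFitResult(
        time_constant=math.nan, rate=math.nan, amplitude=math.nan,
        inversion_factor=None, offset=None, stderr_rate=math.nan,
        stderr_time_constant=math.nan, rms_residual=math.nan,
        converged=False, experiment=experiment, warnings=[msg],
    )


def fit_inversion_recovery(series: DecaySeries) -> RelaxationFitResult:
    """Fit I(t) = I_inf*(1 - B*exp(-t/T1)) and return T1 with its uncertainty.

    Degenerate series (span below ``MIN_SPAN_OVER_NOISE`` times the noise
    estimate) are refused with ``converged=False`` rather than fitted.
    """
    if series.experiment != "inversion_recovery":
        raise ValueError("series is not an inversion-recovery experiment")
    t = np.asarray(series.delays)
    y = np.asarray(series.intensities)

    span = float(y.max() - y.min())
    noise = _noise_estimate(y)
    if span == 0 or span < MIN_SPAN_OVER_NOISE * noise:
        return _failed_result("inversion_recovery", "no recovery detected (flat series)")

    i_inf0 = float(y[-1]) if y[-1] != 0 else float(np.mean(y[-2:]))
    if i_inf0 == 0:
        i_inf0 = span
    b0 = 1.0 - float(y[0]) / i_inf0
    if not np.isfinite(b0) or abs(b0) < 1e-3:
        b0 = 2.0
    t10 = _half_crossing_time(t, y)

    def model(t, t1, i_inf, b):
        return i_inf * (1.0 - b * np.exp(-t / t1))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model, t, y, p0=[t10, i_inf0, b0], maxfev=20000,
                bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            )
    except (RuntimeError, ValueError):
        return _failed_result("inversion_recovery", "nonlinear fit did not converge")

    t1, i_inf, b = (float(v) for v in popt)
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    err_t1 = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else math.nan
    rate = 1.0 / t1
    warn: list[str] = []
    if t1 > 100.0 * t[-1]:
        warn.append("under-sampled recovery: fitted T1 exceeds 100x the longest delay")
    return RelaxationFitResult(
        time_constant=t1, rate=rate, amplitude=i_inf, inversion_factor=b,
        offset=None, stderr_rate=err_t1 / t1**2, stderr_time_constant=err_t1,
        rms_residual=rms, converged=True, experiment="inversion_recovery",
        warnings=warn,
    )


def fit_cpmg_decay(series: DecaySeries, with_offset: bool = False) -> RelaxationFitResult:
    """Fit I(t) = I0*exp(-t/T2) (optionally + baseline offset).

    Raises :class:`DegenerateDataError` when fewer than 4 positive intensities
    are available or when the fitted T2 is non-positive.  The log-linear slope
    estimate over the positive points is reported in ``loglinear_rate``.
    """
    if series.experiment != "cpmg":
        raise ValueError("series is not a CPMG experiment")
    t = np.asarray(series.delays)
    y = np.asarray(series.intensities)

    pos = y > 0
    if pos.sum() < 4:
        raise DegenerateDataError("fewer than 4 positive intensities in CPMG series")
    span = float(y.max() - y.min())
    noise = _noise_estimate(y)
    if span == 0 or span < MIN_SPAN_OVER_NOISE * noise:
        return _failed_result("cpmg", "no decay detected (flat series)")

    i00 = float(y[0])
    t20 = _half_crossing_time(t, y)

    if with_offset:
        def model(t, t2, i0, c):
            return i0 * np.exp(-t / t2) + c
        p0 = [t20, i00, float(y[-1])]
    else:
        def model(t, t2, i0):  # type: ignore[misc]
            return i0 * np.exp(-t / t2)
        p0 = [t20, i00]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError):
        return _failed_result("cpmg", "nonlinear fit did not converge")

    t2 = float(popt[0])
    if t2 <= 0:
        raise DegenerateDataError(f"fitted T2 is non-positive ({t2:.3g} s)")
    i0 = float(popt[1])
    c = float(popt[2]) if with_offset else None
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    err_t2 = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else math.nan

    # log-linear cross-check on the positive (baseline-subtracted) points;
    # residuals weighted by intensity, the usual correction for log-transformed
    # homoscedastic noise
    yy = y - (c or 0.0)
    mask = yy > 0
    slope = (np.polyfit(t[mask], np.log(yy[mask]), 1, w=yy[mask])[0]
             if mask.sum() >= 2 else math.nan)
    return RelaxationFitResult(
        time_constant=t2, rate=1.0 / t2, amplitude=i0, inversion_factor=None,
        offset=c, stderr_rate=err_t2 / t2**2, stderr_time_constant=err_t2,
        rms_residual=rms, converged=True, experiment="cpmg",
        loglinear_rate=float(-slope),
    )


def fit_decay(series: DecaySeries, **kwargs) -> RelaxationFitResult:
    """Dispatch to the fit matching ``series.experiment``."""
    if series.experiment == "inversion_recovery":
        return fit_inversion_recovery(series)
    return fit_cpmg_decay(series, **kwargs)


DECAY_CSV_COLUMNS = [
    "sample_id", "experiment", "signal_label", "temperature_K",
    "field_MHz", "delay_s", "intensity",
]


def read_decays_csv(path) -> list[DecaySeries]:
    """Read decay tables (one row per point) into a list of series.

    Series are keyed by (sample_id, experiment, signal_label, temperature_K,
    field_MHz); within each series rows are sorted by delay.
    """
    df = pd.read_csv(path)
    missing = set(DECAY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"decay CSV missing columns: {sorted(missing)}")
    df["signal_label"] = df["signal_label"].fillna("")
    out: list[DecaySeries] = []
    keys = ["sample_id", "experiment", "signal_label", "temperature_K", "field_MHz"]
    for (sid, exp, label, temp, fld), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("delay_s")
        out.append(DecaySeries(
            sample_id=str(sid), experiment=str(exp),
            delays=tuple(grp["delay_s"]), intensities=tuple(grp["intensity"]),
            temperature=float(temp), field=float(fld), signal_label=str(label),
        ))
    return out


def write_decays_csv(series: Sequence[DecaySeries], path) -> None:
    rows = []
    for s in series:
        for d, i in zip(s.delays, s.intensities):
            rows.append((s.sample_id, s.experiment, s.signal_label,
                         s.temperature, s.field, d, i))
    pd.DataFrame(rows, columns=DECAY_CSV_COLUMNS).to_csv(path, index=False)
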
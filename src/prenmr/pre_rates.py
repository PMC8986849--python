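"""Decomposition of observed relaxation rates and exchange-regime diagnostics.

An observed rate splits as R_obs = R_0 + R_p (diamagnetic + paramagnetic),
and the paramagnetic part further as an inner-sphere (binding) term plus an
outer-sphere term, R_p = f/(tau_M + T_M) + R_os.  R_os is an empirical
quantity here, measured on a cavity-blocked rotaxane control.

Exchange kinetics may only be read off R_p when the guest residence time
tau_M dominates, which requires three conditions to hold:

1. R_p increases with temperature (faster exchange shortens tau_M);
2. R_p is independent of the spectrometer field (tau_M is field-independent);
3. R_2,p ~= R_1,p (both channels see the same residence-time bottleneck).

`diagnose_regime` checks all three and issues a verdict that downstream
kinetics are gated on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InconsistentRatesError, MismatchedConditionsError

Condition = Literal["paramagnetic", "diamagnetic", "blocked_rotaxane"]
Verdict = Literal["tau_M_dominated", "outer_sphere_contaminated", "fast_exchange_suspected"]

#: temperature tolerance for pairing records, K
TEMPERATURE_MATCH_TOL = 0.5
#: R2p/R1p pass band (paper-style condition 3)
DEFAULT_RATIO_BAND = (0.67, 1.3)
#: ratio at which outer-sphere contamination is declared
CONTAMINATED_RATIO = 1.5
#: default max relative R1p discrepancy across fields
DEFAULT_FIELD_TOL = 0.15
#: default R_obs/R_os factor taken as evidence of exchange (threading)
DEFAULT_MIN_FACTOR = 3.0


@dataclass(frozen=True)
class RateRecord:
    """Observed R1/R2 for one sample condition (one temperature, one field)."""

    condition: Condition
    R1_obs: float
    R2_obs: float
    temperature: float  # K
    field: float  # MHz
    stderr_R1: float = 0.0
    stderr_R2: float = 0.0
    host_total: float = 0.0  # M
    guest_total: float = 0.0  # M
    host_id: str = ""
    guest_id: str = ""

    def __post_init__(self) -> None:
        if self.R1_obs < 0 or self.R2_obs < 0:
            raise ValueError("observed rates must be non-negative")
        if self.condition not in ("paramagnetic", "diamagnetic", "blocked_rotaxane"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class PRERates:
    """Paramagnetic rate contributions at one (temperature, field) point."""

    R1_p: float
    R2_p: float
    stderr_R1_p: float
    stderr_R2_p: float
    temperature: float
    field: float
    guest_total: float = 0.0
    R1_inner: float | None = None  # set by correct_outer_sphere
    R2_inner: float | None = None
    stderr_R1_inner: float | None = None
    stderr_R2_inner: float | None = None
    flags: tuple[str, ...] = ()


@dataclass
class RegimeDiagnostics:
    """Outcome of the three tau_M-dominance requirements."""

    dRp_dT_positive: bool
    slope_lnR1p_vs_T: float
    field_independent: bool | None  # None when only one field was measured
    max_field_discrepancy: float | None
    ratio_R2p_R1p: dict[float, float]  # per temperature, uncorrected
    ratio_R2p_R1p_corrected: dict[float, float] | None
    ratio_in_band: bool
    verdict: Verdict
    notes: list[str] = field(default_factory=list)


def _check_matched(a: RateRecord, b: RateRecord, what: str) -> None:
    if abs(a.temperature - b.temperature) > TEMPERATURE_MATCH_TOL:
        raise MismatchedConditionsError(
            f"{what}: temperatures differ ({a.temperature} K vs {b.temperature} K)")
    if a.field != b.field:
        raise MismatchedConditionsError(
            f"{what}: fields differ ({a.field} MHz vs {b.field} MHz)")
    if not math.isclose(a.guest_total, b.guest_total, rel_tol=1e-9, abs_tol=1e-12):
        raise MismatchedConditionsError(
            f"{what}: guest concentrations differ ({a.guest_total} M vs {b.guest_total} M)")


def _subtract(obs: float, base: float, err_obs: float, err_base: float,
              what: str) -> tuple[float, float, list[str]]:
    diff = obs - base
    err = math.hypot(err_obs, err_base)
    flags: list[str] = []
    if diff < 0:
        if err > 0 and diff >= -2.0 * err:
            flags.append(f"{what} negative within noise; clamped to 0")
            diff = 0.0
        else:
            raise InconsistentRatesError(
                f"{what} = {diff:.4g} s^-1 is negative beyond 2 combined stderr")
    return diff, err, flags


def compute_Rp(para: RateRecord, dia: RateRecord) -> PRERates:
    """Paramagnetic contribution R_p = R_obs - R_0, per channel.

    Uncertainties combine in quadrature.  Small negative differences
    (within 2 combined stderr) clamp to zero with a flag; larger ones are an
    error, since the controls are then inconsistent.
    """
    if para.condition != "paramagnetic":
        raise ValueError("first record must be the paramagnetic sample")
    if dia.condition != "diamagnetic":
        raise ValueError("second record must be the diamagnetic control")
    _check_matched(para, dia, "compute_Rp")
    r1, e1, f1 = _subtract(para.R1_obs, dia.R1_obs, para.stderr_R1, dia.stderr_R1, "R1_p")
    r2, e2, f2 = _subtract(para.R2_obs, dia.R2_obs, para.stderr_R2, dia.stderr_R2, "R2_p")
    return PRERates(
        R1_p=r1, R2_p=r2, stderr_R1_p=e1, stderr_R2_p=e2,
        temperature=para.temperature, field=para.field,
        guest_total=para.guest_total, flags=tuple(f1 + f2),
    )


def compute_Ros(rotaxane_para: RateRecord, rotaxane_dia: RateRecord) -> PRERates:
    """Outer-sphere rates from the blocked-rotaxane control pair."""
    if rotaxane_para.condition != "blocked_rotaxane":
        raise ValueError("first record must be the blocked-rotaxane sample")
    if rotaxane_dia.condition != "diamagnetic":
        raise ValueError("second record must be the diamagnetic control")
    _check_matched(rotaxane_para, rotaxane_dia, "compute_Ros")
    r1, e1, f1 = _subtract(rotaxane_para.R1_obs, rotaxane_dia.R1_obs,
                           rotaxane_para.stderr_R1, rotaxane_dia.stderr_R1, "R1_os")
    r2, e2, f2 = _subtract(rotaxane_para.R2_obs, rotaxane_dia.R2_obs,
                           rotaxane_para.stderr_R2, rotaxane_dia.stderr_R2, "R2_os")
    return PRERates(
        R1_p=r1, R2_p=r2, stderr_R1_p=e1, stderr_R2_p=e2,
        temperature=rotaxane_para.temperature, field=rotaxane_para.field,
        guest_total=rotaxane_para.guest_total, flags=tuple(f1 + f2),
    )


def correct_outer_sphere(rates: PRERates, rotaxane_para: RateRecord,
                         rotaxane_dia: RateRecord) -> PRERates:
    """Inner-sphere rates R_inner = R_p - R_os, with R_os from the rotaxane pair.

    The rotaxane records must match the conditions of ``rates`` (temperature
    within 0.5 K, same field and guest concentration).
    """
    if abs(rates.temperature - rotaxane_para.temperature) > TEMPERATURE_MATCH_TOL \
            or rates.field != rotaxane_para.field \
            or not math.isclose(rates.guest_total, rotaxane_para.guest_total,
                                rel_tol=1e-9, abs_tol=1e-12):
        raise MismatchedConditionsError(
            "rotaxane control does not match the conditions of the rates to correct")
    ros = compute_Ros(rotaxane_para, rotaxane_dia)
    r1, e1, f1 = _subtract(rates.R1_p, ros.R1_p, rates.stderr_R1_p, ros.stderr_R1_p,
                           "R1_inner")
    r2, e2, f2 = _subtract(rates.R2_p, ros.R2_p, rates.stderr_R2_p, ros.stderr_R2_p,
                           "R2_inner")
    return replace(
        rates, R1_inner=r1, R2_inner=r2, stderr_R1_inner=e1, stderr_R2_inner=e2,
        flags=rates.flags + tuple(f1 + f2) + tuple(ros.flags),
    )


def diagnose_regime(series: Sequence[PRERates],
                    ratio_band: tuple[float, float] = DEFAULT_RATIO_BAND,
                    field_tol: float = DEFAULT_FIELD_TOL) -> RegimeDiagnostics:
    """Run the three tau_M-dominance checks on a temperature/field grid of rates.

    The R2p/R1p ratio is evaluated before and (when available) after the
    outer-sphere correction; the verdict uses the corrected ratios when the
    series carries them.  Requires >= 3 temperatures; the field check is
    skipped (with a note) when only one field is present.
    """
    if any(p.R1_p <= 0 for p in series):
        raise ValueError("all R1_p must be positive to diagnose the exchange regime")
    temps = sorted({p.temperature for p in series})
    if len(temps) < 3:
        raise ValueError("need at least 3 temperatures to diagnose the regime")
    notes: list[str] = []

    # (1) slope of ln(R1p) vs T, pooled over fields
    T = np.array([p.temperature for p in series])
    lnr = np.log([p.R1_p for p in series])
    slope = float(stats.linregress(T, lnr).slope)
    slope_ok = slope > 0

    # (2) field independence of R1p, per temperature
    fields = sorted({p.field for p in series})
    if len(fields) < 2:
        notes.append("single field measured; field-independence check skipped")
        field_ok: bool | None = None
        max_disc: float | None = None
    else:
        discs = []
        for t in temps:
            vals = [p.R1_p for p in series if p.temperature == t]
            if len(vals) >= 2:
                discs.append((max(vals) - min(vals)) / np.mean(vals))
        max_disc = float(max(discs)) if discs else 0.0
        field_ok = max_disc <= field_tol

    # (3) R2p/R1p per temperature, uncorrected and corrected
    def _ratios(corrected: bool) -> dict[float, float]:
        out: dict[float, float] = {}
        for t in temps:
            pts = [p for p in series if p.temperature == t]
            if corrected:
                pts = [p for p in pts
                       if p.R1_inner is not None and p.R1_inner > 0
                       and p.R2_inner is not None]
                if not pts:
                    continue
                out[t] = float(np.mean([p.R2_inner / p.R1_inner for p in pts]))
            else:
                out[t] = float(np.mean([p.R2_p / p.R1_p for p in pts]))
        return out

    raw = _ratios(False)
    corr = _ratios(True) or None
    effective = corr if corr else raw
    lo, hi = ratio_band
    ratio_ok = all(lo <= r <= hi for r in effective.values())

    if not slope_ok:
        verdict: Verdict = "fast_exchange_suspected"
    elif not ratio_ok:
        worst = max(effective.values())
        verdict = ("outer_sphere_contaminated" if worst > hi
                   else "fast_exchange_suspected")
        if max(raw.values()) >= CONTAMINATED_RATIO:
            verdict = "outer_sphere_contaminated"
            notes.append(
                f"uncorrected R2p/R1p reaches {max(raw.values()):.2f} "
                f"(>= {CONTAMINATED_RATIO}): outer-sphere contamination")
    elif field_ok is False:
        verdict = "fast_exchange_suspected"
        notes.append("field-dependent R1p suggests a relaxation-dominated regime")
    else:
        verdict = "tau_M_dominated"

    return RegimeDiagnostics(
        dRp_dT_positive=slope_ok, slope_lnR1p_vs_T=slope,
        field_independent=field_ok, max_field_discrepancy=max_disc,
        ratio_R2p_R1p=raw, ratio_R2p_R1p_corrected=corr,
        ratio_in_band=ratio_ok, verdict=verdict, notes=notes,
    )


@dataclass(frozen=True)
class ThreadingEvidence:
    ratio_R1: float
    ratio_R2: float
    threading: bool
    min_factor: float


def exchange_evidence(obs: RateRecord, rotaxane: RateRecord,
                      min_factor: float = DEFAULT_MIN_FACTOR) -> ThreadingEvidence:
    """Compare R_obs against the outer-sphere-only rotaxane control.

    R_obs >> R_os supports that guest exchange — and hence threading of the
    host onto the guest — occurs.  Returns per-channel ratios and a boolean
    (both ratios >= ``min_factor``).
    """
    _check_matched(obs, rotaxane, "exchange_evidence")
    if rotaxane.R1_obs <= 0 or rotaxane.R2_obs <= 0:
        raise ValueError("outer-sphere reference rates must be positive")
    r1 = obs.R1_obs / rotaxane.R1_obs
    r2 = obs.R2_obs / rotaxane.R2_obs
    return ThreadingEvidence(ratio_R1=r1, ratio_R2=r2,
                             threading=(r1 >= min_factor and r2 >= min_factor),
                             min_factor=min_factor)


RATES_CSV_COLUMNS = [
    "condition", "host_id", "guest_id", "host_total_M", "guest_total_M",
    "temperature_K", "field_MHz", "R1_obs", "R1_err", "R2_obs", "R2_err",
]


def read_rates_csv(path) -> list[RateRecord]:
    df = pd.read_csv(path)
    missing = set(RATES_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rates CSV missing columns: {sorted(missing)}")
    return [
        RateRecord(
            condition=row.condition, host_id=str(row.host_id), guest_id=str(row.guest_id),
            host_total=float(row.host_total_M), guest_total=float(row.guest_total_M),
            temperature=float(row.temperature_K), field=float(row.field_MHz),
            R1_obs=float(row.R1_obs), stderr_R1=float(row.R1_err),
            R2_obs=float(row.R2_obs), stderr_R2=float(row.R2_err),
        )
        for row in df.itertuples()
    ]


def write_rates_csv(records: Sequence[RateRecord], path) -> None:
    rows = [
        (r.condition, r.host_id, r.guest_id, r.host_total, r.guest_total,
         r.temperature, r.field, r.R1_obs, r.stderr_R1, r.R2_obs, r.stderr_R2)
        for r in records
    ]
    pd.DataFrame(rows, columns=RATES_CSV_COLUMNS).to_csv(path, index=False)
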
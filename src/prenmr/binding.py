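"""1:1 host-guest binding from PRE solvent-reporter titrations.

The association constant of a guest for a paramagnetic host is measured by
watching the longitudinal relaxation rate of a bulk reporter solvent
(chloroform) that occupies the empty host cavity: as guest is titrated in
and displaces the reporter from the paramagnetic centre, the bulk reporter
rate falls from R_empty towards the outer-sphere-only plateau R_sat.  Under
fast solvent exchange the reporter rate is linear in host occupancy,

    R(G) = R_sat + (R_empty - R_sat) * (1 - theta(G)),

with theta the bound-host fraction from exact 1:1 mass action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .constants import R_GAS_KCAL, T_STANDARD
from .exceptions import DegenerateDataError, UnidentifiableFitError

#: occupancy must cross below/above these for Ka to be identifiable
_THETA_LOW, _THETA_HIGH = 0.2, 0.8


@dataclass(frozen=True)
class TitrationPoint:
    guest_total: float  # M
    host_total: float  # M, constant across a series
    reporter_R1_obs: float  # s^-1
    stderr: float = 0.0
    temperature: float = T_STANDARD  # K

    def __post_init__(self) -> None:
        if self.guest_total < 0 or self.host_total < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass
class BindingFitResult:
    """Association constant and endpoint rates from a titration fit."""

    Ka: float  # M^-1
    logKa: float  # log10(Ka * 1 M)
    dG: float  # kcal/mol at `temperature`
    R_empty: float  # s^-1
    R_sat: float  # s^-1
    stderr_logKa: float
    stderr_dG: float
    stderr_R_empty: float
    stderr_R_sat: float
    mc_stderr_logKa: float | None  # Monte-Carlo resampling estimate
    temperature: float
    n_points: int


def bound_host_fraction(Ka: float, host_total: float, guest_total: float,
                        binding_sites: int = 1) -> float:
    """Fraction of host carrying a bound guest under exact 1:1 mass action.

    Uses the numerically stable root  [HG] = 2*H*G / (b + sqrt(b^2 - 4*H*G))
    with b = H + G + 1/Ka, which avoids cancellation for strong binding.
    ``binding_sites`` > 1 treats the host as carrying that many independent
    equivalent cavities (host capacity is scaled).
    """
    if Ka < 0:
        raise ValueError("Ka must be non-negative")
    if host_total < 0 or guest_total < 0:
        raise ValueError("concentrations must be non-negative")
    h = host_total * binding_sites
    g = guest_total
    if Ka == 0 or g == 0:
        return 0.0
    if h == 0:
        # dilute-host limit: isolated site occupancy
        return Ka * g / (1.0 + Ka * g)
    b = h + g + 1.0 / Ka
    disc = b * b - 4.0 * h * g
    complex_conc = 2.0 * h * g / (b + math.sqrt(max(disc, 0.0)))
    return min(complex_conc / h, 1.0)


def predict_reporter_rate(Ka: float, R_empty: float, R_sat: float,
                          host_total: float, guest_total: float) -> float:
    """Bulk-reporter relaxation rate at a given guest concentration.

    Interpolates linearly in host occupancy between the empty-cavity rate
    R_empty and the saturated (outer-sphere-only) rate R_sat.
    """
    if not R_empty >= R_sat >= 0:
        raise ValueError("expect R_empty >= R_sat >= 0 (occupancy shields the reporter)")
    theta = bound_host_fraction(Ka, host_total, guest_total)
    return R_sat + (R_empty - R_sat) * (1.0 - theta)


def ka_to_dG(logKa: float, T: float = T_STANDARD) -> float:
    """Binding free energy (kcal/mol) from log10 Ka, standard state 1 M."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return -R_GAS_KCAL * T * math.log(10.0) * logKa


def dG_to_ka(dG: float, T: float = T_STANDARD) -> float:
    """Inverse of :func:`ka_to_dG`: log10 Ka from a binding free energy."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return -dG / (R_GAS_KCAL * T * math.log(10.0))


def _theta_range(Ka: float, points: Sequence[TitrationPoint]) -> tuple[float, float]:
    th = [bound_host_fraction(Ka, p.host_total, p.guest_total) for p in points]
    return min(th), max(th)


def fit_titration(points: Sequence[TitrationPoint], mc_draws: int = 2000,
                  seed: int = 0) -> BindingFitResult:
    """Nonlinear least-squares fit of (Ka, R_empty, R_sat) to a titration.

    Ka is fitted on the log10 scale for conditioning.  Uncertainties come
    from the fit covariance (delta method) and, when ``mc_draws`` > 0, from
    Monte-Carlo resampling of the residual noise (seeded).  Raises
    :class:`UnidentifiableFitError` when the series has no usable curvature
    (occupancy never exceeds 20% or never drops below 80% at the optimum).
    """
    if len(points) < 5:
        raise DegenerateDataError("need at least 5 titration points")
    hosts = {p.host_total for p in points}
    if len(hosts) != 1:
        raise ValueError("host_total must be constant across the series")
    host = hosts.pop()
    g = np.array([p.guest_total for p in points])
    r = np.array([p.reporter_R1_obs for p in points])
    temperature = float(np.mean([p.temperature for p in points]))

    span = r.max() - r.min()
    if span <= 0 or span < 1e-6 * max(abs(r.max()), 1.0):
        raise UnidentifiableFitError("flat titration series: Ka unidentifiable")

    def model(params, g):
        ka = 10.0 ** params["logKa"].value
        theta = np.array([bound_host_fraction(ka, host, gi) for gi in g])
        return params["R_sat"] + (params["R_empty"] - params["R_sat"]) * (1.0 - theta)

    def residual(params, g, r):
        return model(params, g) - r

    params = lmfit.Parameters()
    # half-drop guest concentration seeds logKa
    mid = r.min() + span / 2.0
    g_mid = g[np.argmin(np.abs(r - mid))]
    ka0 = 1.0 / max(g_mid, 1e-9)
    params.add("logKa", value=math.log10(ka0), min=-3, max=14)
    params.add("R_empty", value=float(r[np.argmin(g)]), min=0)
    params.add("R_sat", value=float(max(r.min(), 1e-6)), min=0)

    out = lmfit.minimize(residual, params, args=(g, r), method="leastsq")
    logka = float(out.params["logKa"].value)
    ka = 10.0 ** logka
    lo, hi = _theta_range(ka, points)
    if hi < _THETA_LOW or lo > _THETA_HIGH:
        raise UnidentifiableFitError(
            f"occupancy spans only [{lo:.2f}, {hi:.2f}]: Ka unidentifiable")

    err_logka = float(out.params["logKa"].stderr or 0.0)
    err_re = float(out.params["R_empty"].stderr or 0.0)
    err_rs = float(out.params["R_sat"].stderr or 0.0)

    mc_err = None
    if mc_draws > 0:
        resid = model(out.params, g) - r
        sigma = float(np.std(resid, ddof=min(3, len(r) - 1)))
        rng = np.random.default_rng(seed)
        draws = []
        fitted = model(out.params, g)
        for _ in range(mc_draws):
            r_star = fitted + rng.normal(0.0, sigma, size=len(r))
            try:
                o = lmfit.minimize(residual, out.params.copy(), args=(g, r_star),
                                   method="leastsq")
                draws.append(float(o.params["logKa"].value))
            except Exception:
                continue
        if len(draws) > 10:
            mc_err = float(np.std(draws))

    dg = ka_to_dG(logka, temperature)
    err_dg = abs(R_GAS_KCAL * temperature * math.log(10.0)) * err_logka
    return BindingFitResult(
        Ka=ka, logKa=logka, dG=dg,
        R_empty=float(out.params["R_empty"].value),
        R_sat=float(out.params["R_sat"].value),
        stderr_logKa=err_logka, stderr_dG=err_dg,
        stderr_R_empty=err_re, stderr_R_sat=err_rs,
        mc_stderr_logKa=mc_err, temperature=temperature, n_points=len(points),
    )


TITRATION_CSV_COLUMNS = [
    "host_id", "guest_id", "host_total_M", "guest_total_M",
    "temperature_K", "R1_obs", "R1_err",
]


def read_titration_csv(path) -> list[TitrationPoint]:
    df = pd.read_csv(path)
    missing = set(TITRATION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
    return [
        TitrationPoint(
            guest_total=float(row.guest_total_M), host_total=float(row.host_total_M),
            reporter_R1_obs=float(row.R1_obs), stderr=float(row.R1_err),
            temperature=float(row.temperature_K),
        )
        for row in df.itertuples()
    ]


def write_titration_csv(points: Sequence[TitrationPoint], path,
                        host_id: str = "host", guest_id: str = "guest") -> None:
    rows = [
        (host_id, guest_id, p.host_total, p.guest_total, p.temperature,
         p.reporter_R1_obs, p.stderr)
        for p in points
    ]
    pd.DataFrame(rows, columns=TITRATION_CSV_COLUMNS).to_csv(path, index=False)
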
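"""Exchange kinetics from inner-sphere paramagnetic rates.

In the tau_M-dominated (slow-to-intermediate exchange) regime the
inner-sphere rate reduces to R_inner = f / tau_M, so the guest residence
time follows directly from the bound mole fraction f and the measured rate,
and its inverse is the observed dissociation rate constant k_d,obs.

When k_d,obs itself depends on guest concentration with a (possibly
non-integer) order n, rates are normalised to a declared reference
concentration: k_d = k_d,obs * (G_ref/G)^n, keeping k_d in s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .binding import bound_host_fraction
from .constants import T_STANDARD
from .exceptions import RegimeGateError


@dataclass(frozen=True)
class ExchangeConditions:
    """Concentrations and affinity fixing the bound guest fraction."""

    host_total: float  # M
    guest_total: float  # M
    Ka: float  # M^-1
    temperature: float = T_STANDARD  # K
    binding_sites: int = 1

    def __post_init__(self) -> None:
        if self.guest_total <= 0:
            raise ValueError("guest_total must be positive")
        if self.Ka <= 0:
            raise ValueError("Ka must be positive")


@dataclass
class ExchangeResult:
    """Per-temperature exchange parameters."""

    f: float
    tau_M: float  # s
    kd_obs: float  # s^-1
    kd: float  # s^-1, order-corrected to the reference guest concentration
    order_n: float
    temperature: float
    stderr_tau_M: float = 0.0
    stderr_kd_obs: float = 0.0
    stderr_kd: float = 0.0


def guest_bound_fraction(c: ExchangeConditions) -> float:
    """Mole fraction f of guest bound to the host.

    Shares the exact 1:1 quadratic with the titration module: f is the
    complex concentration divided by total guest, times the number of
    binding sites (sites are independent and equivalent).
    """
    if c.host_total == 0:
        return 0.0
    theta = bound_host_fraction(c.Ka, c.host_total, c.guest_total,
                                binding_sites=c.binding_sites)
    complex_conc = theta * c.host_total * c.binding_sites
    return min(complex_conc / c.guest_total, 1.0)


def residence_time(R_inner: float, f: float, verdict: str,
                   stderr_R_inner: float = 0.0, force: bool = False,
                   ) -> tuple[float, float, float, float]:
    """Guest residence time tau_M = f / R_inner and k_d,obs = 1/tau_M.

    ``verdict`` must be the diagnostics verdict for the series; anything but
    ``tau_M_dominated`` raises :class:`RegimeGateError` unless ``force`` is
    set, because the simplified relation is only valid in that regime.

    Returns (tau_M, kd_obs, stderr_tau_M, stderr_kd_obs).
    """
    if verdict != "tau_M_dominated" and not force:
        raise RegimeGateError(
            f"residence time requested with verdict {verdict!r}; "
            "the f/tau_M simplification is only valid when tau_M dominates")
    if R_inner <= 0:
        raise ValueError("R_inner must be positive")
    if f <= 0:
        raise ValueError("bound fraction f must be positive")
    tau = f / R_inner
    kd = 1.0 / tau
    rel = stderr_R_inner / R_inner if R_inner > 0 else 0.0
    return tau, kd, tau * rel, kd * rel


def estimate_reaction_order(series: Sequence[tuple[float, float]],
                            ) -> tuple[float, float]:
    """Apparent guest-concentration order of the dissociation rate.

    ``series`` holds (guest_total, kd_obs) pairs at fixed temperature and
    host concentration; the order n is the least-squares slope of
    ln(kd_obs) against ln(guest_total).  Returns (n, stderr_n).
    """
    if len({g for g, _ in series}) < 3:
        raise ValueError("need at least 3 distinct guest concentrations")
    g = np.array([p[0] for p in series], dtype=float)
    k = np.array([p[1] for p in series], dtype=float)
    if np.any(g <= 0) or np.any(k <= 0):
        raise ValueError("concentrations and rates must be positive")
    res = stats.linregress(np.log(g), np.log(k))
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return float(res.slope), stderr


def correct_kd(kd_obs: float, guest_total: float, n: float,
               guest_ref: float) -> float:
    """Normalise k_d,obs for its guest-concentration order.

    k_d = k_d,obs * (G_ref / G)^n, i.e. the rate the system would show at
    the reference concentration; units stay s^-1.  n = 0 is the identity.
    """
    if guest_total <= 0 or guest_ref <= 0:
        raise ValueError("guest concentrations must be positive")
    return kd_obs * (guest_ref / guest_total) ** n


def exchange_from_inner_rate(R_inner: float, conditions: ExchangeConditions,
                             verdict: str, order_n: float = 0.0,
                             guest_ref: float | None = None,
                             stderr_R_inner: float = 0.0,
                             force: bool = False) -> ExchangeResult:
    """Full per-temperature conversion: R_inner -> (f, tau_M, kd_obs, kd)."""
    f = guest_bound_fraction(conditions)
    tau, kd_obs, err_tau, err_kd = residence_time(
        R_inner, f, verdict, stderr_R_inner=stderr_R_inner, force=force)
    ref = conditions.guest_total if guest_ref is None else guest_ref
    kd = correct_kd(kd_obs, conditions.guest_total, order_n, ref)
    scale = kd / kd_obs if kd_obs else 0.0
    return ExchangeResult(
        f=f, tau_M=tau, kd_obs=kd_obs, kd=kd, order_n=order_n,
        temperature=conditions.temperature, stderr_tau_M=err_tau,
        stderr_kd_obs=err_kd, stderr_kd=err_kd * scale,
    )
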
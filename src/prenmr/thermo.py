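"""Eyring activation analysis and threading-rate thermodynamics.

Transition-state theory gives  k = kappa * (k_B T / h) * exp(-dG'/RT)  with
dG' = dH' - T*dS'; linearising,

    ln(k/T) = -dH'/(R) * (1/T) + [ ln(k_B/h) + dS'/R ],

so the activation enthalpy and entropy follow from a straight-line fit of
ln(k/T) on 1/T.  Threading (association) rate constants derive from the
equilibrium relation Ka = k_on / k_d, and a barrier can be assigned to any
rate constant via dG' = -RT ln(k h / (k_B T)) — for bimolecular k_on the
1 M standard state is implicit in using the numeric value of k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import K_BOLTZMANN, PLANCK_H, R_GAS_KCAL, T_STANDARD
from .exceptions import DegenerateDataError

_LN_KB_OVER_H = math.log(K_BOLTZMANN / PLANCK_H)


@dataclass
class EyringFit:
    """Activation parameters from ln(k/T) vs 1/T regression."""

    dH: float  # kcal/mol
    dS: float  # cal/(K mol)
    stderr_dH: float
    stderr_dS: float
    covariance: np.ndarray  # 2x2 cov of (dH [kcal/mol], dS [cal/K/mol])
    n_points: int
    temperature_range: tuple[float, float]

    def dG_at(self, T: float = T_STANDARD) -> float:
        """dG' = dH' - T*dS' (entropy converted cal -> kcal)."""
        return dG_dH_dS_identity(self.dH, self.dS, T)

    def stderr_dG_at(self, T: float = T_STANDARD) -> float:
        grad = np.array([1.0, -T / 1000.0])
        var = float(grad @ self.covariance @ grad)
        return math.sqrt(max(var, 0.0))


def eyring_fit(points: Sequence[tuple[float, float]],
               weights: Sequence[float] | None = None) -> EyringFit:
    """Fit activation enthalpy/entropy to (temperature K, rate constant) pairs.

    Ordinary (or, with ``weights`` on ln(k/T), weighted) least squares.
    Requires at least 3 distinct temperatures and strictly positive rates.
    """
    if len(points) < 3:
        raise DegenerateDataError("need at least 3 (T, k) points for an Eyring fit")
    T = np.array([p[0] for p in points], dtype=float)
    k = np.array([p[1] for p in points], dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    if np.any(k <= 0):
        raise ValueError("rate constants must be positive")
    if len(np.unique(T)) < 3:
        raise DegenerateDataError(
            "degenerate design: need at least 3 distinct temperatures")

    x = 1.0 / T
    y = np.log(k / T)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)

    X = np.column_stack([x, np.ones_like(x)])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ beta
    dof = max(len(x) - 2, 1)
    s2 = float(resid @ W @ resid) / dof
    cov_beta = s2 * np.linalg.inv(xtwx)

    slope, intercept = (float(b) for b in beta)
    dh = -slope * R_GAS_KCAL
    ds_kcal = (intercept - _LN_KB_OVER_H) * R_GAS_KCAL
    # jacobian of (dH, dS[cal]) wrt (slope, intercept)
    J = np.array([[-R_GAS_KCAL, 0.0], [0.0, R_GAS_KCAL * 1000.0]])
    cov = J @ cov_beta @ J.T
    return EyringFit(
        dH=dh, dS=ds_kcal * 1000.0,
        stderr_dH=math.sqrt(max(cov[0, 0], 0.0)),
        stderr_dS=math.sqrt(max(cov[1, 1], 0.0)),
        covariance=cov, n_points=len(points),
        temperature_range=(float(T.min()), float(T.max())),
    )


def eyring_rate(dH: float, dS: float, T: float) -> float:
    """Rate constant from activation parameters (dH kcal/mol, dS cal/K/mol)."""
    dg = dG_dH_dS_identity(dH, dS, T)
    return rate_from_dG(dg, T)


def dG_from_rate(k: float, T: float = T_STANDARD) -> float:
    """Activation free energy (kcal/mol) of a rate constant: -RT ln(k h/(k_B T)).

    For a bimolecular rate constant the numeric value (M^-1 s^-1) is used,
    i.e. a 1 M standard state is implied.
    """
    if k <= 0 or T <= 0:
        raise ValueError("rate constant and temperature must be positive")
    return -R_GAS_KCAL * T * math.log(k * PLANCK_H / (K_BOLTZMANN * T))


def rate_from_dG(dG: float, T: float = T_STANDARD) -> float:
    """Inverse of :func:`dG_from_rate`: k = (k_B T/h) exp(-dG/RT)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return (K_BOLTZMANN * T / PLANCK_H) * math.exp(-dG / (R_GAS_KCAL * T))


def kon_from_Ka_kd(Ka: float, kd: float, Ka_err: float = 0.0,
                   kd_err: float = 0.0) -> tuple[float, float]:
    """Association (threading) rate constant from Ka = k_on/k_d.

    Returns (k_on, stderr) with relative errors combined in quadrature.
    """
    if Ka <= 0 or kd <= 0:
        raise ValueError("Ka and kd must be positive")
    kon = Ka * kd
    rel = math.hypot(Ka_err / Ka, kd_err / kd)
    return kon, kon * rel


def dG_dH_dS_identity(dH: float, dS: float, T: float = T_STANDARD) -> float:
    """dG = dH - T*dS with dH in kcal/mol and dS in cal/(K mol)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return dH - T * dS / 1000.0
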
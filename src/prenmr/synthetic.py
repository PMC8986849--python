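"""Synthetic two-site-exchange data generator with known ground truth.

Generates every input the pipeline consumes — relaxation decay curves,
per-condition rate tables, and reporter-solvent titrations — from a single
:class:`GroundTruth` whose fields are the generative counterparts of the
analysis model:

* the guest residence time tau_M(T) follows transition-state kinetics from
  activation parameters (dH_act, dS_act), scaled by a guest-concentration
  order (G/G_ref)^n;
* the bound-state relaxation time T_M(T) and the outer-sphere background
  R_os(T) carry mild exponential temperature factors;
* the general inner-sphere model R_p = f/(tau_M + T_M) + R_os spans the
  slow, intermediate and fast exchange regimes depending on tau_M/T_M.

Default parameter values emulate a Mn(III) porphyrin cage threading a
viologen guest: logKa 3.68, dH_act 8.35 kcal/mol, dS_act -17.57 cal/K/mol,
order 0.3, host 0.5 mM with 10 equivalents of guest, -10 to 70 C, 300 and
500 MHz.  In the default preset T_M = 0, the regime the simplified f/tau_M
analysis is exact in; finite-T_M presets exist to probe its breakdown.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .binding import predict_reporter_rate
from .exchange import ExchangeConditions, guest_bound_fraction
from .pre_rates import RateRecord
from .relaxometry import DecaySeries
from .thermo import eyring_rate
from .constants import R_GAS_KCAL, T_STANDARD

DEFAULT_TEMPERATURES = tuple(263.15 + 10.0 * i for i in range(9))  # -10..70 C
DEFAULT_FIELDS = (300.0, 500.0)
DEFAULT_HOST_TOTAL = 5.0e-4  # M
DEFAULT_GUEST_TOTAL = 5.0e-3  # M, 10 equivalents


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters for one mock host-guest system."""

    Ka: float = 10.0 ** 3.68  # M^-1
    dH_act: float = 8.35  # kcal/mol, dissociation barrier enthalpy
    dS_act: float = -17.57  # cal/(K mol)
    order_n: float = 0.3  # guest-concentration order of k_d,obs
    guest_ref: float = DEFAULT_GUEST_TOTAL  # M, reference for the order scaling
    binding_sites: int = 1
    # bound-state relaxation times per channel, s (0 = tau_M-dominated limit)
    T1M: float = 0.0
    T2M: float = 0.0
    tm_activation: float = 2.0  # kcal/mol; T_M grows with temperature
    # outer-sphere background per channel at T_ref, s^-1
    R1_os: float = 1.03
    R2_os: float = 1.38
    os_activation: float = 3.0  # kcal/mol; R_os grows towards low temperature
    # diamagnetic baselines, s^-1
    R1_0: float = 0.25
    R2_0: float = 0.40
    # reporter-solvent titration endpoints, s^-1
    R_empty: float = 2.0
    R_sat: float = 0.30
    noise_sigma: float = 0.01  # fractional Gaussian noise on intensities
    T_ref: float = T_STANDARD
    seed: int = 0

    # --- generative model -------------------------------------------------

    def kd(self, T: float, guest_total: float = DEFAULT_GUEST_TOTAL) -> float:
        """Dissociation rate constant at T (Eyring) with guest-order scaling."""
        base = eyring_rate(self.dH_act, self.dS_act, T)
        return base * (guest_total / self.guest_ref) ** self.order_n

    def tau_M(self, T: float, guest_total: float = DEFAULT_GUEST_TOTAL) -> float:
        return 1.0 / self.kd(T, guest_total)

    def _arrhenius(self, base: float, energy: float, T: float, sign: float) -> float:
        if base == 0.0:
            return 0.0
        return base * math.exp(sign * (energy / R_GAS_KCAL) * (1.0 / self.T_ref - 1.0 / T))

    def T1M_at(self, T: float) -> float:
        return self._arrhenius(self.T1M, self.tm_activation, T, +1.0)

    def T2M_at(self, T: float) -> float:
        return self._arrhenius(self.T2M, self.tm_activation, T, +1.0)

    def R_os_at(self, T: float) -> tuple[float, float]:
        # outer-sphere contribution decays with temperature (faster tumbling)
        return (self._arrhenius(self.R1_os, self.os_activation, T, -1.0),
                self._arrhenius(self.R2_os, self.os_activation, T, -1.0))

    def conditions(self, host_total: float = DEFAULT_HOST_TOTAL,
                   guest_total: float = DEFAULT_GUEST_TOTAL,
                   temperature: float = T_STANDARD) -> ExchangeConditions:
        return ExchangeConditions(host_total=host_total, guest_total=guest_total,
                                  Ka=self.Ka, temperature=temperature,
                                  binding_sites=self.binding_sites)

    # --- serialisation ----------------------------------------------------

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# regime presets -----------------------------------------------------------

def default_ground_truth(seed: int = 0, **overrides) -> GroundTruth:
    """Mn-porphyrin/viologen-like system in the pure tau_M-dominated limit."""
    return replace(GroundTruth(seed=seed), **overrides)


def slow_exchange_preset(seed: int = 0) -> GroundTruth:
    """Finite but negligible bound-state relaxation: tau_M ~ 150 * T_M at 25 C."""
    return default_ground_truth(seed, T1M=1.0e-5, T2M=1.0e-5)


def intermediate_exchange_preset(seed: int = 0) -> GroundTruth:
    """tau_M comparable to T_M: the f/tau_M simplification breaks down."""
    return default_ground_truth(seed, T1M=1.0e-3, T2M=1.0e-3)


def fast_exchange_preset(seed: int = 0) -> GroundTruth:
    """tau_M << T_M: R_p tracks T_M(T) and falls with temperature."""
    return default_ground_truth(seed, T1M=0.1, T2M=0.1)


def contaminated_preset(seed: int = 0) -> GroundTruth:
    """Channel-asymmetric outer sphere driving R2p/R1p towards 1.5 at -10 C."""
    return default_ground_truth(seed, R2_os=4.0)


#: host concentration used with the polymer-guest preset, M
VP_HOST_TOTAL = 2.4e-4


def polymer_guest_preset(seed: int = 0) -> GroundTruth:
    """Polymer-viologen-like system: weaker binding, entropy-dominated barrier.

    With host ``VP_HOST_TOTAL`` and 5 mM guest this puts R_obs/R_os near 9-11
    at 25 C — the threading-evidence regime.
    """
    return default_ground_truth(seed, Ka=1692.0, dH_act=3.17, dS_act=-36.89)


# simulators ---------------------------------------------------------------

def simulate_rp_general(gt: GroundTruth, conditions: ExchangeConditions,
                        T: float) -> tuple[float, float]:
    """General inner+outer-sphere rates R_p = f/(tau_M + T_M) + R_os per channel."""
    f = guest_bound_fraction(conditions)
    tau = gt.tau_M(T, conditions.guest_total)
    r1os, r2os = gt.R_os_at(T)
    r1 = f / (tau + gt.T1M_at(T)) + r1os if f > 0 else r1os
    r2 = f / (tau + gt.T2M_at(T)) + r2os if f > 0 else r2os
    return r1, r2


def _decay_pair(sample_id: str, r1: float, r2: float, T: float, fld: float,
                n_delays: int, sigma: float, rng: np.random.Generator,
                signal_label: str) -> list[DecaySeries]:
    t1, t2 = 1.0 / r1, 1.0 / r2
    i_inf = 1.0
    ir_t = np.geomspace(0.01 * t1, 5.0 * t1, n_delays)
    ir_y = i_inf * (1.0 - 2.0 * np.exp(-ir_t / t1))
    cp_t = np.geomspace(0.02 * t2, 3.0 * t2, n_delays)
    cp_y = i_inf * np.exp(-cp_t / t2)
    if sigma > 0:
        ir_y = ir_y + rng.normal(0.0, sigma * i_inf, n_delays)
        cp_y = cp_y + rng.normal(0.0, sigma * i_inf, n_delays)
    return [
        DecaySeries(sample_id=sample_id, experiment="inversion_recovery",
                    delays=tuple(ir_t), intensities=tuple(ir_y),
                    temperature=T, field=fld, signal_label=signal_label),
        DecaySeries(sample_id=sample_id, experiment="cpmg",
                    delays=tuple(cp_t), intensities=tuple(cp_y),
                    temperature=T, field=fld, signal_label=signal_label),
    ]


def simulate_decays(gt: GroundTruth,
                    host_total: float = DEFAULT_HOST_TOTAL,
                    guest_total: float = DEFAULT_GUEST_TOTAL,
                    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
                    fields: Sequence[float] = DEFAULT_FIELDS,
                    n_delays: int = 10,
                    noise_sigma: float | None = None,
                    signal_label: str = "meta-H",
                    rng: np.random.Generator | None = None) -> list[DecaySeries]:
    """Decay curves for the paramagnetic sample and both controls.

    For every (temperature, field) three samples are emitted, each with an
    inversion-recovery and a CPMG series:

    * ``para``      — host + guest: R = R_0 + f/(tau_M+T_M) + R_os
    * ``dia``       — guest only:   R = R_0
    * ``rotaxane``  — blocked host + guest: R = R_0 + R_os  (f forced to 0)
    """
    if n_delays < 6:
        raise ValueError("need at least 6 delays per decay curve")
    sigma = gt.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(gt.seed) if rng is None else rng
    cond = gt.conditions(host_total, guest_total)
    out: list[DecaySeries] = []
    for T in temperatures:
        r1p, r2p = simulate_rp_general(gt, cond, T)
        r1os, r2os = gt.R_os_at(T)
        for fld in fields:
            out += _decay_pair("para", gt.R1_0 + r1p, gt.R2_0 + r2p, T, fld,
                               n_delays, sigma, rng, signal_label)
            out += _decay_pair("dia", gt.R1_0, gt.R2_0, T, fld,
                               n_delays, sigma, rng, signal_label)
            out += _decay_pair("rotaxane", gt.R1_0 + r1os, gt.R2_0 + r2os, T, fld,
                               n_delays, sigma, rng, signal_label)
    return out


def simulate_rates(gt: GroundTruth,
                   host_total: float = DEFAULT_HOST_TOTAL,
                   guest_totals: Sequence[float] = (DEFAULT_GUEST_TOTAL,),
                   temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
                   fields: Sequence[float] = DEFAULT_FIELDS,
                   rate_noise: float = 0.0,
                   host_id: str = "host", guest_id: str = "guest",
                   rng: np.random.Generator | None = None) -> list[RateRecord]:
    """Rate-level records (bypassing decay curves) over a condition grid."""
    rng = np.random.default_rng(gt.seed) if rng is None else rng

    def jitter(x: float) -> float:
        return x * (1.0 + rng.normal(0.0, rate_noise)) if rate_noise > 0 else x

    out: list[RateRecord] = []
    for g in guest_totals:
        cond = gt.conditions(host_total, g)
        for T in temperatures:
            r1p, r2p = simulate_rp_general(gt, cond, T)
            r1os, r2os = gt.R_os_at(T)
            for fld in fields:
                common = dict(temperature=T, field=fld, host_total=host_total,
                              guest_total=g, host_id=host_id, guest_id=guest_id,
                              stderr_R1=rate_noise * (gt.R1_0 + r1p),
                              stderr_R2=rate_noise * (gt.R2_0 + r2p))
                out.append(RateRecord(condition="paramagnetic",
                                      R1_obs=jitter(gt.R1_0 + r1p),
                                      R2_obs=jitter(gt.R2_0 + r2p), **common))
                out.append(RateRecord(condition="diamagnetic",
                                      R1_obs=jitter(gt.R1_0),
                                      R2_obs=jitter(gt.R2_0), **common))
                out.append(RateRecord(condition="blocked_rotaxane",
                                      R1_obs=jitter(gt.R1_0 + r1os),
                                      R2_obs=jitter(gt.R2_0 + r2os), **common))
    return out


def simulate_titration(gt: GroundTruth,
                       host_total: float = DEFAULT_HOST_TOTAL,
                       guest_grid: Sequence[float] | None = None,
                       temperature: float = T_STANDARD,
                       noise_sigma: float | None = None,
                       rng: np.random.Generator | None = None):
    """Reporter-solvent titration points from the ground-truth Ka.

    The default guest grid spans 0 to 20 equivalents of the host (the fit
    needs sub- to super-stoichiometric coverage).
    """
    from .binding import TitrationPoint

    sigma = gt.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(gt.seed) if rng is None else rng
    if guest_grid is None:
        guest_grid = tuple(np.concatenate([
            [0.0], np.geomspace(0.2, 20.0, 11) * host_total]))
    pts = []
    for g in guest_grid:
        r = predict_reporter_rate(gt.Ka, gt.R_empty, gt.R_sat, host_total, g)
        if sigma > 0:
            r += rng.normal(0.0, sigma * gt.R_empty)
        pts.append(TitrationPoint(guest_total=g, host_total=host_total,
                                  reporter_R1_obs=r, stderr=sigma * gt.R_empty,
                                  temperature=temperature))
    return pts
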
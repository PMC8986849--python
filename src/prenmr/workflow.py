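"""End-to-end study driver: CSV inputs -> binding/kinetics/thermodynamics report.

Stage order mirrors the measurement logic: decay fits give observed rates;
rate arithmetic strips the diamagnetic and outer-sphere backgrounds; the
regime diagnostics gate whether exchange kinetics may be read off; the
titration supplies Ka (and hence the bound fraction f); residence times are
order-corrected and regressed on an Eyring line; threading rates follow
from Ka = k_on/k_d.  Kinetics are refused when the diagnostics verdict is
not ``tau_M_dominated`` unless ``force`` is set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import binding, exchange, pre_rates, relaxometry, synthetic, thermo
from .constants import T_STANDARD
from .exceptions import AnalysisError, RegimeGateError

log = logging.getLogger("prenmr")

#: how sample_id values in decay CSVs map onto rate-record conditions
DEFAULT_SAMPLE_MAP = {
    "para": "paramagnetic",
    "dia": "diamagnetic",
    "rotaxane": "blocked_rotaxane",
}

REPORT_SCHEMA_VERSION = 1


@dataclass
class StudyConfig:
    """Validated description of one study's inputs and settings."""

    decays_csv: str | None = None
    rates_csv: str | None = None
    conc_rates_csv: str | None = None  # concentration series for the order fit
    titration_csv: str | None = None
    host_id: str = "host"
    guest_id: str = "guest"
    host_total: float = synthetic.DEFAULT_HOST_TOTAL
    guest_total: float = synthetic.DEFAULT_GUEST_TOTAL
    guest_ref: float | None = None  # defaults to guest_total
    Ka: float | None = None  # used when no titration data are given
    order_n: float | None = None  # override; otherwise fitted from conc series
    binding_sites: int = 1
    reporting_temperature: float = T_STANDARD
    ratio_band: tuple[float, float] = pre_rates.DEFAULT_RATIO_BAND
    field_tol: float = pre_rates.DEFAULT_FIELD_TOL
    min_factor: float = pre_rates.DEFAULT_MIN_FACTOR
    mc_draws: int = 2000
    seed: int = 0
    force: bool = False
    sample_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SAMPLE_MAP))

    def validate(self) -> None:
        for name in ("decays_csv", "rates_csv", "conc_rates_csv", "titration_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")
        if self.decays_csv is None and self.rates_csv is None \
                and self.titration_csv is None:
            raise ValueError("config references no input data at all")


def load_config(path) -> StudyConfig:
    """Load a YAML study config; relative paths resolve against the file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if "ratio_band" in raw:
        raw["ratio_band"] = tuple(raw["ratio_band"])
    cfg = StudyConfig(**raw)
    for name in ("decays_csv", "rates_csv", "conc_rates_csv", "titration_csv"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).is_absolute():
            setattr(cfg, name, str(path.parent / p))
    cfg.validate()
    return cfg


def rates_from_decays(series: list[relaxometry.DecaySeries],
                      sample_map: dict[str, str] | None = None,
                      host_total: float = 0.0, guest_total: float = 0.0,
                      host_id: str = "", guest_id: str = "",
                      ) -> list[pre_rates.RateRecord]:
    """Fit every decay series and assemble per-condition rate records.

    Series are keyed by (sample_id, temperature, field); each key needs one
    inversion-recovery (R1) and one CPMG (R2) series.
    """
    sample_map = dict(DEFAULT_SAMPLE_MAP) if sample_map is None else sample_map
    grouped: dict[tuple, dict[str, relaxometry.RelaxationFitResult]] = {}
    for s in series:
        fit = relaxometry.fit_decay(s)
        if not fit.converged:
            raise AnalysisError(
                f"decay fit failed for {s.sample_id} {s.experiment} at "
                f"{s.temperature} K / {s.field} MHz: {'; '.join(fit.warnings)}")
        grouped.setdefault((s.sample_id, s.temperature, s.field), {})[s.experiment] = fit
    records = []
    for (sid, T, fld), fits in sorted(grouped.items()):
        if "inversion_recovery" not in fits or "cpmg" not in fits:
            raise AnalysisError(
                f"missing paired experiment for sample {sid!r} at {T} K / {fld} MHz")
        if sid not in sample_map:
            raise AnalysisError(f"sample_id {sid!r} has no condition mapping")
        r1, r2 = fits["inversion_recovery"], fits["cpmg"]
        records.append(pre_rates.RateRecord(
            condition=sample_map[sid], R1_obs=r1.rate, R2_obs=r2.rate,
            stderr_R1=r1.stderr_rate, stderr_R2=r2.stderr_rate,
            temperature=T, field=fld, host_total=host_total,
            guest_total=guest_total, host_id=host_id, guest_id=guest_id))
    log.info("fitted %d decay series into %d rate records", len(series), len(records))
    return records


def _pair_records(records: list[pre_rates.RateRecord]) -> list[pre_rates.PRERates]:
    """Pair para/dia/rotaxane records per (T, field, guest) and build R_inner."""
    def key(r):
        return (round(r.temperature, 1), r.field, r.guest_total)

    by_cond: dict[str, dict[tuple, pre_rates.RateRecord]] = {}
    for r in records:
        by_cond.setdefault(r.condition, {})[key(r)] = r
    out = []
    for k, para in sorted(by_cond.get("paramagnetic", {}).items()):
        dia = by_cond.get("diamagnetic", {}).get(k)
        if dia is None:
            raise AnalysisError(f"missing diamagnetic control for (T, field, guest) = {k}")
        rp = pre_rates.compute_Rp(para, dia)
        rot = by_cond.get("blocked_rotaxane", {}).get(k)
        if rot is not None:
            rp = pre_rates.correct_outer_sphere(rp, rot, dia)
        out.append(rp)
    return out


def run_pipeline(config: StudyConfig) -> dict[str, Any]:
    """Execute all stages the config has data for; returns the study report."""
    config.validate()
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "host": config.host_id, "guest": config.guest_id,
        "reporting_temperature_K": config.reporting_temperature,
    }

    # --- observed rates ---------------------------------------------------
    records: list[pre_rates.RateRecord] = []
    if config.decays_csv:
        series = relaxometry.read_decays_csv(config.decays_csv)
        records += rates_from_decays(series, config.sample_map,
                                     config.host_total, config.guest_total,
                                     config.host_id, config.guest_id)
    if config.rates_csv:
        records += pre_rates.read_rates_csv(config.rates_csv)

    diagnostics = None
    prer: list[pre_rates.PRERates] = []
    if records:
        prer = _pair_records(records)
        log.info("R_p = R_obs - R_0 and R_inner = R_p - R_os computed "
                 "for %d condition points", len(prer))
        temps = {p.temperature for p in prer}
        if len(temps) >= 3:
            diagnostics = pre_rates.diagnose_regime(
                prer, ratio_band=config.ratio_band, field_tol=config.field_tol)
            log.info("regime diagnostics verdict: %s", diagnostics.verdict)
            report["diagnostics"] = {
                "verdict": diagnostics.verdict,
                "slope_lnR1p_vs_T": diagnostics.slope_lnR1p_vs_T,
                "field_independent": diagnostics.field_independent,
                "max_field_discrepancy": diagnostics.max_field_discrepancy,
                "ratio_R2p_R1p": {f"{t:.2f}": v for t, v
                                  in diagnostics.ratio_R2p_R1p.items()},
                "ratio_R2p_R1p_corrected": (
                    {f"{t:.2f}": v for t, v
                     in diagnostics.ratio_R2p_R1p_corrected.items()}
                    if diagnostics.ratio_R2p_R1p_corrected else None),
                "notes": diagnostics.notes,
            }

        # threading evidence at the temperature closest to the reporting one
        rot = [r for r in records if r.condition == "blocked_rotaxane"]
        par = [r for r in records if r.condition == "paramagnetic"]
        if rot and par:
            tref = config.reporting_temperature
            best = min(par, key=lambda r: abs(r.temperature - tref))
            match = [r for r in rot if abs(r.temperature - best.temperature) <= 0.5
                     and r.field == best.field]
            if match:
                ev = pre_rates.exchange_evidence(best, match[0], config.min_factor)
                report["threading_evidence"] = {
                    "temperature_K": best.temperature,
                    "ratio_R1": ev.ratio_R1, "ratio_R2": ev.ratio_R2,
                    "threading": ev.threading, "min_factor": ev.min_factor,
                }

    # --- binding ----------------------------------------------------------
    ka = config.Ka
    if config.titration_csv:
        points = binding.read_titration_csv(config.titration_csv)
        fit = binding.fit_titration(points, mc_draws=config.mc_draws,
                                    seed=config.seed)
        ka = fit.Ka
        log.info("titration fit: log Ka = %.3f, dG = %.2f kcal/mol",
                 fit.logKa, fit.dG)
        report["binding"] = {
            "logKa": fit.logKa, "logKa_err": fit.stderr_logKa,
            "logKa_err_mc": fit.mc_stderr_logKa,
            "Ka_Minv": fit.Ka, "dG_kcal": fit.dG, "dG_err": fit.stderr_dG,
            "R_empty": fit.R_empty, "R_sat": fit.R_sat,
            "n_points": fit.n_points,
        }

    # --- exchange kinetics (gated) ----------------------------------------
    if prer and ka is not None:
        verdict = diagnostics.verdict if diagnostics else "tau_M_dominated"
        if verdict != "tau_M_dominated" and not config.force:
            report["kinetics_refused"] = (
                f"diagnostics verdict {verdict!r}; pass force=True to override")
            log.warning("kinetics refused: %s", report["kinetics_refused"])
            return report

        guest_ref = config.guest_ref or config.guest_total

        # reaction order from the concentration series, if provided
        order_n, order_err = config.order_n, None
        if order_n is None and config.conc_rates_csv:
            conc_records = pre_rates.read_rates_csv(config.conc_rates_csv)
            conc_prer = _pair_records(conc_records)
            pairs = []
            for p in conc_prer:
                cond = exchange.ExchangeConditions(
                    host_total=config.host_total, guest_total=p.guest_total,
                    Ka=ka, temperature=p.temperature,
                    binding_sites=config.binding_sites)
                f = exchange.guest_bound_fraction(cond)
                r_inner = p.R1_inner if p.R1_inner is not None else p.R1_p
                pairs.append((p.guest_total, r_inner / f))
            order_n, order_err = exchange.estimate_reaction_order(pairs)
            log.info("guest-concentration order n = %.3f +- %.3f", order_n,
                     order_err)
        if order_n is None:
            order_n = 0.0
        report["order_n"] = order_n
        if order_err is not None:
            report["order_n_err"] = order_err

        rows = []
        for T in sorted({p.temperature for p in prer}):
            pts = [p for p in prer if p.temperature == T]
            r_inner = float(np.mean([
                p.R1_inner if p.R1_inner is not None else p.R1_p for p in pts]))
            err = float(np.mean([
                (p.stderr_R1_inner if p.stderr_R1_inner is not None
                 else p.stderr_R1_p) for p in pts])) / np.sqrt(len(pts))
            cond = exchange.ExchangeConditions(
                host_total=config.host_total, guest_total=config.guest_total,
                Ka=ka, temperature=T, binding_sites=config.binding_sites)
            res = exchange.exchange_from_inner_rate(
                r_inner, cond, verdict, order_n=order_n, guest_ref=guest_ref,
                stderr_R_inner=err, force=config.force)
            rows.append(res)
            log.info("T = %.1f K: f = %.4f, tau_M = %.3e s, kd_obs = %.1f, "
                     "kd = %.1f s^-1", T, res.f, res.tau_M, res.kd_obs, res.kd)
        report["exchange"] = [
            {"temperature_K": r.temperature, "f": r.f, "tau_M_s": r.tau_M,
             "kd_obs": r.kd_obs, "kd": r.kd, "kd_err": r.stderr_kd,
             "order_n": r.order_n}
            for r in rows
        ]

        # --- Eyring: dissociation ----------------------------------------
        if len(rows) >= 3:
            fitk = thermo.eyring_fit([(r.temperature, r.kd) for r in rows])
            trep = config.reporting_temperature
            report["dissociation"] = {
                "dH_kcal": fitk.dH, "dH_err": fitk.stderr_dH,
                "dS_cal": fitk.dS, "dS_err": fitk.stderr_dS,
                "dG_kcal": fitk.dG_at(trep), "dG_err": fitk.stderr_dG_at(trep),
                "n_points": fitk.n_points,
            }
            log.info("Eyring (dissociation): dH = %.2f kcal/mol, dS = %.2f "
                     "cal/K/mol, dG(%.2f K) = %.2f kcal/mol",
                     fitk.dH, fitk.dS, trep, fitk.dG_at(trep))

            # --- threading: kon = Ka * kd --------------------------------
            kon_pts = [(r.temperature, ka * r.kd) for r in rows]
            fit_on = thermo.eyring_fit(kon_pts)
            kd_rep = thermo.eyring_rate(fitk.dH, fitk.dS, trep)
            kon_rep, _ = thermo.kon_from_Ka_kd(ka, kd_rep)
            report["threading"] = {
                "kon_Minv_s": kon_rep,
                "dG_on_kcal": thermo.dG_from_rate(kon_rep, trep),
                "dH_on_kcal": fit_on.dH, "dH_on_err": fit_on.stderr_dH,
                "dS_on_cal": fit_on.dS, "dS_on_err": fit_on.stderr_dS,
            }
            log.info("threading: kon(%.2f K) = %.3g M^-1 s^-1, dG_on = %.2f "
                     "kcal/mol", trep, kon_rep, report["threading"]["dG_on_kcal"])
    return report


# --- report rendering -----------------------------------------------------

_BINDING_COLS = ["host", "guest", "logKa", "logKa_err", "dG_kcal", "dG_err"]
_ACTIVATION_COLS = ["host", "guest", "dH_kcal", "dH_err", "dS_cal", "dS_err",
                    "dG_kcal", "dG_err"]
_THREADING_COLS = ["host", "guest", "kon_Minv_s", "dH_on_kcal", "dH_on_err",
                   "dS_on_cal", "dS_on_err", "dG_on_kcal"]
_EXCHANGE_COLS = ["temperature_K", "f", "tau_M_s", "kd_obs", "kd", "kd_err",
                  "order_n"]


def render_tables(report: dict[str, Any], outdir) -> dict[str, Path]:
    """Write the report as deterministic CSV tables plus a JSON document.

    Emits binding/activation/threading tables shaped like the customary
    host-guest summary tables, an exchange-results table, and report.json
    (which round-trips losslessly through ``json.load``).  Sections absent
    from the report produce empty-but-valid files with headers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    host, guest = report.get("host", ""), report.get("guest", "")
    paths: dict[str, Path] = {}

    def _write(name: str, cols: list[str], rows: list[dict]) -> None:
        df = pd.DataFrame(rows, columns=cols)
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    b = report.get("binding")
    _write("binding_table", _BINDING_COLS,
           [{"host": host, "guest": guest, "logKa": b["logKa"],
             "logKa_err": b["logKa_err"], "dG_kcal": b["dG_kcal"],
             "dG_err": b["dG_err"]}] if b else [])
    d = report.get("dissociation")
    _write("activation_table", _ACTIVATION_COLS,
           [{"host": host, "guest": guest, **{k: d[k] for k in
             ("dH_kcal", "dH_err", "dS_cal", "dS_err", "dG_kcal", "dG_err")}}]
           if d else [])
    t = report.get("threading")
    _write("threading_table", _THREADING_COLS,
           [{"host": host, "guest": guest, **{k: t[k] for k in
             ("kon_Minv_s", "dH_on_kcal", "dH_on_err", "dS_on_cal",
              "dS_on_err", "dG_on_kcal")}}] if t else [])
    _write("exchange_results", _EXCHANGE_COLS, report.get("exchange", []))

    p = outdir / "report.json"
    p.write_text(json.dumps(report, indent=2, default=float) + "\n")
    paths["report"] = p
    return paths


def write_mock_study(outdir, gt: synthetic.GroundTruth | None = None,
                     temperatures=synthetic.DEFAULT_TEMPERATURES,
                     fields=synthetic.DEFAULT_FIELDS,
                     conc_grid=(2.5e-3, 5.0e-3, 1.0e-2, 2.0e-2),
                     n_delays: int = 10) -> Path:
    """Materialise a complete mock study directory with ground-truth sidecar.

    Writes decays.csv (temperature/field grid), conc_rates.csv (guest
    concentration series at 25 C for the order fit), titration.csv,
    ground_truth.json and config.yaml; returns the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt = synthetic.default_ground_truth() if gt is None else gt
    rng = np.random.default_rng(gt.seed)

    decays = synthetic.simulate_decays(gt, temperatures=temperatures,
                                       fields=fields, n_delays=n_delays, rng=rng)
    relaxometry.write_decays_csv(decays, outdir / "decays.csv")
    conc = synthetic.simulate_rates(
        gt, guest_totals=conc_grid, temperatures=(T_STANDARD,),
        fields=fields[:1], rate_noise=0.0, rng=rng)
    pre_rates.write_rates_csv(conc, outdir / "conc_rates.csv")
    titr = synthetic.simulate_titration(gt, rng=rng)
    binding.write_titration_csv(titr, outdir / "titration.csv")
    gt.to_json(outdir / "ground_truth.json")

    cfg = {
        "decays_csv": "decays.csv",
        "conc_rates_csv": "conc_rates.csv",
        "titration_csv": "titration.csv",
        "host_id": "Mn-cage", "guest_id": "viologen",
        "host_total": synthetic.DEFAULT_HOST_TOTAL,
        "guest_total": synthetic.DEFAULT_GUEST_TOTAL,
        "seed": gt.seed,
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path
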
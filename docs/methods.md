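# Methods

## Model and assumptions

The package analyses two-site chemical exchange between a free guest (or
reporter solvent) and a paramagnetic host cavity. The observed relaxation
rate of the free species is

    R_obs = R_0 + R_p,      R_p = f / (tau_M + T_M) + R_os

per channel (longitudinal R_1, transverse R_2). `R_0` is the diamagnetic
baseline measured on a host-free sample; `R_os` is the outer-sphere
contribution measured on a control whose cavity is permanently blocked (a
rotaxane of the same metallohost), so no microscopic outer-sphere theory is
needed; `f` is the bound mole fraction of the observed species, from exact
1:1 mass action; `tau_M` is the mean residence time of the bound guest and
`T_M` its bound-state relaxation time.

The kinetic read-out uses the slow-to-intermediate-exchange simplification
`R_p ≈ f/tau_M + R_os`, valid when `tau_M >> T_M`. Because `T_M` is not
observable in this design, validity is established operationally by three
diagnostics on a temperature/field grid of `R_p`:

1. `d R_p / dT > 0` — exchange accelerates with temperature, so a
   residence-time-limited `R_p` must rise; bound-state relaxation (`T_M`
   dominated) instead falls with temperature.
2. `R_p` independent of spectrometer field — `tau_M` is field-independent,
   `T_M` is not.
3. `R_2,p ≈ R_1,p` — both channels see the same residence-time bottleneck.

Kinetics are gated on the verdict: `residence_time` demands the
`tau_M_dominated` verdict (or an explicit `force`).

Assumptions inherited by every downstream number: 1:1 stoichiometry with one
cavity per host (a `binding_sites` multiplier exists for generality); `K_a`
treated as temperature-independent across the kinetic series (a
per-temperature override is accepted); reporter response linear in host
occupancy (fast solvent exchange averages inner- and outer-sphere rates in
population proportion); transmission coefficient κ = 1 in the Eyring
pre-factor; 1 M standard state both for ΔG of binding and, implicitly, when
a barrier is assigned to a bimolecular k_on via
ΔG‡ = −RT ln(k_on·h/(k_B·T)) — the numeric value of k_on is used, which is
the customary convention for that identity and is documented as a caveat
rather than "corrected".

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| ratio band for R_2,p/R_1,p | — | [0.67, 1.3] | the failure value reported for cold, uncorrected data is ~1.5; 1.3 keeps a margin below it, the band is symmetric on the log scale |
| contamination threshold | — | 1.5 | uncorrected ratios at this level signal outer-sphere dominance at low temperature |
| field tolerance | relative | 0.15 | separates genuine field dependence from scatter between 300- and 500-MHz-class measurements |
| threading min_factor | — | 3 | positive threading cases sit near 9–12×, no-exchange controls at ~1×; 3 separates them decisively |
| temperature pairing tolerance | K | 0.5 | VT calibration accuracy |
| reporting temperature | K | 298.15 | "25 °C" convention of the summary tables (298 K accepted via argument) |
| gas constant | kcal mol⁻¹ K⁻¹ | 1.98720425e−3 | CODATA; kcal/cal units follow the field's tables |
| titration MC draws | — | 2000 | residual-resampling error bars stable to <5 % run-to-run |
| guest_ref for order correction | M | the series' own guest concentration (5 mM default) | keeps k_d in s⁻¹; a declared reference replaces fractional-molar units |

One global reaction order `n` per system is used to correct `k_d,obs` across
the temperature series (estimated at one temperature from a concentration
series); a per-temperature order is possible by calling `correct_kd`
directly.

## Numerical choices

* Decay fits are nonlinear least squares on the raw intensity scale
  (`scipy.optimize.curve_fit`). Inversion recovery is a 3-parameter fit
  `I_inf·(1 − B·e^{−t/T1})` with the inversion factor B free (imperfect
  inversion is the norm; B is reported for QC). CPMG is 2-parameter
  `I_0·e^{−t/T2}` with an optional baseline offset. Initial values: T from
  the half-crossing delay divided by ln 2; amplitudes from the endpoints.
  A series whose span is below 5× the second-difference noise estimate is
  refused (`converged=False`) instead of fitted. Standard errors come from
  the Jacobian-based covariance at the optimum. A weighted log-linear slope
  is reported for CPMG as an independent cross-check (weights ∝ intensity,
  the usual correction for log-transformed homoscedastic noise).
* The bound-host fraction uses the cancellation-safe quadratic root
  `[HG] = 2HG / (b + sqrt(b² − 4HG))`, `b = H + G + 1/K_a`, verified against
  a brute-force root solve to ≤1e−10.
* The titration fit optimises (log10 K_a, R_empty, R_sat) with `lmfit`;
  log-parameterising K_a conditions the problem. Identifiability guard: if
  host occupancy at the optimum never crosses the 20–80 % window the fit is
  rejected as unidentifiable. Errors are reported both by the delta method
  and by seeded Monte-Carlo residual resampling.
* Rate arithmetic (R_p = R_obs − R_0, R_inner = R_p − R_os) propagates
  uncertainties in quadrature; negative differences within 2 combined
  standard errors clamp to zero with a flag, larger ones raise (inconsistent
  controls).
* Eyring regression is (weighted) linear least squares of ln(k/T) on 1/T;
  parameters and their covariance transform linearly from the slope and
  intercept. At least 3 *distinct* temperatures are required; duplicate-only
  designs raise a degenerate-design error.
* Verdict resolution when checks disagree: a non-positive temperature slope
  → `fast_exchange_suspected`; ratios above the band (or uncorrected ratios
  reaching 1.5) → `outer_sphere_contaminated`; ratios below the band or a
  field-dependent R_1,p → `fast_exchange_suspected`.

## What the generator emulates — and what it does not

`synthetic.GroundTruth` drives every input from a single parameter set:
`tau_M(T)` from transition-state kinetics (ΔH‡ = 8.35 kcal/mol,
ΔS‡ = −17.57 cal K⁻¹ mol⁻¹ by default, a Mn-porphyrin/viologen-like
system), scaled by `(G/G_ref)^n` with n = 0.3; `T_M(T)` and `R_os(T)` with
mild Arrhenius-type temperature factors (T_M lengthens, R_os grows towards
low temperature — a rotational-correlation proxy); binding from
log K_a = 3.68; homoscedastic fractional Gaussian noise on decay
intensities (1 % default). Default conditions: host 0.5 mM, guest 5 mM
(10 equivalents), −10 to 70 °C, 300 and 500 MHz. Presets cover the pure
Eq.-2 limit (`T_M = 0`, the default), slow (`tau_M ≈ 150·T_M`),
intermediate (`tau_M ≈ 1.5·T_M`), fast (`tau_M << T_M`), a channel-
asymmetric outer sphere that drives R_2,p/R_1,p to ~1.5 at −10 °C, and a
weaker-binding polymer-guest system (K_a = 1692 M⁻¹, entropy-dominated
barrier) whose observed/outer-sphere ratio sits in the 9–11× threading-
evidence regime.

Not emulated: FIDs, pulse sequences, peak overlap/phasing, temperature-
dependent K_a, J-modulation artifacts, field-dependent T_M, and
heteroscedastic or correlated noise. Passing recovery tests therefore show
that the analysis chain is correct and unbiased under its own model
assumptions — not that those assumptions hold for any particular real
sample; on real data the regime diagnostics are the guard.

Problem sizes used by the test suite and acceptance script — 9 temperatures
× 2 fields × 3 samples × 2 experiments × 10 delays per study, 12-point
titrations, 4-point concentration series, 50 replicate seeds for the noisy
recovery study — were chosen so a full study is a few hundred fits and the
whole validation runs in seconds on one core.

## Known limitations and open choices

* The intermediate-exchange preset passes the diagnostics when `T_1M = T_2M`
  exactly (symmetric `T_M` keeps R_2,p/R_1,p = 1 and the slope positive):
  the three requirements are necessary, not sufficient. Real systems break
  the symmetry (T_2M < T_1M), which is what check 3 exploits; the fast
  preset is detected through the negative temperature slope.
* The order correction normalises to a reference concentration,
  `k_d = k_d,obs·(G_ref/G)^n`, rather than dividing by `[G]^n`; this keeps
  s⁻¹ units at the cost of making `k_d` conditional on the declared
  reference (the series' own standard concentration by default).
* `exchange_evidence` compares raw observed rates (paramagnetic sample vs
  blocked-rotaxane sample) without subtracting `R_0`, matching how the
  ratio is quoted in practice; with the small diamagnetic baselines typical
  here the distinction moves the ratio by well under its decision margin.
* When a study provides no temperature series (e.g. binding-only data) no
  diagnostics verdict exists; the pipeline then skips kinetics rather than
  guessing a regime.
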
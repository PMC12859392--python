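# Methods

## Pharmacokinetic model and its assumptions

`tacmipd` predicts whole-blood tacrolimus concentrations with a
one-compartment model with first-order absorption and elimination,
parameterized on the elimination rate constant `ke` (1/h), the apparent
volume of distribution `V` (L), and a fixed absorption rate constant
`ka = 3.43/h`. Oral and enteral doses are treated identically as
instantaneous inputs to a depot compartment. Bioavailability is not
separately identifiable from oral data and is absorbed into `V` (V ≡ V/F).
There is no lag time, no inter-occasion variability, and elimination is
linear; IV infusions and multi-compartment disposition are out of scope.

Within any span of constant parameters the depot/central system has the
exact solution

    gut(t+dt)     = gut(t)·e^(−ka·dt)
    central(t+dt) = central(t)·e^(−ke·dt) + gut(t)·ka/(ka−ke)·(e^(−ke·dt) − e^(−ka·dt))

so the engine walks dose events, covariate changes, and query times in order
and propagates the state segment by segment with no numeric integration.
Amounts are mg, volumes L; the single mg/L → ng/mL conversion (×1000) lives
in `engine.mgl_to_ngml`. Because the closed form divides by `ka − ke`, an
individual `ke` within 1e−6 relative distance of `ka` (flip-flop kinetics)
is rejected rather than evaluated.

Conventions chosen where practice is ambiguous:

* **Trough convention.** A concentration queried exactly at a dose time is
  the pre-dose value, matching how therapeutic drug monitoring troughs are
  drawn.
* **Time-varying covariates** are piecewise-constant and right-continuous: a
  covariate state applies from its effective time onward, the PK state is
  carried across the boundary, and each segment uses its own closed form.
  This matches EMR covariate records; no interpolation is attempted.
* **Steady state** is defined operationally as the trough after 200
  identical doses (covariates frozen at the last observed state). The
  analytic infinite-superposition trough is also exposed
  (`steady_state_trough_exact`) and the two agree to better than 1e−6
  relative whenever `ke·τ` is not vanishingly small.

## Covariate model

Age enters `V` and creatinine clearance and fluconazole co-therapy enter
`ke`:

    ke = theta_ke · (CrCl/CrCl_ref)^beta_crcl · beta_flu^[fluconazole] · exp(eta_ke)
    V  = theta_V  · (age/age_ref)^beta_age · exp(eta_V)

Power laws on the continuous covariates and a multiplicative fraction for
fluconazole are the standard pharmacometric parameterization; all
coefficients and the reference values (defaults `CrCl_ref` = 120
mL/min/1.73 m², `age_ref` = 5.7 y, the cohort medians) are config-driven.
Every downstream check (engine fidelity, dose targeting, ETA recovery) holds
for any positive-parameter instantiation, so correctness does not hinge on
one particular published coefficient set.

The demo model (`tacmipd.demo_model()`, also `examples/model_illustrative.yaml`)
is **illustrative, not clinical**: `theta_ke` = 0.08/h, `theta_V` = 75 L,
`beta_crcl` = 0.35, `beta_flu` = 0.7 (fluconazole inhibits CYP3A-mediated
clearance), `beta_age` = 0.8, `omega_ke` = 0.40, `omega_V` = 0.35 (log-scale
SDs, i.e. ~40%/35% between-subject CV), `sigma_add` = 1.5 ng/mL. These were
chosen once as pharmacologically plausible for pediatric oral tacrolimus —
a typical 0.05 mg/kg q12h regimen yields troughs near the 10–14 ng/mL
range — and are what the self-validation protocol uses. The CLI refuses to
fit or dose without an explicit model file.

## MAP individualization

With additive residual error and a diagonal between-subject covariance, the
posterior mode of `(eta_ke, eta_V)` minimizes

    OFV(eta) = Σ_i (C_obs,i − C_pred,i(eta))²/sigma_add² + eta_ke²/omega_ke² + eta_V²/omega_V²

Constant terms (ln sigma², ln omega²) are dropped: sigma and omega are fixed
during individualization, so they shift the objective without moving the
minimizer. Observations below the assay's linear floor (1 ng/mL) are
excluded with a warning; no below-quantification-limit likelihood method is
applied. A patient with no usable observations yields an explicit
"prior-only" result (eta = 0) rather than a silent one.

The minimizer is coordinate descent: bounded Brent line searches over
`eta_ke` then `eta_V` on [−5ω, +5ω] (bracket doubled when the minimizer
lands on a bound), starting from the prior mode (0, 0), sweeping until the
objective improves by less than 1e−10. Two numerical choices deserve note:

* **Pattern acceleration** (on by default). When many troughs inform the
  fit, the likelihood creates a narrow valley in which `eta_ke` and `eta_V`
  are strongly correlated, and pure axis-aligned descent zigzags with a
  per-sweep contraction so close to 1 that thousands of sweeps still leave a
  visible gap to the minimum. After each sweep, one extra bounded line
  search along the sweep's net displacement (the classic pattern move)
  removes the stall; fits then converge in ~10–20 sweeps. The method remains
  a deterministic sequence of 1-D minimizations, monotone in the objective.
* **Tie-breaking.** A candidate step is accepted only on strict improvement,
  so on a flat stretch the current (more shrunken, closer-to-zero) eta is
  kept and output is deterministic.

The sweep cap is 5000 (a safety net — the accelerated method never
approaches it); a fit that exhausts it is returned flagged
`converged=False`, never as an unflagged answer.

## Dose suggestion

The PK is linear in dose, so the dose attaining a target steady-state trough
is `target / trough(1 mg probe)` with the probe trough computed by the
200-dose simulation at the patient's last-observed covariates and MAP
parameters. The suggestion is cross-checked internally by re-simulating 200
doses of the suggested amount and must land within 1e−6 relative of target
before any rounding; a practical rounding increment (e.g. 0.1 mg for
suspensions) is optional, off by default, and reported separately from the
exact dose. Defaults: target 12 ng/mL, interval 12 h, therapeutic range
10–14 ng/mL — all configurable.

## Virtual cohort generator

`validation.generate_cohort` emulates the retrospective study population
used to validate the original tool: 30 covariate/dosing templates × 10
random-effect draws = 300 simulated patient datasets. Per template: age is
log-uniform on 0.1–17.7 y; creatinine clearance log-normal with median 122.4
mL/min/1.73 m² (log-SD 0.5) truncated to 15.6–442.2; fluconazole use is
Bernoulli(0.5), discontinued mid-history at a dose boundary with probability
0.3 when present; dosing is 0.05 mg/kg every 12 h (weight from a smooth
pediatric weight-for-age curve) for 2–50 doses; 1–21 trough sampling times
are drawn from the pre-dose instants. Per replicate, `eta ~ N(0, ω²)` and
troughs get additive `N(0, sigma_add²)` noise truncated at zero. Everything
derives from one `numpy` generator seeded by the spec, so cohorts are
byte-reproducible.

What this emulates — and what it does not: the generator reproduces the
*design* (sample sizes, covariate ranges, sampling pattern) of a real TDM
cohort, under exactly the model the fitter assumes. Passing validation
therefore demonstrates mathematical fidelity (engine vs independent
integrator, dose solver vs target, optimizer vs grid reference), not
predictive performance on real children, where model misspecification,
dosing-record errors, within-day variability, and CRRT-like physiology the
model does not encode all intrude.

## Validation protocol and oracles

Three tests, reported as max/mean percent differences
(100·|a − b|/|b| with the oracle or target as denominator b):

1. **Engine fidelity**: individual `ke`/`V` versus an independently coded
   parameter map, and predicted concentrations at the sampling times versus
   an adaptive numeric integrator (DOP853, rtol 1e−10) of the piecewise ODE
   system.
2. **Dose-target attainment**: suggested 12-h dose per patient, 200 doses
   simulated, trough versus the 12 ng/mL target.
3. **ETA fidelity**: coordinate-descent MAP ETAs versus a dense-grid
   (81×81 over ±5ω) minimizer with nested walk-and-shrink refinement,
   compared after exponentiation (how they act on `ke` and `V`). Mirroring a
   per-subject comparison, one replicate per template with ≥3 usable troughs
   is fitted, topped up to 30 patients.

The oracles deliberately share no code with the engine or estimator (an
import-boundary test enforces this). The grid oracle exploits the model's
structure — the central amount depends only on `eta_ke` and the volume only
on `eta_V` — to evaluate the whole surface by one vectorized recursion; its
refinement re-centers the window at constant width whenever the incumbent
lands on a window edge (so it can travel along the likelihood valley) and
shrinks to ±1 cell otherwise, down to a grid step of 1e−8, an order tighter
than any assertion made against it.

The report compares each row against the regression bounds in
`validation.REFERENCE_BOUNDS` (maximum percent differences of 0.00997 for
`ke`, 0.00803 for `V`, 0.0155 for concentration, 0.0407 for dose-target
deviation, and 0.211/0.230 for the exponentiated ETAs). A correct
implementation sits orders of magnitude below them — observed maxima are
~1e−13 % (parameters, dose target), ~1e−8 % (concentrations, limited by the
ODE oracle's tolerance), and ~3e−3 % (ETAs, limited by the two optimizers'
termination rules) — so a breach signals a regression, not imprecision.

## Problem sizes and runtime

Default problem sizes are the protocol's own: 300 simulated patients for the
engine and dose tests, 30 fitted patients for the ETA test, 200 doses per
steady-state evaluation. The full protocol (`tacmipd validate` or
`scripts/acceptance.py`) completes in well under a minute on a single core;
the dominant costs are the numeric ODE oracle and the 30 grid fits.

## Known limitations

* Point MAP estimates only — no posterior uncertainty on eta, no FOCE.
* No handling of concentrations above the assay's linear range (40 ng/mL)
  beyond flagging; no BLQ likelihood method below 1 ng/mL.
* Times are decimal hours since first dose (a datetime converter utility is
  provided); datasets are CSV only.
* The generator draws covariates to be plausible, not distribution-matched
  to any real cohort beyond medians and ranges.
* Not intended for patients on continuous renal replacement therapy, where
  creatinine clearance stops being a usable surrogate covariate.
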
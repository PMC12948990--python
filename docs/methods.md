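# Methods

## Model

The digital twin is a third-order impulsive ODE per subject:

    dx1/dt = (a − n)·x1 − E(x3)·x1
    dx2/dt = n·x1 + E(x3)·x1 − w·x2
    dx3/dt = −c·x3 − k1·x3/(k2 + x3)
    E(x)   = b·x/(ED50 + x)

`x1` is proliferating tumor volume (mm³), `x2` dead volume still part of
the palpable mass, `x3` the circulating drug level in injected-dose
equivalents (mg/kg).  The modelled phenomena are exponential proliferation
(`a`), spontaneous necrosis (`n`), washout of dead tissue from the measured
mass (`w`), a saturable (Emax) drug kill acting on the viable compartment
only (`b`, `ED50`), and drug elimination with a linear plus a saturable
(Michaelis–Menten) pathway (`c`, `k1`, `k2`).  Doses are instantaneous
boluses: only `x3` jumps, by exactly the administered dose.  Assumptions
worth making explicit:

* kill is routed into the dead compartment, so a treated tumor does not
  shrink on calipers until washout removes the killed volume;
* the kill term acts on `x1` only (total volume is not drug-sensitive);
* one drug state; no multi-compartment liposome/free-drug split, no
  volume-of-distribution conversion (a single calibration scalar in the PK
  fit maps dose-equivalent units to assay units when needed);
* no explicit resistance mechanism: relapse in the model arises only from
  drug decay while the growth rate exceeds the kill rate.

The vector field is swappable (`simulate(..., rhs_override=...)`) so
variant functional forms can be explored without touching callers.

## Numerics

Reference integration is piecewise LSODA (scipy) with rtol 1e-7 / atol
1e-9, split at every dose time so no step crosses an impulse; dense output
on a 0.1-day grid by default.  Planner/controller inner loops use a
fixed-step classic Runge–Kutta kernel (numba-compiled when available, pure
Python otherwise) at dt = 0.02–0.1 day; at the default steps it agrees with
the reference to better than 1e-5 relative, and the test suite pins
closed-form exponential limits at 1e-6 relative.  States in [−1e-9, 0) are
clipped to zero; anything more negative raises (it would indicate a solver
or model defect).  Grid points that coincide with a dose time report the
post-impulse state.

## Measurement

Two caliper-volume formulas are carried side by side and never mixed
silently: `V = L·W²/2` (tag `lw2`) drives protocol logic — the ~200 mm³
treatment trigger and ~2000 mm³ endpoint — while `V = (π/3)(L·W)^{3/2}`
(tag `geometric`) is available as the model-facing volume for pilot-style
fits.  The synthetic observation process samples total volume on the
measurement calendar (every 2nd day by default; a Mon/Wed/Fri weekday
pattern is supported), inverts the `lw2` formula at a per-subject aspect
ratio, and applies mean-corrected multiplicative log-normal noise (CV 5%
by default) to each dimension.  This noise model is a synthetic-only
convention — no claim is made about real caliper error structure.  The
necrotic-ratio statistic `N/(N+V)` consumes classified pixel counts only;
image processing is out of scope.

## Identification

Fitting is bounded nonlinear least squares in log10-parameter space
(positivity by construction), with residuals on log volume (multiplicative
error, matching the observation convention), seeded multi-start (5 starts
by default; ties to the first start), and delta-method standard errors from
the Gauss–Newton Jacobian.  The tumor fit frees (a, b, ED50) by default and
assumes the subject is fully viable and drug-free at its first measurement
— hence fits should start from pre-treatment data.  Series without any dose
automatically freeze the drug parameters at their initialization with a
warning (structurally unidentifiable).  The plasma fit integrates the drug
state from `x3(0) = dose` per dose group and fits (c, k1, k2) on log
levels; the dose-equivalent→assay calibration scalar is fixed at 1 by
default and can be freed (with the study's 6-point design it is only
weakly separable from k1/k2).

Population analysis is the standard two-stage approximation of a nonlinear
mixed-effects model: a pooled fit for typical values, per-subject refits
initialized at and ridge-shrunk (log-scale penalty, weight configurable)
toward them, and between-subject variability as the SD of per-subject log
estimates.  A full marginal-likelihood NLME engine could be slotted behind
the same interface.

The MPC loop's online update is a warm-started re-fit with a trust-region
bound (default 0.15 log10 per call) to prevent controller chatter, on the
full window by default or a sliding window.  The sliding-window variant
re-anchors the model at the window's first observation under the
viable/drug-free assumption; mid-therapy this is an approximation, traded
for bounded per-epoch cost.

## Dose planning

**PDPK.**  Stage 1 holds the drug level at the 99%-effect concentration
`MIC₁ = 0.99·ED50/0.01`; once every observed volume in a trailing 14-day
window is below 20 mm³ the planner switches to the regrowth-prevention
level `MIC₂ = (a−n)·ED50/(b−(a−n))` (flagged infeasible if `b ≤ a−n`).
"Minimal doses" is implemented as greedy per-injection minimality: at each
injection time on a daily grid, the smallest dose on a 0.1 mg/kg lattice
(bounds 0–6 mg/kg) keeping the predicted level ≥ MIC until the next
injection, verified on a dense grid rather than at injection times only.
Greedy minimality is auditable (any one-step reduction breaks coverage) but
is not a global optimum over the horizon; a horizon-wide minimizer could
replace it behind the same interface.  If even the maximal dose cannot
cover an interval the plan is returned flagged partial with the gap marked.

**MPC.**  Cost `q·∫(x1+x2)² dt + r·(Σ doses)²` (trapezoid on the dense
grid; total volume, since only the total is measurable), defaults q = 1,
r = 50.  Defaults: 7-day horizon, daily injection offsets, daily decision
cadence, dose bounds 0–6 mg/kg, an 18 mg/kg cap per rolling 14-day window
(a lifetime cap is available), 1-day minimum spacing.  Horizon length,
weights and cap are reimplementation choices — the in-vivo values are not
published.  Optimization is bounded Powell from seeded multi-starts (zeros,
warm start from the previous epoch's shifted plan, box center, random);
the cumulative cap enters as a quadratic penalty, boundary-riding solutions
are projected back inside, and an independent auditor re-checks every
emitted decision.  On two-dose instances the optimizer is validated against
exhaustive 0.1 mg/kg lattice search.  The closed loop estimates the state
by propagating the identified model and rescaling the volume split to the
latest observation; there is no separate state estimator beyond that, since
volume is observed directly.

## Protocols and survival

The tumor-triggered baseline starts at the first measurement with `lw2`
volume ≥ 200 mm³ and re-doses 6 mg/kg when the observed volume relapses to
its treatment-start value or has not strictly decreased versus the start of
the trailing 10-day window, never more often than every 10 days.  The
algorithm arms share the phase structure: untreated growth (I), a single
fixed 4 or 6 mg/kg dose at the trigger (II), identification on the
accumulated data at the 200 mm³ relapse, then individualized therapy (III)
— an open-loop PDPK plan re-issued every 30-day window (or a single window
in pilot mode, followed by observation), or closed-loop MPC — until the
2000 mm³ endpoint or a 400-day censoring bound (300 days in the trial
scenario).  If identification fails, the arm degrades to tumor-triggered
dosing with a flag.  An independent protocol auditor re-derives every
dose's justification from the recorded observations.

Survival time starts at the second dose (isolating the individualized
phase); single-dose records use the first dose; zero-dose records are
excluded.  Kaplan–Meier and the two-sample log-rank test are implemented
from the life-table definitions and verified against a hand-computed
example and an independent library; hazard ratios and 95% CIs come from a
Cox proportional-hazards fit (lifelines).

## Synthetic cohort

The generator emulates the study designs with log-normal per-subject
parameters around calibrated medians (a 0.25, n 0.05, w 1.2, b 0.30,
ED50 0.015, c 1.10, k1 0.30, k2 1.0; log-SDs 0.2–0.60), engraftment
volumes ~30 mm³, per-subject aspect ratios ~1.2, and one root seed with
per-subject child streams (adding a subject never perturbs the others).
The medians are calibration choices, not measured values, chosen once so
that the generator's own sanity gates hold: untreated growth 200 → 2000 mm³
in about two weeks; a single 6 mg/kg bolus produces a visible
remission-and-relapse arc; the stage-1 99% MIC is reachable under the
6 mg/kg per-dose cap (so the planner's "smaller dose than MTD" regime is
exercised); and drug persistence is short enough (roughly half-day effective
half-life) that dosing rhythm matters, which is what separates continuous
maintenance from 10-day MTD cycles in the absence of a resistance
mechanism.  That last point is the key fidelity trade-off: the real
liposomal drug circulates far longer, and real control-arm failures are
driven by acquired resistance, which this model deliberately omits.
Passing trials therefore demonstrate the machinery (identification,
planning, control, survival analysis) under a plausible heterogeneous
cohort — not a quantitative reproduction of any in-vivo effect size.

Trial-scale runs use a documented coarser MPC configuration (6-day
horizon, injections at offsets 0/2/4 days, 3-day decision cadence, 2
optimizer starts, identification refresh every third epoch, sliding 90-day
window) and a 300-day censoring bound so a ten-seed, 49-subject study
completes in minutes on one CPU; the library defaults remain the daily
regime.

## Known limitations

* No toxicity or body-mass model: dose caps are the only safety surrogate.
* ED50 is weakly identified from caliper data alone; overestimates inflate
  MIC₁ and can make a plan infeasible, in which case the planner delivers
  capped doses and flags the gaps (the trial treats this as part of the
  protocol, and it is visible in the coverage reports).
* The squared-sum dose cost makes receding-horizon plans non-separable
  across epochs, so exact tail consistency holds only for r = 0 (tested in
  that regime).
* Survival comparisons on 16-subject arms with few events carry wide
  confidence intervals; the directional (hazard ratio < 1) statement is the
  claim, not the magnitude.
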
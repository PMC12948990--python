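"""Receding-horizon nonlinear model predictive control of dosing.

At each decision epoch the controller

1. takes the latest (noisy) caliper observation,
2. refreshes its parameter estimates (:func:`chemoplan.identification.online_update`),
3. forecasts tumor evolution over a prediction horizon with injections at
   fixed offsets but free magnitudes, and
4. picks the magnitudes minimizing a quadratic cost — integrated squared
   total tumor volume against the squared sum of administered doses —
   subject to per-injection bounds, a cumulative-dose cap over a rolling
   window, and a minimum inter-injection spacing,

then administers only the doses falling due before the next epoch and
repeats (receding horizon).  The truth ("plant") evolved between epochs is a
separate simulated subject whose parameters generally differ from the
controller's estimates (plant-model mismatch is the default test regime).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from ._integrate import rk4_path, rk4_sq_volume_integral
from .dynamics import DoseEvent, ModelParameters, Trajectory, TumorState, simulate
from .identification import FitResult, online_update
from .measurement import CaliperSeries, ObservationModel, VolumeFormula

__all__ = [
    "MPCConfig",
    "ControlDecision",
    "horizon_cost",
    "optimize_step",
    "lattice_search",
    "audit_decision",
    "run_closed_loop",
]

_BIG = 1e9  # constraint penalty weight


@dataclass(frozen=True)
class MPCConfig:
    """Controller settings (all times in days, doses in mg/kg).

    The library defaults follow a daily-adjustment regime: 7-day horizon,
    daily injection offsets, daily decision cadence.  Trial-scale runs use a
    coarser documented configuration (see cohort scenarios).
    """

    prediction_horizon: float = 7.0
    injection_offsets: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    dose_min: float = 0.0
    dose_max: float = 6.0
    cumulative_cap: float = 18.0
    cumulative_window: float = 14.0
    cap_mode: str = "rolling"  # or "lifetime"
    min_spacing: float = 1.0
    tumor_weight: float = 1.0  # q
    dose_weight: float = 50.0  # r
    decision_cadence: float = 1.0
    n_starts: int = 5
    sim_dt: float = 0.05
    maxiter: int = 60
    maxfev: int = 1000  # per-start budget of cost evaluations

    def __post_init__(self):
        if self.prediction_horizon <= 0:
            raise ValueError("prediction_horizon must be > 0")
        if any(not 0 <= t < self.prediction_horizon for t in self.injection_offsets):
            raise ValueError("injection offsets must lie in [0, horizon)")
        if self.tumor_weight < 0 or self.dose_weight < 0:
            raise ValueError("cost weights must be >= 0")
        if self.tumor_weight == 0 and self.dose_weight == 0:
            raise ValueError("at least one cost weight must be positive")
        if not 0 <= self.dose_min <= self.dose_max:
            raise ValueError("need 0 <= dose_min <= dose_max")
        if self.cap_mode not in ("rolling", "lifetime"):
            raise ValueError("cap_mode must be 'rolling' or 'lifetime'")


@dataclass
class ControlDecision:
    """One epoch's optimized dose vector and its justification."""

    epoch_day: float
    injection_times: np.ndarray  # absolute days
    doses: np.ndarray
    cost: float
    predicted: Trajectory | None = None
    converged: bool = True
    feasible: bool = True
    n_iter: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def total_dose(self) -> float:
        return float(np.sum(self.doses))


def horizon_cost(
    times: np.ndarray,
    total_volume: np.ndarray,
    doses: Sequence[float],
    tumor_weight: float,
    dose_weight: float,
) -> float:
    """Quadratic stage cost: q·∫(x1+x2)² dt + r·(Σ doses)².

    The tumor term is a trapezoidal integral over the prediction grid (not
    endpoint-only); zero iff the tumor is identically zero and no drug is
    given.
    """
    sq = np.asarray(total_volume, dtype=float) ** 2
    integral = float(np.trapezoid(sq, np.asarray(times, dtype=float)))
    dose_sum = float(np.sum(doses))
    return tumor_weight * integral + dose_weight * dose_sum**2


def _cap_violation(doses, times, past, cap, window, mode) -> float:
    """Worst cumulative-cap excess over all injection instants (0 if none)."""
    if math.isinf(cap):
        return 0.0
    events = sorted(past + list(zip(times, doses)))
    worst = 0.0
    for t, _ in zip(times, doses):
        if mode == "lifetime":
            tot = sum(d for tt, d in events if tt <= t + 1e-9)
        else:
            tot = sum(d for tt, d in events if t - window < tt <= t + 1e-9)
        worst = max(worst, tot - cap)
    return worst


def _spacing_bounds(times, past, config) -> list[tuple[float, float]]:
    """Per-dose box bounds with spacing enforced against past injections.

    Offsets on the horizon grid already respect the spacing among
    themselves when the grid spacing >= min_spacing; an injection time too
    close to an already-administered dose gets its upper bound forced to 0.
    """
    last_past = max((t for t, d in past if d > 0), default=-math.inf)
    out = []
    for t in times:
        if t - last_past < config.min_spacing - 1e-9:
            out.append((0.0, 0.0))
        else:
            out.append((config.dose_min, config.dose_max))
    return out


def _predict(params, state, times_rel, doses, horizon, dt):
    ev = [(t, d) for t, d in zip(times_rel, doses) if d > 0]
    t_arr, states = rk4_path(params.as_tuple(), state, ev, horizon, dt=dt)
    return t_arr, states


def _objective_factory(params, state, times_rel, horizon, config, past, epoch_day):
    coeffs = params.as_tuple()
    q, r = config.tumor_weight, config.dose_weight
    abs_times = [epoch_day + t for t in times_rel]

    def objective(doses):
        doses = np.clip(doses, 0.0, None)
        ev = [(t, d) for t, d in zip(times_rel, doses) if d > 0]
        integral, _ = rk4_sq_volume_integral(coeffs, state, ev, horizon,
                                             dt=config.sim_dt)
        cost = q * integral + r * float(np.sum(doses)) ** 2
        excess = _cap_violation(
            doses, abs_times, past, config.cumulative_cap,
            config.cumulative_window, config.cap_mode,
        )
        if excess > 0:
            cost += _BIG * excess**2
        return cost

    return objective


def lattice_search(
    state_estimate: TumorState,
    params: ModelParameters,
    config: MPCConfig,
    step: float = 0.1,
    past_doses: Sequence[tuple[float, float]] = (),
    epoch_day: float = 0.0,
) -> ControlDecision:
    """Exhaustive grid search over the dose lattice — the documented oracle.

    Enumerates every combination of doses on a ``step`` lattice within the
    per-dose bounds and returns the feasible combination of least cost.
    Exponential in the number of injections; intended for <= 2–3 free doses.
    """
    times_rel = list(config.injection_offsets)
    abs_times = np.array([epoch_day + t for t in times_rel])
    past = list(past_doses)
    bounds = _spacing_bounds(abs_times, past, config)
    objective = _objective_factory(
        params, state_estimate.as_tuple(), times_rel,
        config.prediction_horizon, config, past, epoch_day,
    )
    axes = []
    for lo, hi in bounds:
        n = int(round((hi - lo) / step))
        axes.append(lo + step * np.arange(n + 1) if n > 0 else np.array([lo]))
    best = None
    best_doses = None
    for combo in itertools.product(*axes):
        cost = objective(np.array(combo))
        if best is None or cost < best - 1e-15:
            best = cost
            best_doses = np.array(combo)
    feasible = (
        _cap_violation(
            best_doses, abs_times, past, config.cumulative_cap,
            config.cumulative_window, config.cap_mode,
        )
        <= 1e-9
    )
    return ControlDecision(
        epoch_day, abs_times, best_doses, float(best),
        converged=True, feasible=feasible,
        diagnostics={"method": "lattice", "step": step},
    )


def optimize_step(
    state_estimate: TumorState,
    params: ModelParameters | FitResult,
    config: MPCConfig,
    past_doses: Sequence[tuple[float, float]] = (),
    epoch_day: float = 0.0,
    seed: int = 0,
    warm_start: np.ndarray | None = None,
) -> ControlDecision:
    """One receding-horizon optimization: choose dose magnitudes.

    Bounded multi-start local search (Powell) over the dose vector; the
    cumulative cap enters as a quadratic penalty and is re-audited on the
    returned decision.  Deterministic given ``seed``.  Ties are broken by
    lowest cost, then lowest total dose, then first start.
    """
    if isinstance(params, FitResult):
        params = params.params
    times_rel = list(config.injection_offsets)
    abs_times = np.array([epoch_day + t for t in times_rel])
    past = list(past_doses)
    bounds = _spacing_bounds(abs_times, past, config)
    objective = _objective_factory(
        params, state_estimate.as_tuple(), times_rel,
        config.prediction_horizon, config, past, epoch_day,
    )
    k = len(times_rel)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)]
    if warm_start is not None:
        starts.append(np.clip(np.asarray(warm_start, dtype=float), lo, hi))
    starts.append((lo + hi) / 2.0)
    while len(starts) < max(1, config.n_starts):
        starts.append(lo + rng.uniform(0.0, 1.0, size=k) * (hi - lo))
    best = None
    for idx, x0 in enumerate(starts[: config.n_starts]):
        # the start itself is a candidate: a local method must never hand
        # back something worse than where it began
        cand = (objective(x0), float(np.sum(x0)), idx, x0, 0, True)
        if best is None or cand[:3] < best[:3]:
            best = cand
        if np.all(hi <= 0):
            continue
        sol = minimize(
            objective, x0, method="Powell",
            bounds=list(zip(lo, hi)),
            options={"maxiter": config.maxiter, "maxfev": config.maxfev,
                     "xtol": 1e-4, "ftol": 1e-8},
        )
        res_x = np.clip(sol.x, lo, hi)
        cand = (objective(res_x), float(np.sum(res_x)), idx, res_x,
                int(sol.nit), bool(sol.success))
        if cand[:3] < best[:3]:
            best = cand
    cost, _, idx, doses, nit, ok = best
    doses = np.where(doses < 1e-3, 0.0, doses)  # snap sub-quantum dust to zero
    # project numerically boundary-riding solutions back inside the cap
    for _ in range(5):
        excess = _cap_violation(
            doses, abs_times, past, config.cumulative_cap,
            config.cumulative_window, config.cap_mode,
        )
        tot = float(np.sum(doses))
        if excess <= 1e-9 or tot <= 0:
            break
        doses = doses * max(0.0, 1.0 - (excess + 1e-9) / tot)
    cost = objective(doses)
    excess = _cap_violation(
        doses, abs_times, past, config.cumulative_cap,
        config.cumulative_window, config.cap_mode,
    )
    t_arr, states = _predict(
        params, state_estimate.as_tuple(), times_rel, doses,
        config.prediction_horizon, config.sim_dt,
    )
    # drop duplicate times at impulses for the Trajectory grid contract
    keep = np.concatenate([[True], np.diff(t_arr) > 0])
    predicted = Trajectory(
        t_arr[keep] + epoch_day, np.clip(states[keep], 0.0, None),
        [DoseEvent(epoch_day + t, d) for t, d in zip(times_rel, doses) if d > 0],
    )
    return ControlDecision(
        epoch_day, abs_times, doses, float(cost), predicted,
        converged=ok, feasible=excess <= 1e-9, n_iter=nit,
        diagnostics={"start_index": idx, "n_starts": len(starts), "seed": seed},
    )


def audit_decision(
    decision: ControlDecision,
    config: MPCConfig,
    past_doses: Sequence[tuple[float, float]] = (),
) -> list[str]:
    """Independent constraint check of an emitted decision.

    Returns a list of human-readable violations (empty when clean).  This
    auditor recomputes every constraint from the raw numbers; it never
    trusts the optimizer's own feasibility report.
    """
    violations = []
    for t, d in zip(decision.injection_times, decision.doses):
        if d < config.dose_min - 1e-9 or d > config.dose_max + 1e-9:
            violations.append(f"dose {d:.3g} at day {t:g} outside bounds")
    events = sorted(list(past_doses) + [
        (float(t), float(d))
        for t, d in zip(decision.injection_times, decision.doses)
        if d > 0
    ])
    positive = [(t, d) for t, d in events if d > 0]
    for (t1, _), (t2, _) in zip(positive, positive[1:]):
        if t2 - t1 < config.min_spacing - 1e-9:
            violations.append(f"injections at {t1:g} and {t2:g} closer than spacing")
    excess = _cap_violation(
        decision.doses, decision.injection_times, list(past_doses),
        config.cumulative_cap, config.cumulative_window, config.cap_mode,
    )
    if excess > 1e-9:
        violations.append(f"cumulative cap exceeded by {excess:.3g} mg/kg")
    return violations


def run_closed_loop(
    truth_params: ModelParameters,
    truth_state: TumorState,
    estimate: FitResult,
    config: MPCConfig,
    observation: ObservationModel | None = None,
    start_day: float = 0.0,
    max_days: float = 400.0,
    endpoint_volume: float = 2000.0,
    prior_series: CaliperSeries | None = None,
    prior_doses: Sequence[DoseEvent] = (),
    update_interval: int = 1,
    identification_enabled: bool = True,
    seed: int = 0,
    subject_id: str = "subject",
):
    """Closed-loop MPC on a simulated truth subject.

    The truth (plant) advances with the high-accuracy integrator; the
    controller only ever sees noisy caliper observations and its own
    parameter estimates.  Returns a
    :class:`chemoplan.protocols.SubjectRecord` with the full audit trail
    (observations, estimates per epoch, decisions, administered doses).
    ``update_interval`` re-identifies every k-th epoch.  Fully deterministic
    under ``seed``.
    """
    from .measurement import CaliperMeasurement, dims_from_volume
    from .protocols import SubjectRecord  # local import: avoids module cycle

    if observation is None:
        observation = ObservationModel(noise_cv=0.0)
    rng = np.random.default_rng(seed)
    sigma = (
        math.sqrt(math.log(1.0 + observation.noise_cv**2))
        if observation.noise_cv > 0
        else 0.0
    )
    measurements = list(prior_series.measurements) if prior_series else []
    all_doses: list[DoseEvent] = sorted(prior_doses)
    est = estimate
    decisions: list[ControlDecision] = []
    truth = truth_state
    day = float(start_day)
    endpoint_day = None
    warm = None
    epoch = 0
    truth_times = [day]
    truth_states = [truth.as_tuple()]
    while day < start_day + max_days - 1e-9:
        # --- observe ---------------------------------------------------
        total = truth.total_volume
        if total > 0:
            length, width = dims_from_volume(total, observation.aspect_ratio)
            if sigma > 0:
                length *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
                width *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
            if length < width:
                length, width = width, length
            if not measurements or day > measurements[-1].day + 1e-9:
                measurements.append(CaliperMeasurement(day, length, width))
        series = CaliperSeries(subject_id, measurements)
        obs_vol = (
            measurements[-1].volume(VolumeFormula.LW2) if measurements else 0.0
        )
        if obs_vol >= endpoint_volume:
            endpoint_day = day
            break
        # --- identify ---------------------------------------------------
        if identification_enabled and epoch % max(1, update_interval) == 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = online_update(est, series, all_doses, seed=seed + epoch,
                                    window_days=90.0, max_nfev=30)
        # --- state estimate: model-propagated split rescaled to the
        #     observed total (only the total is measurable) ---------------
        model_x1, model_x2, model_x3 = _controller_state(
            est.params, series, all_doses, day
        )
        model_total = model_x1 + model_x2
        if model_total > 1e-9 and obs_vol > 0:
            f = obs_vol / model_total
            state_est = TumorState(model_x1 * f, model_x2 * f, model_x3)
        else:
            state_est = TumorState(max(obs_vol, 0.0), 0.0, model_x3)
        # --- optimize ---------------------------------------------------
        decision = optimize_step(
            state_est, est, config,
            past_doses=[(e.time, e.dose) for e in all_doses],
            epoch_day=day, seed=seed + 10_000 + epoch, warm_start=warm,
        )
        decisions.append(decision)
        warm = np.roll(decision.doses, -1)
        # --- administer doses due before the next epoch -----------------
        next_day = min(day + config.decision_cadence, start_day + max_days)
        due = [
            (t - day, d)
            for t, d in zip(decision.injection_times, decision.doses)
            if d > 0 and t < next_day - 1e-9
        ]
        for t_rel, d in due:
            all_doses.append(DoseEvent(day + t_rel, float(d)))
        # --- advance the truth ------------------------------------------
        span = next_day - day
        traj = simulate(
            truth_params, truth,
            [DoseEvent(t, d) for t, d in due],
            horizon=span, grid_step=min(0.25, span),
        )
        truth = traj.final_state()
        truth_times.append(next_day)
        truth_states.append(truth.as_tuple())
        day = next_day
        epoch += 1
    truth_traj = Trajectory(np.array(truth_times), np.array(truth_states), [])
    return SubjectRecord(
        subject_id=subject_id,
        arm="mpc",
        series=CaliperSeries(subject_id, measurements),
        doses=sorted(all_doses),
        endpoint_day=endpoint_day,
        max_day=day,
        decisions=decisions,
        final_estimate=est,
        truth_trajectory=truth_traj,
    )


def _controller_state(params, series, doses, day):
    """Propagate the controller's model from its first observation to ``day``."""
    if len(series) == 0:
        return 0.0, 0.0, 0.0
    t0 = float(series.days[0])
    v0 = float(series.volumes(VolumeFormula.LW2)[0])
    ev = [(d.time - t0, d.dose) for d in doses if t0 <= d.time <= day]
    span = max(day - t0, 1e-6)
    _, states = rk4_path(params.as_tuple(), (v0, 0.0, 0.0), ev, span, dt=0.05,
                         sample_times=np.array([span]))
    return float(states[0, 0]), float(states[0, 1]), float(states[0, 2])
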
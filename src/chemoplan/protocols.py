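"""Treatment protocols and the phase structure of an in-silico study.

Three arms are encoded:

* ``tumor_triggered`` — the conventional baseline: a maximum tolerated dose
  (MTD, 6 mg/kg) whenever the observed volume relapses to its size at the
  start of treatment or has failed to decrease over the trailing 10 days,
  at most every 10 days.  Treatment starts at the first measurement with
  observed volume >= 200 mm³ and the subject reaches its endpoint at
  2000 mm³ (both on the length·width²/2 caliper volume).
* ``pdpk`` — after a single fixed standard dose and model identification,
  an open-loop MIC-maintenance plan (re-issued per planning window in
  main-study mode; a single 30-day window in pilot mode).
* ``mpc`` — after the same standard phase, closed-loop model predictive
  control.

All arms share the phase structure: Phase I untreated growth to the 200 mm³
trigger; Phase II a single fixed dose with response monitoring; parameter
identification on the Phase I–II data at the 200 mm³ relapse; Phase III
individualized therapy to the endpoint (or the censoring bound).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import DoseEvent, ModelParameters, TumorState, simulate
from .identification import FitResult, TumorGrowthModel, online_update
from .measurement import (
    CaliperMeasurement,
    CaliperSeries,
    ObservationModel,
    VolumeFormula,
    dims_from_volume,
)
from .pdpk import (
    PDPKConfig,
    STAGE_REGROWTH,
    mic_effectiveness,
    mic_regrowth,
    plan_schedule,
    select_stage,
)

log = logging.getLogger(__name__)

__all__ = [
    "ProtocolConfig",
    "SubjectRecord",
    "run_tumor_triggered",
    "run_arm",
    "survival_time",
    "audit_tumor_triggered",
]

ARMS = ("tumor_triggered", "pdpk", "mpc")


@dataclass(frozen=True)
class ProtocolConfig:
    """Study-protocol constants (volumes on the length·width²/2 formula)."""

    start_threshold: float = 200.0  # mm³, treatment trigger
    endpoint_volume: float = 2000.0  # mm³, humane endpoint
    mtd_dose: float = 6.0  # mg/kg
    no_decrease_window: float = 10.0  # days
    min_dose_interval: float = 10.0  # days between MTD treatments
    standard_dose: float = 6.0  # Phase-II fixed dose (4 or 6 for AATD arms)
    max_duration: float = 400.0  # censoring bound, days
    pilot_mode: bool = False  # 30-day optimized window then observation only

    def __post_init__(self):
        if not 0 < self.start_threshold < self.endpoint_volume:
            raise ValueError("need 0 < start_threshold < endpoint_volume")


@dataclass
class SubjectRecord:
    """Complete treatment history of one (virtual) subject."""

    subject_id: str
    arm: str
    series: CaliperSeries
    doses: list[DoseEvent]
    endpoint_day: float | None  # None = censored
    max_day: float
    decisions: list = field(default_factory=list)
    final_estimate: FitResult | None = None
    truth_trajectory: object | None = None
    degraded: bool = False  # identification failed; fell back to MTD rule
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        times = [d.time for d in self.doses]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        if (
            self.endpoint_day is not None
            and self.doses
            and self.endpoint_day < self.doses[-1].time - 1e-9
        ):
            raise ValueError("endpoint day precedes the last dose")

    @property
    def event(self) -> bool:
        return self.endpoint_day is not None

    @property
    def cumulative_dose(self) -> float:
        return sum(d.dose for d in self.doses)

    @property
    def n_doses(self) -> int:
        return len(self.doses)


class _Plant:
    """Simulated truth advanced on the measurement calendar with noisy readout."""

    def __init__(self, params, state, observation: ObservationModel, seed: int,
                 subject_id: str):
        self.params = params
        self.state = state
        self.obs = observation
        self.rng = np.random.default_rng(seed)
        self.sigma = (
            math.sqrt(math.log(1.0 + observation.noise_cv**2))
            if observation.noise_cv > 0
            else 0.0
        )
        self.measurements: list[CaliperMeasurement] = []
        self.doses: list[DoseEvent] = []
        self.subject_id = subject_id
        self.day = 0.0

    def measure(self) -> float:
        """Take a caliper reading now; returns observed lw2 volume (mm³)."""
        total = self.state.total_volume
        if total <= 0:
            return 0.0
        length, width = dims_from_volume(total, self.obs.aspect_ratio)
        if self.sigma > 0:
            length *= math.exp(self.rng.normal(-0.5 * self.sigma**2, self.sigma))
            width *= math.exp(self.rng.normal(-0.5 * self.sigma**2, self.sigma))
        if length < width:
            length, width = width, length
        m = CaliperMeasurement(self.day, length, width)
        self.measurements.append(m)
        return m.volume(VolumeFormula.LW2)

    def dose(self, dose_mgkg: float):
        if dose_mgkg <= 0:
            return
        self.doses.append(DoseEvent(self.day, float(dose_mgkg)))
        self.state = TumorState(
            self.state.proliferating_volume,
            self.state.dead_volume,
            self.state.drug_level + dose_mgkg,
        )

    def advance(self, span: float, doses_within: list[tuple[float, float]] = ()):
        """Advance the truth ``span`` days; doses_within are (offset, dose)."""
        if span <= 0:
            return
        for off, d in doses_within:
            self.doses.append(DoseEvent(self.day + off, float(d)))
        traj = simulate(
            self.params, self.state,
            [DoseEvent(off, d) for off, d in doses_within],
            horizon=span, grid_step=min(0.5, span),
        )
        self.state = traj.final_state()
        self.day += span

    def series(self) -> CaliperSeries:
        return CaliperSeries(self.subject_id, list(self.measurements))


def run_tumor_triggered(
    truth_params: ModelParameters,
    truth_state: TumorState,
    config: ProtocolConfig | None = None,
    observation: ObservationModel | None = None,
    seed: int = 0,
    subject_id: str = "subject",
    first_dose: float | None = None,
) -> SubjectRecord:
    """Run the MTD tumor-triggered baseline on a simulated subject.

    First dose at the first measurement day whose observed volume crosses
    the start threshold; re-dose whenever the observed volume has relapsed
    to its value at treatment start OR has not decreased (strictly) versus
    the start of the trailing 10-day window — both subject to the 10-day
    minimum interval.  Runs to the 2000 mm³ endpoint or the censoring bound.
    A tumor that never triggers yields a zero-dose censored record.
    """
    config = config or ProtocolConfig()
    observation = observation or ObservationModel()
    plant = _Plant(truth_params, truth_state, observation, seed, subject_id)
    baseline = None
    last_dose_day = -math.inf
    endpoint_day = None
    mtd = first_dose if first_dose is not None else config.mtd_dose
    while plant.day <= config.max_duration + 1e-9:
        vol = plant.measure()
        if vol >= config.endpoint_volume:
            endpoint_day = plant.day
            break
        give = 0.0
        if baseline is None:
            if vol >= config.start_threshold:
                baseline = vol
                give = mtd
        elif plant.day - last_dose_day >= config.min_dose_interval - 1e-9:
            relapsed = vol >= baseline
            stalled = _not_decreased(
                plant.measurements, plant.day, config.no_decrease_window
            )
            if relapsed or stalled:
                give = config.mtd_dose
        if give > 0:
            plant.dose(give)
            last_dose_day = plant.day
        plant.advance(observation.cadence)
    return SubjectRecord(
        subject_id=subject_id,
        arm="tumor_triggered",
        series=plant.series(),
        doses=plant.doses,
        endpoint_day=endpoint_day,
        max_day=plant.day,
    )


def _not_decreased(measurements, day, window) -> bool:
    """Observed volume has not strictly decreased vs the trailing window start."""
    start = day - window
    past = [m for m in measurements if start - 1e-9 <= m.day <= day + 1e-9]
    if not past or past[0].day > start + 1e-9 + 1.0:
        return False  # window not fully covered by observations
    v_start = past[0].volume(VolumeFormula.LW2)
    v_now = past[-1].volume(VolumeFormula.LW2)
    return v_now >= v_start


def audit_tumor_triggered(record: SubjectRecord, config: ProtocolConfig) -> list[str]:
    """Independent protocol check: every dose must satisfy its trigger rule.

    Works purely from the recorded observation series and dose times; returns
    a list of violations (empty when the record is clean).
    """
    violations = []
    obs = {m.day: m.volume(VolumeFormula.LW2) for m in record.series}
    if not record.doses:
        return violations
    first = record.doses[0]
    v0 = obs.get(first.time)
    if v0 is None or v0 < config.start_threshold:
        violations.append(
            f"first dose at day {first.time:g} without threshold crossing"
        )
        v0 = config.start_threshold
    for prev, cur in zip(record.doses, record.doses[1:]):
        if cur.time - prev.time < config.min_dose_interval - 1e-9:
            violations.append(
                f"doses at {prev.time:g} and {cur.time:g} closer than "
                f"{config.min_dose_interval:g} days"
            )
        v = obs.get(cur.time)
        if v is None:
            violations.append(f"dose at day {cur.time:g} without a measurement")
            continue
        relapsed = v >= v0
        stalled = _not_decreased(
            record.series.measurements, cur.time, config.no_decrease_window
        )
        if not (relapsed or stalled):
            violations.append(
                f"dose at day {cur.time:g} with volume {v:.1f} triggered neither rule"
            )
    return violations


def survival_time(
    record: SubjectRecord, config: ProtocolConfig | None = None
) -> tuple[float, bool]:
    """Survival time (days) and event indicator for one record.

    With >= 2 doses the clock starts at the second dose (isolating the
    individualized phase); with exactly one dose it starts at that dose;
    zero-dose records are excluded (ValueError).  Subjects that never reach
    the endpoint are censored at the run's last day.
    """
    config = config or ProtocolConfig()
    if record.n_doses == 0:
        raise ValueError("zero-dose record: excluded from survival analysis")
    origin = record.doses[1].time if record.n_doses >= 2 else record.doses[0].time
    if record.endpoint_day is not None:
        if record.endpoint_day < origin:
            raise ValueError("inconsistent record: endpoint precedes origin dose")
        return record.endpoint_day - origin, True
    return record.max_day - origin, False


def run_arm(
    truth_params: ModelParameters,
    truth_state: TumorState,
    arm: str,
    config: ProtocolConfig | None = None,
    observation: ObservationModel | None = None,
    init_params: ModelParameters | None = None,
    pdpk_config: PDPKConfig | None = None,
    mpc_config=None,
    seed: int = 0,
    subject_id: str = "subject",
    fit_free: tuple = ("growth_rate", "max_kill_rate", "ed50"),
    fit_starts: int = 3,
) -> SubjectRecord:
    """Run one subject through its arm's full phase structure.

    ``init_params`` seeds the identification (population-typical values).
    On identification failure the subject degrades to the tumor-triggered
    rule with ``degraded=True`` on the record.
    """
    config = config or ProtocolConfig()
    observation = observation or ObservationModel()
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if arm == "tumor_triggered":
        return run_tumor_triggered(
            truth_params, truth_state, config, observation, seed, subject_id
        )

    plant = _Plant(truth_params, truth_state, observation, seed, subject_id)
    notes: list[str] = []
    endpoint_day = None
    # ---- Phase I: untreated growth to the trigger -----------------------
    triggered = False
    while plant.day <= config.max_duration + 1e-9:
        vol = plant.measure()
        if vol >= config.endpoint_volume:
            endpoint_day = plant.day
            break
        if vol >= config.start_threshold:
            triggered = True
            break
        plant.advance(observation.cadence)
    if not triggered:
        return SubjectRecord(
            subject_id, arm, plant.series(), plant.doses, endpoint_day,
            plant.day, notes=["never reached the treatment trigger"],
        )
    # ---- Phase II: single fixed standard dose, monitor to relapse -------
    plant.dose(config.standard_dose)
    phase2_day = plant.day
    relapsed = False
    while plant.day <= config.max_duration + 1e-9:
        plant.advance(observation.cadence)
        vol = plant.measure()
        if vol >= config.endpoint_volume:
            endpoint_day = plant.day
            break
        if plant.day > phase2_day and vol >= config.start_threshold:
            relapsed = True
            break
    if not relapsed:
        return SubjectRecord(
            subject_id, arm, plant.series(), plant.doses, endpoint_day,
            plant.day, notes=notes + ["no relapse after standard therapy"],
        )
    # ---- identification on Phase I–II data ------------------------------
    init = init_params or truth_params  # fallback: oracle initialization
    estimate = None
    try:
        model = TumorGrowthModel(plant.series(), plant.doses)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            estimate = model.fit(init, free=fit_free, n_starts=fit_starts, seed=seed)
        if not np.isfinite(estimate.objective):
            estimate = None
    except (ValueError, RuntimeError) as exc:
        notes.append(f"identification failed: {exc}")
    if estimate is None:
        log.warning("%s: identification failed; degrading to MTD rule", subject_id)
        rec = _continue_tumor_triggered(plant, config, endpoint_day)
        rec.arm = arm
        rec.degraded = True
        rec.notes = notes + ["degraded to tumor-triggered dosing"]
        return rec
    # ---- Phase III: individualized therapy ------------------------------
    if arm == "mpc":
        from .mpc import MPCConfig, run_closed_loop

        mpc_config = mpc_config or MPCConfig()
        rec = run_closed_loop(
            truth_params, plant.state, estimate, mpc_config,
            observation=observation, start_day=plant.day,
            max_days=config.max_duration - plant.day,
            endpoint_volume=config.endpoint_volume,
            prior_series=plant.series(), prior_doses=plant.doses,
            update_interval=3, seed=seed + 1, subject_id=subject_id,
        )
        rec.notes = notes + rec.notes
        return rec
    # pdpk arm
    return _run_pdpk_phase3(
        plant, estimate, config, observation, pdpk_config or PDPKConfig(),
        notes, seed, subject_id,
    )


def _run_pdpk_phase3(plant, estimate, config, observation, pcfg, notes, seed,
                     subject_id):
    """Open-loop MIC plans, re-issued per planning window (main-study mode)."""
    endpoint_day = None
    therapy_start = plant.day
    est = estimate
    decisions = []
    drug_level = 0.0  # controller's belief; Phase-II dose has largely cleared
    while plant.day < config.max_duration - 1e-9:
        window = plant.series().window(
            plant.day - pcfg.switch_duration, plant.day
        )
        stage = select_stage(window, pcfg)
        mic = (
            mic_regrowth(est.params)
            if stage == STAGE_REGROWTH
            else mic_effectiveness(est.params, pcfg.effectiveness_level)
        )
        if not mic.feasible:
            notes.append(f"infeasible MIC at day {plant.day:g}; skipping window")
            plan = None
        else:
            plan = plan_schedule(est.params, mic, pcfg, initial_level=drug_level,
                                 start_day=plant.day)
            decisions.append(plan)
        # execute the window on the measurement calendar
        window_end = min(plant.day + pcfg.planning_horizon, config.max_duration)
        plan_events = list(plan.dose_events) if plan is not None else []
        while plant.day < window_end - 1e-9:
            step = min(observation.cadence, window_end - plant.day)
            due = [
                (e.time - plant.day, e.dose)
                for e in plan_events
                if plant.day - 1e-9 <= e.time < plant.day + step - 1e-9
            ]
            plant.advance(step, due)
            vol = plant.measure()
            if vol >= config.endpoint_volume:
                endpoint_day = plant.day
                break
        if endpoint_day is not None:
            break
        if plan is not None:
            drug_level = float(plan.predicted.x3[-1])
        if config.pilot_mode:
            # single optimized window, then observation to endpoint
            while plant.day <= config.max_duration + 1e-9:
                plant.advance(observation.cadence)
                vol = plant.measure()
                if vol >= config.endpoint_volume:
                    endpoint_day = plant.day
                    break
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = online_update(est, plant.series(), plant.doses, seed=seed,
                                window_days=90.0, max_nfev=30)
    rec = SubjectRecord(
        subject_id, "pdpk", plant.series(), plant.doses, endpoint_day,
        plant.day, decisions=decisions, final_estimate=est, notes=notes,
    )
    if therapy_start and not rec.doses:
        rec.notes.append("planner emitted no doses")
    return rec


def _continue_tumor_triggered(plant, config, endpoint_day):
    """Finish a subject under the MTD rule after a mid-run degradation."""
    baseline = None
    last_dose_day = -math.inf
    for d in plant.doses:
        last_dose_day = d.time
    if plant.measurements:
        # treatment already started; its first dose volume is the baseline
        first_dose_day = plant.doses[0].time if plant.doses else None
        if first_dose_day is not None:
            for m in plant.measurements:
                if abs(m.day - first_dose_day) < 1e-9:
                    baseline = m.volume(VolumeFormula.LW2)
                    break
    if baseline is None:
        baseline = config.start_threshold
    while plant.day <= config.max_duration + 1e-9 and endpoint_day is None:
        plant.advance(plant.obs.cadence)
        vol = plant.measure()
        if vol >= config.endpoint_volume:
            endpoint_day = plant.day
            break
        if plant.day - last_dose_day >= config.min_dose_interval - 1e-9:
            stalled = _not_decreased(
                plant.measurements, plant.day, config.no_decrease_window
            )
            if vol >= baseline or stalled:
                plant.dose(config.mtd_dose)
                last_dose_day = plant.day
    return SubjectRecord(
        plant.subject_id, "tumor_triggered", plant.series(), plant.doses,
        endpoint_day, plant.day,
    )
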
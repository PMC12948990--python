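"""Seeded virtual-mouse cohorts and in-silico study scenarios.

The generator stands in for an undeposited animal cohort: per-subject
parameters are log-normal draws around population medians, each subject fed
by its own child stream of one root seed (adding a subject never perturbs
the others).  Two scenario builders emulate the study designs this toolkit
is exercised on:

* :func:`make_pilot_scenario` — fixed Phase-II dose groups (0.5/1/4/6
  mg/kg), a plasma-sampling sidecar at day 8 post-dose, a single 30-day
  optimized-therapy window followed by observation to the endpoint.
* :func:`make_main_scenario` — 49 subjects randomized to three arms
  (tumor-triggered control, PDPK, MPC), standard-therapy doses 4 or 6 mg/kg
  for the algorithm arms, a PK-profiling sidecar on the minute grid
  {0, 5, 30, 60, 1440, 7200} at 0.6 and 6 mg/kg, therapy to the 2000 mm³
  endpoint.

Default population medians are calibration choices, not measured values:
they are set so an untreated tumor grows 200 → 2000 mm³ in about two weeks,
a single 6 mg/kg bolus produces a remission-and-relapse arc of a few weeks,
and the stage-1 (99%) MIC is reachable under the 6 mg/kg per-dose cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import ModelParameters, TumorState, simulate, DoseEvent
from .identification import PlasmaSample
from .measurement import ObservationModel
from .mpc import MPCConfig
from .pdpk import PDPKConfig
from .protocols import ProtocolConfig, run_arm

__all__ = [
    "PopulationSpec",
    "VirtualSubject",
    "Scenario",
    "DEFAULT_POPULATION",
    "sample_cohort",
    "sample_pk_sidecar",
    "make_pilot_scenario",
    "make_main_scenario",
    "run_trial",
]

#: calibrated median mouse (see module docstring); rates in 1/day, levels in
#: injected-dose-equivalent mg/kg
DEFAULT_MEDIANS = ModelParameters(
    growth_rate=0.25,
    necrosis_rate=0.05,
    washout_rate=1.20,
    max_kill_rate=0.30,
    ed50=0.015,
    clearance=1.10,
    elimination_vmax=0.30,
    elimination_km=1.0,
)

#: between-subject log-SDs; growth/kill/ED50/clearance carry most of the
#: biological variability, structural rates less
DEFAULT_LOG_SD = {
    "growth_rate": 0.60,
    "necrosis_rate": 0.20,
    "washout_rate": 0.20,
    "max_kill_rate": 0.35,
    "ed50": 0.35,
    "clearance": 0.25,
    "elimination_vmax": 0.20,
    "elimination_km": 0.20,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Distributional description of a virtual cohort."""

    medians: ModelParameters = DEFAULT_MEDIANS
    log_sd: dict = field(default_factory=lambda: dict(DEFAULT_LOG_SD))
    engraftment_volume_median: float = 30.0  # mm³ at study day 0
    engraftment_volume_log_sd: float = 0.30
    aspect_ratio_median: float = 1.2
    aspect_ratio_log_sd: float = 0.08
    observation: ObservationModel = ObservationModel(cadence=2, noise_cv=0.05)
    seed: int = 0

    def __post_init__(self):
        for name, sd in self.log_sd.items():
            if sd < 0:
                raise ValueError(f"log_sd[{name!r}] must be >= 0")
            if getattr(self.medians, name) <= 0 and sd > 0:
                raise ValueError(f"cannot put variability on zero median {name!r}")
        if self.engraftment_volume_median <= 0:
            raise ValueError("engraftment volume median must be > 0")


DEFAULT_POPULATION = PopulationSpec()


@dataclass
class VirtualSubject:
    """One simulated mouse: true parameters, initial state, arm assignment."""

    subject_id: str
    params: ModelParameters
    initial_state: TumorState
    arm: str = ""
    standard_dose: float = 6.0
    aspect_ratio: float = 1.2
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "true_params": self.params.to_dict(),  # simulation-only ground truth
            "initial_volume_mm3": self.initial_state.total_volume,
            "arm": self.arm,
            "standard_dose": self.standard_dose,
            "aspect_ratio": self.aspect_ratio,
            "seed": self.seed,
        }


def sample_cohort(
    spec: PopulationSpec, n: int, seed: int | None = None
) -> list[VirtualSubject]:
    """Draw ``n`` independent subjects; deterministic under the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = root.spawn(n)
    subjects = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        draws = {}
        for name in spec.medians.to_dict():
            med = getattr(spec.medians, name)
            sd = spec.log_sd.get(name, 0.0)
            draws[name] = med * np.exp(rng.normal(0.0, sd)) if sd > 0 else med
        params = ModelParameters.from_dict(draws)
        v0 = spec.engraftment_volume_median * np.exp(
            rng.normal(0.0, spec.engraftment_volume_log_sd)
        )
        ar = max(
            1.0,
            spec.aspect_ratio_median
            * np.exp(rng.normal(0.0, spec.aspect_ratio_log_sd)),
        )
        subject_seed = int(rng.integers(0, 2**31 - 1))
        subjects.append(
            VirtualSubject(
                subject_id=f"M{i + 1:03d}",
                params=params,
                initial_state=TumorState(v0, 0.0, 0.0),
                aspect_ratio=float(ar),
                seed=subject_seed,
            )
        )
    return subjects


def sample_pk_sidecar(
    params: ModelParameters,
    doses: tuple[float, ...],
    times_min: tuple[float, ...],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> dict[float, list[PlasmaSample]]:
    """Simulated plasma samples after single boluses at the given dose levels.

    Pre-dose samples (time 0) report level 0 — the sample is drawn before
    the injection.  Optional multiplicative log-normal assay noise.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0
    out: dict[float, list[PlasmaSample]] = {}
    for dose in doses:
        t_days = np.array(sorted(times_min)) / 1440.0
        traj = simulate(
            params,
            TumorState(0.0, 0.0, 0.0),
            [DoseEvent(0.0, dose)],
            horizon=max(float(t_days.max()), 1e-3),
            t_eval=np.maximum(t_days, 0.0),
        )
        samples = []
        for t_min, level in zip(sorted(times_min), traj.x3):
            if t_min <= 0:
                samples.append(PlasmaSample(0.0, 0.0))
                continue
            val = float(level)
            if sigma > 0:
                val *= float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            samples.append(PlasmaSample(float(t_min), val))
        out[float(dose)] = samples
    return out


@dataclass
class Scenario:
    """A fully specified in-silico study: cohort plus protocol settings."""

    name: str
    subjects: list[VirtualSubject]
    protocol: ProtocolConfig
    pdpk: PDPKConfig
    mpc: MPCConfig
    observation: ObservationModel
    pk_design: dict[float, tuple[float, ...]]  # dose -> sampling minutes
    population: PopulationSpec
    seed: int

    def validate(self):
        arms = {s.arm for s in self.subjects}
        unknown = arms - {"tumor_triggered", "pdpk", "mpc", ""}
        if unknown:
            raise ValueError(f"unknown arms in scenario: {unknown}")
        if self.protocol.endpoint_volume <= self.protocol.start_threshold:
            raise ValueError("endpoint must exceed start threshold")
        return True

    def manifest(self) -> dict:
        return {
            "name": self.name,
            "seed": self.seed,
            "n_subjects": len(self.subjects),
            "subjects": [s.to_dict() for s in self.subjects],
            "protocol": {
                "start_threshold": self.protocol.start_threshold,
                "endpoint_volume": self.protocol.endpoint_volume,
                "mtd_dose": self.protocol.mtd_dose,
                "max_duration": self.protocol.max_duration,
                "pilot_mode": self.protocol.pilot_mode,
            },
            "pk_design": {str(d): list(t) for d, t in self.pk_design.items()},
        }


PILOT_PHASE2_DOSES = (0.5, 1.0, 4.0, 6.0)
PK_MINUTE_GRID = (0.0, 5.0, 30.0, 60.0, 1440.0, 7200.0)
PK_PROFILE_DOSES = (0.6, 6.0)


def make_pilot_scenario(
    spec: PopulationSpec = DEFAULT_POPULATION,
    seed: int = 0,
    n_per_group: int = 3,
) -> Scenario:
    """Pilot design: Phase-II dose groups 0.5/1/4/6 mg/kg, day-8 PK sidecar,
    one 30-day optimized window, then observation to the endpoint."""
    n = n_per_group * len(PILOT_PHASE2_DOSES)
    subjects = sample_cohort(spec, n, seed)
    rng = np.random.default_rng(seed + 1)
    arms = ["pdpk", "mpc"]
    for i, s in enumerate(subjects):
        s.standard_dose = PILOT_PHASE2_DOSES[i % len(PILOT_PHASE2_DOSES)]
        s.arm = arms[int(rng.integers(0, 2))]
    protocol = ProtocolConfig(pilot_mode=True, standard_dose=6.0)
    # plasma sampled once, 8 days after the Phase-II dose
    pk_design = {d: (8.0 * 1440.0,) for d in PILOT_PHASE2_DOSES}
    return Scenario(
        name="pilot",
        subjects=subjects,
        protocol=protocol,
        pdpk=PDPKConfig(),
        mpc=MPCConfig(),
        observation=spec.observation,
        pk_design=pk_design,
        population=spec,
        seed=seed,
    )


def make_main_scenario(
    spec: PopulationSpec = DEFAULT_POPULATION,
    seed: int = 0,
    n_subjects: int = 49,
    max_duration: float = 320.0,
) -> Scenario:
    """Main-study design: 49 subjects randomized over three arms.

    Standard-therapy dose is 6 mg/kg for the control arm and alternates
    4/6 mg/kg within the algorithm arms; therapy runs to the 2000 mm³
    endpoint (censoring bound ``max_duration``).  The MPC settings here are
    the trial-scale configuration (6-day horizon, injections at offsets
    0/2/4 d, 3-day decision cadence) documented in the methods note.
    """
    subjects = sample_cohort(spec, n_subjects, seed)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n_subjects)
    arm_of = {}
    arms = ("tumor_triggered", "pdpk", "mpc")
    for rank, idx in enumerate(order):
        arm_of[idx] = arms[rank % 3]
    aatd_counter = 0
    for i, s in enumerate(subjects):
        s.arm = arm_of[i]
        if s.arm == "tumor_triggered":
            s.standard_dose = 6.0
        else:
            s.standard_dose = (4.0, 6.0)[aatd_counter % 2]
            aatd_counter += 1
    protocol = ProtocolConfig(
        pilot_mode=False, max_duration=max_duration, standard_dose=6.0
    )
    mpc = MPCConfig(
        prediction_horizon=6.0,
        injection_offsets=(0.0, 2.0, 4.0),
        decision_cadence=3.0,
        n_starts=2,
        maxiter=8,
        maxfev=80,
        sim_dt=0.1,
    )
    pk_design = {d: PK_MINUTE_GRID for d in PK_PROFILE_DOSES}
    return Scenario(
        name="main",
        subjects=subjects,
        protocol=protocol,
        pdpk=PDPKConfig(),
        mpc=mpc,
        observation=spec.observation,
        pk_design=pk_design,
        population=spec,
        seed=seed,
    )


def run_trial(scenario: Scenario, progress: bool = False):
    """Run every subject through its arm; returns (records_by_arm, records).

    Each subject's protocol noise and optimizer seeds derive from its own
    child seed, so the run is deterministic under the scenario seed and
    permutation-invariant at the arm level.
    """
    scenario.validate()
    records_by_arm: dict[str, list] = {}
    records = []
    init = scenario.population.medians  # identification starts at typical values
    for s in scenario.subjects:
        protocol = replace(scenario.protocol, standard_dose=s.standard_dose)
        obs = replace(scenario.observation, aspect_ratio=s.aspect_ratio)
        rec = run_arm(
            s.params,
            s.initial_state,
            s.arm,
            config=protocol,
            observation=obs,
            init_params=init,
            pdpk_config=scenario.pdpk,
            mpc_config=scenario.mpc,
            seed=s.seed,
            subject_id=s.subject_id,
        )
        records.append(rec)
        records_by_arm.setdefault(s.arm, []).append(rec)
        if progress:
            status = (
                f"event d{rec.endpoint_day:.0f}" if rec.event else "censored"
            )
            print(f"  {s.subject_id} [{s.arm}] {status}, "
                  f"{rec.n_doses} doses ({rec.cumulative_dose:.1f} mg/kg)")
    return records_by_arm, records
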
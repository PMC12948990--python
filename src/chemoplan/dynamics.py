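"""Digital twin of a treated tumor: a third-order impulsive ODE system.

The model tracks three states of a tumor-bearing subject:

* ``x1`` — proliferating (viable) tumor volume, mm³;
* ``x2`` — dead (necrotic) tumor volume still contributing to the measured
  mass, mm³;
* ``x3`` — circulating drug level in injected-dose-equivalent units, mg/kg.

Dynamics (per day)::

    dx1/dt = (a - n)·x1 - E(x3)·x1
    dx2/dt = n·x1 + E(x3)·x1 - w·x2
    dx3/dt = -c·x3 - k1·x3/(k2 + x3)

with the saturable pharmacodynamic kill rate ``E(x) = b·x/(ED50 + x)``.
Proliferating volume grows exponentially at net rate ``a - n``; spontaneous
necrosis (``n``) and drug kill route volume into the dead compartment, which
is washed out at first-order rate ``w``.  Drug elimination combines linear
clearance ``c`` with a Michaelis–Menten (saturable) pathway ``(k1, k2)``.
Only the total ``x1 + x2`` is observable by caliper.

Doses are instantaneous boluses (tail-vein injection): at a dose time only
``x3`` jumps, by exactly the administered dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from ._integrate import IntegrationError, integrate_piecewise, rk4_path

__all__ = [
    "ModelParameters",
    "TumorState",
    "DoseEvent",
    "Trajectory",
    "IntegrationError",
    "drug_effect",
    "net_growth_rate",
    "rhs",
    "apply_dose",
    "simulate",
]

#: states more negative than this signal a solver/model bug; above it they are
#: treated as round-off and clipped to zero.
NEGATIVE_CLIP_TOL = 1e-9

_PARAM_FIELDS = (
    "growth_rate",
    "necrosis_rate",
    "washout_rate",
    "max_kill_rate",
    "ed50",
    "clearance",
    "elimination_vmax",
    "elimination_km",
)


@dataclass(frozen=True)
class ModelParameters:
    """Per-subject rate constants of the tumor/PK model.

    Parameters
    ----------
    growth_rate : float
        Proliferation rate ``a`` of viable tumor volume (1/day).
    necrosis_rate : float
        Spontaneous necrosis rate ``n`` (1/day), routing x1 → x2.
    washout_rate : float
        Washout rate ``w`` of dead volume from the measured mass (1/day).
    max_kill_rate : float
        Maximal drug-induced kill rate ``b`` (1/day) at saturating drug level.
    ed50 : float
        Median effective dose: drug level producing half-maximal kill
        (dose-equivalent units, mg/kg).
    clearance : float
        Linear drug clearance ``c`` (1/day).
    elimination_vmax : float
        Saturable elimination capacity ``k1`` (dose-equivalent units/day).
    elimination_km : float
        Saturable elimination half-saturation level ``k2`` (dose-equivalent
        units).
    """

    growth_rate: float
    necrosis_rate: float
    washout_rate: float
    max_kill_rate: float
    ed50: float
    clearance: float
    elimination_vmax: float
    elimination_km: float

    def __post_init__(self):
        for name in _PARAM_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.ed50 <= 0:
            raise ValueError("ed50 must be > 0")
        if self.elimination_km <= 0:
            raise ValueError("elimination_km must be > 0")
        if self.growth_rate <= self.necrosis_rate:
            warnings.warn(
                "growth_rate <= necrosis_rate: untreated tumor does not grow",
                stacklevel=2,
            )

    # short aliases used throughout the numerics
    @property
    def a(self) -> float:
        return self.growth_rate

    @property
    def n(self) -> float:
        return self.necrosis_rate

    @property
    def w(self) -> float:
        return self.washout_rate

    @property
    def b(self) -> float:
        return self.max_kill_rate

    @property
    def c(self) -> float:
        return self.clearance

    @property
    def k1(self) -> float:
        return self.elimination_vmax

    @property
    def k2(self) -> float:
        return self.elimination_km

    def as_tuple(self) -> tuple:
        return (self.a, self.n, self.w, self.b, self.ed50, self.c, self.k1, self.k2)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in _PARAM_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{name: float(d[name]) for name in _PARAM_FIELDS})

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class TumorState:
    """Instantaneous state: viable volume, dead volume (mm³), drug level (mg/kg)."""

    proliferating_volume: float
    dead_volume: float
    drug_level: float

    def __post_init__(self):
        for name in ("proliferating_volume", "dead_volume", "drug_level"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def total_volume(self) -> float:
        """Caliper-observable tumor volume, x1 + x2 (mm³)."""
        return self.proliferating_volume + self.dead_volume

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.proliferating_volume, self.dead_volume, self.drug_level)


@dataclass(frozen=True, order=True)
class DoseEvent:
    """A bolus administration: day of injection and dose in mg/kg."""

    time: float
    dose: float

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


def _check_schedule(schedule: Sequence[DoseEvent]) -> list[DoseEvent]:
    events = list(schedule)
    for prev, nxt in zip(events, events[1:]):
        if nxt.time <= prev.time:
            raise ValueError("dose times must be strictly increasing")
    return events


@dataclass
class Trajectory:
    """Dense model solution on a time grid, with the doses that shaped it."""

    time: np.ndarray
    states: np.ndarray  # shape (n, 3): columns x1, x2, x3
    dose_events: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.time.size, 3):
            raise ValueError("states must have shape (len(time), 3)")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def x3(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def total_volume(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]

    def state_at(self, t: float) -> TumorState:
        """State at time ``t`` by linear interpolation on the output grid."""
        vals = [float(np.interp(t, self.time, self.states[:, j])) for j in range(3)]
        vals = [0.0 if -NEGATIVE_CLIP_TOL < v < 0 else v for v in vals]
        return TumorState(*vals)

    def final_state(self) -> TumorState:
        return TumorState(*(float(v) for v in self.states[-1]))

    def to_frame(self):
        """Tidy frame with columns day, x1_mm3, x2_mm3, total_mm3, x3_mgkg."""
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.time,
                "x1_mm3": self.x1,
                "x2_mm3": self.x2,
                "total_mm3": self.total_volume,
                "x3_mgkg": self.x3,
            }
        )

    def plot(self, ax=None):
        """Quick look: volume compartments and drug level vs time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time, self.total_volume, label="total volume (mm³)")
        ax.plot(self.time, self.x1, "--", label="viable (mm³)")
        ax.plot(self.time, self.x2, ":", label="dead (mm³)")
        ax2 = ax.twinx()
        ax2.plot(self.time, self.x3, color="tab:red", alpha=0.6, label="drug (mg/kg)")
        for ev in self.dose_events:
            ax.axvline(ev.time, color="0.8", lw=0.5)
        ax.set_xlabel("day")
        ax.set_ylabel("volume (mm³)")
        ax2.set_ylabel("drug level (mg/kg eq.)")
        ax.legend(loc="upper left")
        return ax


def drug_effect(drug_level: float, params: ModelParameters) -> float:
    """Saturable (Emax) kill rate ``b·x/(ED50 + x)`` in 1/day.

    Half-maximal at ``drug_level == ed50``; bounded above by ``b``; strictly
    increasing and concave in the drug level.
    """
    if drug_level < 0:
        raise ValueError("drug_level must be >= 0")
    return params.b * drug_level / (params.ed50 + drug_level)


def net_growth_rate(drug_level: float, params: ModelParameters) -> float:
    """Instantaneous net growth rate of viable volume, ``(a-n) - E(x3)``.

    Positive sign means the viable compartment regrows at this drug level;
    zero is the regrowth-prevention boundary used by the stage-two MIC.
    """
    if drug_level < 0:
        raise ValueError("drug_level must be >= 0")
    return (params.a - params.n) - drug_effect(drug_level, params)


def rhs(state: TumorState, params: ModelParameters) -> tuple[float, float, float]:
    """Time derivative of (x1, x2, x3) in units per day."""
    x1, x2, x3 = state.as_tuple()
    kill = drug_effect(x3, params)
    dx1 = (params.a - params.n) * x1 - kill * x1
    dx2 = params.n * x1 + kill * x1 - params.w * x2
    dx3 = -params.c * x3 - params.k1 * x3 / (params.k2 + x3)
    return (dx1, dx2, dx3)


def apply_dose(state: TumorState, dose: float) -> TumorState:
    """Instantaneous bolus: raise the drug level by ``dose``, volumes unchanged."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return TumorState(
        state.proliferating_volume, state.dead_volume, state.drug_level + dose
    )


def _clip_states(arr: np.ndarray) -> np.ndarray:
    low = arr.min()
    if low < -NEGATIVE_CLIP_TOL:
        raise IntegrationError(
            f"state went negative beyond tolerance (min {low:.3e})", (np.nan, np.nan)
        )
    return np.clip(arr, 0.0, None)


def simulate(
    params: ModelParameters,
    initial: TumorState,
    schedule: Sequence[DoseEvent] = (),
    horizon: float = 30.0,
    grid_step: float = 0.1,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    t_eval: Iterable[float] | None = None,
    rhs_override: Callable | None = None,
    fast: bool = False,
    fast_dt: float = 0.02,
) -> Trajectory:
    """Simulate the digital twin over ``[0, horizon]`` days.

    Integration is split at every dose time so the solver never steps across
    an impulse; at a dose time only the drug state jumps (by exactly the
    dose).  The default output grid is uniform with step ``grid_step``;
    ``t_eval`` overrides it.  ``rhs_override(t, y) -> dy`` swaps the vector
    field (the functional pieces are configuration, not hard-coded callers).
    ``fast=True`` switches to the fixed-step Runge–Kutta path used internally
    by the planners (documented accuracy ~1e-8 relative at the default step).

    Raises
    ------
    IntegrationError
        If the solver fails; the exception carries the failing interval.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    events = _check_schedule(schedule)
    if events and (events[0].time < 0 or events[-1].time > horizon):
        raise ValueError("schedule times must lie within [0, horizon]")
    if t_eval is None:
        n_pts = int(round(horizon / grid_step))
        grid = np.linspace(0.0, horizon, n_pts + 1)
    else:
        grid = np.asarray(list(t_eval), dtype=float)
    ev = [(e.time, e.dose) for e in events]
    if fast and rhs_override is None:
        _, states = rk4_path(
            params.as_tuple(), initial.as_tuple(), ev, horizon, dt=fast_dt,
            sample_times=grid,
        )
    else:
        # grid handed to the piecewise integrator must not include t=0 twice;
        # prepend the initial state manually when the grid starts at 0
        states = np.empty((grid.size, 3))
        inner = grid
        starts_at_zero = grid.size and abs(grid[0]) <= 1e-12
        if starts_at_zero:
            inner = grid[1:]
        y0 = list(initial.as_tuple())
        # doses at exactly t=0 are applied before integration starts
        res = integrate_piecewise(
            params.as_tuple(), tuple(y0), ev, horizon, inner,
            rtol=rtol, atol=atol, rhs=rhs_override,
        )
        if starts_at_zero:
            y0_rep = list(initial.as_tuple())
            for t, d in ev:
                if abs(t) <= 1e-12:
                    y0_rep[2] += d
            states[0] = y0_rep
            states[1:] = res
        else:
            states = res
    states = _clip_states(states)
    return Trajectory(grid, states, events)
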
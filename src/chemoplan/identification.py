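"""Parameter identification from sparse observables.

Two fitted-model classes follow the familiar model/results pattern:

* :class:`TumorGrowthModel` — estimates tumor parameters (growth, necrosis,
  washout, kill, ED50 and optionally PK constants) from a caliper series plus
  the dosing record, by nonlinear least squares on log-volume residuals
  (multiplicative measurement error).
* :class:`PKDecayModel` — estimates the drug-elimination constants
  (clearance ``c``, saturable capacity ``k1``, half-saturation ``k2``) from
  sparse plasma samples taken after single boluses at one or more dose
  levels.

Both ``fit()`` methods run bounded multi-start least squares in log-parameter
space (positivity for free), return a results object carrying estimates,
standard errors, objective, convergence diagnostics and a ``summary()``
table.  The population-level routine approximates a nonlinear mixed-effects
analysis by the standard two-stage scheme: a pooled fit gives typical values;
per-subject refits are shrunk toward them by a configurable log-scale ridge
penalty; between-subject variability is the SD of the per-subject
log-estimates.  ``online_update`` is the trust-region re-fit the MPC loop
calls between doses.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._integrate import rk4_path
from .dynamics import DoseEvent, ModelParameters
from .measurement import CaliperSeries, VolumeFormula

__all__ = [
    "PlasmaSample",
    "FitResult",
    "PKResults",
    "PopulationResults",
    "TumorGrowthModel",
    "PKDecayModel",
    "IdentifiabilityError",
    "fit_individual",
    "fit_pk",
    "fit_population",
    "online_update",
]

PARAM_NAMES = (
    "growth_rate",
    "necrosis_rate",
    "washout_rate",
    "max_kill_rate",
    "ed50",
    "clearance",
    "elimination_vmax",
    "elimination_km",
)

#: parameters estimable from tumor-volume data by default; PK constants come
#: from the plasma fit and stay fixed here
DEFAULT_FREE = ("growth_rate", "max_kill_rate", "ed50")

_FLOOR = 1e-12  # volume floor inside log residuals


class IdentifiabilityError(ValueError):
    """The sampling design cannot constrain the requested parameters."""


@dataclass(frozen=True)
class PlasmaSample:
    """One plasma drug measurement: minutes since dosing and measured level."""

    time_min: float
    level: float

    def __post_init__(self):
        if self.time_min < 0 or self.level < 0:
            raise ValueError("time and level must be >= 0")

    @property
    def time_days(self) -> float:
        return self.time_min / 1440.0


def _data_hash(*chunks) -> str:
    h = hashlib.sha256()
    for c in chunks:
        h.update(json.dumps(c, sort_keys=True, default=float).encode())
    return h.hexdigest()[:16]


@dataclass
class FitResult:
    """Estimates with uncertainty and diagnostics from a single fit."""

    params: ModelParameters
    bse: dict[str, float | None]
    objective: float
    converged: bool
    free: tuple[str, ...]
    n_obs: int
    last_day: float
    nfev: int = 0
    message: str = ""
    notes: list[str] = field(default_factory=list)
    data_hash: str = ""
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            "Tumor/PK model fit",
            "=" * 58,
            f"n obs: {self.n_obs}    objective (0.5*SSR): {self.objective:.6g}",
            f"converged: {self.converged}    nfev: {self.nfev}",
            f"{'parameter':<20}{'estimate':>12}{'std err':>12}{'free':>6}",
            "-" * 58,
        ]
        for name in PARAM_NAMES:
            est = getattr(self.params, name)
            se = self.bse.get(name)
            se_s = f"{se:.4g}" if se is not None else "--"
            lines.append(
                f"{name:<20}{est:>12.5g}{se_s:>12}{('yes' if name in self.free else 'no'):>6}"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse,
            "objective": self.objective,
            "converged": self.converged,
            "free": list(self.free),
            "n_obs": self.n_obs,
            "last_day": self.last_day,
            "nfev": self.nfev,
            "message": self.message,
            "notes": self.notes,
            "data_hash": self.data_hash,
            "seed": self.seed,
        }


@dataclass
class PKResults:
    """Results of the plasma-decay fit (c, k1, k2 and optional scale)."""

    clearance: float
    elimination_vmax: float
    elimination_km: float
    scale: float
    bse: dict[str, float | None]
    objective: float
    converged: bool
    free: tuple[str, ...]
    n_obs: int
    nfev: int = 0
    message: str = ""

    def apply_to(self, params: ModelParameters) -> ModelParameters:
        """Copy the PK estimates into a tumor parameter set."""
        return params.replace(
            clearance=self.clearance,
            elimination_vmax=self.elimination_vmax,
            elimination_km=self.elimination_km,
        )

    def summary(self) -> str:
        lines = [
            "Plasma PK decay fit",
            "=" * 50,
            f"n obs: {self.n_obs}    objective: {self.objective:.6g}",
            f"converged: {self.converged}",
            f"{'parameter':<20}{'estimate':>12}{'std err':>12}",
            "-" * 50,
        ]
        for name in ("clearance", "elimination_vmax", "elimination_km", "scale"):
            se = self.bse.get(name)
            se_s = f"{se:.4g}" if se is not None else "--"
            lines.append(f"{name:<20}{getattr(self, name):>12.5g}{se_s:>12}")
        return "\n".join(lines)


@dataclass
class PopulationResults:
    """Two-stage population analysis: typical values, subject fits, BSV."""

    population: ModelParameters
    subjects: list[FitResult]
    bsv_log_sd: dict[str, float]
    shrinkage_weight: float

    def summary(self) -> str:
        lines = [
            f"Population fit ({len(self.subjects)} subjects, "
            f"shrinkage weight {self.shrinkage_weight:g})",
            "=" * 58,
            f"{'parameter':<20}{'typical':>12}{'BSV log-SD':>14}",
            "-" * 58,
        ]
        for name in PARAM_NAMES:
            sd = self.bsv_log_sd.get(name)
            sd_s = f"{sd:.4g}" if sd is not None else "--"
            lines.append(f"{name:<20}{getattr(self.population, name):>12.5g}{sd_s:>14}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "population": self.population.to_dict(),
            "subjects": [s.to_dict() for s in self.subjects],
            "bsv_log_sd": self.bsv_log_sd,
            "shrinkage_weight": self.shrinkage_weight,
        }


def _default_bounds(init: ModelParameters, free: Sequence[str]) -> dict:
    return {name: (getattr(init, name) / 100.0, getattr(init, name) * 100.0) for name in free}


def _multistart_least_squares(
    residual, x0_log, bounds_log, n_starts, seed, max_nfev=None
):
    """Seeded multi-start bounded least squares in log10-parameter space.

    Start 0 is the supplied initialization; the rest perturb it uniformly
    inside the box.  Best objective wins; ties go to the first start.
    """
    rng = np.random.default_rng(seed)
    lo, hi = bounds_log
    best = None
    for s in range(max(1, n_starts)):
        if s == 0:
            x0 = np.clip(x0_log, lo, hi)
        else:
            x0 = np.clip(x0_log + rng.uniform(-0.35, 0.35, size=len(x0_log)), lo, hi)
        try:
            sol = least_squares(
                residual, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
            )
        except Exception:  # noqa: BLE001 — a failed start is not fatal
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    return best


def _standard_errors(sol, names, estimates):
    """Delta-method SEs from the log10-space Jacobian; None when singular."""
    bse: dict[str, float | None] = {n: None for n in PARAM_NAMES}
    m, p = sol.jac.shape
    if m <= p:
        return bse
    try:
        jtj = sol.jac.T @ sol.jac
        cov_log = np.linalg.inv(jtj) * (2.0 * sol.cost / (m - p))
    except np.linalg.LinAlgError:
        return bse
    ln10 = np.log(10.0)
    for i, name in enumerate(names):
        var = cov_log[i, i]
        if var >= 0 and np.isfinite(var):
            bse[name] = float(estimates[i] * ln10 * np.sqrt(var))
    return bse


class TumorGrowthModel:
    """Nonlinear least-squares model of a caliper series under known dosing.

    Parameters
    ----------
    series : CaliperSeries
        Observed measurements.  Time is re-zeroed at the first measurement;
        the initial state assumes the tumor is fully viable and drug-free at
        that instant (pre-treatment data should therefore be included).
    doses : sequence of DoseEvent
        Administered boluses, in absolute days on the same clock as the series.
    formula : VolumeFormula
        Which caliper formula supplies the model-facing volumes.
    log_residuals : bool
        Residuals on log volume (default, multiplicative error) or raw volume.
    """

    def __init__(
        self,
        series: CaliperSeries,
        doses: Sequence[DoseEvent] = (),
        formula: VolumeFormula = VolumeFormula.LW2,
        log_residuals: bool = True,
        sim_dt: float = 0.05,
    ):
        if len(series) < 4:
            raise ValueError("need at least 4 measurements to fit")
        vols = series.volumes(formula)
        if np.all(vols <= 0):
            raise ValueError("degenerate series: no positive volumes")
        self.series = series
        self.formula = formula
        self.log_residuals = log_residuals
        self.sim_dt = sim_dt
        self.t0 = float(series.days[0])
        self.obs_days = series.days - self.t0
        self.obs_vols = vols
        self.doses = sorted(doses)
        self.events = [
            (d.time - self.t0, d.dose) for d in self.doses if d.time >= self.t0
        ]
        self.horizon = float(max(self.obs_days[-1], max((t for t, _ in self.events), default=0.0)))
        self._hash = _data_hash(
            list(map(float, self.obs_days)), list(map(float, self.obs_vols)),
            self.events,
        )

    # -- forward model -----------------------------------------------------
    def predict_volumes(self, params: ModelParameters, days=None) -> np.ndarray:
        """Model total volume on the given days (default: observation days)."""
        days = self.obs_days if days is None else np.asarray(days, dtype=float)
        y0 = (float(self.obs_vols[0]), 0.0, 0.0)
        _, states = rk4_path(
            params.as_tuple(), y0, self.events, max(self.horizon, days.max()),
            dt=self.sim_dt, sample_times=days,
        )
        return states[:, 0] + states[:, 1]

    def _residual_builder(self, init, free, shrink_to, shrink_weight):
        base = init.to_dict()

        def residual(x_log):
            p = dict(base)
            for name, v in zip(free, x_log):
                p[name] = 10.0**v
            try:
                params = ModelParameters.from_dict(p)
            except ValueError:
                return np.full(len(self.obs_vols) + len(free), 1e6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred = self.predict_volumes(params)
            if self.log_residuals:
                res = np.log(np.maximum(pred, _FLOOR)) - np.log(
                    np.maximum(self.obs_vols, _FLOOR)
                )
            else:
                res = pred - self.obs_vols
            if shrink_weight > 0 and shrink_to is not None:
                pen = np.sqrt(shrink_weight) * np.array(
                    [
                        np.log10(10.0**v) - np.log10(getattr(shrink_to, name))
                        for name, v in zip(free, x_log)
                    ]
                )
                res = np.concatenate([res, pen])
            elif shrink_to is not None:
                res = np.concatenate([res, np.zeros(len(free))])
            return res

        return residual

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        init: ModelParameters,
        free: Sequence[str] | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
        n_starts: int = 5,
        seed: int = 0,
        shrink_to: ModelParameters | None = None,
        shrink_weight: float = 0.0,
        max_nfev: int | None = None,
    ) -> FitResult:
        free = tuple(free) if free is not None else DEFAULT_FREE
        notes: list[str] = []
        drug_names = {"max_kill_rate", "ed50", "clearance", "elimination_vmax", "elimination_km"}
        if not self.events and any(f in drug_names for f in free):
            dropped = tuple(f for f in free if f in drug_names)
            free = tuple(f for f in free if f not in drug_names)
            notes.append(
                "no doses in data window: drug parameters "
                f"{dropped} not identifiable; returned at initialization"
            )
            warnings.warn(notes[-1], stacklevel=2)
        if not free:
            return FitResult(
                params=init, bse={n: None for n in PARAM_NAMES}, objective=float("nan"),
                converged=False, free=(), n_obs=len(self.obs_vols),
                last_day=float(self.series.days[-1]), notes=notes,
                data_hash=self._hash, seed=seed,
            )
        for f in free:
            if getattr(init, f) <= 0:
                raise ValueError(f"free parameter {f} needs a positive initialization")
        b = _default_bounds(init, free)
        if bounds:
            b.update({k: v for k, v in bounds.items() if k in free})
        lo = np.log10([b[f][0] for f in free])
        hi = np.log10([b[f][1] for f in free])
        x0 = np.log10([getattr(init, f) for f in free])
        residual = self._residual_builder(init, free, shrink_to, shrink_weight)
        sol = _multistart_least_squares(residual, x0, (lo, hi), n_starts, seed, max_nfev)
        if sol is None:
            return FitResult(
                params=init, bse={n: None for n in PARAM_NAMES}, objective=float("inf"),
                converged=False, free=free, n_obs=len(self.obs_vols),
                last_day=float(self.series.days[-1]),
                message="all optimizer starts failed", notes=notes,
                data_hash=self._hash, seed=seed,
            )
        est = {name: 10.0**v for name, v in zip(free, sol.x)}
        params = ModelParameters.from_dict({**init.to_dict(), **est})
        bse = _standard_errors(sol, free, [est[f] for f in free])
        return FitResult(
            params=params,
            bse=bse,
            objective=float(sol.cost),
            converged=bool(sol.status > 0),
            free=free,
            n_obs=len(self.obs_vols),
            last_day=float(self.series.days[-1]),
            nfev=int(sol.nfev),
            message=str(sol.message),
            notes=notes,
            data_hash=self._hash,
            seed=seed,
        )


class PKDecayModel:
    """Fit the drug-elimination submodel to sparse post-bolus plasma samples.

    ``samples_by_dose`` maps administered dose (mg/kg) to the plasma samples
    taken after that bolus.  The model integrates the drug state from
    ``x3(0) = dose`` and compares ``scale · x3(t)`` with the measured levels
    on the log scale.  Pre-dose (zero-level) samples anchor nothing in a
    single-bolus decay and are excluded.  The calibration ``scale`` maps
    dose-equivalent units to the measured concentration units; by default it
    is fixed at 1 (levels already in dose-equivalent units) and can be freed.
    """

    PK_NAMES = ("clearance", "elimination_vmax", "elimination_km")

    def __init__(
        self,
        samples_by_dose: dict[float, Sequence[PlasmaSample]],
        sim_dt: float = 0.01,
    ):
        self.groups = {
            float(d): [s for s in ss if s.level > 0 or s.time_min > 0]
            for d, ss in samples_by_dose.items()
        }
        self.groups = {d: ss for d, ss in self.groups.items() if ss}
        if not self.groups:
            raise ValueError("no usable plasma samples")
        times = {s.time_min for ss in self.groups.values() for s in ss}
        if len(times) < 3:
            raise IdentifiabilityError(
                "need samples at >= 3 distinct times to fit the decay"
            )
        self.n_obs = sum(len(ss) for ss in self.groups.values())
        self.sim_dt = sim_dt

    def predict(self, dose: float, times_min, c, k1, k2, scale=1.0) -> np.ndarray:
        t_days = np.asarray(times_min, dtype=float) / 1440.0
        horizon = max(float(t_days.max()), 1e-6)
        _, states = rk4_path(
            (0.0, 0.0, 0.0, 0.0, 1.0, c, k1, k2),
            (0.0, 0.0, float(dose)),
            [],
            horizon,
            dt=self.sim_dt,
            sample_times=t_days,
        )
        return scale * states[:, 2]

    def fit(
        self,
        init: tuple[float, float, float] = (0.2, 0.2, 1.0),
        fit_scale: bool = False,
        scale_init: float = 1.0,
        bounds: dict[str, tuple[float, float]] | None = None,
        n_starts: int = 5,
        seed: int = 0,
    ) -> PKResults:
        names = list(self.PK_NAMES) + (["scale"] if fit_scale else [])
        x0_vals = list(init) + ([scale_init] if fit_scale else [])
        default_b = {n: (v / 100.0, v * 100.0) for n, v in zip(names, x0_vals)}
        if bounds:
            default_b.update({k: v for k, v in bounds.items() if k in names})
        lo = np.log10([default_b[n][0] for n in names])
        hi = np.log10([default_b[n][1] for n in names])
        x0 = np.log10(x0_vals)

        doses = sorted(self.groups)
        obs_t = {d: np.array([s.time_min for s in self.groups[d]]) for d in doses}
        obs_y = {d: np.array([s.level for s in self.groups[d]]) for d in doses}

        def residual(x_log):
            v = 10.0**x_log
            c, k1, k2 = v[0], v[1], v[2]
            scale = v[3] if fit_scale else scale_init
            res = []
            for d in doses:
                pred = self.predict(d, obs_t[d], c, k1, k2, scale)
                res.append(
                    np.log(np.maximum(pred, _FLOOR))
                    - np.log(np.maximum(obs_y[d], _FLOOR))
                )
            return np.concatenate(res)

        sol = _multistart_least_squares(residual, x0, (lo, hi), n_starts, seed)
        if sol is None:
            raise RuntimeError("PK fit failed from every start")
        est = {n: 10.0**v for n, v in zip(names, sol.x)}
        bse_all = _standard_errors(sol, names, [est[n] for n in names])
        bse = {n: bse_all.get(n) for n in ("clearance", "elimination_vmax", "elimination_km")}
        bse["scale"] = bse_all.get("scale") if fit_scale else None
        return PKResults(
            clearance=est["clearance"],
            elimination_vmax=est["elimination_vmax"],
            elimination_km=est["elimination_km"],
            scale=est.get("scale", scale_init),
            bse=bse,
            objective=float(sol.cost),
            converged=bool(sol.status > 0),
            free=tuple(names),
            n_obs=self.n_obs,
            nfev=int(sol.nfev),
            message=str(sol.message),
        )


# ---------------------------------------------------------------------------
# spec-surface convenience functions
# ---------------------------------------------------------------------------


def fit_individual(
    series: CaliperSeries,
    doses: Sequence[DoseEvent],
    init: ModelParameters,
    free: Sequence[str] | None = None,
    bounds: dict | None = None,
    formula: VolumeFormula = VolumeFormula.LW2,
    n_starts: int = 5,
    seed: int = 0,
    **kw,
) -> FitResult:
    """Fit one subject's tumor parameters; see :class:`TumorGrowthModel`."""
    model = TumorGrowthModel(series, doses, formula=formula)
    return model.fit(init, free=free, bounds=bounds, n_starts=n_starts, seed=seed, **kw)


def fit_pk(
    samples_by_dose: dict[float, Sequence[PlasmaSample]],
    init: tuple[float, float, float] = (0.2, 0.2, 1.0),
    **kw,
) -> PKResults:
    """Fit (c, k1, k2) to sparse plasma decays; see :class:`PKDecayModel`."""
    return PKDecayModel(samples_by_dose).fit(init=init, **kw)


def fit_population(
    cohort: Sequence[tuple[CaliperSeries, Sequence[DoseEvent]]],
    init: ModelParameters,
    free: Sequence[str] | None = None,
    shrinkage_weight: float = 1.0,
    formula: VolumeFormula = VolumeFormula.LW2,
    n_starts: int = 3,
    seed: int = 0,
) -> PopulationResults:
    """Two-stage population analysis over >= 3 subjects.

    Stage 1 pools all subjects' residuals into one fit for typical values;
    stage 2 refits each subject initialized at — and ridge-shrunk toward —
    the typical values.  Between-subject variability per parameter is the SD
    of the per-subject log10 estimates (reported on the natural-log scale).
    """
    if len(cohort) < 3:
        raise ValueError("population fit requires >= 3 subjects")
    free = tuple(free) if free is not None else DEFAULT_FREE
    models = [TumorGrowthModel(s, d, formula=formula) for s, d in cohort]

    base = init.to_dict()
    b = _default_bounds(init, free)
    lo = np.log10([b[f][0] for f in free])
    hi = np.log10([b[f][1] for f in free])
    x0 = np.log10([getattr(init, f) for f in free])

    def pooled_residual(x_log):
        p = dict(base)
        for name, v in zip(free, x_log):
            p[name] = 10.0**v
        params = ModelParameters.from_dict(p)
        res = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for m in models:
                pred = m.predict_volumes(params)
                res.append(
                    np.log(np.maximum(pred, _FLOOR))
                    - np.log(np.maximum(m.obs_vols, _FLOOR))
                )
        return np.concatenate(res)

    sol = _multistart_least_squares(pooled_residual, x0, (lo, hi), n_starts, seed)
    if sol is None:
        raise RuntimeError("pooled population fit failed")
    pop = ModelParameters.from_dict(
        {**base, **{name: 10.0**v for name, v in zip(free, sol.x)}}
    )

    subjects = []
    for i, m in enumerate(models):
        fr = m.fit(
            pop, free=free, n_starts=n_starts, seed=seed + 1 + i,
            shrink_to=pop, shrink_weight=shrinkage_weight,
        )
        subjects.append(fr)

    bsv = {}
    for name in free:
        logs = np.log([getattr(s.params, name) for s in subjects])
        bsv[name] = float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0
    return PopulationResults(pop, subjects, bsv, shrinkage_weight)


def online_update(
    previous: FitResult,
    series: CaliperSeries,
    doses: Sequence[DoseEvent],
    max_log_step: float = 0.15,
    window_days: float | None = None,
    formula: VolumeFormula = VolumeFormula.LW2,
    n_starts: int = 1,
    max_nfev: int = 40,
    seed: int = 0,
) -> FitResult:
    """Warm-started re-fit for the MPC loop with a trust-region step bound.

    Each free parameter may move at most ``max_log_step`` in log10 per call
    (anti-chatter).  Default fits the full observation window; pass
    ``window_days`` for a sliding window.  With no new observations since
    ``previous`` the previous result is returned unchanged; on failure the
    previous estimate is carried forward with a warning.
    """
    if len(series) == 0 or float(series.days[-1]) <= previous.last_day:
        return previous
    if window_days is not None:
        series = series.window(series.days[-1] - window_days, series.days[-1])
    free = previous.free or DEFAULT_FREE
    bounds = {
        name: (
            getattr(previous.params, name) * 10.0 ** (-max_log_step),
            getattr(previous.params, name) * 10.0 ** (max_log_step),
        )
        for name in free
    }
    try:
        model = TumorGrowthModel(series, doses, formula=formula)
        result = model.fit(
            previous.params, free=free, bounds=bounds,
            n_starts=n_starts, seed=seed, max_nfev=max_nfev,
        )
    except ValueError as exc:
        warnings.warn(f"online update failed ({exc}); carrying previous estimate")
        return previous
    if not result.converged and not np.isfinite(result.objective):
        warnings.warn("online update did not converge; carrying previous estimate")
        return previous
    return result
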
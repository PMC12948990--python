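"""Internal integrators for the three-state tumor/PK system.

Two paths share the same right-hand side:

* :func:`integrate_piecewise` — reference path built on
  :func:`scipy.integrate.solve_ivp` (stiff-capable LSODA, tight tolerances,
  never stepping across a dose impulse).  Used by the public
  :func:`chemoplan.dynamics.simulate`.
* :func:`rk4_path` — fixed-step classic Runge-Kutta in plain Python floats.
  The system is smooth and mildly stiff at most, so a 0.02–0.05 day step is
  far inside the asymptotic regime; this path exists because planners and
  controllers evaluate thousands of candidate schedules per decision and the
  adaptive solver's per-call overhead dominates at that scale.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["integrate_piecewise", "rk4_path", "rk4_final_state"]


def _make_rhs(a, n, w, b, ed50, c, k1, k2):
    def rhs(t, y):
        x1, x2, x3 = y
        x3p = x3 if x3 > 0.0 else 0.0
        kill = b * x3p / (ed50 + x3p)
        dx1 = (a - n) * x1 - kill * x1
        dx2 = n * x1 + kill * x1 - w * x2
        dx3 = -c * x3p - k1 * x3p / (k2 + x3p)
        return (dx1, dx2, dx3)

    return rhs


class IntegrationError(RuntimeError):
    """Adaptive solver failed on an interval.

    Carries the failing interval as ``(t0, t1)`` in :attr:`interval`.
    """

    def __init__(self, message: str, interval: tuple[float, float]):
        super().__init__(message)
        self.interval = interval


def integrate_piecewise(
    coeffs: tuple,
    y0: tuple[float, float, float],
    events: list[tuple[float, float]],
    t_end: float,
    grid: np.ndarray,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    rhs=None,
) -> np.ndarray:
    """Integrate from t=0 to t_end with dose impulses, sampling on ``grid``.

    ``events`` is a list of (time, dose) with strictly increasing times in
    [0, t_end]; each dose is added to the third state instantaneously.  The
    returned array has shape (len(grid), 3); a grid point that coincides with
    a dose time reports the post-impulse state.
    """
    f = rhs if rhs is not None else _make_rhs(*coeffs)
    grid = np.asarray(grid, dtype=float)
    out = np.empty((grid.size, 3))
    y = [float(v) for v in y0]
    t0 = 0.0
    # breakpoints: dose times then horizon end
    breakpoints = [(t, d) for t, d in events] + [(t_end, None)]
    filled = 0
    eps = 1e-9  # grid/event coincidence tolerance, days
    for t1, dose in breakpoints:
        if t1 < t0 - eps:
            raise ValueError("event times must be non-decreasing")
        if dose is not None and abs(t1 - t0) <= eps:
            # impulse at current instant (possibly t=0 or coincident events)
            y[2] += dose
            continue
        # grid points strictly inside (t0, t1); points at t1 are reported
        # post-impulse, points at t0 were reported by the previous segment
        sel = (grid > t0 + eps) & (grid < t1 - eps)
        t_eval = grid[sel]
        # sample the pre-impulse state at t1 only to continue integration
        sol = solve_ivp(
            f,
            (t0, t1),
            y,
            method="LSODA",
            t_eval=np.concatenate([t_eval, [t1]]),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{t0:g}, {t1:g}]: {sol.message}", (t0, t1)
            )
        k = int(sel.sum())
        if k:
            out[filled : filled + k] = sol.y[:, :k].T
            filled += k
        y = [float(sol.y[0, -1]), float(sol.y[1, -1]), float(sol.y[2, -1])]
        if dose is not None:
            y[2] += dose
        # report grid points sitting (numerically) on t1 post-impulse
        on = np.abs(grid - t1) <= eps
        k_on = int(on.sum())
        if k_on:
            out[filled : filled + k_on] = np.array(y)
            filled += k_on
        t0 = t1
    # grid point at exactly 0 (pre-loop) — handled here for grids starting at 0
    if filled != grid.size:
        raise ValueError("grid points outside [0, horizon]")
    return out


def _py_rk4_segment(x1, x2, x3, h, nsteps, a, n, w, b, ed50, c, k1, k2, out):
    """Advance nsteps of size h from (x1,x2,x3); fill ``out`` when non-empty.

    Returns the final state.  ``out`` has shape (nsteps, 3) (or (0, 3) for a
    final-state-only run).
    """
    store = out.shape[0] > 0
    an = a - n
    for i in range(nsteps):
        x3p = x3 if x3 > 0.0 else 0.0
        kl = b * x3p / (ed50 + x3p)
        d1a = an * x1 - kl * x1
        d2a = n * x1 + kl * x1 - w * x2
        d3a = -c * x3p - k1 * x3p / (k2 + x3p)
        u1 = x1 + 0.5 * h * d1a
        u2 = x2 + 0.5 * h * d2a
        u3 = x3 + 0.5 * h * d3a
        u3p = u3 if u3 > 0.0 else 0.0
        kl = b * u3p / (ed50 + u3p)
        d1b = an * u1 - kl * u1
        d2b = n * u1 + kl * u1 - w * u2
        d3b = -c * u3p - k1 * u3p / (k2 + u3p)
        u1 = x1 + 0.5 * h * d1b
        u2 = x2 + 0.5 * h * d2b
        u3 = x3 + 0.5 * h * d3b
        u3p = u3 if u3 > 0.0 else 0.0
        kl = b * u3p / (ed50 + u3p)
        d1c = an * u1 - kl * u1
        d2c = n * u1 + kl * u1 - w * u2
        d3c = -c * u3p - k1 * u3p / (k2 + u3p)
        u1 = x1 + h * d1c
        u2 = x2 + h * d2c
        u3 = x3 + h * d3c
        u3p = u3 if u3 > 0.0 else 0.0
        kl = b * u3p / (ed50 + u3p)
        d1d = an * u1 - kl * u1
        d2d = n * u1 + kl * u1 - w * u2
        d3d = -c * u3p - k1 * u3p / (k2 + u3p)
        s = h / 6.0
        x1 += s * (d1a + 2.0 * d1b + 2.0 * d1c + d1d)
        x2 += s * (d2a + 2.0 * d2b + 2.0 * d2c + d2d)
        x3 += s * (d3a + 2.0 * d3b + 2.0 * d3c + d3d)
        if x3 < 0.0:
            x3 = 0.0
        if store:
            out[i, 0] = x1
            out[i, 1] = x2
            out[i, 2] = x3
    return x1, x2, x3


def _py_rk4_sq_integral(x1, x2, x3, h, nsteps, a, n, w, b, ed50, c, k1, k2):
    """Trapezoidal integral of (x1+x2)^2 over the segment, fused with RK4."""
    acc = 0.0
    prev = (x1 + x2) ** 2
    an = a - n
    for _ in range(nsteps):
        x3p = x3 if x3 > 0.0 else 0.0
        kl = b * x3p / (ed50 + x3p)
        d1a = an * x1 - kl * x1
        d2a = n * x1 + kl * x1 - w * x2
        d3a = -c * x3p - k1 * x3p / (k2 + x3p)
        u1 = x1 + 0.5 * h * d1a
        u2 = x2 + 0.5 * h * d2a
        u3 = x3 + 0.5 * h * d3a
        u3p = u3 if u3 > 0.0 else 0.0
        kl = b * u3p / (ed50 + u3p)
        d1b = an * u1 - kl * u1
        d2b = n * u1 + kl * u1 - w * u2
        d3b = -c * u3p - k1 * u3p / (k2 + u3p)
        u1 = x1 + 0.5 * h * d1b
        u2 = x2 + 0.5 * h * d2b
        u3 = x3 + 0.5 * h * d3b
        u3p = u3 if u3 > 0.0 else 0.0
        kl = b * u3p / (ed50 + u3p)
        d1c = an * u1 - kl * u1
        d2c = n * u1 + kl * u1 - w * u2
        d3c = -c * u3p - k1 * u3p / (k2 + u3p)
        u1 = x1 + h * d1c
        u2 = x2 + h * d2c
        u3 = x3 + h * d3c
        u3p = u3 if u3 > 0.0 else 0.0
        kl = b * u3p / (ed50 + u3p)
        d1d = an * u1 - kl * u1
        d2d = n * u1 + kl * u1 - w * u2
        d3d = -c * u3p - k1 * u3p / (k2 + u3p)
        s = h / 6.0
        x1 += s * (d1a + 2.0 * d1b + 2.0 * d1c + d1d)
        x2 += s * (d2a + 2.0 * d2b + 2.0 * d2c + d2d)
        x3 += s * (d3a + 2.0 * d3b + 2.0 * d3c + d3d)
        if x3 < 0.0:
            x3 = 0.0
        cur = (x1 + x2) ** 2
        acc += 0.5 * h * (prev + cur)
        prev = cur
    return acc, x1, x2, x3


try:  # compiled kernels; the pure-Python bodies above are the fallback
    from numba import njit

    _rk4_segment = njit(cache=True)(_py_rk4_segment)
    _rk4_sq_integral = njit(cache=True)(_py_rk4_sq_integral)
except ImportError:  # pragma: no cover - numba is normally available
    _rk4_segment = _py_rk4_segment
    _rk4_sq_integral = _py_rk4_sq_integral

_EMPTY = np.empty((0, 3))


def rk4_path(coeffs, y0, events, t_end, dt=0.05, sample_times=None):
    """Fast fixed-step path; returns (times, states) as float arrays.

    Dose impulses are applied exactly at their event times (segments are cut
    there).  If ``sample_times`` is given, states are linearly interpolated
    onto it from the internal step grid.
    """
    a, n, w, b, ed50, c, k1, k2 = coeffs
    x1, x2, x3 = float(y0[0]), float(y0[1]), float(y0[2])
    times = [np.array([0.0])]
    path = [np.array([[x1, x2, x3]])]
    t0 = 0.0
    for t1, dose in sorted(events) + [(float(t_end), None)]:
        if t1 > t0 + 1e-12:
            span = t1 - t0
            nsteps = max(1, int(round(span / dt)))
            h = span / nsteps
            seg = np.empty((nsteps, 3))
            x1, x2, x3 = _rk4_segment(
                x1, x2, x3, h, nsteps, a, n, w, b, ed50, c, k1, k2, seg
            )
            times.append(t0 + h * np.arange(1, nsteps + 1))
            path.append(seg)
        if dose is not None:
            x3 += dose
            # keep times strictly increasing across the jump so interpolation
            # at the dose time reports the post-impulse state
            last = times[-1]
            if last[-1] >= t1 - 1e-9:
                last[-1] = t1 - 1e-9
            times.append(np.array([t1]))
            path.append(np.array([[x1, x2, x3]]))
        t0 = t1
    t_arr = np.concatenate(times)
    s_arr = np.concatenate(path)
    if sample_times is not None:
        st = np.asarray(sample_times, dtype=float)
        out = np.empty((st.size, 3))
        for j in range(3):
            out[:, j] = np.interp(st, t_arr, s_arr[:, j])
        return st, out
    return t_arr, s_arr


def rk4_final_state(coeffs, y0, events, t_end, dt=0.05):
    """Final state only (no path storage) — the planner/controller hot path."""
    a, n, w, b, ed50, c, k1, k2 = coeffs
    x1, x2, x3 = float(y0[0]), float(y0[1]), float(y0[2])
    t0 = 0.0
    for t1, dose in sorted(events) + [(float(t_end), None)]:
        if t1 > t0 + 1e-12:
            span = t1 - t0
            nsteps = max(1, int(round(span / dt)))
            x1, x2, x3 = _rk4_segment(
                x1, x2, x3, span / nsteps, nsteps, a, n, w, b, ed50, c, k1, k2,
                _EMPTY,
            )
        if dose is not None:
            x3 += dose
        t0 = t1
    return [x1, x2, x3]


def rk4_sq_volume_integral(coeffs, y0, events, t_end, dt=0.05):
    """Trapezoidal ∫(x1+x2)² dt over [0, t_end] with impulses; fused kernel.

    Returns (integral, final_state).  Matches a trapezoid over the dense RK4
    step grid (impulses change only x3, so they add no area)."""
    a, n, w, b, ed50, c, k1, k2 = coeffs
    x1, x2, x3 = float(y0[0]), float(y0[1]), float(y0[2])
    acc = 0.0
    t0 = 0.0
    for t1, dose in sorted(events) + [(float(t_end), None)]:
        if t1 > t0 + 1e-12:
            span = t1 - t0
            nsteps = max(1, int(round(span / dt)))
            part, x1, x2, x3 = _rk4_sq_integral(
                x1, x2, x3, span / nsteps, nsteps, a, n, w, b, ed50, c, k1, k2
            )
            acc += part
        if dose is not None:
            x3 += dose
        t0 = t1
    return acc, [x1, x2, x3]
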
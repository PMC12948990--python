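"""MPC controller: cost properties, oracle equivalence, closed loop."""

import numpy as np
import pytest

from chemoplan import (
    DoseEvent,
    FitResult,
    MPCConfig,
    ModelParameters,
    TumorState,
    audit_decision,
    horizon_cost,
    lattice_search,
    optimize_step,
    run_closed_loop,
    simulate,
)
from chemoplan.identification import PARAM_NAMES


def _perfect_estimate(params):
    return FitResult(
        params=params, bse={n: None for n in PARAM_NAMES}, objective=0.0,
        converged=True, free=(), n_obs=0, last_day=-1.0,
    )


@pytest.fixture
def two_dose_config():
    return MPCConfig(
        prediction_horizon=4.0,
        injection_offsets=(0.0, 2.0),
        dose_weight=5.0,
        n_starts=5,
        sim_dt=0.05,
    )


class TestHorizonCost:
    def test_zero_at_cured_untreated(self):
        t = np.linspace(0, 7, 71)
        assert horizon_cost(t, np.zeros_like(t), [0, 0], 1.0, 1.0) == 0.0

    def test_dose_weight_ablation(self):
        t = np.linspace(0, 7, 71)
        v = np.full_like(t, 50.0)
        c1 = horizon_cost(t, v, [1, 2], 1.0, 0.0)
        c2 = horizon_cost(t, v, [5, 6], 1.0, 0.0)
        assert c1 == c2

    def test_quadratic_dose_homogeneity(self):
        t = np.linspace(0, 7, 71)
        v = np.full_like(t, 50.0)
        base = horizon_cost(t, v, [1, 2], 0.0, 3.0)
        assert horizon_cost(t, v, [2, 4], 0.0, 3.0) == pytest.approx(4 * base)

    def test_tumor_term_is_time_integral(self):
        t = np.linspace(0, 2, 201)
        v = np.full_like(t, 10.0)
        assert horizon_cost(t, v, [], 1.0, 0.0) == pytest.approx(200.0, rel=1e-9)


class TestOptimizeStep:
    def test_cured_subject_gets_no_dose(self, params, two_dose_config):
        dec = optimize_step(
            TumorState(0.0, 0.0, 0.0), params, two_dose_config, seed=0
        )
        assert np.all(dec.doses == 0.0)

    def test_matches_lattice_oracle(self, params, two_dose_config):
        """On 2-dose horizons the optimizer agrees with exhaustive search
        within one 0.1 mg/kg lattice step per coordinate and 0.1% in cost."""
        rng = np.random.default_rng(42)
        for trial in range(5):
            v0 = float(rng.uniform(20, 400))
            state = TumorState(v0, v0 * float(rng.uniform(0, 0.3)), 0.0)
            dec = optimize_step(state, params, two_dose_config, seed=trial)
            oracle = lattice_search(state, params, two_dose_config, step=0.1)
            assert np.all(np.abs(dec.doses - oracle.doses) <= 0.1 + 1e-9)
            assert dec.cost <= oracle.cost * 1.001

    def test_weight_asymptotics(self, params):
        state = TumorState(300.0, 30.0, 0.0)
        heavy_r = MPCConfig(
            prediction_horizon=4.0, injection_offsets=(0.0, 2.0),
            dose_weight=1e9, n_starts=3,
        )
        dec = optimize_step(state, params, heavy_r, seed=0)
        assert dec.total_dose == pytest.approx(0.0, abs=0.01)
        zero_r = MPCConfig(
            prediction_horizon=4.0, injection_offsets=(0.0, 2.0),
            dose_weight=0.0, cumulative_cap=float("inf"), n_starts=3,
        )
        dec = optimize_step(state, params, zero_r, seed=0)
        # fast-growing tumor, free drug: both doses pinned at the cap
        assert np.all(dec.doses >= zero_r.dose_max - 0.05)

    def test_monotone_in_tumor_weight(self, params):
        state = TumorState(60.0, 10.0, 0.0)
        totals = []
        for q in (0.01, 0.1, 1.0, 10.0):
            cfg = MPCConfig(
                prediction_horizon=4.0, injection_offsets=(0.0, 2.0),
                tumor_weight=q, dose_weight=100.0, n_starts=5,
            )
            totals.append(optimize_step(state, params, cfg, seed=0).total_dose)
        for lo, hi in zip(totals, totals[1:]):
            assert hi >= lo - 0.05

    def test_deterministic_under_seed(self, params, two_dose_config):
        state = TumorState(150.0, 10.0, 0.5)
        d1 = optimize_step(state, params, two_dose_config, seed=9)
        d2 = optimize_step(state, params, two_dose_config, seed=9)
        assert np.array_equal(d1.doses, d2.doses)
        assert d1.cost == d2.cost


class TestConstraints:
    def test_auditor_passes_clean_decision(self, params, two_dose_config):
        dec = optimize_step(
            TumorState(200.0, 0.0, 0.0), params, two_dose_config, seed=0
        )
        assert audit_decision(dec, two_dose_config) == []

    def test_auditor_flags_bound_violation(self, params, two_dose_config):
        dec = optimize_step(
            TumorState(200.0, 0.0, 0.0), params, two_dose_config, seed=0
        )
        dec.doses = np.array([99.0, 0.0])
        assert any("outside bounds" in v for v in audit_decision(dec, two_dose_config))

    def test_auditor_flags_spacing_violation(self, params):
        cfg = MPCConfig(
            prediction_horizon=4.0, injection_offsets=(0.0, 2.0), min_spacing=1.0
        )
        dec = optimize_step(TumorState(200.0, 0.0, 0.0), params, cfg, seed=0)
        dec.doses = np.array([3.0, 3.0])
        past = [(-0.5, 6.0)]  # a dose half a day before the first offset
        assert any("spacing" in v for v in audit_decision(dec, cfg, past))

    def test_cumulative_cap_respected(self, params):
        cfg = MPCConfig(
            prediction_horizon=4.0, injection_offsets=(0.0, 2.0),
            cumulative_cap=4.0, cumulative_window=14.0, dose_weight=0.0,
            n_starts=3,
        )
        dec = optimize_step(TumorState(500.0, 0.0, 0.0), params, cfg, seed=0)
        assert dec.feasible
        assert dec.total_dose <= 4.0 + 1e-6
        assert audit_decision(dec, cfg) == []

    def test_spacing_forces_zero_near_past_dose(self, params):
        cfg = MPCConfig(
            prediction_horizon=4.0, injection_offsets=(0.0, 2.0),
            min_spacing=1.0, dose_weight=0.0, n_starts=2,
        )
        dec = optimize_step(
            TumorState(500.0, 0.0, 0.0), params, cfg,
            past_doses=[(-0.5, 6.0)], epoch_day=0.0, seed=0,
        )
        assert dec.doses[0] == 0.0  # too close to the previous injection


class TestClosedLoop:
    def test_null_controller_reproduces_untreated_growth(self, params):
        cfg = MPCConfig(
            prediction_horizon=4.0, injection_offsets=(0.0, 2.0),
            dose_max=0.0, decision_cadence=2.0, n_starts=1,
        )
        start = TumorState(50.0, 0.0, 0.0)
        rec = run_closed_loop(
            params, start, _perfect_estimate(params), cfg,
            max_days=10.0, identification_enabled=False, seed=0,
        )
        assert rec.cumulative_dose == 0.0
        ref = simulate(params, start, [], horizon=10.0)
        assert rec.truth_trajectory.states[-1][0] == pytest.approx(
            ref.x1[-1], rel=1e-5
        )

    def test_controls_tumor_with_perfect_model(self, params):
        cfg = MPCConfig(
            prediction_horizon=6.0, injection_offsets=(0.0, 2.0, 4.0),
            decision_cadence=2.0, n_starts=2, maxfev=150,
        )
        start = TumorState(250.0, 0.0, 0.0)
        rec = run_closed_loop(
            params, start, _perfect_estimate(params), cfg,
            max_days=40.0, identification_enabled=False, seed=1,
        )
        final_total = sum(rec.truth_trajectory.states[-1][:2])
        assert final_total < 250.0
        assert rec.cumulative_dose > 0.0

    def test_bitwise_deterministic(self, params):
        cfg = MPCConfig(
            prediction_horizon=4.0, injection_offsets=(0.0, 2.0),
            decision_cadence=2.0, n_starts=2,
        )
        kw = dict(max_days=12.0, identification_enabled=False, seed=7)
        r1 = run_closed_loop(
            params, TumorState(220.0, 0.0, 0.0), _perfect_estimate(params), cfg, **kw
        )
        r2 = run_closed_loop(
            params, TumorState(220.0, 0.0, 0.0), _perfect_estimate(params), cfg, **kw
        )
        assert [(d.time, d.dose) for d in r1.doses] == [
            (d.time, d.dose) for d in r2.doses
        ]
        assert np.array_equal(r1.truth_trajectory.states, r2.truth_trajectory.states)

    def test_receding_horizon_tail_consistency(self, params):
        """With a perfect model, no noise and a separable cost (r = 0), the
        shrunken-horizon subproblem at the next epoch reproduces the tail of
        the previous decision within optimizer tolerance."""
        full = MPCConfig(
            prediction_horizon=6.0, injection_offsets=(0.0, 2.0, 4.0),
            dose_weight=0.0, cumulative_cap=float("inf"),
            n_starts=3, maxfev=400,
        )
        tail = MPCConfig(
            prediction_horizon=4.0, injection_offsets=(0.0, 2.0),
            dose_weight=0.0, cumulative_cap=float("inf"),
            n_starts=3, maxfev=400,
        )
        state = TumorState(400.0, 0.0, 0.0)
        dec1 = optimize_step(state, params, full, seed=0)
        applied = [
            DoseEvent(t, d)
            for t, d in zip(dec1.injection_times, dec1.doses)
            if d > 0 and t < 2.0
        ]
        traj = simulate(params, state, applied, horizon=2.0)
        dec2 = optimize_step(traj.final_state(), params, tail, seed=1)
        assert dec2.doses[0] == pytest.approx(dec1.doses[1], abs=0.2)
        assert dec2.doses[1] == pytest.approx(dec1.doses[2], abs=0.2)
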
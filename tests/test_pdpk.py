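"""Two-stage MIC planner: analytic MICs, stage switch, greedy schedules."""

import math

import numpy as np
import pytest

from chemoplan import (
    CaliperMeasurement,
    CaliperSeries,
    ModelParameters,
    PDPKConfig,
    dims_from_volume,
    drug_effect,
    mic_effectiveness,
    mic_regrowth,
    net_growth_rate,
    plan_schedule,
    select_stage,
)
from chemoplan.pdpk import STAGE_EFFECTIVENESS, STAGE_REGROWTH


@pytest.fixture
def mic_params():
    # a-n = 0.1, b = 0.3, ED50 = 5 (the worked MIC example set)
    return ModelParameters(0.15, 0.05, 0.1, 0.3, 5.0, 0.2, 0.0, 1.0)


class TestMICEffectiveness:
    def test_99_percent_value(self, mic_params):
        mic = mic_effectiveness(mic_params, 0.99)
        assert mic.concentration == pytest.approx(495.0)
        assert mic.strategy == STAGE_EFFECTIVENESS

    def test_half_effectiveness_is_ed50(self, mic_params):
        assert mic_effectiveness(mic_params, 0.5).concentration == pytest.approx(5.0)

    def test_round_trip_through_pd_model(self, mic_params):
        """Evaluating the MIC back through the kill term returns the level."""
        for level in (0.5, 0.9, 0.99, 0.999):
            mic = mic_effectiveness(mic_params, level)
            achieved = drug_effect(mic.concentration, mic_params) / mic_params.b
            assert achieved == pytest.approx(level, abs=1e-12)

    def test_monotone_in_level(self, mic_params):
        assert (
            mic_effectiveness(mic_params, 0.999).concentration
            > mic_effectiveness(mic_params, 0.99).concentration
        )

    def test_full_effectiveness_infeasible(self, mic_params):
        assert not mic_effectiveness(mic_params, 1.0).feasible


class TestMICRegrowth:
    def test_worked_example(self, mic_params):
        mic = mic_regrowth(mic_params)
        assert mic.concentration == pytest.approx(2.5)
        assert mic.strategy == STAGE_REGROWTH

    def test_zeroes_net_growth(self, mic_params):
        mic = mic_regrowth(mic_params)
        assert net_growth_rate(mic.concentration, mic_params) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_shrinking_tumor_needs_nothing(self):
        with pytest.warns(UserWarning):
            p = ModelParameters(0.05, 0.1, 0.1, 0.3, 5.0, 0.2, 0.0, 1.0)
        assert mic_regrowth(p).concentration == 0.0

    def test_infeasible_when_kill_saturates_below_growth(self):
        p = ModelParameters(0.4, 0.0, 0.1, 0.4, 5.0, 0.2, 0.0, 1.0)
        assert not mic_regrowth(p).feasible

    def test_below_stage_one_mic_when_moderate_growth(self, mic_params):
        # (a-n)/b = 1/3 < 0.99: the stage switch reduces the target level
        assert (
            mic_regrowth(mic_params).concentration
            < mic_effectiveness(mic_params, 0.99).concentration
        )


def _flat_series(volume, days):
    ms = []
    for d in days:
        length, width = dims_from_volume(volume, 1.2)
        ms.append(CaliperMeasurement(d, length, width))
    return CaliperSeries("s", ms)


class TestSelectStage:
    CFG = PDPKConfig()

    def test_low_plateau_switches(self):
        series = _flat_series(15.0, range(0, 15, 2))
        assert select_stage(series, self.CFG) == STAGE_REGROWTH

    def test_one_violation_resets(self):
        ms = list(_flat_series(15.0, range(0, 13, 2)).measurements)
        length, width = dims_from_volume(25.0, 1.2)
        ms.append(CaliperMeasurement(14, length, width))
        assert select_stage(CaliperSeries("s", ms), self.CFG) == STAGE_EFFECTIVENESS

    def test_short_window_is_conservative(self):
        series = _flat_series(15.0, range(0, 8, 2))
        assert select_stage(series, self.CFG) == STAGE_EFFECTIVENESS

    def test_boundary_plateau_by_bisection(self):
        """Largest constant plateau that still switches sits just under the
        volume threshold (the threshold itself is exclusive)."""
        days = range(0, 15, 2)
        lo, hi = 1.0, 40.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if select_stage(_flat_series(mid, days), self.CFG) == STAGE_REGROWTH:
                lo = mid
            else:
                hi = mid
        assert lo == pytest.approx(self.CFG.switch_volume, rel=1e-6)
        just_above = self.CFG.switch_volume * (1 + 1e-6)
        assert (
            select_stage(_flat_series(just_above, days), self.CFG)
            == STAGE_EFFECTIVENESS
        )


class TestPlanSchedule:
    def test_linear_pk_maintenance_dose_closed_form(self):
        """With linear PK only, the steady daily top-up is MIC·(e^c - 1)."""
        p = ModelParameters(0.15, 0.05, 0.1, 0.3, 5.0, 0.2, 0.0, 1.0)
        mic = mic_regrowth(p)  # 2.5
        cfg = PDPKConfig(dose_step=1e-6, dose_max=50.0, planning_horizon=10.0)
        plan = plan_schedule(p, mic, cfg, initial_level=mic.concentration)
        expected = mic.concentration * (math.exp(p.clearance * 1.0) - 1.0)
        steady = [e.dose for e in plan.dose_events]
        assert steady[-1] == pytest.approx(expected, rel=1e-3)
        assert plan.coverage_ok()

    def test_no_topup_when_level_already_high(self):
        p = ModelParameters(0.15, 0.05, 0.1, 0.3, 5.0, 0.2, 0.0, 1.0)
        mic = mic_regrowth(p)
        cfg = PDPKConfig(planning_horizon=5.0, dose_max=50.0)
        start = mic.concentration * math.exp(p.clearance * cfg.planning_horizon)
        plan = plan_schedule(p, mic, cfg, initial_level=start * 1.01)
        assert plan.dose_events == []
        assert plan.coverage_ok()

    def test_coverage_everywhere_on_dense_grid(self, params):
        mic = mic_effectiveness(params, 0.99)
        plan = plan_schedule(params, mic, PDPKConfig(planning_horizon=14.0))
        assert plan.coverage_ok()
        covered = plan.predicted.x3 >= mic.concentration - 1e-9
        # every grid point from the first injection onward is covered
        assert covered[1:].all()

    def test_single_step_reduction_breaks_coverage(self, params):
        """Greedy minimality: shaving one quantum off any positive dose
        violates the MIC constraint in that dose's interval."""
        from chemoplan.pdpk import _min_level_over_interval

        cfg = PDPKConfig(planning_horizon=7.0)
        mic = mic_effectiveness(params, 0.99)
        plan = plan_schedule(params, mic, cfg)
        assert plan.coverage_ok()
        times = list(cfg.injection_times()) + [cfg.planning_horizon]
        for cov in plan.coverage:
            if cov["dose"] <= cfg.dose_min:
                continue
            # re-simulate this interval with the dose reduced one step
            i = times.index(cov["t_start"])
            # reconstruct the level carried into the interval
            level_in = cov["min_level"]  # level at interval end >= MIC
            lvl = _min_level_over_interval(
                params,
                _carried_level(params, plan, cfg, cov["t_start"]),
                cov["dose"] - cfg.dose_step,
                times[i + 1] - times[i],
                0.02,
            )
            assert lvl < mic.concentration

    def test_partial_plan_flagged_when_cap_insufficient(self):
        p = ModelParameters(0.3, 0.0, 0.1, 0.35, 0.5, 3.0, 0.5, 1.0)
        mic = mic_effectiveness(p, 0.99)  # 49.5, far above any bounded dose
        plan = plan_schedule(p, mic, PDPKConfig(planning_horizon=3.0))
        assert not plan.feasible
        assert any(not c["covered"] for c in plan.coverage)

    def test_deterministic(self, params):
        cfg = PDPKConfig(planning_horizon=10.0)
        mic = mic_effectiveness(params, 0.99)
        p1 = plan_schedule(params, mic, cfg)
        p2 = plan_schedule(params, mic, cfg)
        assert [(e.time, e.dose) for e in p1.dose_events] == [
            (e.time, e.dose) for e in p2.dose_events
        ]

    def test_infeasible_mic_rejected(self, params):
        bad = mic_effectiveness(params, 1.0)
        with pytest.raises(ValueError):
            plan_schedule(params, bad, PDPKConfig())


def _carried_level(params, plan, cfg, t_start):
    """Drug level entering an interval, from the plan's own prediction."""
    if t_start == 0.0:
        prior = [c["dose"] for c in plan.coverage if c["t_start"] < t_start]
        return 0.0
    idx = int(np.argmin(np.abs(plan.predicted.time - t_start)))
    level = plan.predicted.x3[idx]
    # subtract the dose injected at t_start itself (prediction is post-dose)
    dose_here = next(
        (c["dose"] for c in plan.coverage if c["t_start"] == t_start), 0.0
    )
    return max(level - dose_here, 0.0)
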
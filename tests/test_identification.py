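"""Parameter identification: recovery, determinism, shrinkage, PK fits."""

import warnings

import numpy as np
import pytest

from chemoplan import (
    DoseEvent,
    ModelParameters,
    ObservationModel,
    PKDecayModel,
    PlasmaSample,
    TumorGrowthModel,
    TumorState,
    fit_individual,
    fit_pk,
    fit_population,
    observe,
    online_update,
    simulate,
)
from chemoplan.identification import IdentifiabilityError


def _noiseless_series(params, v0=30.0, doses=(), horizon=40.0, cadence=2):
    traj = simulate(
        params, TumorState(v0, 0.0, 0.0),
        [DoseEvent(t, d) for t, d in doses], horizon=horizon,
    )
    return observe(traj, ObservationModel(cadence=cadence, noise_cv=0.0))


@pytest.fixture
def truth():
    return ModelParameters(0.25, 0.05, 0.5, 0.3, 0.025, 0.6, 0.3, 1.0)


class TestFitIndividual:
    def test_fixed_point_at_truth(self, truth):
        series = _noiseless_series(truth, doses=[(10.0, 6.0)])
        res = fit_individual(series, [DoseEvent(10.0, 6.0)], truth, n_starts=1)
        assert res.converged
        assert res.objective < 1e-8
        for name in res.free:
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-3
            )

    def test_growth_rate_recovery_untreated(self, truth):
        """One free parameter on untreated noiseless growth: sub-0.1% recovery."""
        series = _noiseless_series(truth, horizon=20.0)
        init = truth.replace(growth_rate=0.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_individual(series, [], init, free=("growth_rate",))
        assert res.params.growth_rate == pytest.approx(truth.growth_rate, rel=1e-3)
        assert res.bse["growth_rate"] is not None

    def test_recovery_from_offset_init(self, truth):
        """Free (a, b, ED50) recovered within 1% from a biased start."""
        series = _noiseless_series(truth, doses=[(10.0, 6.0)], horizon=50.0)
        init = truth.replace(
            growth_rate=truth.growth_rate * 1.3,
            max_kill_rate=truth.max_kill_rate * 0.7,
            ed50=truth.ed50 * 2.0,
        )
        res = fit_individual(series, [DoseEvent(10.0, 6.0)], init, seed=0)
        for name in ("growth_rate", "max_kill_rate"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=0.01
            )

    def test_untreated_series_freezes_drug_parameters(self, truth):
        series = _noiseless_series(truth, horizon=20.0)
        with pytest.warns(UserWarning, match="not identifiable"):
            res = fit_individual(
                series, [], truth, free=("growth_rate", "max_kill_rate", "ed50")
            )
        assert res.params.max_kill_rate == truth.max_kill_rate
        assert res.bse["max_kill_rate"] is None
        assert any("not identifiable" in n for n in res.notes)

    def test_deterministic(self, truth):
        series = _noiseless_series(truth, doses=[(10.0, 6.0)])
        init = truth.replace(growth_rate=0.35)
        r1 = fit_individual(series, [DoseEvent(10.0, 6.0)], init, seed=3)
        r2 = fit_individual(series, [DoseEvent(10.0, 6.0)], init, seed=3)
        assert r1.params.to_dict() == r2.params.to_dict()
        assert r1.objective == r2.objective

    def test_objective_never_worse_than_init(self, truth):
        traj = simulate(
            truth, TumorState(30.0, 0.0, 0.0), [DoseEvent(10.0, 6.0)],
            horizon=40.0,
        )
        series = observe(traj, ObservationModel(cadence=2, noise_cv=0.1, seed=5))
        init = truth.replace(growth_rate=0.35, max_kill_rate=0.2)
        model = TumorGrowthModel(series, [DoseEvent(10.0, 6.0)])
        res = model.fit(init, n_starts=3, seed=0)
        # objective at the supplied initialization
        free = res.free
        import numpy as _np

        resid = model._residual_builder(init, free, None, 0.0)
        x0 = _np.log10([getattr(init, f) for f in free])
        obj_init = 0.5 * float(_np.sum(resid(x0) ** 2))
        assert res.objective <= obj_init + 1e-12

    def test_degenerate_series_rejected(self):
        from chemoplan.measurement import CaliperMeasurement, CaliperSeries

        ms = [CaliperMeasurement(d, 1.0, 0.5) for d in range(3)]
        with pytest.raises(ValueError, match="at least 4"):
            TumorGrowthModel(CaliperSeries("s", ms))

    def test_summary_renders(self, truth):
        series = _noiseless_series(truth, doses=[(10.0, 6.0)])
        res = fit_individual(series, [DoseEvent(10.0, 6.0)], truth, n_starts=1)
        text = res.summary()
        assert "growth_rate" in text and "estimate" in text


class TestFitPK:
    GRID = (0.0, 5.0, 30.0, 60.0, 1440.0, 7200.0)  # minutes

    def _samples(self, params, doses, grid=None):
        from chemoplan.cohort import sample_pk_sidecar

        return sample_pk_sidecar(params, doses, grid or self.GRID)

    def test_linear_decay_recovery(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = ModelParameters(0, 0, 0, 0, 1.0, 0.1, 0.0, 1.0)
        dense = tuple(float(t) for t in np.linspace(0, 7200, 25))
        samples = self._samples(p, (6.0,), dense)
        res = fit_pk(samples, init=(0.3, 0.05, 1.0),
                     bounds={"elimination_vmax": (1e-9, 1e-8)})
        assert res.clearance == pytest.approx(0.1, rel=0.01)

    def test_two_dose_sparse_design_recovery(self, truth):
        """The 0.6/6 mg/kg design on the minute grid identifies all of
        (c, k1, k2) within 10% without noise."""
        samples = self._samples(truth, (0.6, 6.0))
        res = fit_pk(samples, init=(0.3, 0.15, 0.5), seed=0)
        assert res.clearance == pytest.approx(truth.clearance, rel=0.10)
        assert res.elimination_vmax == pytest.approx(
            truth.elimination_vmax, rel=0.10
        )
        assert res.elimination_km == pytest.approx(truth.elimination_km, rel=0.10)

    def test_objective_near_zero_at_truth(self, truth):
        samples = self._samples(truth, (0.6, 6.0))
        res = fit_pk(
            samples,
            init=(truth.clearance, truth.elimination_vmax, truth.elimination_km),
            n_starts=1,
        )
        assert res.objective < 1e-6

    def test_single_time_design_rejected(self):
        samples = {6.0: [PlasmaSample(30.0, 3.0), PlasmaSample(30.0, 3.1)]}
        with pytest.raises(IdentifiabilityError):
            PKDecayModel(samples)

    def test_apply_to_transfers_estimates(self, truth):
        samples = self._samples(truth, (0.6, 6.0))
        res = fit_pk(samples, init=(0.3, 0.15, 0.5))
        merged = res.apply_to(truth.replace(clearance=0.01))
        assert merged.clearance == pytest.approx(res.clearance)


class TestFitPopulation:
    def test_homogeneous_cohort_zero_bsv(self, truth):
        cohort = []
        for i in range(3):
            series = _noiseless_series(truth, doses=[(10.0, 6.0)])
            cohort.append((series, [DoseEvent(10.0, 6.0)]))
        pop = fit_population(cohort, truth, shrinkage_weight=1.0, n_starts=1)
        for name in ("growth_rate", "max_kill_rate"):
            assert getattr(pop.population, name) == pytest.approx(
                getattr(truth, name), rel=0.02
            )
            assert pop.bsv_log_sd[name] == pytest.approx(0.0, abs=0.02)

    def test_heterogeneous_bsv_recovered(self, truth):
        rng = np.random.default_rng(0)
        cohort = []
        gen_sd = 0.2
        for i in range(12):
            p = truth.replace(
                growth_rate=truth.growth_rate * float(np.exp(rng.normal(0, gen_sd)))
            )
            series = _noiseless_series(p, doses=[(10.0, 6.0)])
            cohort.append((series, [DoseEvent(10.0, 6.0)]))
        pop = fit_population(
            cohort, truth, free=("growth_rate", "max_kill_rate"),
            shrinkage_weight=0.01, n_starts=1,
        )
        sample_sd = float(
            np.std(np.log([truth.growth_rate
                           * np.exp(rng2) for rng2 in []] or
                          [getattr(s.params, "growth_rate") for s in pop.subjects]),
                   ddof=1)
        )
        assert pop.bsv_log_sd["growth_rate"] == pytest.approx(gen_sd, rel=0.35)

    def test_requires_three_subjects(self, truth):
        series = _noiseless_series(truth, doses=[(10.0, 6.0)])
        with pytest.raises(ValueError, match=">= 3"):
            fit_population([(series, [DoseEvent(10.0, 6.0)])], truth)

    def test_shrinkage_limits(self, truth):
        """Infinite shrinkage pins subjects at population values; zero
        shrinkage reproduces the unpenalized individual fit."""
        p_subj = truth.replace(growth_rate=0.32)
        series = _noiseless_series(p_subj, doses=[(10.0, 6.0)])
        cohort = [(series, [DoseEvent(10.0, 6.0)])] * 3
        tight = fit_population(cohort, truth, shrinkage_weight=1e6, n_starts=1)
        loose = fit_population(cohort, truth, shrinkage_weight=0.0, n_starts=1)
        pop_a = tight.population.growth_rate
        for s in tight.subjects:
            assert s.params.growth_rate == pytest.approx(pop_a, rel=1e-3)
        free_fit = fit_individual(
            series, [DoseEvent(10.0, 6.0)], loose.population, n_starts=1
        )
        assert loose.subjects[0].params.growth_rate == pytest.approx(
            free_fit.params.growth_rate, rel=1e-3
        )


class TestOnlineUpdate:
    def test_no_new_observations_idempotent(self, truth):
        series = _noiseless_series(truth, doses=[(10.0, 6.0)])
        res = fit_individual(series, [DoseEvent(10.0, 6.0)], truth, n_starts=1)
        again = online_update(res, series, [DoseEvent(10.0, 6.0)])
        assert again is res

    def test_converges_with_accumulating_data(self, truth):
        init = truth.replace(growth_rate=0.35, max_kill_rate=0.24)
        doses = [DoseEvent(10.0, 6.0)]
        prev = fit_individual(
            _noiseless_series(truth, doses=[(10.0, 6.0)], horizon=20.0),
            doses, init, n_starts=1, seed=0,
        )
        for horizon in (30.0, 40.0, 50.0):
            series = _noiseless_series(truth, doses=[(10.0, 6.0)], horizon=horizon)
            prev = online_update(prev, series, doses)
        assert prev.params.growth_rate == pytest.approx(truth.growth_rate, rel=0.02)

    def test_step_bound_limits_movement(self, truth):
        """A single update moves each parameter at most the trust-region step."""
        init = truth.replace(growth_rate=truth.growth_rate * 3.0)
        doses = [DoseEvent(10.0, 6.0)]
        short = _noiseless_series(truth, doses=[(10.0, 6.0)], horizon=20.0)
        prev = fit_individual(short, doses, init, free=("growth_rate",),
                              bounds={"growth_rate": (init.growth_rate * 0.999,
                                                      init.growth_rate * 1.001)},
                              n_starts=1)
        longer = _noiseless_series(truth, doses=[(10.0, 6.0)], horizon=30.0)
        step = 0.15
        upd = online_update(prev, longer, doses, max_log_step=step)
        ratio = upd.params.growth_rate / prev.params.growth_rate
        assert 10 ** (-step) - 1e-9 <= ratio <= 10**step + 1e-9
        # truth is far below: the update should move down, onto the bound
        assert ratio == pytest.approx(10 ** (-step), rel=1e-3)
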
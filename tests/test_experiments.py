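import numpy as np
import pytest

import pgpdyn as pg
from pgpdyn.experiments import make_protocol_schedule, response_amplitude
from pgpdyn.grid import quadrature_weights


class TestMixtureScenario:
    def test_sensitive_only_masses(self, params):
        scen = pg.make_mixture_scenario((1, 0), n_init=2.0e4)
        state = scen.initial_state(params)
        n1, n2 = pg.total_cells(state)
        assert n2 == 0.0
        assert n1 == pytest.approx(2.0e4, rel=1e-9)

    def test_three_to_one_split(self, params):
        scen = pg.make_mixture_scenario("3:1", n_init=2.0e4)
        n1, n2 = pg.total_cells(scen.initial_state(params))
        assert n1 == pytest.approx(1.5e4, rel=1e-9)
        assert n2 == pytest.approx(5.0e3, rel=1e-9)

    def test_unknown_ratio_lists_allowed(self):
        with pytest.raises(ValueError, match="1:0.*0:1.*1:1.*3:1.*7:1"):
            pg.make_mixture_scenario((2, 1))

    def test_one_to_one_with_dox_design(self):
        scen = pg.make_mixture_scenario((1, 1), dose=50.0, n_init=2.0e4, horizon=96.0)
        assert scen.schedule.concentration(10.0) == 50.0
        assert scen.initial_masses() == (1.0e4, 1.0e4)

    def test_transient_reduction_then_regrowth_under_drug(self, params):
        # mixtures under 50 nM dip below the seeding count, then regrow
        for ratio in ((1, 1), (3, 1)):
            traj = pg.simulate(
                pg.make_mixture_scenario(ratio, dose=50.0, horizon=96.0), params
            )
            tot = traj.total()
            assert tot.min() < tot[0]
            assert tot[-1] > 2.0 * tot.min()


class TestMediumExchange:
    def test_fresh_medium_has_no_mvs(self, params):
        scen = pg.make_medium_exchange_scenario(dox=False, conditioned=False)
        assert scen.initial_state(params).M == 0.0
        assert scen.schedule.total_on_time() == 0.0

    def test_conditioned_medium_load_from_nested_simulation(self, params):
        scen = pg.make_medium_exchange_scenario(dox=False, conditioned=True)
        m0 = scen.initial_state(params).M
        assert m0 == pytest.approx(pg.conditioned_medium_mv_load(params), rel=1e-9)
        assert m0 > 0.0

    def test_four_conditions(self, params):
        names = set()
        for dox in (False, True):
            for cm in (False, True):
                scen = pg.make_medium_exchange_scenario(dox=dox, conditioned=cm)
                names.add(scen.name)
                assert scen.horizon == 48.0
                assert scen.init_ratio == (1, 0)
                assert scen.schedule.concentration(1.0) == (50.0 if dox else 0.0)
        assert len(names) == 4

    def test_dox_plus_cm_shifts_most(self, params):
        # final mean activity ordering matches the four-curve contrast:
        # fresh < CM < DOX < DOX+CM
        means = {}
        for dox in (False, True):
            for cm in (False, True):
                scen = pg.make_medium_exchange_scenario(dox=dox, conditioned=cm)
                state = pg.simulate(scen, params).states[-1]
                w = quadrature_weights(scen.grid)
                u = state.u1.values
                means[(dox, cm)] = float(w @ (scen.grid.centers * u) / (w @ u))
        assert means[(False, False)] < means[(False, True)]
        assert means[(False, True)] < means[(True, False)]
        assert means[(True, False)] < means[(True, True)]


class TestSortingScenario:
    def test_initial_profile_matches_resistant_basal(self, params):
        scen = pg.make_sorting_scenario()
        state = scen.initial_state(params)
        grid = scen.grid
        w = quadrature_weights(grid)
        mean = float(w @ (grid.centers * state.u1.values) / (w @ state.u1.values))
        assert abs(mean - params.b2) <= grid.dx
        assert pg.total_cells(state)[0] == pytest.approx(scen.n_init, rel=1e-9)
        assert pg.total_cells(state)[1] == 0.0
        assert scen.schedule.total_on_time() == 0.0

    def test_mean_shifted_but_incomplete_at_60h(self, params):
        scen = pg.make_sorting_scenario(horizon=60.0)
        traj = pg.simulate(scen, params)
        grid = scen.grid
        u = traj.states[-1].u1.values
        mean = float((grid.centers * u).sum() / u.sum())
        assert params.b1 + grid.dx < mean < params.b2 - grid.dx


class TestProtocols:
    @pytest.mark.parametrize(
        "proto,expected",
        [
            (1, ((0.0, 120.0),)),
            (2, ((0.0, 60.0), (180.0, 240.0))),
            (3, ((0.0, 24.0), (48.0, 72.0), (96.0, 120.0), (144.0, 168.0), (192.0, 216.0))),
        ],
    )
    def test_exact_intervals_and_on_time(self, proto, expected):
        sched = make_protocol_schedule(proto, dose=100.0)
        assert tuple((a, b) for a, b, _ in sched.intervals) == expected
        assert sched.horizon == 240.0
        assert sched.total_on_time() == 120.0

    def test_unknown_protocol(self):
        with pytest.raises(ValueError, match="protocol"):
            make_protocol_schedule(4, dose=100.0)


class TestGrowthDelay:
    def _logistic_traj(self, times, shift=0.0):
        n = 2e4 * np.exp(0.03 * np.maximum(times - shift, 0.0))
        totals = np.vstack([n, np.zeros_like(n)])
        return pg.Trajectory(times=times, states=[], totals=totals, M_series=np.zeros_like(times))

    def test_identical_curves_have_zero_delay(self):
        t = np.arange(0.0, 241.0)
        d = pg.growth_delay(self._logistic_traj(t), self._logistic_traj(t))
        assert d.delay_h == 0.0 and not d.flagged

    def test_recovers_synthetic_shift(self):
        t = np.arange(0.0, 241.0)
        d = pg.growth_delay(self._logistic_traj(t, shift=48.0), self._logistic_traj(t))
        assert d.delay_h == pytest.approx(48.0, abs=1.0)

    def test_no_regrowth_is_flagged(self):
        t = np.arange(0.0, 101.0)
        dying = self._logistic_traj(t)
        dying.totals[0] = 2e4 * np.exp(-0.02 * t)
        d = pg.growth_delay(dying, self._logistic_traj(t))
        assert d.flagged and d.delay_h == t[-1]

    def test_threshold_method_matches_shift_for_pure_lag(self):
        t = np.arange(0.0, 241.0)
        d = pg.growth_delay(
            self._logistic_traj(t, shift=48.0), self._logistic_traj(t), method="threshold"
        )
        assert d.delay_h == pytest.approx(48.0, abs=1.0)

    def test_mismatched_times_rejected(self):
        a = self._logistic_traj(np.arange(0.0, 100.0))
        b = self._logistic_traj(np.arange(0.0, 50.0))
        with pytest.raises(ValueError):
            pg.growth_delay(a, b)


class TestResponseAmplitude:
    def test_monotone_curve_has_zero_amplitude(self):
        t = np.arange(0.0, 50.0)
        n = np.exp(0.05 * t)
        traj = pg.Trajectory(times=t, states=[], totals=np.vstack([n, 0 * n]), M_series=0 * t)
        assert response_amplitude(traj) == 0.0

    def test_single_drawdown(self):
        t = np.arange(0.0, 5.0)
        n = np.array([10.0, 30.0, 12.0, 20.0, 25.0])
        traj = pg.Trajectory(times=t, states=[], totals=np.vstack([n, 0 * n]), M_series=0 * t)
        assert response_amplitude(traj) == pytest.approx(18.0)
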
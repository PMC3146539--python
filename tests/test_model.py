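"""Kinetics of the 28-state ITAM-pair model: the phosphatase-inhibition
function, conservation, steady states, the 49-state symmetry oracle and the
qualitative response features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_rate_dict
from oracle_49 import (
    observables_49,
    ordered_from_reduced,
    reduced_from_ordered,
    simulate_49,
)
from ipfcm.model import (
    _COUNT_BOUND,
    _COUNT_PY319,
    _COUNT_PY493,
    RateParameters,
    StimulationSchedule,
    build_rate_matrices,
    compute_observables,
    derivative_field,
    phosphatase_activity,
    resting_steady_state,
    simulate_timecourse,
)
from ipfcm.states import N_PAIR, PAIR_INDEX, PAIR_STATES, ItamState


NO_DOSE = StimulationSchedule(dose_times=(), horizon=60.0)


class TestPhosphataseActivity:
    def test_unity_before_first_dose(self):
        sched = StimulationSchedule(dose_times=(5.0,), horizon=60.0)
        assert phosphatase_activity(0.0, sched, 0.05, 20.0) == 1.0
        assert phosphatase_activity(4.99, sched, 0.05, 20.0) == 1.0

    def test_reset_to_f_min_at_dose(self):
        sched = StimulationSchedule(dose_times=(0.0, 20.0), horizon=60.0)
        assert phosphatase_activity(0.0, sched, 0.05, 20.0) == pytest.approx(0.05)
        assert phosphatase_activity(20.0, sched, 0.05, 20.0) == pytest.approx(0.05)

    def test_closed_form_recovery_at_tau(self):
        sched = StimulationSchedule(dose_times=(0.0,), horizon=60.0)
        f_min, tau = 0.1, 15.0
        expected = f_min + (1 - f_min) * (1 - math.exp(-1.0))
        assert phosphatase_activity(tau, sched, f_min, tau) == pytest.approx(expected, rel=1e-12)

    def test_vectorized_matches_scalar(self):
        sched = StimulationSchedule(dose_times=(0.0, 10.0), horizon=60.0)
        ts = np.linspace(0, 30, 13)
        vec = phosphatase_activity(ts, sched, 0.02, 25.0)
        scal = [phosphatase_activity(float(t), sched, 0.02, 25.0) for t in ts]
        np.testing.assert_allclose(vec, scal, rtol=1e-12)


class TestDerivativeField:
    def test_zero_rates_zero_field(self):
        p = RateParameters(
            k_itam_p=0, k_itam_dp=0, k_on=0, k_off=0,
            k_y319=0, k_y319_dp=0, k_y493=0, k_y493_dp=0,
        )
        x = np.full(N_PAIR, 1.0 / N_PAIR)
        np.testing.assert_array_equal(derivative_field(1.0, x, p, NO_DOSE), 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_probability_conservation(self, seed):
        """The generator conserves total occupancy for arbitrary states and
        random rate sets."""
        rng = np.random.default_rng(seed)
        p = RateParameters(**random_rate_dict(rng))
        x = rng.dirichlet(np.ones(N_PAIR))
        dx = derivative_field(3.0, x, p, StimulationSchedule())
        assert abs(dx.sum()) < 1e-12

    def test_invalid_state_rejected(self):
        p = RateParameters()
        bad = np.full(N_PAIR, 1.0 / N_PAIR)
        bad[0] -= 0.5
        bad[1] += 0.3  # sums to 0.8
        with pytest.raises(ValueError):
            derivative_field(0.0, bad, p, NO_DOSE)
        neg = np.full(N_PAIR, 1.0 / N_PAIR)
        neg[0], neg[1] = -0.1, neg[1] + 0.1 + neg[0]
        with pytest.raises(ValueError):
            derivative_field(0.0, neg, p, NO_DOSE)


class TestSymmetryOracle:
    @pytest.mark.parametrize("trial", range(5))
    def test_reduced_dynamics_match_ordered_bruteforce(self, trial):
        """28-state trajectories agree with an independently assembled
        49-ordered-state model on all marginals and observables."""
        rng = np.random.default_rng(1000 + trial)
        pd = random_rate_dict(rng)
        params = RateParameters(**pd)
        sched = StimulationSchedule(dose_times=(0.0, 20.0), horizon=45.0)
        times = [0.0, 1.0, 3.0, 7.0, 20.0, 30.0, 45.0]
        traj = simulate_timecourse(params, sched, times)
        x0 = ordered_from_reduced(PAIR_STATES, resting_steady_state(params))
        _, s49 = simulate_49(pd, (0.0, 20.0), times, x0)
        z49, p319, p493 = observables_49(s49)
        np.testing.assert_allclose(traj.states @ _COUNT_BOUND, z49, atol=1e-8)
        np.testing.assert_allclose(traj.states @ _COUNT_PY319, p319, atol=1e-8)
        np.testing.assert_allclose(traj.states @ _COUNT_PY493, p493, atol=1e-8)
        red = np.array([reduced_from_ordered(PAIR_STATES, row) for row in s49])
        np.testing.assert_allclose(traj.states, red, atol=1e-8)


class TestRestingSteadyState:
    def test_residual_below_tolerance(self, default_params):
        x = resting_steady_state(default_params)
        dx = derivative_field(0.0, x, default_params, NO_DOSE)
        assert np.max(np.abs(dx)) < 1e-10
        assert x.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(x >= 0)

    def test_binomial_product_law_without_zap_binding(self):
        """With k_on = 0 the two ITAMs are independent two-site units: each
        site is phosphorylated with probability a/(a+b), giving binomial
        single-ITAM occupancies and a product law over the pair."""
        a, b = 0.3, 0.7
        p = RateParameters(k_itam_p=a, k_itam_dp=b, k_on=0.0)
        x = resting_steady_state(p)
        q = a / (a + b)
        single = {
            ItamState.U: (1 - q) ** 2,
            ItamState.P1: 2 * q * (1 - q),
            ItamState.P2: q ** 2,
        }
        expected = np.zeros(N_PAIR)
        for (s, t), i in PAIR_INDEX.items():
            if s in single and t in single:
                expected[i] = single[s] * single[t] * (1 if s == t else 2)
        np.testing.assert_allclose(x, expected, atol=1e-10)

    def test_absorbing_state_with_irreversible_forward_rates(self):
        """All dephosphorylation and unbinding off: the chain absorbs into
        the fully phosphorylated double-ZAP70 state."""
        p = RateParameters(
            k_itam_p=1.0, k_itam_dp=0.0, k_on=1.0, k_off=0.0,
            k_y319=1.0, k_y319_dp=0.0, k_y493=1.0, k_y493_dp=0.0,
        )
        x = resting_steady_state(p)
        i = PAIR_INDEX[(ItamState.Z319_493, ItamState.Z319_493)]
        assert x[i] == pytest.approx(1.0, abs=1e-9)


class TestSimulateTimecourse:
    def test_no_dose_trajectory_is_constant(self, default_params):
        traj = simulate_timecourse(default_params, NO_DOSE, [0, 10, 30, 60])
        x0 = resting_steady_state(default_params)
        np.testing.assert_allclose(traj.states, np.tile(x0, (4, 1)), atol=1e-9)

    def test_conservation_along_trajectory(self, default_params, single_dose):
        traj = simulate_timecourse(default_params, single_dose, np.linspace(0, 60, 31))
        assert traj.max_drift < 1e-8

    def test_tolerance_convergence(self, default_params, single_dose):
        times = [0, 2, 5, 10, 20, 60]
        coarse = simulate_timecourse(default_params, single_dose, times)
        fine = simulate_timecourse(
            default_params, single_dose, times, rtol=0.5e-9, atol=0.5e-11
        )
        o1 = compute_observables(coarse)
        o2 = compute_observables(fine)
        for col in ("bound_Z", "bound_pY319", "bound_pY493"):
            np.testing.assert_allclose(o1[col], o2[col], rtol=1e-6, atol=1e-12)

    def test_double_dose_raises_late_py319(self, default_params):
        single = StimulationSchedule(dose_times=(0.0,), horizon=60.0)
        double = StimulationSchedule(dose_times=(0.0, 20.0), horizon=60.0)
        v1 = compute_observables(
            simulate_timecourse(default_params, single, [60.0])
        )["bound_pY319"].iloc[0]
        v2 = compute_observables(
            simulate_timecourse(default_params, double, [60.0])
        )["bound_pY319"].iloc[0]
        assert v2 > v1

    def test_negative_times_rejected(self, default_params, single_dose):
        with pytest.raises(ValueError):
            simulate_timecourse(default_params, single_dose, [-1.0, 5.0])


class TestObservables:
    def _delta_trajectory(self, pair, params):
        x = np.zeros(N_PAIR)
        x[PAIR_INDEX[pair]] = 1.0
        from ipfcm.model import Trajectory

        return Trajectory(
            times=np.array([0.0]), states=x[None, :], params=params,
            schedule=NO_DOSE,
        )

    def test_fully_phosphorylated_pair(self, default_params):
        traj = self._delta_trajectory(
            (ItamState.Z319_493, ItamState.Z319_493), default_params
        )
        obs = compute_observables(traj)
        assert obs["bound_Z"].iloc[0] == pytest.approx(2 * default_params.s_Z)
        assert obs["bound_pY319"].iloc[0] == pytest.approx(2 * default_params.s_pY)
        assert obs["bound_pY493"].iloc[0] == pytest.approx(2.0)
        assert obs["ratio"].iloc[0] == pytest.approx(
            default_params.s_pY / default_params.s_Z
        )

    def test_empty_pair_gives_missing_ratio(self, default_params):
        traj = self._delta_trajectory((ItamState.U, ItamState.U), default_params)
        obs = compute_observables(traj)
        assert obs["bound_Z"].iloc[0] == 0.0
        assert obs["bound_pY319"].iloc[0] == 0.0
        assert np.isnan(obs["ratio"].iloc[0])

    def test_scales_applied(self):
        p = RateParameters(s_Z=3.0, s_pY=0.5)
        traj = self._delta_trajectory((ItamState.Z, ItamState.Z319), p)
        obs = compute_observables(traj)
        assert obs["bound_Z"].iloc[0] == pytest.approx(6.0)
        assert obs["bound_pY319"].iloc[0] == pytest.approx(0.5)


class TestQualitativeDynamics:
    GRID = np.arange(0.0, 60.01, 0.25)

    def test_ratio_dip_and_recovery(self, default_params, single_dose):
        """The bound pY319/ZAP70 ratio drops below its resting value right
        after the dose (influx of unphosphorylated ZAP70) and ends above it."""
        obs = compute_observables(
            simulate_timecourse(default_params, single_dose, self.GRID)
        )
        r = obs["ratio"].to_numpy()
        r0 = r[0]
        r2 = r[np.searchsorted(self.GRID, 2.0)]
        assert r2 < r0
        assert r[-1] > r0
        assert np.nanmin(r) < r0

    def test_recruitment_peaks_before_phosphorylation(self, default_params, single_dose):
        obs = compute_observables(
            simulate_timecourse(default_params, single_dose, self.GRID)
        )
        t_z = self.GRID[obs["bound_Z"].to_numpy().argmax()]
        t_py = self.GRID[obs["bound_pY319"].to_numpy().argmax()]
        assert 0 < t_z < t_py
        assert 5.0 <= t_z <= 15.0
        assert 12.0 <= t_py <= 30.0

    @pytest.mark.parametrize("trial", range(4))
    def test_y493_peaks_no_earlier_than_y319(self, trial, single_dose):
        """Y493 phosphorylation requires an opened (pY319) partner, so its
        time course must lag Y319's for any parameters with k_y493 > 0."""
        rng = np.random.default_rng(40 + trial)
        pd = random_rate_dict(rng)
        params = RateParameters(**pd)
        obs = compute_observables(simulate_timecourse(params, single_dose, self.GRID))
        t319 = self.GRID[obs["bound_pY319"].to_numpy().argmax()]
        t493 = self.GRID[obs["bound_pY493"].to_numpy().argmax()]
        assert t493 >= t319

    def test_stronger_inhibition_increases_response(self, default_params, single_dose):
        """Lower residual phosphatase activity weakly increases bound ZAP70
        and bound pY319 at every time after the dose."""
        times = np.linspace(0.5, 60, 24)
        prev_z = prev_py = None
        for f_min in (0.2, 0.05, 0.01):
            obs = compute_observables(
                simulate_timecourse(default_params.replace(f_min=f_min), single_dose, times)
            )
            z, py = obs["bound_Z"].to_numpy(), obs["bound_pY319"].to_numpy()
            if prev_z is not None:
                assert np.all(z >= prev_z - 1e-9)
                assert np.all(py >= prev_py - 1e-9)
            prev_z, prev_py = z, py


def test_symmetric_state_combinatorial_factor():
    """A symmetric pair state feeds each asymmetric product at twice the
    single-site rate (either ITAM can react)."""
    p = RateParameters(
        k_itam_p=0.5, k_itam_dp=0, k_on=0, k_off=0,
        k_y319=0, k_y319_dp=0, k_y493=0, k_y493_dp=0,
    )
    a_const, a_deph = build_rate_matrices(p)
    i_uu = PAIR_INDEX[(ItamState.U, ItamState.U)]
    i_up1 = PAIR_INDEX[(ItamState.U, ItamState.P1)]
    # U->P1 is itself a two-site random phosphorylation: per-ITAM rate 2*0.5
    assert a_const[i_up1, i_uu] == pytest.approx(2 * (2 * 0.5))
    assert a_deph[i_up1, i_uu] == 0.0
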
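"""Wilson-Cowan integrator, activity classification and coupling tuning."""

import numpy as np
import pytest

from chimerabrain.dynamics import (
    SimConfig,
    StateTrajectory,
    StimulusSpec,
    WCParams,
    build_delay_matrix,
    classify_activity,
    sigmoid,
    sigmoid_max,
    simulate,
    stimulate_each_region,
    tune_global_coupling,
)

from conftest import make_connectome


def single_region_connectome():
    return make_connectome(np.zeros((1, 1)), coords=np.zeros((1, 3)))


def estimate_period(E: np.ndarray, times: np.ndarray) -> float:
    """Mean interval between upward midline crossings."""
    x = E - E.mean()
    up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    assert len(up) >= 3, "need several oscillations to estimate a period"
    return float(np.diff(times[up]).mean())


class TestSigmoid:
    @pytest.mark.parametrize("a,theta", [(1.3, 4.0), (2.0, 3.7), (0.5, 1.0)])
    def test_zero_at_origin_and_bounds(self, a, theta):
        assert sigmoid(0.0, a, theta) == pytest.approx(0.0, abs=1e-15)
        smax = sigmoid_max(a, theta)
        assert 0 < smax < 1
        assert sigmoid(1e3, a, theta) == pytest.approx(smax, abs=1e-12)
        assert sigmoid(10.0, a, theta) < smax  # strict for finite x

    def test_midpoint_value(self):
        a, theta = 1.3, 4.0
        assert sigmoid(theta, a, theta) == pytest.approx(
            0.5 - 1 / (1 + np.exp(a * theta))
        )

    def test_monotone(self):
        x = np.linspace(-10, 10, 201)
        y = sigmoid(x, 1.3, 4.0)
        assert (np.diff(y) > 0).all()

    def test_theta_zero_max(self):
        assert sigmoid_max(2.0, 0.0) == pytest.approx(0.5)

    def test_invalid_growth_rate(self):
        with pytest.raises(ValueError):
            sigmoid(0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            sigmoid_max(0.0, 1.0)


class TestDelayMatrix:
    def test_unit_arithmetic(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        dm = build_delay_matrix(coords, v_d=10.0)
        assert dm.delays[0, 1] == pytest.approx(10.0)  # 100 mm at 10 m/s -> 10 ms

    def test_coincident_and_symmetric(self, rng):
        coords = rng.uniform(-50, 50, (5, 3))
        coords[1] = coords[0]
        dm = build_delay_matrix(coords)
        assert dm.delays[0, 1] == 0.0
        assert np.array_equal(dm.delays, dm.delays.T)


class TestWCParams:
    def test_inhibitory_coupling_locked_to_excitatory(self):
        p = WCParams(C_E=2.0)
        assert p.C_I == 0.5
        assert p.with_coupling(8.0).C_I == 2.0

    def test_validation(self):
        with pytest.raises(ValueError):
            WCParams(tau=0.0)
        with pytest.raises(ValueError):
            WCParams(sigma=-1.0)


class TestSimulate:
    def test_origin_is_exact_fixed_point(self):
        """P=0, sigma=0, E(0)=I(0)=0: the state stays exactly 0 for
        over 1e5 steps."""
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        c = make_connectome(W)
        cfg = SimConfig(dt=1e-3, transient=0.0, record_window=110.0,
                        initial_value=0.0, record_stride=100)
        params = WCParams(C_E=2.0, sigma=0.0)
        traj = simulate(c, params, None, cfg)
        assert np.all(traj.E == 0.0)
        assert np.all(traj.I == 0.0)

    def test_noise_free_determinism(self, toy_connectome):
        cfg = SimConfig(transient=20.0, record_window=50.0)
        params = WCParams(C_E=1.5, sigma=0.0)
        t1 = simulate(toy_connectome, params, StimulusSpec(0), cfg)
        t2 = simulate(toy_connectome, params, StimulusSpec(0), cfg)
        assert np.array_equal(t1.E, t2.E)
        assert np.array_equal(t1.I, t2.I)

    def test_seeded_noise_determinism(self, toy_connectome):
        cfg = SimConfig(transient=20.0, record_window=50.0, seed=7)
        params = WCParams(C_E=1.5)
        t1 = simulate(toy_connectome, params, StimulusSpec(0), cfg)
        t2 = simulate(toy_connectome, params, StimulusSpec(0), cfg)
        assert np.array_equal(t1.E, t2.E)

    def test_single_region_oscillates_with_period_convergence(self):
        """A stimulated region at P=1.15 sustains a limit cycle; halving
        dt changes the period by under 2%."""
        c = single_region_connectome()
        params = WCParams(C_E=1.0, sigma=0.0)
        periods = {}
        for dt in (1e-3, 5e-4):
            cfg = SimConfig(dt=dt, transient=300.0, record_window=500.0,
                            record_stride=int(round(1e-2 / dt)))
            traj = simulate(c, params, StimulusSpec(0, 1.15), cfg)
            E = traj.E_steady[:, 0]
            assert E.max() - E.min() > 0.05  # far above quiescent baseline
            up = np.flatnonzero((E[:-1] < E.mean()) & (E[1:] >= E.mean()))
            assert len(up) >= 5
            periods[dt] = estimate_period(E, traj.times)
        assert abs(periods[1e-3] - periods[5e-4]) / periods[5e-4] < 0.02

    @pytest.mark.parametrize("dist_mm", [20.0, 50.0, 117.0])
    def test_delay_correctness_by_signal_front(self, dist_mm):
        """Starting from the exact zero fixed point, a stimulated
        region's influence reaches its neighbour after precisely the
        conduction delay: the neighbour departs from 0 at tau_d, give
        or take one integration step."""
        dt = 1e-3
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        coords = np.array([[0.0, 0, 0], [dist_mm, 0, 0]])
        c = make_connectome(W, coords=coords)
        cfg = SimConfig(dt=dt, transient=0.0, record_window=20.0,
                        initial_value=0.0, record_stride=1, delay_quantum=1)
        traj = simulate(c, WCParams(C_E=2.0, sigma=0.0),
                        StimulusSpec(0, 1.15), cfg)
        assert traj.E[1, 0] != 0.0  # stimulus acts immediately
        first = int(np.flatnonzero(traj.E[:, 1] != 0.0)[0])
        tau_d = dist_mm / 10.0  # ms
        assert abs(first * dt - tau_d) <= 2 * dt

    def test_max_delay_must_fit(self):
        coords = np.array([[0.0, 0, 0], [5000.0, 0, 0]])  # 500 ms delay
        c = make_connectome(np.array([[0.0, 1.0], [1.0, 0.0]]), coords=coords)
        cfg = SimConfig(transient=10.0, record_window=10.0)
        with pytest.raises(ValueError, match="delay"):
            simulate(c, WCParams(sigma=0.0), None, cfg)


class TestClassifyActivity:
    @staticmethod
    def traj_from_signal(x):
        x = np.asarray(x, dtype=float)[:, None]
        return StateTrajectory(E=x, I=np.zeros_like(x),
                               times=np.arange(len(x), dtype=float),
                               steady_slice=slice(0, len(x)))

    def test_zero_is_quiescent(self):
        assert classify_activity(self.traj_from_signal(np.zeros(500))) == "quiescent"

    def test_sinusoid_is_active(self):
        t = np.linspace(0, 10, 500)
        assert classify_activity(self.traj_from_signal(0.1 * np.sin(t))) == "active"

    def test_damped_oscillation_goes_quiescent(self):
        t = np.linspace(0, 200, 2000)
        sig = 0.1 * np.exp(-t / 5.0) * np.sin(2 * np.pi * t / 3.0)
        sig[t < 150] = 0.0  # only the decayed tail is 'steady state'
        assert classify_activity(self.traj_from_signal(sig)) == "quiescent"

    def test_empty_window_rejected(self):
        traj = StateTrajectory(E=np.zeros((0, 1)), I=np.zeros((0, 1)),
                               times=np.zeros(0), steady_slice=slice(0, 0))
        with pytest.raises(ValueError):
            classify_activity(traj)


def two_region_ring(dist=30.0, w=0.6):
    W = np.array([[0.0, w], [w, 0.0]])
    coords = np.array([[0.0, 0, 0], [dist, 0, 0]])
    return make_connectome(W, coords=coords)


TUNE_CFG = SimConfig(transient=100.0, record_window=100.0, record_stride=10,
                     delay_quantum=4)


class TestTuneGlobalCoupling:
    def test_bracket_width_and_endpoint_classes(self):
        c = two_region_ring()
        res = tune_global_coupling(c, WCParams(), TUNE_CFG, tolerance=1e-6)
        lo, hi = res.bracket
        assert hi - lo <= 1e-6
        quiet = WCParams(C_E=res.C_E, sigma=0.0)
        traj = simulate(c, quiet, None, TUNE_CFG)
        assert classify_activity(traj) == "quiescent"
        active = simulate(c, WCParams(C_E=hi, sigma=0.0), None, TUNE_CFG)
        assert classify_activity(active) == "active"

    def test_idempotent_from_returned_bracket(self):
        c = two_region_ring()
        res = tune_global_coupling(c, WCParams(), TUNE_CFG, tolerance=1e-4)
        res2 = tune_global_coupling(
            c, WCParams(), TUNE_CFG, tolerance=1e-4, initial_bracket=res.bracket
        )
        assert res2.C_E == res.C_E

    def test_grid_scan_oracle(self):
        """On a 2-region toy the bisection result matches the activity
        onset located by a 100-point grid scan."""
        c = two_region_ring()
        res = tune_global_coupling(c, WCParams(), TUNE_CFG, tolerance=1e-3)
        grid = np.linspace(max(res.C_E - 0.5, 0.01), res.C_E + 0.5, 100)
        states = []
        for ce in grid:
            traj = simulate(c, WCParams(C_E=ce, sigma=0.0), None, TUNE_CFG)
            states.append(classify_activity(traj) == "active")
        states = np.array(states)
        crossings = np.flatnonzero(~states[:-1] & states[1:])
        assert len(crossings) >= 1
        onset = grid[crossings[0] + 1]
        step = grid[1] - grid[0]
        assert abs(res.C_E - onset) <= step + 1e-3

    def test_no_bifurcation_raises(self):
        # an isolated region never activates from coupling alone
        c = single_region_connectome()
        with pytest.raises(RuntimeError, match="no bifurcation"):
            tune_global_coupling(c, WCParams(), TUNE_CFG, coupling_cap=100.0)


class TestStimulateEachRegion:
    def test_subset_and_determinism(self, toy_connectome):
        cfg = SimConfig(transient=20.0, record_window=40.0, seed=3)
        params = WCParams(C_E=1.0)
        out = stimulate_each_region(toy_connectome, params, cfg, regions=[2])
        assert set(out) == {2}
        again = stimulate_each_region(toy_connectome, params, cfg, regions=[2, 0])
        assert np.array_equal(out[2].E, again[2].E)  # seed depends on region only

    def test_weakly_coupled_block_stays_quiescent(self):
        """Stimulating one block of a near-block-diagonal connectome
        leaves the opposite block at the fixed point."""
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        W[1, 2] = W[2, 1] = 1e-4  # epsilon bridge
        coords = np.array([[0, 0, 0], [20, 0, 0], [120, 0, 0], [140, 0, 0]],
                          dtype=float)
        c = make_connectome(W, coords=coords)
        cfg = SimConfig(transient=150.0, record_window=150.0)
        params = WCParams(C_E=1.0, sigma=0.0)
        out = stimulate_each_region(c, params, cfg, regions=[0])
        traj = out[0]
        assert traj.E_steady[:, 0].max() > 0.05  # stimulated block active
        assert np.abs(traj.E_steady[:, 2:]).mean() < 1e-3
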
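"""Coupling, RK4 integration, network runs, and the clamped-partner protocol."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pitnet as pn
from pitnet._kernels import HAVE_NUMBA
from pitnet.model_core import CellState, cell_rhs
from pitnet.netgen import CellNetwork
from pitnet.netsim import ClampProtocol, SimConfig, coupling_current, integrate
from pitnet import events as ev


class TestCouplingCurrent:
    def test_equal_voltages_no_current(self):
        assert coupling_current(-40.0, [-40.0, -40.0], 0.05) == 0.0

    @given(st.floats(-80, 20), st.floats(-80, 20))
    def test_pairwise_antisymmetry(self, vi, vj):
        g = 0.05
        assert coupling_current(vi, [vj], g) == -coupling_current(vj, [vi], g)

    def test_hand_value(self):
        # g_c (V_i - V_j) = 0.05 * 40
        assert coupling_current(-20.0, [-60.0], 0.05) == pytest.approx(2.0)

    def test_network_currents_conserve_charge(self, net20):
        rng = np.random.default_rng(0)
        v = rng.uniform(-70, 0, size=20)
        total = sum(
            coupling_current(v[i], [v[j] for j in net20.neighbors(i)], 0.05)
            for i in range(20)
        )
        assert abs(total) < 1e-10


class TestGenericRK4:
    def test_zero_rhs_constant(self):
        _, y = integrate(lambda t, y: 0 * y, [2.0], dt=0.1, t_end=5.0)
        assert np.all(y == 2.0)

    def test_exponential_decay_fourth_order(self):
        """Halving dt shrinks the max error by ~2^4 on dy/dt = -y."""
        errs = {}
        for dt in (0.1, 0.05):
            t, y = integrate(lambda t, y: -y, [1.0], dt=dt, t_end=5.0)
            errs[dt] = np.max(np.abs(y[:, 0] - np.exp(-t)))
        ratio = errs[0.1] / errs[0.05]
        assert 12.0 < ratio < 20.0

    def test_blowup_names_the_step(self):
        with pytest.raises(FloatingPointError, match=r"step \d+"):
            integrate(lambda t, y: y * y, [1.0], dt=0.5, t_end=60.0)


class TestRunNetwork:
    def test_decoupled_network_equals_single_cell_runs(self, two_cell_net):
        init = [CellState(-58.0, 0.1, 0.11, 0.1), CellState(-61.0, 0.1, 0.09, 0.1)]
        cfg = SimConfig(dt=0.5, t_end=3000, t_transient=0, g_c=0.0, init=init)
        traj = pn.run_network(two_cell_net, None, cfg)
        for i, p in enumerate(pn.params_for(two_cell_net)):
            solo = pn.run_single_cell(p, cfg, init=init[i])
            assert np.allclose(traj.v[i], solo.v[0], atol=1e-9)
            assert np.allclose(traj.c[i], solo.c[0], atol=1e-12)

    def test_matches_independent_rhs_composition_oracle(self):
        """Kernel output reproduces a generic RK4 over the hand-assembled
        coupled right-hand side (cell_rhs + pairwise gap-junction sums)."""
        net = CellNetwork(
            3, frozenset({(0, 1), (1, 2)}), types=("burster", "spiker", "spiker")
        )
        params = pn.params_for(net)
        cfg = SimConfig(dt=0.5, t_end=1500, t_transient=0, g_c=0.05, seed=7)
        y0 = cfg.initial_states(3)

        def rhs(t, y):
            y = y.reshape(3, 4)
            out = np.empty_like(y)
            for i in range(3):
                ic = coupling_current(
                    y[i, 0], [y[j, 0] for j in net.neighbors(i)], cfg.g_c
                )
                out[i] = cell_rhs(CellState(*y[i]), params[i], ic)
            return out.reshape(-1)

        _, y = integrate(rhs, y0.reshape(-1), dt=cfg.dt, t_end=cfg.t_end)
        traj = pn.run_network(net, params, cfg)
        oracle_v = y.reshape(-1, 3, 4)[:, :, 0].T
        assert np.abs(traj.v - oracle_v).max() < 1e-6

    def test_identical_config_bit_identical_trajectories(self, two_cell_net):
        cfg = SimConfig(dt=0.5, t_end=2000, t_transient=0, g_c=0.05, seed=5)
        a = pn.run_network(two_cell_net, None, cfg)
        b = pn.run_network(two_cell_net, None, cfg)
        assert np.array_equal(a.v, b.v) and np.array_equal(a.c, b.c)

    def test_identical_coupled_bursters_stay_exactly_synchronous(self):
        net = CellNetwork(2, frozenset({(0, 1)}), types=("burster", "burster"))
        init = [CellState(-60.0, 0.1, 0.1, 0.1)] * 2
        cfg = SimConfig(dt=0.5, t_end=5000, t_transient=0, g_c=0.05, init=init)
        traj = pn.run_network(net, None, cfg)
        assert np.array_equal(traj.v[0], traj.v[1])

    @pytest.mark.skipif(not HAVE_NUMBA, reason="numba backend unavailable")
    def test_numba_and_numpy_backends_agree(self, two_cell_net):
        cfg = SimConfig(dt=0.5, t_end=500, t_transient=0, g_c=0.05, seed=3)
        a = pn.run_network(two_cell_net, None, cfg, backend="numba")
        b = pn.run_network(two_cell_net, None, cfg, backend="numpy")
        assert np.allclose(a.v, b.v, atol=1e-9)

    def test_event_classification_converges_in_dt(self, two_cell_net, strong_pair):
        """Halving the step leaves the classified event sequences unchanged."""
        cfg = SimConfig(dt=0.25, t_end=60_000, t_transient=20_000, g_c=0.05, seed=1)
        finer = pn.run_network(two_cell_net, None, cfg)
        for cell in range(2):
            coarse = ev.event_train(strong_pair, cell).labels
            fine = ev.event_train(finer, cell).labels
            assert coarse == fine

    def test_mismatched_params_rejected(self, two_cell_net):
        with pytest.raises(ValueError):
            pn.run_network(
                two_cell_net, [pn.burster_params()], SimConfig(t_end=10, t_transient=0)
            )


class TestClampedPartner:
    def test_no_coupling_identical_to_uncoupled(self):
        cfg = SimConfig(dt=0.5, t_end=3000, t_transient=0, g_c=0.0, seed=2)
        plain = pn.run_single_cell(pn.spiker_params(), cfg)
        proto = ClampProtocol(v_fix=-20.0, windows=((500.0, 800.0),), g_c=0.0)
        clamped = pn.run_with_clamped_partner(pn.spiker_params(), proto, cfg)
        assert np.array_equal(plain.v, clamped.v)

    def test_plateau_level_pulses_convert_spiker(
        self, uncoupled_burster, uncoupled_spiker
    ):
        """Square voltage pulses at the burster's plateau level, delivered
        during its active phases, elicit multi-spike bursts from the spiker
        in a majority of the pulse windows."""
        proto = ev.clamp_protocol_from_trace(uncoupled_burster, g_c=0.05)
        cfg = SimConfig(dt=0.5, t_end=60_000, t_transient=20_000, g_c=0.0, seed=1)
        traj = pn.run_with_clamped_partner(pn.spiker_params(), proto, cfg)
        train = ev.event_train(traj, 0)
        windows = [w for w in proto.windows if w[0] >= cfg.t_transient]
        hit = sum(
            any(
                e.n_peaks >= 2 and e.t_start < w1 + 20 and e.t_end > w0 - 20
                for e in train.events
            )
            for w0, w1 in windows
        )
        assert hit / len(windows) > 0.5

    def test_silent_level_clamp_is_a_mild_perturbation(
        self, uncoupled_burster, uncoupled_spiker
    ):
        """Clamping the partner at the spiker's own inter-event minimum
        perturbs the event rate modestly and never converts the cell."""
        base_train = ev.event_train(uncoupled_spiker, 0)
        v_min = float(uncoupled_spiker.window().v[0].min())
        windows = ev.active_phase_windows(
            uncoupled_burster.v[0], uncoupled_burster.dt
        )
        proto = ClampProtocol(v_fix=v_min, windows=tuple(windows), g_c=0.05)
        cfg = SimConfig(dt=0.5, t_end=60_000, t_transient=20_000, g_c=0.0, seed=1)
        traj = pn.run_with_clamped_partner(pn.spiker_params(), proto, cfg)
        train = ev.event_train(traj, 0)
        converted, frac = ev.is_converted_burster(train)
        assert not converted
        rel = abs(len(train.events) - len(base_train.events)) / len(base_train.events)
        assert rel < 0.2

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            ClampProtocol(v_fix=-20, windows=((0, 100), (50, 200)), g_c=0.05)


class TestConfigAndTrajectory:
    def test_config_json_round_trip(self, tmp_path):
        cfg = SimConfig(dt=0.5, t_end=100, t_transient=50, g_c=0.01, seed=4)
        path = tmp_path / "sim.json"
        cfg.to_json(path)
        assert SimConfig.from_json(path) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [dict(dt=0.0), dict(t_transient=-1.0), dict(t_transient=30.0, t_end=20.0),
         dict(g_c=-0.1)],
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**{"t_end": 20.0, **kwargs})

    def test_trajectory_window_frame_and_csv(self, tmp_path, two_cell_net):
        cfg = SimConfig(dt=0.5, t_end=1000, t_transient=400, g_c=0.05, seed=1)
        traj = pn.run_network(two_cell_net, None, cfg)
        w = traj.window()
        assert w.times[0] >= 400.0
        frame = traj.to_frame()
        assert list(frame.columns[:6]) == ["time_ms", "V_0", "n_0", "c_0", "b_0", "s_0"]
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path)
        assert np.allclose(back["V_1"].to_numpy(), traj.v[1])

    def test_seeded_jitter_is_reproducible_and_bounded(self):
        cfg = SimConfig(t_end=10.0, t_transient=0.0, seed=11)
        a, b = cfg.initial_states(6), cfg.initial_states(6)
        assert np.array_equal(a, b)
        assert np.all(np.abs(a[:, 0] + 60.0) <= 1.0)
        assert np.all(np.abs(a[:, 2] / 0.1 - 1.0) <= 0.05)
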
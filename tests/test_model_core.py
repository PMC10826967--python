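"""Single-cell model: gating, currents, right-hand side, secretion."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import pitnet as pn
from pitnet.model_core import (
    CellParams,
    CellState,
    activation_inf,
    cell_rhs,
    ionic_currents,
    secretion,
    sk_activation,
)
from pitnet import events as ev


class TestActivation:
    @pytest.mark.parametrize(
        "v, nu, l, expected",
        [
            (-5.0, -5.0, 10.0, 0.5),       # half-activation voltage
            (-20.0, -20.0, 12.0, 0.5),
            (-75.0, -5.0, 10.0, 1.0 / (1.0 + math.exp(7.0))),
        ],
    )
    def test_boltzmann_values(self, v, nu, l, expected):
        assert activation_inf(v, nu, l) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-100, 100), st.floats(-100, 100))
    def test_monotone_increasing_and_bounded(self, v, nu):
        lo, hi = activation_inf(v, nu, 10.0), activation_inf(v + 1e-3, nu, 10.0)
        assert 0.0 < lo < 1.0
        assert hi > lo

    def test_rejects_nonfinite_voltage_and_bad_slope(self):
        with pytest.raises(ValueError):
            activation_inf(float("nan"), -5.0, 10.0)
        with pytest.raises(ValueError):
            activation_inf(0.0, -5.0, 0.0)


class TestSKActivation:
    @pytest.mark.parametrize(
        "c, expected", [(0.4, 0.5), (0.0, 0.0), (0.8, 0.8)]
    )
    def test_hill_values(self, c, expected):
        assert sk_activation(c, 0.4) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0, 50))
    def test_bounded_below_one(self, c):
        assert 0.0 <= sk_activation(c, 0.4) < 1.0

    def test_rejects_negative_calcium(self):
        with pytest.raises(ValueError):
            sk_activation(-0.1)


class TestCurrents:
    def test_zero_driving_force_and_closed_channels(self):
        p = pn.burster_params()
        cur = ionic_currents(CellState(v=p.v_l, n=0.0, c=0.2, b=0.0), p)
        assert cur["I_L"] == 0.0
        assert cur["I_Kdr"] == 0.0
        assert cur["I_BK"] == 0.0

    def test_kdr_current_hand_value(self):
        p = pn.burster_params()
        cur = ionic_currents(CellState(v=0.0, n=0.5, c=0.1, b=0.1), p)
        # g_Kdr * n * (V - V_K) = 2.5 * 0.5 * 75
        assert cur["I_Kdr"] == pytest.approx(93.75, rel=1e-12)


class TestRhs:
    def test_no_conductances_no_drift(self):
        p = CellParams(g_kdr=0, g_ca=0, g_l=0, g_sk=0, g_bk=0)
        dv = cell_rhs(CellState(v=-40.0, n=0.2, c=0.3, b=0.2), p)[0]
        assert dv == 0.0

    def test_gating_equilibrium(self):
        p = pn.burster_params()
        v = -30.0
        n_eq = activation_inf(v, p.nu_n, p.l_n)
        dn = cell_rhs(CellState(v=v, n=n_eq, c=0.2, b=0.1), p)[1]
        assert dn == pytest.approx(0.0, abs=1e-15)

    def test_spiker_rest_state_found_by_root_oracle(self):
        """At the numerically located equilibrium every component vanishes.

        The rest state is reduced to a scalar problem: at equilibrium
        n = n_inf(V), b = b_inf(V) and c = -alpha*I_Ca/k_c, leaving a
        single voltage equation solved by bisection.
        """
        p = pn.spiker_params()

        def v_balance(v):
            n = activation_inf(v, p.nu_n, p.l_n)
            b = activation_inf(v, p.nu_b, p.l_b)
            i_ca = ionic_currents(CellState(v=v, n=n, c=0.0, b=b), p)["I_Ca"]
            c = max(-p.alpha * i_ca / p.k_c, 0.0)
            return cell_rhs(CellState(v=v, n=n, c=c, b=b), p)[0]

        grid = np.linspace(-74.0, 0.0, 300)
        vals = [v_balance(v) for v in grid]
        idx = next(
            i for i in range(len(grid) - 1) if vals[i] * vals[i + 1] < 0
        )
        v_rest = brentq(v_balance, grid[idx], grid[idx + 1], xtol=1e-14)
        n = activation_inf(v_rest, p.nu_n, p.l_n)
        b = activation_inf(v_rest, p.nu_b, p.l_b)
        i_ca = ionic_currents(CellState(v=v_rest, n=n, c=0.0, b=b), p)["I_Ca"]
        state = CellState(v=v_rest, n=n, c=-p.alpha * i_ca / p.k_c, b=b)
        rhs = cell_rhs(state, p)
        scale = np.array([100.0, 1.0, 1.0, 1.0])  # mV vs unit-interval scales
        assert np.linalg.norm(rhs / scale) < 1e-10

    def test_rejects_nonfinite_coupling(self):
        with pytest.raises(ValueError):
            cell_rhs(CellState(), pn.burster_params(), float("inf"))


class TestSecretion:
    def test_midpoint_saturation_and_floor(self):
        assert secretion(0.27 + 0.6 * 0.082) == pytest.approx(0.5, rel=1e-12)
        assert secretion(50.0) == pytest.approx(1.0, abs=1e-12)
        assert secretion(0.0) == pytest.approx(
            1.0 / (1.0 + math.exp(5.0 * (0.27 / 0.082 + 0.6))), rel=1e-9
        )

    @given(st.floats(0, 0.6))
    def test_strictly_increasing_below_saturation(self, c):
        assert secretion(c + 1e-4) > secretion(c)

    def test_rejects_negative_calcium(self):
        with pytest.raises(ValueError):
            secretion(-0.2)


class TestParams:
    def test_table_defaults_select_cell_class(self):
        assert pn.burster_params().g_bk == 1.0
        assert pn.spiker_params().g_bk == 0.0
        assert pn.spiker_params().g_kdr == pn.burster_params().g_kdr

    def test_json_round_trip_and_defaults(self, tmp_path):
        p = pn.burster_params()
        path = tmp_path / "cell.json"
        p.to_json(path)
        assert CellParams.from_json(path) == p
        # missing keys fall back to table defaults
        q = CellParams.from_dict({"g_BK": 0.0})
        assert q == pn.spiker_params()
        with pytest.raises(KeyError):
            CellParams.from_dict({"g_XX": 1.0})

    @pytest.mark.parametrize(
        "kwargs",
        [dict(g_ca=-1.0), dict(c_m=0.0), dict(tau_n=-5.0), dict(f_c=0.0),
         dict(k_sk=0.0), dict(l_m=-1.0)],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CellParams(**kwargs)

    def test_state_validation(self):
        with pytest.raises(ValueError):
            CellState(n=1.5)
        with pytest.raises(ValueError):
            CellState(c=-0.1)


class TestIntrinsicPatterns:
    """Uncoupled table-parameter cells produce their nominal firing classes."""

    def test_burster_events_are_multi_peaked(self, uncoupled_burster):
        train = ev.event_train(uncoupled_burster, 0)
        assert len(train.events) > 10
        assert all(e.n_peaks >= 2 for e in train.events)

    def test_spiker_events_are_single_spikes(self, uncoupled_spiker):
        train = ev.event_train(uncoupled_spiker, 0)
        assert len(train.events) > 10
        assert all(e.label == "spike" for e in train.events)

    def test_burster_calcium_and_secretion_exceed_spiker(
        self, uncoupled_burster, uncoupled_spiker
    ):
        wb, ws = uncoupled_burster.window(), uncoupled_spiker.window()
        assert wb.c.mean() > ws.c.mean()
        assert wb.s.mean() > ws.s.mean()

    def test_state_bounds_hold_along_trajectories(
        self, uncoupled_burster, uncoupled_spiker
    ):
        for traj in (uncoupled_burster, uncoupled_spiker):
            assert np.all((traj.n >= 0) & (traj.n <= 1))
            assert np.all((traj.b >= 0) & (traj.b <= 1))
            assert np.all(traj.c > 0)
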
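"""Coupled-network simulation.

Cells are coupled through gap junctions, modelled as ohmic links: the
current into cell i from neighbor j is g_c (V_i - V_j), so every
pairwise exchange cancels and the coupling conserves charge across the
network.  The full system (4 state variables per cell) is integrated
with a classic fixed-step 4th-order Runge-Kutta scheme at dt = 0.5 ms.

Initial conditions default to a common rest-like state with small
seeded per-cell jitter (+-1 mV on V, +-5% on c) so that identical cells
do not start artificially synchronized; both the base state and the
jitter rule can be overridden through :class:`SimConfig`.

The voltage-clamped-partner protocol replaces a coupled burster by a
square-pulse voltage source: during each listed window the cell feels
an input current g_c (V - V_fix), and outside the windows nothing.
This isolates *what* about a bursting neighbor converts a spiker: only
the elevated plateau voltage, not the detailed burst waveform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import CellParams, CellState, burster_params, secretion, spiker_params
from .netgen import BURSTER, CellNetwork

__all__ = [
    "SimConfig",
    "Trajectory",
    "ClampProtocol",
    "coupling_current",
    "integrate",
    "params_for",
    "run_network",
    "run_single_cell",
    "run_with_clamped_partner",
    "simulate_batch",
]

#: default initial state shared by all cells before jitter
DEFAULT_INIT = CellState(v=-60.0, n=0.1, c=0.1, b=0.1)


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    ``t_transient`` is discarded before any analysis (the trajectory
    still contains it; analysis helpers use ``analysis_window``).
    ``init`` may be a list of per-cell CellState; None applies the
    seeded-jitter rule to :data:`DEFAULT_INIT`.
    """

    dt: float = 0.5            # ms
    t_end: float = 20_000.0    # ms
    t_transient: float = 10_000.0  # ms
    g_c: float = 0.002         # nS (table default; experiments override)
    seed: Optional[int] = None
    init: Optional[Sequence[CellState]] = None
    jitter_v: float = 1.0      # mV, uniform half-width
    jitter_c: float = 0.05     # relative, uniform half-width

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.t_transient < self.t_end:
            raise ValueError("need 0 <= t_transient < t_end")
        if self.g_c < 0:
            raise ValueError("g_c must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def initial_states(self, n_cells: int) -> np.ndarray:
        """(n_cells, 4) array of initial [V, n, c, b] rows."""
        if self.init is not None:
            if len(self.init) != n_cells:
                raise ValueError(
                    f"{len(self.init)} initial states for {n_cells} cells"
                )
            return np.array([s.as_array() for s in self.init])
        rng = np.random.default_rng(self.seed)
        y = np.tile(DEFAULT_INIT.as_array(), (n_cells, 1))
        y[:, 0] += rng.uniform(-self.jitter_v, self.jitter_v, size=n_cells)
        y[:, 2] *= 1.0 + rng.uniform(-self.jitter_c, self.jitter_c, size=n_cells)
        return y

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        d = {
            "dt": self.dt,
            "t_end": self.t_end,
            "t_transient": self.t_transient,
            "g_c": self.g_c,
            "seed": self.seed,
        }
        if self.init is not None:
            d["init"] = [[s.v, s.n, s.c, s.b] for s in self.init]
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "SimConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        init = d.pop("init", None)
        if init is not None:
            init = [CellState(*row) for row in init]
        return cls(init=init, **d)


@dataclass(frozen=True)
class ClampProtocol:
    """Square-pulse stand-in for a coupled bursting partner.

    During each (start, end) window the partner is held at ``v_fix`` and
    the cell receives the gap-junction current g_c (V - v_fix).
    """

    v_fix: float
    windows: tuple
    g_c: float = 0.05

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for t0, t1 in self.windows:
            if t1 <= t0:
                raise ValueError(f"empty clamp window ({t0}, {t1})")
            if t0 < prev_end:
                raise ValueError("clamp windows must be ordered, non-overlapping")
            prev_end = t1


@dataclass
class Trajectory:
    """Simulated time courses for all cells of one network.

    ``v``, ``n``, ``c``, ``b`` have shape (n_cells, n_times); ``s`` is
    the secretion readout derived from ``c``.  ``analysis_window`` is
    the post-transient (t0, t1) interval the config prescribed.
    """

    times: np.ndarray
    v: np.ndarray
    n: np.ndarray
    c: np.ndarray
    b: np.ndarray
    analysis_window: tuple = (0.0, np.inf)
    _s: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.v.shape != (self.n_cells, self.times.size):
            raise ValueError("state arrays must be (n_cells, n_times)")
        dts = np.diff(self.times)
        if dts.size and not np.allclose(dts, dts[0]):
            raise ValueError("time grid must be uniform")

    @property
    def n_cells(self) -> int:
        return self.v.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def s(self) -> np.ndarray:
        if self._s is None:
            self._s = secretion(self.c)
        return self._s

    def window(self, t0: Optional[float] = None, t1: Optional[float] = None) -> "Trajectory":
        """Sub-trajectory restricted to [t0, t1] (defaults: analysis window)."""
        if t0 is None:
            t0 = self.analysis_window[0]
        if t1 is None:
            t1 = self.analysis_window[1]
        mask = (self.times >= t0) & (self.times <= t1)
        return Trajectory(
            times=self.times[mask],
            v=self.v[:, mask],
            n=self.n[:, mask],
            c=self.c[:, mask],
            b=self.b[:, mask],
            analysis_window=(t0, min(t1, float(self.times[-1]))),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: time, then V/n/c/b/s columns per cell."""
        cols = {"time_ms": self.times}
        for i in range(self.n_cells):
            cols[f"V_{i}"] = self.v[i]
            cols[f"n_{i}"] = self.n[i]
            cols[f"c_{i}"] = self.c[i]
            cols[f"b_{i}"] = self.b[i]
            cols[f"s_{i}"] = self.s[i]
        return pd.DataFrame(cols)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def coupling_current(v_i: float, neighbor_vs: Sequence[float], g_c: float) -> float:
    """Total gap-junction current out of cell i: sum_j g_c (V_i - V_j) (pA)."""
    if g_c < 0:
        raise ValueError("g_c must be >= 0")
    return float(sum(g_c * (v_i - v_j) for v_j in neighbor_vs))


def integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0,
    dt: float,
    t_end: float,
    t0: float = 0.0,
) -> tuple:
    """Generic fixed-step RK4: returns (times, Y) with Y[k] the state at times[k].

    Raises FloatingPointError naming the step index if the state stops
    being finite.
    """
    if dt <= 0 or t_end <= t0:
        raise ValueError("need dt > 0 and t_end > t0")
    y = np.atleast_1d(np.asarray(y0, dtype=float))
    n_steps = int(round((t_end - t0) / dt))
    times = t0 + dt * np.arange(n_steps + 1)
    out = np.empty((n_steps + 1,) + y.shape)
    out[0] = y
    for k in range(n_steps):
        t = times[k]
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite state at step {k + 1}")
        out[k + 1] = y
    return times, out


def params_for(
    net: CellNetwork,
    burster: Optional[CellParams] = None,
    spiker: Optional[CellParams] = None,
) -> list:
    """Per-cell parameter list matching the network's type labels."""
    burster = burster or burster_params()
    spiker = spiker or spiker_params()
    net._require_labels()
    return [burster if t == BURSTER else spiker for t in net.types]


# ---------------------------------------------------------------------------
# Network runs
# ---------------------------------------------------------------------------

def run_network(
    net: CellNetwork,
    params: Union[Sequence[CellParams], None],
    cfg: SimConfig,
    record_stride: int = 1,
    backend: Optional[str] = None,
) -> Trajectory:
    """Integrate the full coupled network and return its Trajectory.

    ``params`` is a per-cell list (see :func:`params_for`); None derives
    it from the network labels with table-default burster/spiker cells.
    """
    if params is None:
        params = params_for(net)
    if len(params) != net.n_nodes:
        raise ValueError(f"{len(params)} parameter sets for {net.n_nodes} cells")
    P = _kernels.pack_params(params)
    gbk = np.array([[p.g_bk for p in params]])
    indptr, indices = _kernels.csr_adjacency(net)
    y0 = cfg.initial_states(net.n_nodes)
    V = np.ascontiguousarray(y0[:, 0][None, :])
    n = np.ascontiguousarray(y0[:, 1][None, :])
    c = np.ascontiguousarray(y0[:, 2][None, :])
    b = np.ascontiguousarray(y0[:, 3][None, :])
    n_steps = cfg.n_steps
    n_rec = _kernels.n_record_slots(n_steps, 0, record_stride)
    shape = (1, net.n_nodes, n_rec)
    Vr, nr, cr, br = (np.empty(shape) for _ in range(4))
    s_sum = np.zeros((1, net.n_nodes))
    status, _ = _kernels.rk4_network(
        V, n, c, b, gbk, P, indptr, indices, cfg.g_c, cfg.dt, n_steps,
        0, record_stride, Vr, nr, cr, br, 1, n_steps + 1, s_sum,
        backend=backend,
    )
    if status >= 0:
        raise FloatingPointError(f"non-finite membrane potential at step {status}")
    times = cfg.dt * record_stride * np.arange(n_rec)
    return Trajectory(
        times=times, v=Vr[0], n=nr[0], c=cr[0], b=br[0],
        analysis_window=(cfg.t_transient, cfg.t_end),
    )


def run_single_cell(
    params: CellParams,
    cfg: SimConfig,
    init: Optional[CellState] = None,
    backend: Optional[str] = None,
) -> Trajectory:
    """Uncoupled single-cell run (a 2-node network with g_c = 0 shortcut)."""
    proto = ClampProtocol(v_fix=0.0, windows=(), g_c=0.0)
    return run_with_clamped_partner(params, proto, cfg, init=init, backend=backend)


def run_with_clamped_partner(
    params: CellParams,
    proto: ClampProtocol,
    cfg: SimConfig,
    init: Optional[CellState] = None,
    backend: Optional[str] = None,
) -> Trajectory:
    """Single cell driven by a voltage-clamped partner during set windows.

    With an empty window list (or g_c = 0) this is a plain uncoupled run.
    """
    if init is None:
        states = cfg.init
        init = states[0] if states else DEFAULT_INIT
    P = _kernels.pack_params([params])[:, 0].copy()
    windows = np.array(proto.windows, dtype=float).reshape(-1, 2)
    n_steps = cfg.n_steps
    Vr, nr, cr, br = (np.empty(n_steps + 1) for _ in range(4))
    status = _kernels.rk4_clamped(
        init.v, init.n, init.c, init.b, params.g_bk, P,
        windows, proto.g_c, proto.v_fix, cfg.dt, n_steps, Vr, nr, cr, br,
        backend=backend,
    )
    if status >= 0:
        raise FloatingPointError(f"non-finite membrane potential at step {status}")
    times = cfg.dt * np.arange(n_steps + 1)
    return Trajectory(
        times=times, v=Vr[None, :], n=nr[None, :], c=cr[None, :], b=br[None, :],
        analysis_window=(cfg.t_transient, cfg.t_end),
    )


def simulate_batch(
    net: CellNetwork,
    gbk: np.ndarray,
    cfg: SimConfig,
    base_params: Optional[CellParams] = None,
    init_seeds: Optional[Sequence[int]] = None,
    record_v: bool = True,
    backend: Optional[str] = None,
) -> dict:
    """Advance B placements of one structural network in lock-step.

    ``gbk`` is the (B, n_cells) matrix of per-cell BK conductances (the
    only parameter that differs between placements; all other parameters
    come from ``base_params``).  Voltage is recorded over the
    post-transient analysis window only; the secretion readout is
    accumulated at every post-transient step.  Returns a dict with
    ``times`` (analysis window), ``v`` (B, N, T) and ``s_mean`` (B, N),
    the per-cell time-averaged secretion.
    """
    gbk = np.ascontiguousarray(gbk, dtype=float)
    B, N = gbk.shape
    if N != net.n_nodes:
        raise ValueError("gbk width must equal the cell count")
    base = base_params or spiker_params()
    P = _kernels.pack_params([base] * N)
    indptr, indices = _kernels.csr_adjacency(net)
    if init_seeds is None:
        rng = np.random.default_rng(cfg.seed)
        init_seeds = rng.integers(2**31, size=B)
    V = np.empty((B, N)); n = np.empty((B, N))
    c = np.empty((B, N)); b = np.empty((B, N))
    for k, s in enumerate(init_seeds):
        y0 = replace(cfg, seed=int(s), init=None).initial_states(N)
        V[k], n[k], c[k], b[k] = y0.T
    n_steps = cfg.n_steps
    acc_start = int(round(cfg.t_transient / cfg.dt))
    # recording starts with the analysis window, or never (sink arrays)
    rec_start = acc_start if record_v else n_steps + 1
    n_rec = max(_kernels.n_record_slots(n_steps, rec_start, 1), 1)
    Vr = np.empty((B, N, n_rec))
    # n/c/b histories are not needed for sweeps: 1-slot sinks, rec_full = 0
    nr = np.empty((B, N, 1)); cr = np.empty((B, N, 1)); br = np.empty((B, N, 1))
    s_sum = np.zeros((B, N))
    status, n_acc = _kernels.rk4_network(
        V, n, c, b, gbk, P, indptr, indices, cfg.g_c, cfg.dt, n_steps,
        rec_start, 1, Vr, nr, cr, br, 0, acc_start, s_sum, backend=backend,
    )
    if status >= 0:
        raise FloatingPointError(f"non-finite membrane potential at step {status}")
    times = cfg.dt * (acc_start + np.arange(n_rec))
    return {
        "times": times,
        "v": Vr if record_v else None,
        "s_mean": s_sum / n_acc,
        "n_acc": n_acc,
    }
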
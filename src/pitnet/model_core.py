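"""Single-cell pituitary lactotroph model.

The model is a Hodgkin-Huxley-style conductance-based description of a
pituitary lactotroph with four state variables: membrane potential ``V``
(mV), delayed-rectifier K+ activation ``n``, free cytosolic Ca2+
concentration ``c`` (uM), and BK-channel activation ``b``.  Five ionic
currents flow across the membrane: a delayed-rectifier K+ current (Kdr),
an L-type Ca2+ current (Ca, with instantaneous activation m = m_inf(V)),
a big-conductance Ca2+-activated K+ current (BK), a small-conductance
Ca2+-activated K+ current (SK, gated by ``c``), and an ohmic leak.

With the default parameters the cell is an intrinsic *pseudo-plateau
burster*: bursts of small-amplitude spikes riding on a depolarized
plateau.  Setting the BK conductance ``g_bk`` to zero removes the
fast-activating K+ feedback and turns the cell into an intrinsic *tonic
spiker*.  That one conductance is the only source of cell heterogeneity
used throughout the package.

A dimensionless secretion readout ``s(c)`` — a steep sigmoid of cytosolic
Ca2+ — serves as the surrogate for hormone exocytosis, which requires
cooperative Ca2+ binding at release sites.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "CellParams",
    "CellState",
    "burster_params",
    "spiker_params",
    "activation_inf",
    "sk_activation",
    "ionic_currents",
    "cell_rhs",
    "secretion",
    "SECRETION_MIDPOINT",
]

#: JSON keys (standard symbol names) <-> dataclass attribute names.
_JSON_KEYS = {
    "C_m": "c_m",
    "g_Kdr": "g_kdr",
    "g_Ca": "g_ca",
    "g_L": "g_l",
    "g_SK": "g_sk",
    "g_BK": "g_bk",
    "V_Ca": "v_ca",
    "V_K": "v_k",
    "V_L": "v_l",
    "tau_n": "tau_n",
    "tau_b": "tau_b",
    "nu_n": "nu_n",
    "nu_m": "nu_m",
    "nu_b": "nu_b",
    "l_n": "l_n",
    "l_m": "l_m",
    "l_b": "l_b",
    "alpha": "alpha",
    "f_c": "f_c",
    "k_c": "k_c",
    "k_SK": "k_sk",
}
_ATTR_TO_JSON = {v: k for k, v in _JSON_KEYS.items()}


@dataclass(frozen=True)
class CellParams:
    """Parameters of one lactotroph cell.

    Defaults describe an intrinsic burster; ``g_bk = 0`` gives an
    intrinsic spiker.  Units: capacitance pF, conductances nS, voltages
    mV, time constants ms, ``alpha`` uM/fC, ``k_c`` 1/ms, ``k_sk`` uM.
    """

    c_m: float = 5.0        # membrane capacitance, pF
    g_kdr: float = 2.5      # delayed-rectifier K+ conductance, nS
    g_ca: float = 2.1       # L-type Ca2+ conductance, nS
    g_l: float = 0.2        # leak conductance, nS
    g_sk: float = 2.0       # SK conductance, nS
    g_bk: float = 1.0       # BK conductance, nS; 0 => intrinsic spiker
    v_ca: float = 60.0      # Ca2+ reversal potential, mV
    v_k: float = -75.0      # K+ reversal potential, mV
    v_l: float = -50.0      # leak reversal potential, mV
    tau_n: float = 30.0     # Kdr activation time constant, ms
    tau_b: float = 5.0      # BK activation time constant, ms
    nu_n: float = -5.0      # Kdr half-activation voltage, mV
    nu_m: float = -20.0     # Ca activation half-activation voltage, mV
    nu_b: float = -5.0      # BK half-activation voltage, mV
    l_n: float = 10.0       # Kdr slope factor, mV
    l_m: float = 12.0       # Ca slope factor, mV
    l_b: float = 2.0        # BK slope factor, mV
    alpha: float = 0.0015   # current-to-concentration factor, uM/fC
    f_c: float = 0.005      # fraction of cytosolic Ca2+ that is free
    k_c: float = 0.12       # Ca2+ pump (removal) rate, 1/ms
    k_sk: float = 0.4       # SK half-activation Ca2+ concentration, uM

    def __post_init__(self) -> None:
        for name in ("g_kdr", "g_ca", "g_l", "g_sk", "g_bk"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")
        for name in ("tau_n", "tau_b", "l_n", "l_m", "l_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.f_c <= 1:
            raise ValueError("f_c must lie in (0, 1]")
        if self.k_sk <= 0:
            raise ValueError("k_sk must be > 0")

    @property
    def is_burster(self) -> bool:
        """True if the cell is an intrinsic burster (g_bk > 0)."""
        return self.g_bk > 0

    # -- JSON round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        """Flat dict keyed by the standard symbol names (``g_BK`` etc.)."""
        return {_ATTR_TO_JSON[f.name]: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CellParams":
        """Build from a flat symbol-keyed dict; missing keys keep defaults."""
        unknown = set(d) - set(_JSON_KEYS)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{_JSON_KEYS[k]: float(v) for k, v in d.items()})

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "CellParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def burster_params(**overrides) -> CellParams:
    """Default parameters: an intrinsic pseudo-plateau burster (g_bk = 1 nS)."""
    return CellParams(**overrides)


def spiker_params(**overrides) -> CellParams:
    """Intrinsic tonic spiker: the burster with the BK conductance removed."""
    overrides.setdefault("g_bk", 0.0)
    return CellParams(**overrides)


@dataclass
class CellState:
    """State of one cell: V (mV), n, c (uM), b."""

    v: float = -60.0
    n: float = 0.1
    c: float = 0.1
    b: float = 0.1

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.v, self.n, self.c, self.b))):
            raise ValueError("cell state must be finite")
        if not 0 <= self.n <= 1 or not 0 <= self.b <= 1:
            raise ValueError("gating variables n, b must lie in [0, 1]")
        if self.c < 0:
            raise ValueError("Ca2+ concentration c must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.n, self.c, self.b], dtype=float)

    @classmethod
    def from_array(cls, y) -> "CellState":
        v, n, c, b = np.asarray(y, dtype=float)
        return cls(v=v, n=n, c=c, b=b)


# ---------------------------------------------------------------------------
# Gating, currents, right-hand side
# ---------------------------------------------------------------------------

def activation_inf(v, nu, l):
    """Boltzmann equilibrium activation 1 / (1 + exp((nu - v) / l)).

    ``nu`` is the half-activation voltage and ``l`` the slope factor
    (both mV, ``l > 0``).  Strictly increasing in ``v``.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    if np.any(np.asarray(l) <= 0):
        raise ValueError("slope factor l must be > 0")
    out = 1.0 / (1.0 + np.exp((nu - v) / l))
    return float(out) if out.ndim == 0 else out


def sk_activation(c, k_sk=0.4):
    """SK-channel equilibrium activation c^2 / (c^2 + k_sk^2)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("Ca2+ concentration must be >= 0")
    if np.any(np.asarray(k_sk) <= 0):
        raise ValueError("k_sk must be > 0")
    out = c * c / (c * c + k_sk * k_sk)
    return float(out) if out.ndim == 0 else out


def ionic_currents(state: CellState, p: CellParams) -> dict:
    """All five membrane currents (pA) at the given state.

    The Ca2+ current uses the quasi-steady activation m = m_inf(V).
    Outward currents are positive.
    """
    v, n, c, b = state.v, state.n, state.c, state.b
    m_inf = activation_inf(v, p.nu_m, p.l_m)
    return {
        "I_Kdr": p.g_kdr * n * (v - p.v_k),
        "I_Ca": p.g_ca * m_inf * (v - p.v_ca),
        "I_BK": p.g_bk * b * (v - p.v_k),
        "I_SK": p.g_sk * sk_activation(c, p.k_sk) * (v - p.v_k),
        "I_L": p.g_l * (v - p.v_l),
    }


def cell_rhs(state: CellState, p: CellParams, i_c: float = 0.0) -> np.ndarray:
    """Time derivative (dV, dn, dc, db) of one cell.

    ``i_c`` is the total gap-junction current flowing out of this cell
    (pA); it enters the voltage equation alongside the ionic currents.
    ``b`` is always integrated, but for a spiker (g_bk = 0) it is inert:
    I_BK is identically zero, so it does not feed back on the dynamics.
    """
    if not math.isfinite(i_c):
        raise ValueError("coupling current must be finite")
    cur = ionic_currents(state, p)
    i_tot = cur["I_Kdr"] + cur["I_Ca"] + cur["I_BK"] + cur["I_SK"] + cur["I_L"] + i_c
    dv = -i_tot / p.c_m
    dn = (activation_inf(state.v, p.nu_n, p.l_n) - state.n) / p.tau_n
    dc = -p.f_c * (p.alpha * cur["I_Ca"] + p.k_c * state.c)
    db = (activation_inf(state.v, p.nu_b, p.l_b) - state.b) / p.tau_b
    return np.array([dv, dn, dc, db])


#: Ca2+ concentration (uM) at which the secretion sigmoid crosses 1/2.
SECRETION_MIDPOINT = 0.27 + 0.6 * 0.082


def secretion(c):
    """Dimensionless secretion readout s(c) = 1/(1 + exp(-5((c-0.27)/0.082 - 0.6))).

    A steep sigmoid of cytosolic Ca2+ standing in for the cooperative
    Ca2+ dependence of exocytosis; it crosses 1/2 at c ~= 0.319 uM,
    between the Ca2+ levels typical of tonic spiking and of bursting, so
    that s rises substantially during each burst and barely at all
    during isolated spikes.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("Ca2+ concentration must be >= 0")
    out = 1.0 / (1.0 + np.exp(-5.0 * ((c - 0.27) / 0.082 - 0.6)))
    return float(out) if out.ndim == 0 else out
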
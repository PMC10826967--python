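"""Folded-node fast/slow analysis of the intrinsic spiker.

The spiker (g_BK = 0) is a 3-variable system in which the membrane
potential ``V`` is fast while the Kdr activation ``n`` and the Ca2+
concentration ``c`` are slow.  Writing the fast equation as
dV/dt = F(V, n, c), the *critical manifold* is the surface F = 0.
Because F is linear in ``n`` (only the Kdr current carries it), the
manifold is globally a graph n = h(V, c), so (V, c) is a global chart.

On the manifold the slow flow, projected to the chart by total
differentiation of the constraint, has dV/dt = -(F_n nd + F_c cd)/F_V,
which blows up on the *fold curve* F_V = 0 where the manifold loses
normal hyperbolicity.  Rescaling time by -F_V gives the regular
*desingularized system*

    dV/dtau = F_n * nd + F_c * cd,      dc/dtau = -F_V * cd,

(``nd``, ``cd`` the slow right-hand sides with n = h(V, c)).  Ordinary
equilibria of this system off the fold are true equilibria; equilibria
*on* the fold are folded singularities.  A *folded node* — both
eigenvalues of the desingularized Jacobian real with the same sign —
organizes a twisted region of the slow manifold.  With eigenvalue
ratio mu = lambda_weak / lambda_strong in (0, 1), the folded node
carries k secondary canards where 2k + 1 < 1/mu < 2k + 3; a trajectory
entering the sector between canards gamma_{j-1} and gamma_j performs j
small loops — the small spikes of a pseudo-plateau burst.

A constant gap-junction input g_c (V - V_fix) from a depolarized
partner is added directly to the fast equation; it shifts the folded
node (and the canards with it) to higher Ca2+ values, which is how a
bursting neighbor moves the twisted region into the path of the
spiker's trajectory and converts it to bursting.

All algebra (F, h, the desingularized field and its Jacobian) is built
symbolically and lambdified once per model, then evaluated numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import sympy as sp
from scipy.optimize import brentq, root

from .model_core import CellParams, spiker_params

__all__ = [
    "ReducedModel",
    "FoldedNode",
    "critical_manifold_n",
    "desingularized_rhs",
    "fold_curve_points",
    "find_folded_node",
    "find_folded_singularities",
    "secondary_canard_count",
]

#: physiological search box for folded singularities
V_BOX = (-75.0, 60.0)
C_BOX = (1e-6, 2.0)

RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class FoldedNode:
    """A folded singularity with node classification data.

    ``mu`` is the weak/strong eigenvalue ratio; ``canard_count`` the
    number of secondary canards (None at resonance or for non-nodes).
    ``kind`` is ``"node"``, ``"saddle"``, or ``"focus"``.
    """

    v: float
    c: float
    n: float
    lambda_strong: float
    lambda_weak: float
    kind: str
    residual: float

    @property
    def mu(self) -> float:
        return self.lambda_weak / self.lambda_strong

    @property
    def canard_count(self) -> Optional[int]:
        if self.kind != "node":
            return None
        try:
            return secondary_canard_count(self.mu)
        except ValueError:
            return None

    def as_dict(self) -> dict:
        return {
            "V": self.v,
            "c": self.c,
            "n": self.n,
            "lambda_strong": self.lambda_strong,
            "lambda_weak": self.lambda_weak,
            "mu": self.mu,
            "kind": self.kind,
            "canard_count": self.canard_count,
            "residual": self.residual,
        }


class ReducedModel:
    """1-fast/2-slow reduction of the intrinsic spiker, optionally driven.

    ``input_gc``/``input_vfix`` add the constant-partner gap-junction
    current g_c (V - V_fix) to the fast equation (the voltage-clamped
    partner of the conversion experiments).  Requires g_bk = 0: the BK
    variable b is absent from the reduction.
    """

    def __init__(
        self,
        params: Optional[CellParams] = None,
        input_gc: float = 0.0,
        input_vfix: float = -20.0,
    ):
        params = params or spiker_params()
        if params.g_bk != 0:
            raise ValueError("fast/slow reduction is defined for the spiker (g_bk = 0)")
        if input_gc < 0:
            raise ValueError("input conductance must be >= 0")
        self.params = params
        self.input_gc = float(input_gc)
        self.input_vfix = float(input_vfix)
        self._build()

    def _build(self) -> None:
        p = self.params
        V, n, c = sp.symbols("V n c", real=True)
        minf = 1 / (1 + sp.exp((p.nu_m - V) / p.l_m))
        ninf = 1 / (1 + sp.exp((p.nu_n - V) / p.l_n))
        i_ca = p.g_ca * minf * (V - p.v_ca)
        i_kdr = p.g_kdr * n * (V - p.v_k)
        i_sk = p.g_sk * (c**2 / (c**2 + p.k_sk**2)) * (V - p.v_k)
        i_l = p.g_l * (V - p.v_l)
        i_in = self.input_gc * (V - self.input_vfix)
        F = -(i_kdr + i_ca + i_sk + i_l + i_in) / p.c_m
        # critical manifold: F linear in n -> global graph n = h(V, c)
        h = sp.solve(F, n)[0]
        F_V, F_n, F_c = (sp.diff(F, x) for x in (V, n, c))
        ndot = (ninf - n) / p.tau_n
        cdot = -p.f_c * (p.alpha * i_ca + p.k_c * c)
        G1 = (F_n * ndot + F_c * cdot).subs(n, h)
        G2 = (-F_V * cdot).subs(n, h)
        FV_h = F_V.subs(n, h)
        J = sp.Matrix([[sp.diff(G1, V), sp.diff(G1, c)],
                       [sp.diff(G2, V), sp.diff(G2, c)]])
        lam = lambda expr: sp.lambdify((V, c), expr, "numpy")
        self._h = lam(h)
        self._F = sp.lambdify((V, n, c), F, "numpy")
        self._FV = lam(FV_h)
        self._G1 = lam(G1)
        self._G2 = lam(G2)
        self._J = lam(J)

    # numeric surface ------------------------------------------------------

    def fast_rhs(self, v, n, c):
        """F(V, n, c): dV/dt of the reduced (3-variable) spiker."""
        return self._F(v, n, c)

    def manifold_n(self, v, c):
        if np.any(np.isclose(v, self.params.v_k)):
            raise ZeroDivisionError(
                "critical manifold is singular at V = V_K (Kdr driving force vanishes)"
            )
        return self._h(v, c)

    def fold_residual(self, v, c):
        """F_V on the manifold; zero on the fold curve."""
        return self._FV(v, c)

    def desingularized(self, v, c):
        """(dV/dtau, dc/dtau) of the desingularized slow flow."""
        return float(self._G1(v, c)), float(self._G2(v, c))

    def jacobian(self, v, c) -> np.ndarray:
        """Jacobian of the desingularized field at (V, c)."""
        return np.array(self._J(v, c), dtype=float)


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def critical_manifold_n(v, c, model: ReducedModel):
    """n on the critical manifold at (V, c): solves F(V, n, c) = 0 for n."""
    return model.manifold_n(v, c)


def desingularized_rhs(v: float, c: float, model: ReducedModel) -> tuple:
    """Desingularized slow flow and its Jacobian at a chart point (V, c)."""
    return model.desingularized(v, c), model.jacobian(v, c)


def fold_voltages(
    model: ReducedModel,
    n_grid: int = 400,
    v_box: tuple = V_BOX,
) -> list:
    """Voltages of the fold lines F_V = 0.

    On the critical manifold F_V is independent of c — substituting
    n = h(V, c) cancels the SK term (SK and Kdr share the K+ reversal
    and F is linear in n) — so each fold is a line of constant V and
    the fold curve is fully described by these voltages.
    """
    c_probe = 0.3  # arbitrary: F_V on the manifold does not depend on c
    vs = np.linspace(v_box[0] + 1e-6, v_box[1], n_grid)
    r = np.array([model.fold_residual(v, c_probe) for v in vs])
    out = []
    for i in np.where(np.sign(r[:-1]) * np.sign(r[1:]) < 0)[0]:
        out.append(
            brentq(lambda vv: model.fold_residual(vv, c_probe), vs[i], vs[i + 1],
                   xtol=1e-13)
        )
    return out


def fold_curve_points(
    model: ReducedModel,
    n_grid: int = 400,
    v_box: tuple = V_BOX,
    c_box: tuple = C_BOX,
    n_c: int = 50,
) -> np.ndarray:
    """Sample the fold curve F_V = 0 as (V, c) rows (lines of constant V)."""
    cs = np.linspace(c_box[0], c_box[1], n_c)
    return np.array(
        [(v, c) for v in fold_voltages(model, n_grid=n_grid, v_box=v_box) for c in cs]
    )


def _classify(J: np.ndarray) -> tuple:
    lams = np.linalg.eigvals(J)
    if np.abs(lams.imag).max() > 1e-9 * max(np.abs(lams).max(), 1.0):
        return "focus", lams
    lams = np.sort(lams.real)
    if lams[0] * lams[1] < 0:
        return "saddle", lams
    return "node", lams


def find_folded_singularities(
    model: ReducedModel,
    n_grid: int = 400,
) -> list:
    """All folded singularities in the physiological box, classified.

    Scans each fold line for sign changes of the desingularized flow
    component G1 (which vanishes together with G2 on the fold), then
    polishes each candidate with a multivariate root solve on
    {F_V = 0, G1 = 0}.
    """
    out = []
    cs = np.linspace(C_BOX[0], C_BOX[1], 400)
    for v_f in fold_voltages(model, n_grid=n_grid):
        g1 = np.array([model.desingularized(v_f, c)[0] for c in cs])
        idx = np.where(np.sign(g1[:-1]) * np.sign(g1[1:]) < 0)[0]
        for i in idx:
            guess = (v_f, 0.5 * (cs[i] + cs[i + 1]))
            sol = root(
                lambda x: [model.fold_residual(x[0], x[1]),
                           model.desingularized(x[0], x[1])[0]],
                guess,
                tol=1e-12,
            )
            if not sol.success:
                continue
            v_s, c_s = sol.x
            if not (V_BOX[0] <= v_s <= V_BOX[1] and 0 <= c_s <= C_BOX[1]):
                continue
            n_s = float(model.manifold_n(v_s, c_s))
            resid = max(
                abs(model.fast_rhs(v_s, n_s, c_s)),
                abs(model.fold_residual(v_s, c_s)),
                abs(model.desingularized(v_s, c_s)[0]),
                abs(model.desingularized(v_s, c_s)[1]),
            )
            kind, lams = _classify(model.jacobian(v_s, c_s))
            if kind == "focus":
                ls = lw = float("nan")
            else:
                ls, lw = (lams[np.argmax(np.abs(lams))], lams[np.argmin(np.abs(lams))])
            fn = FoldedNode(
                v=float(v_s), c=float(c_s), n=n_s,
                lambda_strong=float(ls), lambda_weak=float(lw),
                kind=kind, residual=float(resid),
            )
            if not any(abs(f.v - fn.v) < 1e-6 and abs(f.c - fn.c) < 1e-9 for f in out):
                out.append(fn)
    return out


def find_folded_node(model: ReducedModel, n_grid: int = 400) -> FoldedNode:
    """The folded *node* of the model (error if none exists in the box)."""
    nodes = [f for f in find_folded_singularities(model, n_grid=n_grid)
             if f.kind == "node" and 0 < f.mu < 1]
    if not nodes:
        raise ValueError("no folded node singularity in the physiological box")
    nodes.sort(key=lambda f: f.residual)
    node = nodes[0]
    if node.residual > RESIDUAL_TOL:
        raise ArithmeticError(
            f"folded-node residual {node.residual:.2e} exceeds {RESIDUAL_TOL}"
        )
    return node


def secondary_canard_count(mu: float) -> int:
    """Secondary canards of a folded node: k with 2k + 1 < 1/mu < 2k + 3.

    Raises at resonance (1/mu an odd integer), where the count is
    undefined.
    """
    if not 0 < mu < 1:
        raise ValueError("folded-node eigenvalue ratio mu must lie in (0, 1)")
    inv = 1.0 / mu
    if inv > 1 and abs(inv - round(inv)) < 1e-9 and round(inv) % 2 == 1:
        raise ValueError(f"resonance: 1/mu = {inv:.0f} is an odd integer")
    return int(np.floor((inv - 1) / 2))
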
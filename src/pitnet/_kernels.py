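"""Fixed-step RK4 integration kernels for coupled lactotroph networks.

Two interchangeable backends: a numba-jitted kernel (used when numba
imports cleanly) and a vectorized pure-numpy fallback.  Both integrate a
*batch* of B independent networks that share one structural graph and
one parameter set except for the per-cell BK conductance, which is the
(B, N) placement matrix.  Batching is what makes the placement sweeps
cheap: one kernel call advances hundreds of placements in lock-step.

Cell parameters are packed in a (20, N) array ``P`` with the row layout
given by the ``P_*`` constants.  The gap-junction current into cell i is
g_c * sum_j (V_i - V_j) over the CSR-encoded neighbor list.

Kernels return a status integer: -1 on success, else the 1-based step
index at which a non-finite membrane potential was first observed.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# parameter row indices in the packed (20, N) array
P_CM, P_GKDR, P_GCA, P_GL, P_GSK = 0, 1, 2, 3, 4
P_VCA, P_VK, P_VL = 5, 6, 7
P_TAUN, P_TAUB = 8, 9
P_NUN, P_NUM, P_NUB = 10, 11, 12
P_LN, P_LM, P_LB = 13, 14, 15
P_ALPHA, P_FC, P_KC, P_KSK = 16, 17, 18, 19
N_PARAM_ROWS = 20

_ROW_ATTRS = (
    "c_m", "g_kdr", "g_ca", "g_l", "g_sk",
    "v_ca", "v_k", "v_l",
    "tau_n", "tau_b",
    "nu_n", "nu_m", "nu_b",
    "l_n", "l_m", "l_b",
    "alpha", "f_c", "k_c", "k_sk",
)


def pack_params(params_list) -> np.ndarray:
    """Pack per-cell CellParams into the (20, N) kernel layout (g_bk apart)."""
    P = np.empty((N_PARAM_ROWS, len(params_list)))
    for i, p in enumerate(params_list):
        for row, attr in enumerate(_ROW_ATTRS):
            P[row, i] = getattr(p, attr)
    return P


def csr_adjacency(net) -> tuple:
    """CSR neighbor lists (indptr, indices) of a CellNetwork."""
    nbrs = [net.neighbors(v) for v in range(net.n_nodes)]
    indptr = np.zeros(net.n_nodes + 1, dtype=np.int64)
    for v, nb in enumerate(nbrs):
        indptr[v + 1] = indptr[v] + len(nb)
    indices = np.array([w for nb in nbrs for w in nb], dtype=np.int64)
    return indptr, indices


def n_record_slots(n_steps: int, rec_start: int, rec_stride: int) -> int:
    return (n_steps - rec_start) // rec_stride + 1


# ---------------------------------------------------------------------------
# numba backend
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs_nb(V, n, c, b, gbk, P, indptr, indices, gc, dV, dn, dc, db):
    B, N = V.shape
    for s in range(B):
        for i in range(N):
            v = V[s, i]
            minf = 1.0 / (1.0 + math.exp((P[P_NUM, i] - v) / P[P_LM, i]))
            ninf = 1.0 / (1.0 + math.exp((P[P_NUN, i] - v) / P[P_LN, i]))
            binf = 1.0 / (1.0 + math.exp((P[P_NUB, i] - v) / P[P_LB, i]))
            ica = P[P_GCA, i] * minf * (v - P[P_VCA, i])
            ikdr = P[P_GKDR, i] * n[s, i] * (v - P[P_VK, i])
            ibk = gbk[s, i] * b[s, i] * (v - P[P_VK, i])
            c2 = c[s, i] * c[s, i]
            isk = P[P_GSK, i] * (c2 / (c2 + P[P_KSK, i] * P[P_KSK, i])) * (v - P[P_VK, i])
            il = P[P_GL, i] * (v - P[P_VL, i])
            ic = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                ic += v - V[s, indices[k]]
            ic *= gc
            dV[s, i] = -(ikdr + ica + ibk + isk + il + ic) / P[P_CM, i]
            dn[s, i] = (ninf - n[s, i]) / P[P_TAUN, i]
            dc[s, i] = -P[P_FC, i] * (P[P_ALPHA, i] * ica + P[P_KC, i] * c[s, i])
            db[s, i] = (binf - b[s, i]) / P[P_TAUB, i]


@njit(cache=True)
def _rk4_network_nb(V, n, c, b, gbk, P, indptr, indices, gc, dt, n_steps,
                    rec_start, rec_stride, Vr, nr, cr, br, rec_full,
                    acc_start, s_sum):
    B, N = V.shape
    k1V = np.empty((B, N)); k1n = np.empty((B, N)); k1c = np.empty((B, N)); k1b = np.empty((B, N))
    k2V = np.empty((B, N)); k2n = np.empty((B, N)); k2c = np.empty((B, N)); k2b = np.empty((B, N))
    k3V = np.empty((B, N)); k3n = np.empty((B, N)); k3c = np.empty((B, N)); k3b = np.empty((B, N))
    k4V = np.empty((B, N)); k4n = np.empty((B, N)); k4c = np.empty((B, N)); k4b = np.empty((B, N))
    Vt = np.empty((B, N)); nt = np.empty((B, N)); ct = np.empty((B, N)); bt = np.empty((B, N))
    r = 0
    n_acc = 0
    if rec_start == 0:
        Vr[:, :, 0] = V
        if rec_full:
            nr[:, :, 0] = n; cr[:, :, 0] = c; br[:, :, 0] = b
        r = 1
    if acc_start == 0:
        for s in range(B):
            for i in range(N):
                s_sum[s, i] += 1.0 / (1.0 + math.exp(-5.0 * ((c[s, i] - 0.27) / 0.082 - 0.6)))
        n_acc += 1
    h = dt
    for step in range(1, n_steps + 1):
        _rhs_nb(V, n, c, b, gbk, P, indptr, indices, gc, k1V, k1n, k1c, k1b)
        for s in range(B):
            for i in range(N):
                Vt[s, i] = V[s, i] + 0.5 * h * k1V[s, i]
                nt[s, i] = n[s, i] + 0.5 * h * k1n[s, i]
                ct[s, i] = c[s, i] + 0.5 * h * k1c[s, i]
                bt[s, i] = b[s, i] + 0.5 * h * k1b[s, i]
        _rhs_nb(Vt, nt, ct, bt, gbk, P, indptr, indices, gc, k2V, k2n, k2c, k2b)
        for s in range(B):
            for i in range(N):
                Vt[s, i] = V[s, i] + 0.5 * h * k2V[s, i]
                nt[s, i] = n[s, i] + 0.5 * h * k2n[s, i]
                ct[s, i] = c[s, i] + 0.5 * h * k2c[s, i]
                bt[s, i] = b[s, i] + 0.5 * h * k2b[s, i]
        _rhs_nb(Vt, nt, ct, bt, gbk, P, indptr, indices, gc, k3V, k3n, k3c, k3b)
        for s in range(B):
            for i in range(N):
                Vt[s, i] = V[s, i] + h * k3V[s, i]
                nt[s, i] = n[s, i] + h * k3n[s, i]
                ct[s, i] = c[s, i] + h * k3c[s, i]
                bt[s, i] = b[s, i] + h * k3b[s, i]
        _rhs_nb(Vt, nt, ct, bt, gbk, P, indptr, indices, gc, k4V, k4n, k4c, k4b)
        ok = True
        for s in range(B):
            for i in range(N):
                V[s, i] += h / 6.0 * (k1V[s, i] + 2.0 * k2V[s, i] + 2.0 * k3V[s, i] + k4V[s, i])
                n[s, i] += h / 6.0 * (k1n[s, i] + 2.0 * k2n[s, i] + 2.0 * k3n[s, i] + k4n[s, i])
                c[s, i] += h / 6.0 * (k1c[s, i] + 2.0 * k2c[s, i] + 2.0 * k3c[s, i] + k4c[s, i])
                b[s, i] += h / 6.0 * (k1b[s, i] + 2.0 * k2b[s, i] + 2.0 * k3b[s, i] + k4b[s, i])
                if not math.isfinite(V[s, i]):
                    ok = False
        if not ok:
            return step, n_acc
        if step >= rec_start and (step - rec_start) % rec_stride == 0:
            Vr[:, :, r] = V
            if rec_full:
                nr[:, :, r] = n; cr[:, :, r] = c; br[:, :, r] = b
            r += 1
        if step >= acc_start:
            for s in range(B):
                for i in range(N):
                    s_sum[s, i] += 1.0 / (1.0 + math.exp(-5.0 * ((c[s, i] - 0.27) / 0.082 - 0.6)))
            n_acc += 1
    return -1, n_acc


@njit(cache=True)
def _in_windows(t, windows):
    for w in range(windows.shape[0]):
        if windows[w, 0] <= t < windows[w, 1]:
            return True
    return False


@njit(cache=True)
def _rhs_cell_nb(v, n, c, b, gbk, P, i_ext):
    minf = 1.0 / (1.0 + math.exp((P[P_NUM] - v) / P[P_LM]))
    ninf = 1.0 / (1.0 + math.exp((P[P_NUN] - v) / P[P_LN]))
    binf = 1.0 / (1.0 + math.exp((P[P_NUB] - v) / P[P_LB]))
    ica = P[P_GCA] * minf * (v - P[P_VCA])
    ikdr = P[P_GKDR] * n * (v - P[P_VK])
    ibk = gbk * b * (v - P[P_VK])
    c2 = c * c
    isk = P[P_GSK] * (c2 / (c2 + P[P_KSK] * P[P_KSK])) * (v - P[P_VK])
    il = P[P_GL] * (v - P[P_VL])
    dv = -(ikdr + ica + ibk + isk + il + i_ext) / P[P_CM]
    dn = (ninf - n) / P[P_TAUN]
    dc = -P[P_FC] * (P[P_ALPHA] * ica + P[P_KC] * c)
    db = (binf - b) / P[P_TAUB]
    return dv, dn, dc, db


@njit(cache=True)
def _rk4_clamped_nb(v0, n0, c0, b0, gbk, P, windows, gc_in, v_fix,
                    dt, n_steps, Vr, nr, cr, br):
    v, n, c, b = v0, n0, c0, b0
    Vr[0] = v; nr[0] = n; cr[0] = c; br[0] = b
    for step in range(1, n_steps + 1):
        t = (step - 1) * dt

        g1 = gc_in if _in_windows(t, windows) else 0.0
        k1 = _rhs_cell_nb(v, n, c, b, gbk, P, g1 * (v - v_fix))
        gm = gc_in if _in_windows(t + 0.5 * dt, windows) else 0.0
        v2 = v + 0.5 * dt * k1[0]
        k2 = _rhs_cell_nb(v2, n + 0.5 * dt * k1[1], c + 0.5 * dt * k1[2],
                          b + 0.5 * dt * k1[3], gbk, P, gm * (v2 - v_fix))
        v3 = v + 0.5 * dt * k2[0]
        k3 = _rhs_cell_nb(v3, n + 0.5 * dt * k2[1], c + 0.5 * dt * k2[2],
                          b + 0.5 * dt * k2[3], gbk, P, gm * (v3 - v_fix))
        g4 = gc_in if _in_windows(t + dt, windows) else 0.0
        v4 = v + dt * k3[0]
        k4 = _rhs_cell_nb(v4, n + dt * k3[1], c + dt * k3[2],
                          b + dt * k3[3], gbk, P, g4 * (v4 - v_fix))
        v += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        n += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        c += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        b += dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if not math.isfinite(v):
            return step
        Vr[step] = v; nr[step] = n; cr[step] = c; br[step] = b
    return -1


# ---------------------------------------------------------------------------
# numpy backend
# ---------------------------------------------------------------------------

def _rhs_np(V, n, c, b, gbk, P, L, gc):
    minf = 1.0 / (1.0 + np.exp((P[P_NUM] - V) / P[P_LM]))
    ninf = 1.0 / (1.0 + np.exp((P[P_NUN] - V) / P[P_LN]))
    binf = 1.0 / (1.0 + np.exp((P[P_NUB] - V) / P[P_LB]))
    ica = P[P_GCA] * minf * (V - P[P_VCA])
    ikdr = P[P_GKDR] * n * (V - P[P_VK])
    ibk = gbk * b * (V - P[P_VK])
    c2 = c * c
    isk = P[P_GSK] * (c2 / (c2 + P[P_KSK] ** 2)) * (V - P[P_VK])
    il = P[P_GL] * (V - P[P_VL])
    ic = gc * (V @ L)
    dV = -(ikdr + ica + ibk + isk + il + ic) / P[P_CM]
    dn = (ninf - n) / P[P_TAUN]
    dc = -P[P_FC] * (P[P_ALPHA] * ica + P[P_KC] * c)
    db = (binf - b) / P[P_TAUB]
    return dV, dn, dc, db


def _secretion_np(c):
    return 1.0 / (1.0 + np.exp(-5.0 * ((c - 0.27) / 0.082 - 0.6)))


def _rk4_network_np(V, n, c, b, gbk, P, indptr, indices, gc, dt, n_steps,
                    rec_start, rec_stride, Vr, nr, cr, br, rec_full,
                    acc_start, s_sum):
    # rebuild the (symmetric) Laplacian from CSR so that V @ L sums g_c (V_i - V_j)
    N = V.shape[1]
    L = np.zeros((N, N))
    for i in range(N):
        for k in range(indptr[i], indptr[i + 1]):
            L[indices[k], i] -= 1.0
        L[i, i] = indptr[i + 1] - indptr[i]
    r = 0
    n_acc = 0
    if rec_start == 0:
        Vr[:, :, 0] = V
        if rec_full:
            nr[:, :, 0] = n; cr[:, :, 0] = c; br[:, :, 0] = b
        r = 1
    if acc_start == 0:
        s_sum += _secretion_np(c)
        n_acc += 1
    h = dt
    for step in range(1, n_steps + 1):
        k1 = _rhs_np(V, n, c, b, gbk, P, L, gc)
        k2 = _rhs_np(V + 0.5 * h * k1[0], n + 0.5 * h * k1[1],
                     c + 0.5 * h * k1[2], b + 0.5 * h * k1[3], gbk, P, L, gc)
        k3 = _rhs_np(V + 0.5 * h * k2[0], n + 0.5 * h * k2[1],
                     c + 0.5 * h * k2[2], b + 0.5 * h * k2[3], gbk, P, L, gc)
        k4 = _rhs_np(V + h * k3[0], n + h * k3[1], c + h * k3[2],
                     b + h * k3[3], gbk, P, L, gc)
        V += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        n += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        c += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        b += h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if not np.all(np.isfinite(V)):
            return step, n_acc
        if step >= rec_start and (step - rec_start) % rec_stride == 0:
            Vr[:, :, r] = V
            if rec_full:
                nr[:, :, r] = n; cr[:, :, r] = c; br[:, :, r] = b
            r += 1
        if step >= acc_start:
            s_sum += _secretion_np(c)
            n_acc += 1
    return -1, n_acc


def _rk4_clamped_np(v0, n0, c0, b0, gbk, P, windows, gc_in, v_fix,
                    dt, n_steps, Vr, nr, cr, br):
    def rhs(v, n, c, b, i_ext):
        minf = 1.0 / (1.0 + math.exp((P[P_NUM] - v) / P[P_LM]))
        ninf = 1.0 / (1.0 + math.exp((P[P_NUN] - v) / P[P_LN]))
        binf = 1.0 / (1.0 + math.exp((P[P_NUB] - v) / P[P_LB]))
        ica = P[P_GCA] * minf * (v - P[P_VCA])
        ikdr = P[P_GKDR] * n * (v - P[P_VK])
        ibk = gbk * b * (v - P[P_VK])
        c2 = c * c
        isk = P[P_GSK] * (c2 / (c2 + P[P_KSK] ** 2)) * (v - P[P_VK])
        il = P[P_GL] * (v - P[P_VL])
        return (-(ikdr + ica + ibk + isk + il + i_ext) / P[P_CM],
                (ninf - n) / P[P_TAUN],
                -P[P_FC] * (P[P_ALPHA] * ica + P[P_KC] * c),
                (binf - b) / P[P_TAUB])

    def gate(t):
        for w0, w1 in windows:
            if w0 <= t < w1:
                return gc_in
        return 0.0

    v, n, c, b = v0, n0, c0, b0
    Vr[0] = v; nr[0] = n; cr[0] = c; br[0] = b
    for step in range(1, n_steps + 1):
        t = (step - 1) * dt
        g1, gm, g4 = gate(t), gate(t + 0.5 * dt), gate(t + dt)
        k1 = rhs(v, n, c, b, g1 * (v - v_fix))
        v2 = v + 0.5 * dt * k1[0]
        k2 = rhs(v2, n + 0.5 * dt * k1[1], c + 0.5 * dt * k1[2],
                 b + 0.5 * dt * k1[3], gm * (v2 - v_fix))
        v3 = v + 0.5 * dt * k2[0]
        k3 = rhs(v3, n + 0.5 * dt * k2[1], c + 0.5 * dt * k2[2],
                 b + 0.5 * dt * k2[3], gm * (v3 - v_fix))
        v4 = v + dt * k3[0]
        k4 = rhs(v4, n + dt * k3[1], c + dt * k3[2], b + dt * k3[3],
                 g4 * (v4 - v_fix))
        v += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        n += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        c += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        b += dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if not math.isfinite(v):
            return step
        Vr[step] = v; nr[step] = n; cr[step] = c; br[step] = b
    return -1


# dispatchers -----------------------------------------------------------------

def rk4_network(*args, backend=None):
    """Advance a (B, N) batch; see module docstring for the contract."""
    use_nb = HAVE_NUMBA if backend is None else (backend == "numba")
    return (_rk4_network_nb if use_nb else _rk4_network_np)(*args)


def rk4_clamped(*args, backend=None):
    use_nb = HAVE_NUMBA if backend is None else (backend == "numba")
    return (_rk4_clamped_nb if use_nb else _rk4_clamped_np)(*args)
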
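"""Compiled inner loop of the network integrator.

The whole operator-split step — Rush-Larsen gate relaxation (via lookup
tables of the gate steady states and per-step relaxation factors on a fine
voltage grid), junction gate relaxation, assembly of the implicit voltage
system and its exact solve — is one numba-compiled kernel.  Two solve paths
exist:

* ``center`` attachment (cube lattices): static condensation of every cell
  interior onto its central compartment, then a banded Cholesky solve of the
  condensed cell-graph system (bandwidth minimised by a reverse
  Cuthill-McKee ordering precomputed at assembly) and back substitution.
* ``ends`` attachment (chains): the compartments of consecutive cells form
  one global tridiagonal system (the junction is the off-diagonal between
  the facing end compartments), solved by a single Thomas sweep.

A pure-numpy fallback in :mod:`.network` covers environments without numba;
results agree to solver round-off.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


#: voltage grid of the gate lookup tables (mV)
TABLE_V_LO = -130.0
TABLE_V_HI = 80.0
TABLE_DV = 0.05


def hh_rate_sums(v: np.ndarray, q10: float):
    """(alpha, alpha+beta) for m, h, n at q10 — table construction helper."""
    x = v + 40.0
    a_m = q10 * 0.1 * np.where(np.abs(x) < 1e-7, 10.0, x / -np.expm1(-x / 10.0))
    b_m = q10 * 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = q10 * 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = q10 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    x = v + 55.0
    a_n = q10 * 0.01 * np.where(np.abs(x) < 1e-7, 10.0, x / -np.expm1(-x / 10.0))
    b_n = q10 * 0.125 * np.exp(-(v + 65.0) / 80.0)
    return (a_m, a_m + b_m), (a_h, a_h + b_h), (a_n, a_n + b_n)


def build_gate_tables(q10_values: np.ndarray, dt: float) -> np.ndarray:
    """Tables ``[q, 0:6, i]`` = (m_inf, exp(-s_m dt), h_inf, exp(-s_h dt),
    n_inf, exp(-s_n dt)) on the voltage grid, per distinct q10."""
    v = np.arange(TABLE_V_LO, TABLE_V_HI + TABLE_DV / 2, TABLE_DV)
    tabs = np.empty((len(q10_values), 6, len(v)))
    for qi, q in enumerate(q10_values):
        for gi, (a, s) in enumerate(hh_rate_sums(v, float(q))):
            tabs[qi, 2 * gi] = a / s
            tabs[qi, 2 * gi + 1] = np.exp(-s * dt)
    return tabs


@njit(cache=True)
def step_kernel(v, m, h, n,                      # (n_cells, n_seg) state
                gna, gk, gl, ena, ek, el, c_nf,  # (n_cells, n_seg)
                qidx,                            # (n_cells,) table index
                tabs,                            # (nq, 6, npts) gate tables
                i_stim,                          # (n_cells, n_seg) nA
                w_pos, w_neg,                    # (J,) junction gates
                is_dyn, g_static,                # (J,)
                g_main, g_res, n_ch, v0j, a_al, a_be, lam,  # (J,)
                cell_a, cell_b, perm,            # (J,), (J,), (n_cells,)
                seg_a, seg_b,                    # (J,) attachment segments
                ends_mode,                       # 0 = condensed, 1 = Thomas
                g_ax, theta, dt, mid, bw,
                D, R, V, Lb, bp, gj_out):        # work buffers
    n_cells, n_seg = v.shape
    J = cell_a.shape[0]
    e_off = -theta * g_ax
    dv_inv = 1.0 / TABLE_DV
    npts = tabs.shape[2]

    # (1) membrane gates at frozen v; assemble implicit diagonal and rhs
    for c in range(n_cells):
        qi = qidx[c]
        for s in range(n_seg):
            vv = v[c, s]
            u = (vv - TABLE_V_LO) * dv_inv
            if u < 0.0:
                u = 0.0
            elif u > npts - 1.001:
                u = npts - 1.001
            i0 = int(u)
            fr = u - i0
            m_inf = tabs[qi, 0, i0] + (tabs[qi, 0, i0 + 1] - tabs[qi, 0, i0]) * fr
            em = tabs[qi, 1, i0] + (tabs[qi, 1, i0 + 1] - tabs[qi, 1, i0]) * fr
            h_inf = tabs[qi, 2, i0] + (tabs[qi, 2, i0 + 1] - tabs[qi, 2, i0]) * fr
            eh = tabs[qi, 3, i0] + (tabs[qi, 3, i0 + 1] - tabs[qi, 3, i0]) * fr
            n_inf = tabs[qi, 4, i0] + (tabs[qi, 4, i0 + 1] - tabs[qi, 4, i0]) * fr
            en = tabs[qi, 5, i0] + (tabs[qi, 5, i0 + 1] - tabs[qi, 5, i0]) * fr
            mm = m_inf + (m[c, s] - m_inf) * em
            hh = h_inf + (h[c, s] - h_inf) * eh
            nn = n_inf + (n[c, s] - n_inf) * en
            m[c, s] = mm
            h[c, s] = hh
            n[c, s] = nn

            g_na = gna[c, s] * mm * mm * mm * hh
            g_k = gk[c, s] * nn * nn * nn * nn
            g_l = gl[c, s]
            g_ion = g_na + g_k + g_l
            drive = g_na * ena[c, s] + g_k * ek[c, s] + g_l * el[c, s]
            cdt = c_nf[c, s] / dt
            if n_seg == 1:
                axd = 0.0
            elif s == 0 or s == n_seg - 1:
                axd = g_ax
            else:
                axd = 2.0 * g_ax
            lv = axd * vv
            if s > 0:
                lv -= g_ax * v[c, s - 1]
            if s < n_seg - 1:
                lv -= g_ax * v[c, s + 1]
            D[c, s] = cdt + theta * (g_ion + axd)
            R[c, s] = cdt * vv + drive + i_stim[c, s] \
                - (1.0 - theta) * (g_ion * vv + lv)

    # (2) junction gates at frozen vj; conductances frozen over the step
    for j in range(J):
        if is_dyn[j]:
            vj = v[cell_a[j], seg_a[j]] - v[cell_b[j], seg_b[j]]
            for gate in range(2):
                svj = vj if gate == 0 else -vj
                ea = a_al[j] * (svj - v0j[j])
                if ea > 60.0:
                    ea = 60.0
                elif ea < -60.0:
                    ea = -60.0
                eb = a_be[j] * (svj - v0j[j])
                if eb > 60.0:
                    eb = 60.0
                elif eb < -60.0:
                    eb = -60.0
                al = lam[j] * math.exp(-ea)
                be = lam[j] * math.exp(eb)
                sw = al + be
                winf = al / sw
                if gate == 0:
                    w_pos[j] = winf + (w_pos[j] - winf) * math.exp(-sw * dt)
                else:
                    w_neg[j] = winf + (w_neg[j] - winf) * math.exp(-sw * dt)
            gj_out[j] = n_ch[j] * (g_res[j] + (g_main[j] - g_res[j])
                                   * w_pos[j] * w_neg[j]) * 1e-3
        else:
            gj_out[j] = g_static[j]

    if ends_mode == 1:
        # chains with end-to-end junctions: one global tridiagonal system
        for j in range(J):  # junction j couples cells (j, j+1)
            g = gj_out[j] * 1e-3
            D[cell_a[j], seg_a[j]] += g
            D[cell_b[j], seg_b[j]] += g
        Df = D.reshape(n_cells * n_seg)
        Rf = R.reshape(n_cells * n_seg)
        Vf = V.reshape(n_cells * n_seg)
        N = n_cells * n_seg
        for p in range(1, N):
            s = p % n_seg
            if s == 0:
                off = -gj_out[p // n_seg - 1] * 1e-3  # junction link
            else:
                off = e_off
            w = off / Df[p - 1]
            Df[p] -= w * off
            Rf[p] -= w * Rf[p - 1]
        Vf[N - 1] = Rf[N - 1] / Df[N - 1]
        for p in range(N - 2, -1, -1):
            s = (p + 1) % n_seg
            if s == 0:
                off = -gj_out[(p + 1) // n_seg - 1] * 1e-3
            else:
                off = e_off
            Vf[p] = (Rf[p] - off * Vf[p + 1]) / Df[p]
        for c in range(n_cells):
            for s in range(n_seg):
                v[c, s] = V[c, s]
        return

    # (3) eliminate cell interiors onto the central compartment
    for c in range(n_cells):
        for s in range(1, mid + 1):
            w = e_off / D[c, s - 1]
            D[c, s] -= w * e_off
            R[c, s] -= w * R[c, s - 1]
        for s in range(n_seg - 2, mid - 1, -1):
            w = e_off / D[c, s + 1]
            D[c, s] -= w * e_off
            R[c, s] -= w * R[c, s + 1]

    # (4) condensed cell-graph system in RCM order, banded Cholesky
    if J > 0:
        for d in range(bw + 1):
            for i in range(n_cells):
                Lb[d, i] = 0.0
        for c in range(n_cells):
            Lb[0, perm[c]] = D[c, mid]
            bp[perm[c]] = R[c, mid]
        for j in range(J):
            ra = perm[cell_a[j]]
            rb = perm[cell_b[j]]
            g = gj_out[j] * 1e-3  # nS -> uS
            Lb[0, ra] += g
            Lb[0, rb] += g
            if ra > rb:
                lo, d = rb, ra - rb
            else:
                lo, d = ra, rb - ra
            Lb[d, lo] -= g

        for jc in range(n_cells):
            kmin = jc - bw
            if kmin < 0:
                kmin = 0
            ssum = Lb[0, jc]
            for k in range(kmin, jc):
                ssum -= Lb[jc - k, k] * Lb[jc - k, k]
            dj = math.sqrt(ssum)
            Lb[0, jc] = dj
            imax = jc + bw + 1
            if imax > n_cells:
                imax = n_cells
            for i in range(jc + 1, imax):
                ssum = Lb[i - jc, jc]
                kmin = i - bw
                if kmin < 0:
                    kmin = 0
                for k in range(kmin, jc):
                    ssum -= Lb[i - k, k] * Lb[jc - k, k]
                Lb[i - jc, jc] = ssum / dj
        for i in range(n_cells):           # forward solve L y = b
            kmin = i - bw
            if kmin < 0:
                kmin = 0
            ssum = bp[i]
            for k in range(kmin, i):
                ssum -= Lb[i - k, k] * bp[k]
            bp[i] = ssum / Lb[0, i]
        for i in range(n_cells - 1, -1, -1):  # backward solve L^T x = y
            kmax = i + bw + 1
            if kmax > n_cells:
                kmax = n_cells
            ssum = bp[i]
            for k in range(i + 1, kmax):
                ssum -= Lb[k - i, i] * bp[k]
            bp[i] = ssum / Lb[0, i]
        for c in range(n_cells):
            V[c, mid] = bp[perm[c]]
    else:
        for c in range(n_cells):
            V[c, mid] = R[c, mid] / D[c, mid]

    # (5) back substitution through the cell interiors
    for c in range(n_cells):
        for s in range(mid - 1, -1, -1):
            V[c, s] = (R[c, s] - e_off * V[c, s + 1]) / D[c, s]
        for s in range(mid + 1, n_seg):
            V[c, s] = (R[c, s] - e_off * V[c, s - 1]) / D[c, s]
    for c in range(n_cells):
        for s in range(n_seg):
            v[c, s] = V[c, s]
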
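"""Assembly and time integration of the multicellular compartmental system.

Each cell is an unbranched cylinder of ``n_segments`` isopotential
compartments joined by axial conductances ``(pi d^2 / 4) / (Ra dx)``; cells
never share cytoplasm, so the only intercellular pathway is the gap junction
attached between the *central* compartments of the two coupled cells (the
same compartment the voltage recorders read).

Time stepping is operator-split, one global step per ``dt``:

1. membrane gates advance by Rush-Larsen (exact exponential) relaxation at
   the frozen voltage;
2. junction gates advance the same way at the frozen transjunctional voltage;
3. the voltage system — capacitance, ionic conductances at the updated
   gates, axial coupling and stimulus currents (trapezoidal, theta = 1/2)
   plus the junctional coupling at the frozen conductances (backward Euler)
   — is solved exactly in one linear solve per step.

The solve exploits the network's structure by static condensation (domain
decomposition): each cell's unbranched interior is a tridiagonal block
touching the rest of the network only through its central attachment
compartment, so a two-sided Thomas sweep per cell eliminates the interiors
onto the attachment nodes, the small Schur system on the cell graph (one
unknown per cell, junction conductances off-diagonal) is solved directly,
and the interiors are recovered by back substitution.  This is exact for
the implicit system — arbitrarily strong coupling stays stable and the
intracellular series resistance to the junction carries no splitting error —
at O(n_compartments) cost per step.  A numba kernel (see ``_kernels``) runs
the step when numba is importable; the numpy path is the reference.

Units: mV, ms, nA, uS, nF (so C dv/dt, g*v and injected currents are all nA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import HAVE_NUMBA, step_kernel
from .junctions import ConnexinParams, StaticJunction
from .membrane import IntegrationError, MembraneParams, resting_state
from .topology import Topology

__all__ = [
    "CellGeometry",
    "StimulusSpec",
    "NetworkState",
    "SimulationResult",
    "Network",
    "assemble_system",
    "run_simulation",
]


@dataclass(frozen=True)
class CellGeometry:
    """Cylinder geometry of one smooth-muscle cell.

    Defaults: 200 um long, 6 um diameter, 51 segments, 181 ohm cm axial
    resistivity.  ``n_segments`` must be odd so a central compartment exists
    for recording and junction attachment.
    """

    length: float = 200.0            # um
    diameter: float = 6.0            # um
    n_segments: int = 51
    axial_resistivity: float = 181.0  # ohm cm

    def __post_init__(self) -> None:
        if min(self.length, self.diameter, self.axial_resistivity) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.n_segments < 1 or self.n_segments % 2 == 0:
            raise ValueError("n_segments must be a positive odd integer")

    @property
    def segment_area_cm2(self) -> float:
        """Lateral membrane area of one compartment (cm^2)."""
        dx_cm = (self.length / self.n_segments) * 1e-4
        return float(np.pi * self.diameter * 1e-4 * dx_cm)

    @property
    def axial_conductance_uS(self) -> float:
        """Axial conductance between adjacent compartments (uS)."""
        dx_cm = (self.length / self.n_segments) * 1e-4
        cross_cm2 = np.pi * (self.diameter * 1e-4) ** 2 / 4.0
        return float(cross_cm2 / (self.axial_resistivity * dx_cm) * 1e6)

    @property
    def central_segment(self) -> int:
        return (self.n_segments - 1) // 2


@dataclass(frozen=True)
class StimulusSpec:
    """Current pulse into one compartment of one cell.

    ``compartment=None`` targets the cell's central compartment.  Amplitude
    in nA, onset/duration in ms.
    """

    cell: int
    onset: float
    duration: float
    amplitude: float
    compartment: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")


@dataclass
class NetworkState:
    """Full dynamical state: per-compartment voltage and HH gates, one gate
    pair per junction (meaningful for dynamic junctions), current time."""

    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    w_pos: np.ndarray
    w_neg: np.ndarray
    t: float = 0.0


@dataclass
class SimulationResult:
    """Recorded traces on a shared time base.

    ``v`` maps cell id -> central-compartment membrane potential (mV);
    ``g`` maps junction index -> junctional conductance (nS).
    """

    t: np.ndarray
    v: dict = field(default_factory=dict)
    g: dict = field(default_factory=dict)
    dt: float = 0.0

    def save(self, directory) -> None:
        """Write each trace as two-column delimited text with a header."""
        import os

        os.makedirs(directory, exist_ok=True)
        for cell, trace in self.v.items():
            np.savetxt(os.path.join(directory, f"v_cell{cell}.tsv"),
                       np.column_stack([self.t, trace]),
                       header="time_ms\tv_mV", delimiter="\t", comments="")
        for j, trace in self.g.items():
            np.savetxt(os.path.join(directory, f"g_junction{j}.tsv"),
                       np.column_stack([self.t, trace]),
                       header="time_ms\tg_nS", delimiter="\t", comments="")


class Network:
    """An assembled, simulatable syncytium.

    Construct via :func:`assemble_system`.  Per-compartment quantities are
    (n_cells, n_segments) arrays; junction quantities are flat arrays in
    topology adjacency order.
    """

    #: theta-weighting of the implicit voltage solve (1/2 = trapezoidal)
    theta: float = 0.5

    def __init__(self, topology: Topology, geometry: CellGeometry,
                 membrane_map: list[MembraneParams], coupling,
                 junction_attachment: str = "auto") -> None:
        if len(membrane_map) != topology.n_cells:
            raise ValueError(
                f"membrane_map has {len(membrane_map)} entries for "
                f"{topology.n_cells} cells")
        self.topology = topology
        self.geometry = geometry
        self.membrane_map = list(membrane_map)
        n_cells, n_seg = topology.n_cells, geometry.n_segments
        self.n_comp = n_cells * n_seg

        area = geometry.segment_area_cm2
        shape = (n_cells, n_seg)

        def grid(attr, scale=1.0):
            col = np.array([getattr(p, attr) for p in membrane_map])
            return np.broadcast_to(col[:, None] * scale, shape).copy()

        self.gbar_na = grid("gbar_na", area * 1e6)   # uS per compartment
        self.gbar_k = grid("gbar_k", area * 1e6)
        self.g_leak = grid("g_leak", area * 1e6)
        self.e_na = grid("e_na")
        self.e_k = grid("e_k")
        self.e_leak = grid("e_leak")
        self.c_nF = grid("cm", area * 1e3)           # nF per compartment
        self.q10 = grid("q10_factor")

        self._cell_a = np.array([a for a, _ in topology.adjacency], dtype=np.int64)
        self._cell_b = np.array([b for _, b in topology.adjacency], dtype=np.int64)
        self._setup_attachment(junction_attachment)
        self._setup_coupling(coupling)
        self._setup_ordering()
        self._alloc_buffers()
        self.q10_cells = np.array([p.q10_factor for p in membrane_map])
        self._tab_dt = None
        self._tabs = None
        self._qidx = None

    def _setup_attachment(self, mode: str) -> None:
        """Where junctions attach: facing end compartments for chains (a 1-D
        cable of end-to-end cells), central compartments for lattices (no
        preferred axis; keeps the cube isotropic)."""
        if mode == "auto":
            mode = "ends" if self.topology.kind == "chain" else "center"
        if mode not in ("ends", "center"):
            raise ValueError("junction_attachment must be 'auto', 'ends' or 'center'")
        if mode == "ends":
            consecutive = all(b == a + 1 for a, b in self.topology.adjacency)
            if not consecutive:
                raise ValueError("end attachment requires a chain topology")
        self.junction_attachment = mode
        n_seg = self.geometry.n_segments
        mid = self.geometry.central_segment
        n_j = self.topology.n_junctions
        if mode == "ends":
            self._seg_a = np.full(n_j, n_seg - 1, dtype=np.int64)
            self._seg_b = np.zeros(n_j, dtype=np.int64)
        else:
            self._seg_a = np.full(n_j, mid, dtype=np.int64)
            self._seg_b = np.full(n_j, mid, dtype=np.int64)

    def _ensure_tables(self, dt: float) -> None:
        from ._kernels import build_gate_tables

        if self._tab_dt == dt:
            return
        uniq, inverse = np.unique(self.q10_cells, return_inverse=True)
        self._tabs = build_gate_tables(uniq, dt)
        self._qidx = inverse.astype(np.int64)
        self._tab_dt = dt

    # ------------------------------------------------------------ assembly

    def _setup_coupling(self, coupling) -> None:
        n_j = self.topology.n_junctions
        if isinstance(coupling, (int, float)):
            coupling = StaticJunction(float(coupling))
        if isinstance(coupling, (StaticJunction, ConnexinParams)):
            coupling = [coupling] * n_j
        coupling = list(coupling)
        if len(coupling) != n_j:
            raise ValueError(f"need {n_j} junction models, got {len(coupling)}")
        for c in coupling:
            if not isinstance(c, (StaticJunction, ConnexinParams)):
                raise TypeError(
                    "junction models must be StaticJunction or ConnexinParams")
        self.junction_models = coupling
        self.is_dyn = np.array(
            [isinstance(c, ConnexinParams) for c in coupling], dtype=np.uint8)

        def jarr(attr, default=0.0):
            return np.array([getattr(c, attr, default) for c in coupling],
                            dtype=float)

        self.g_static = jarr("g_total")            # nS (0 for dynamic)
        self.j_g_main = jarr("g_main", 1.0)        # pS
        self.j_g_res = jarr("g_residual", 0.5)
        self.j_n_ch = jarr("n_channels", 1.0)
        self.j_v0 = jarr("v0", 1.0)
        self.j_a_al = jarr("a_alpha", 0.0)
        self.j_a_be = jarr("a_beta", 0.0)
        self.j_lam = jarr("lambda_rate", 1.0)

    def _setup_ordering(self) -> None:
        """Reverse Cuthill-McKee ordering of the cell graph for the banded
        condensed solve."""
        n_cells = self.topology.n_cells
        if self.topology.n_junctions == 0:
            self._perm = np.arange(n_cells, dtype=np.int64)
            self._bw = 0
            return
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import reverse_cuthill_mckee

        ones = np.ones(len(self._cell_a))
        adj = coo_matrix((ones, (self._cell_a, self._cell_b)),
                         shape=(n_cells, n_cells))
        adj = (adj + adj.T).tocsr()
        order = reverse_cuthill_mckee(adj, symmetric_mode=True)
        pos = np.empty(n_cells, dtype=np.int64)
        pos[order] = np.arange(n_cells, dtype=np.int64)
        self._perm = pos
        self._bw = int(np.max(np.abs(pos[self._cell_a] - pos[self._cell_b])))

    def _alloc_buffers(self) -> None:
        n_cells, n_seg = self.topology.n_cells, self.geometry.n_segments
        self._D = np.empty((n_cells, n_seg))
        self._R = np.empty((n_cells, n_seg))
        self._V = np.empty((n_cells, n_seg))
        self._Lb = np.empty((self._bw + 1, n_cells))
        self._bp = np.empty(n_cells)
        self._gj = np.empty(self.topology.n_junctions)
        self._i_stim = np.zeros((n_cells, n_seg))

    # --------------------------------------------------------------- state

    def initial_state(self, v_init: float | None = None) -> NetworkState:
        """Uniform initialisation: every compartment at a common resting
        potential with gates at their steady states there (the standard
        simulator convention); junction gates fully open.

        ``v_init`` defaults to the resting potential of the baseline
        (lowest-gNa) membrane.  Pacemaker cells share the same starting
        voltage — their raised Na conductance leaves them poised to
        oscillate once triggered rather than parked at a depolarised
        pseudo-rest.
        """
        if v_init is None:
            baseline = min(self.membrane_map, key=lambda p: p.gbar_na)
            v_init = resting_state(baseline)[0]
        from .membrane import gate_inf_tau

        m_inf, _, h_inf, _, n_inf, _ = gate_inf_tau(v_init)
        shape = (self.topology.n_cells, self.geometry.n_segments)
        n_j = self.topology.n_junctions
        # junction gates equilibrated at vj = 0 (w_inf(0) < 1 for a gated
        # subtype); starting from w = 1 would superimpose a spurious
        # rest-relaxation decay on the junctional conductance traces
        w0 = np.ones(n_j)
        dyn = self.is_dyn.astype(bool)
        if dyn.any():
            x = np.clip((self.j_a_al + self.j_a_be) * (0.0 - self.j_v0),
                        -120.0, 120.0)
            w_inf0 = 1.0 / (1.0 + np.exp(x))
            w0[dyn] = w_inf0[dyn]
        return NetworkState(
            v=np.full(shape, float(v_init)),
            m=np.full(shape, m_inf), h=np.full(shape, h_inf),
            n=np.full(shape, n_inf),
            w_pos=w0, w_neg=w0.copy(), t=0.0)

    def transjunctional_voltage(self, state: NetworkState, junction: int) -> float:
        """vj = v(side A) - v(side B) at the attachment compartments."""
        a, b = self.topology.adjacency[junction]
        return float(state.v[a, self._seg_a[junction]]
                     - state.v[b, self._seg_b[junction]])

    def junction_conductances(self, state: NetworkState) -> np.ndarray:
        """Conductance (nS) of every junction, in topology adjacency order."""
        g_dyn = self.j_n_ch * (self.j_g_res + (self.j_g_main - self.j_g_res)
                               * state.w_pos * state.w_neg) * 1e-3
        return np.where(self.is_dyn.astype(bool), g_dyn, self.g_static)

    # ---------------------------------------------------------------- step

    def step(self, state: NetworkState, dt: float,
             i_stim: np.ndarray | None = None) -> NetworkState:
        """Advance the network by one step of ``dt`` ms (state updated in
        place).  ``i_stim`` is a per-compartment injected current array
        (nA), shaped (n_cells, n_segments), held constant over the step."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if i_stim is None:
            self._i_stim[:] = 0.0
            i_stim = self._i_stim
        if HAVE_NUMBA:
            self._ensure_tables(dt)
            step_kernel(state.v, state.m, state.h, state.n,
                        self.gbar_na, self.gbar_k, self.g_leak,
                        self.e_na, self.e_k, self.e_leak, self.c_nF,
                        self._qidx, self._tabs, i_stim,
                        state.w_pos, state.w_neg,
                        self.is_dyn, self.g_static,
                        self.j_g_main, self.j_g_res, self.j_n_ch,
                        self.j_v0, self.j_a_al, self.j_a_be, self.j_lam,
                        self._cell_a, self._cell_b, self._perm,
                        self._seg_a, self._seg_b,
                        1 if self.junction_attachment == "ends" else 0,
                        self.geometry.axial_conductance_uS, self.theta, dt,
                        self.geometry.central_segment, self._bw,
                        self._D, self._R, self._V, self._Lb, self._bp,
                        self._gj)
        else:
            self._step_numpy(state, dt, i_stim)
        v = state.v
        if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > 500.0:
            raise IntegrationError(
                f"voltage diverged at t={state.t:.3f} ms (dt={dt} ms too large?)")
        state.t += dt
        return state

    # -- reference numpy implementation (used when numba is unavailable) --

    def _hh_rate_arrays(self, v: np.ndarray):
        q = self.q10
        x = v + 40.0
        a_m = q * 0.1 * np.where(np.abs(x) < 1e-7, 10.0, x / -np.expm1(-x / 10.0))
        b_m = q * 4.0 * np.exp(-(v + 65.0) / 18.0)
        a_h = q * 0.07 * np.exp(-(v + 65.0) / 20.0)
        b_h = q / (1.0 + np.exp(-(v + 35.0) / 10.0))
        x = v + 55.0
        a_n = q * 0.01 * np.where(np.abs(x) < 1e-7, 10.0, x / -np.expm1(-x / 10.0))
        b_n = q * 0.125 * np.exp(-(v + 65.0) / 80.0)
        return a_m, b_m, a_h, b_h, a_n, b_n

    def _step_numpy(self, state: NetworkState, dt: float,
                    i_stim: np.ndarray) -> None:
        v = state.v
        a_m, b_m, a_h, b_h, a_n, b_n = self._hh_rate_arrays(v)
        for x, a, b in ((state.m, a_m, b_m), (state.h, a_h, b_h),
                        (state.n, a_n, b_n)):
            s = a + b
            x_inf = a / s
            x *= np.exp(-s * dt)
            x += x_inf * -np.expm1(-s * dt)

        mid = self.geometry.central_segment
        if self.topology.n_junctions:
            dyn = self.is_dyn.astype(bool)
            vj = v[self._cell_a, self._seg_a] - v[self._cell_b, self._seg_b]
            for w, sign in ((state.w_pos, 1.0), (state.w_neg, -1.0)):
                xa = np.clip(self.j_a_al * (sign * vj - self.j_v0), -60, 60)
                xb = np.clip(self.j_a_be * (sign * vj - self.j_v0), -60, 60)
                alpha = self.j_lam * np.exp(-xa)
                beta = self.j_lam * np.exp(xb)
                s = alpha + beta
                w_inf = alpha / s
                w_new = w_inf + (w - w_inf) * np.exp(-s * dt)
                w[dyn] = w_new[dyn]
            g_j = self.junction_conductances(state)
        else:
            g_j = np.empty(0)

        th = self.theta
        g_na = self.gbar_na * state.m**3 * state.h
        g_k = self.gbar_k * state.n**4
        g_ion = g_na + g_k + self.g_leak
        drive = g_na * self.e_na + g_k * self.e_k + self.g_leak * self.e_leak
        c_dt = self.c_nF / dt
        g_ax = self.geometry.axial_conductance_uS
        n_seg = self.geometry.n_segments
        ax_diag = np.full(n_seg, 2.0 * g_ax)
        if n_seg > 1:
            ax_diag[0] = ax_diag[-1] = g_ax
        else:
            ax_diag[:] = 0.0
        lv = ax_diag * v
        if n_seg > 1:
            lv[:, :-1] -= g_ax * v[:, 1:]
            lv[:, 1:] -= g_ax * v[:, :-1]
        D = c_dt + th * (g_ion + ax_diag)
        R = c_dt * v + drive + i_stim - (1.0 - th) * (g_ion * v + lv)
        n_cells = self.topology.n_cells

        if self.junction_attachment == "ends" and self.topology.n_junctions:
            from scipy.linalg import solve_banded

            n_comp = self.n_comp
            g_uS = g_j * 1e-3
            Df = D.reshape(-1).copy()
            Rf = R.reshape(-1).copy()
            ends_a = self._cell_a * n_seg + self._seg_a
            ends_b = self._cell_b * n_seg + self._seg_b
            np.add.at(Df, ends_a, g_uS)
            np.add.at(Df, ends_b, g_uS)
            off = np.full(n_comp - 1, -th * g_ax)
            off[ends_a] = -g_uS  # link (c, n_seg-1) -> (c+1, 0)
            ab = np.zeros((3, n_comp))
            ab[0, 1:] = off
            ab[1] = Df
            ab[2, :-1] = off
            state.v[:] = solve_banded((1, 1), ab, Rf).reshape(n_cells, n_seg)
            return

        e = -th * g_ax
        D = D.copy()
        R = R.copy()
        for s in range(1, mid + 1):
            w = e / D[:, s - 1]
            D[:, s] -= w * e
            R[:, s] -= w * R[:, s - 1]
        for s in range(n_seg - 2, mid - 1, -1):
            w = e / D[:, s + 1]
            D[:, s] -= w * e
            R[:, s] -= w * R[:, s + 1]

        if self.topology.n_junctions:
            from scipy.sparse import coo_matrix
            from scipy.sparse.linalg import splu

            g_uS = g_j * 1e-3
            d = D[:, mid].copy()
            np.add.at(d, self._cell_a, g_uS)
            np.add.at(d, self._cell_b, g_uS)
            rows = np.concatenate([np.arange(n_cells), self._cell_a,
                                   self._cell_b])
            cols = np.concatenate([np.arange(n_cells), self._cell_b,
                                   self._cell_a])
            vals = np.concatenate([d, -g_uS, -g_uS])
            mat = coo_matrix((vals, (rows, cols)),
                             shape=(n_cells, n_cells)).tocsc()
            v_mid = splu(mat).solve(R[:, mid])
        else:
            v_mid = R[:, mid] / D[:, mid]

        V = np.empty_like(D)
        V[:, mid] = v_mid
        for s in range(mid - 1, -1, -1):
            V[:, s] = (R[:, s] - e * V[:, s + 1]) / D[:, s]
        for s in range(mid + 1, n_seg):
            V[:, s] = (R[:, s] - e * V[:, s - 1]) / D[:, s]
        state.v[:] = V


def assemble_system(
    topology: Topology,
    geometry: CellGeometry | None = None,
    membrane_map: list[MembraneParams] | None = None,
    coupling=StaticJunction(0.0),
    junction_attachment: str = "auto",
) -> Network:
    """Build a simulatable :class:`Network` from a topology.

    ``membrane_map`` defaults to identical baseline cells; ``coupling`` may
    be a conductance in nS, a :class:`StaticJunction`, a
    :class:`ConnexinParams` subtype (applied to every junction), or an
    explicit per-junction list.
    """
    geometry = geometry if geometry is not None else CellGeometry()
    if membrane_map is None:
        membrane_map = [MembraneParams()] * topology.n_cells
    return Network(topology, geometry, membrane_map, coupling,
                   junction_attachment=junction_attachment)


def run_simulation(
    network: Network,
    stimuli: list[StimulusSpec],
    duration: float,
    dt: float = 0.025,
    record_cells: list[int] | None = None,
    record_junctions: list[int] | None = None,
    sample_every: int = 1,
    state: NetworkState | None = None,
) -> SimulationResult:
    """Integrate the network and record the requested traces.

    Records the central-compartment voltage of ``record_cells`` and the
    conductance of ``record_junctions`` every ``sample_every`` steps
    (including the initial sample).  Bit-for-bit reproducible for identical
    inputs.  A zero duration returns an empty result.
    """
    if duration < 0 or dt <= 0:
        raise ValueError("duration must be >= 0 and dt > 0")
    record_cells = list(record_cells) if record_cells else []
    record_junctions = list(record_junctions) if record_junctions else []
    for c in record_cells:
        if not (0 <= c < network.topology.n_cells):
            raise ValueError(f"recorder references unknown cell {c}")
    for j in record_junctions:
        if not (0 <= j < network.topology.n_junctions):
            raise ValueError(f"recorder references unknown junction {j}")
    for s in stimuli:
        if not (0 <= s.cell < network.topology.n_cells):
            raise ValueError(f"stimulus references unknown cell {s.cell}")
        comp = s.compartment
        if comp is not None and not (0 <= comp < network.geometry.n_segments):
            raise ValueError(f"stimulus references unknown compartment {comp}")

    n_steps = int(round(duration / dt))
    if n_steps == 0:
        return SimulationResult(t=np.empty(0), dt=dt)
    state = state if state is not None else network.initial_state()

    mid = network.geometry.central_segment
    rec_cells = np.array(record_cells, dtype=int)
    stim_targets = [(s, s.cell, mid if s.compartment is None else s.compartment)
                    for s in stimuli]

    n_samples = n_steps // sample_every + 1
    t_out = np.empty(n_samples)
    v_out = np.empty((len(record_cells), n_samples))
    g_out = np.empty((len(record_junctions), n_samples))

    def record(k: int) -> None:
        t_out[k] = state.t
        if len(rec_cells):
            v_out[:, k] = state.v[rec_cells, mid]
        if record_junctions:
            g_out[:, k] = network.junction_conductances(state)[record_junctions]

    record(0)
    k = 1
    i_stim = np.zeros((network.topology.n_cells, network.geometry.n_segments))
    for step in range(n_steps):
        t = step * dt
        i_stim[:] = 0.0
        active = False
        for s, cell, comp in stim_targets:
            if s.onset <= t < s.onset + s.duration:
                i_stim[cell, comp] += s.amplitude
                active = True
        network.step(state, dt, i_stim if active else None)
        if (step + 1) % sample_every == 0:
            record(k)
            k += 1

    result = SimulationResult(t=t_out[:k], dt=dt)
    for i, c in enumerate(record_cells):
        result.v[c] = v_out[i, :k]
    for i, j in enumerate(record_junctions):
        result.g[j] = g_out[i, :k]
    return result
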
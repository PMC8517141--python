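"""Hodgkin-Huxley membrane kinetics and single-cell (isopotential) dynamics.

The excitable machinery of every cell in the syncytium is the classical
squid-axon Hodgkin-Huxley (HH) mechanism: a fast sodium conductance
``gNa = gbar_na * m^3 * h``, a delayed-rectifier potassium conductance
``gK = gbar_k * n^4`` and an ohmic leak.  Each ionic current is
``I_X = g_X * (V - E_X)`` (mA/cm^2 with densities in S/cm^2 and V in mV).

Two departures from the textbook model matter here:

* **Slowed AP variants.**  All six gate rate constants can be multiplied by a
  single dimensionless factor ``q10_factor`` (a temperature-coefficient
  rescaling).  Values below 1 stretch the gate time constants and hence the
  action-potential time course without moving any steady state; the named
  variants HH, HH-50 and HH-500 produce APs of roughly 5, 50 and 500 ms.
* **Pacemaking by raised gbar_na.**  Increasing the peak sodium conductance
  above the standard 0.12 S/cm^2 converts the cell from a single-AP responder
  into a sustained oscillator; :func:`find_oscillation_threshold` locates the
  smallest such value on a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MembraneParams",
    "GateState",
    "APVariant",
    "AP_VARIANTS",
    "hh_rates",
    "gate_inf_tau",
    "ionic_current",
    "resting_state",
    "StimulusPulse",
    "simulate_isopotential_cell",
    "rheobase",
    "find_oscillation_threshold",
    "OscillationThreshold",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when a voltage trace leaves the physically plausible range."""


@dataclass(frozen=True)
class MembraneParams:
    """HH membrane densities and passive properties for one cell.

    Conductances are specific (S/cm^2), ``cm`` is specific capacitance
    (uF/cm^2), reversal potentials are in mV.  ``q10_factor`` multiplies all
    six gate rate constants (1 = classical kinetics).
    """

    gbar_na: float = 0.12
    gbar_k: float = 0.036
    g_leak: float = 3.0e-4
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.3
    cm: float = 1.0
    q10_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gbar_na", "gbar_k", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cm <= 0:
            raise ValueError(f"cm must be > 0, got {self.cm}")
        if self.q10_factor <= 0:
            raise ValueError(f"q10_factor must be > 0, got {self.q10_factor}")

    def with_gbar_na(self, gbar_na: float) -> "MembraneParams":
        return replace(self, gbar_na=gbar_na)

    def with_variant(self, variant: "APVariant | str") -> "MembraneParams":
        if isinstance(variant, str):
            variant = AP_VARIANTS[variant]
        return replace(self, q10_factor=variant.q10)


class GateState(NamedTuple):
    """Dimensionless HH gating variables, each confined to [0, 1]."""

    m: float
    h: float
    n: float


@dataclass(frozen=True)
class APVariant:
    """A named AP time-course variant: the classical mechanism with all gate
    rates multiplied by ``q10``."""

    name: str
    q10: float


AP_VARIANTS = {
    "HH": APVariant("HH", 1.0),
    "HH-50": APVariant("HH-50", 0.0556),
    "HH-500": APVariant("HH-500", 0.00524),
}


def _vexp_ratio(x: np.ndarray | float, scale: float) -> np.ndarray | float:
    """x / (1 - exp(-x/scale)) with its analytic limit (= scale) at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, scale, safe / -np.expm1(-safe / scale))
    return out if out.ndim else float(out)


def hh_rates(v, q10_factor: float = 1.0):
    """Six HH rate constants (1/ms) at membrane potential ``v`` (mV).

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)``, each the
    classical squid-axon expression multiplied by ``q10_factor``.  The
    removable singularities of alpha_m (at -40 mV) and alpha_n (at -55 mV) are
    evaluated by their analytic limits.  Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    q = float(q10_factor)
    a_m = 0.1 * _vexp_ratio(v + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    a_n = 0.01 * _vexp_ratio(v + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    rates = tuple(q * r for r in (a_m, b_m, a_h, b_h, a_n, b_n))
    if v.ndim == 0:
        return tuple(float(r) for r in rates)
    return rates


def gate_inf_tau(v, q10_factor: float = 1.0):
    """Steady states and time constants ``(m_inf, tau_m, h_inf, tau_h, n_inf,
    tau_n)`` at ``v``.

    ``x_inf = alpha/(alpha+beta)`` is independent of ``q10_factor`` (the
    factor cancels); ``tau = 1/(alpha+beta)`` scales as ``1/q10_factor``.
    """
    a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(v, q10_factor)
    out = []
    for a, b in ((a_m, b_m), (a_h, b_h), (a_n, b_n)):
        s = a + b
        out.extend((a / s, 1.0 / s))
    return tuple(out)


def ionic_current(v, gates: GateState, p: MembraneParams):
    """Total ionic current density (mA/cm^2) and the per-channel breakdown.

    Returns ``(total, {"na": I_Na, "k": I_K, "leak": I_L})`` with
    ``I_Na = gbar_na m^3 h (v - e_na)`` etc.  Positive current is outward
    (hyperpolarising when fed into ``C dv/dt = -I_ion``).
    """
    m, h, n = gates
    for x in (m, h, n):
        if np.any(np.asarray(x) < 0) or np.any(np.asarray(x) > 1):
            raise ValueError("gating variables must lie in [0, 1]")
    i_na = p.gbar_na * m**3 * h * (v - p.e_na)
    i_k = p.gbar_k * n**4 * (v - p.e_k)
    i_leak = p.g_leak * (v - p.e_leak)
    return i_na + i_k + i_leak, {"na": i_na, "k": i_k, "leak": i_leak}


def resting_state(p: MembraneParams) -> tuple[float, GateState]:
    """Resting potential and steady-state gates.

    Solves ``I_ion(v, gates_inf(v)) = 0`` for the root nearest the classical
    -65 mV rest (for strongly pacemaking parameter sets additional roots may
    exist; the hyperpolarised one is the conventional starting point).
    """

    def f(v: float) -> float:
        m_inf, _, h_inf, _, n_inf, _ = gate_inf_tau(v)
        total, _ = ionic_current(v, GateState(m_inf, h_inf, n_inf), p)
        return total

    grid = np.linspace(-90.0, -20.0, 281)
    vals = np.array([f(v) for v in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-10))
    if roots:
        v0 = min(roots, key=lambda r: abs(r - (-65.0)))
    else:
        # strongly pacemaking parameter sets can lose the resting fixed
        # point altogether; start from the quasi-rest where the net ionic
        # current is smallest (the cell then fires spontaneously)
        v0 = float(grid[np.argmin(np.abs(vals))])
    m_inf, _, h_inf, _, n_inf, _ = gate_inf_tau(v0)
    return v0, GateState(m_inf, h_inf, n_inf)


@dataclass(frozen=True)
class StimulusPulse:
    """Rectangular current pulse: ``amplitude`` nA injected from ``onset`` for
    ``duration`` ms (positive = depolarising)."""

    onset: float = 1.0
    duration: float = 1.0
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")

    def current(self, t: float) -> float:
        if self.onset <= t < self.onset + self.duration:
            return self.amplitude
        return 0.0


# Membrane area of the default cell cylinder (200 um x 6 um diameter); kept
# here so isolated-cell runs and network cells share one surface area.
DEFAULT_CELL_AREA_CM2 = float(np.pi * 6e-4 * 200e-4)


def simulate_isopotential_cell(
    p: MembraneParams,
    stimulus: StimulusPulse | None,
    duration: float,
    dt: float = 0.025,
    area_cm2: float = DEFAULT_CELL_AREA_CM2,
    v_init: float | None = None,
):
    """Integrate a single isopotential HH cell; returns ``(t, v)`` arrays (ms, mV).

    The cell starts from its resting fixed point (gates at the steady states
    of the resting potential) unless ``v_init`` overrides the voltage.  The
    integrator matches the network scheme: exact-exponential (Rush-Larsen)
    gate relaxation at frozen voltage, then a semi-implicit voltage update
    with the conductances evaluated at the new gates.  Deterministic for
    fixed inputs.
    """
    if duration < 0 or dt <= 0:
        raise ValueError("duration must be >= 0 and dt > 0")
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt
    v_rest, gates = resting_state(p)
    v = v_rest if v_init is None else float(v_init)
    m, h, n = gates
    c = p.cm * area_cm2 * 1e3          # nF
    g_scale = area_cm2 * 1e6           # S/cm^2 -> uS
    out = np.empty(n_steps + 1)
    out[0] = v
    for i in range(1, n_steps + 1):
        a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(v, p.q10_factor)
        m = _rl(m, a_m, b_m, dt)
        h = _rl(h, a_h, b_h, dt)
        n = _rl(n, a_n, b_n, dt)
        g_na = p.gbar_na * m**3 * h * g_scale
        g_k = p.gbar_k * n**4 * g_scale
        g_l = p.g_leak * g_scale
        g_tot = g_na + g_k + g_l
        i_stim = stimulus.current(t[i - 1]) if stimulus is not None else 0.0
        drive = g_na * p.e_na + g_k * p.e_k + g_l * p.e_leak
        theta = 0.5  # trapezoidal voltage weighting, matching the network
        num = (c / dt) * v + drive + i_stim - (1.0 - theta) * g_tot * v
        den = (c / dt) + theta * g_tot
        v = num / den
        out[i] = v
    if not np.all(np.isfinite(out)) or np.max(np.abs(out)) > 200.0:
        raise IntegrationError(
            f"voltage left [-200, 200] mV (dt={dt} ms likely too large)"
        )
    return t, out


def _rl(x: float, a: float, b: float, dt: float) -> float:
    """One Rush-Larsen step: exact relaxation of x toward a/(a+b)."""
    s = a + b
    x_inf = a / s
    return x_inf + (x - x_inf) * np.exp(-s * dt)


def rheobase(
    p: MembraneParams,
    pulse_duration: float = 1.0,
    area_cm2: float = DEFAULT_CELL_AREA_CM2,
    start_nA: float = 0.0125,
    max_doublings: int = 24,
) -> float:
    """Smallest pulse amplitude on a doubling ladder that elicits a spike.

    A 1 ms pulse is applied to the resting cell and the amplitude doubled from
    ``start_nA`` until the trace crosses 0 mV.  The observation window scales
    with the variant's time constants (slow variants spike late).
    """
    window = 20.0 / p.q10_factor
    dt = min(0.025 / p.q10_factor, 0.1)
    amp = start_nA
    for _ in range(max_doublings):
        stim = StimulusPulse(onset=1.0, duration=pulse_duration, amplitude=amp)
        _, v = simulate_isopotential_cell(p, stim, duration=1.0 + window, dt=dt,
                                          area_cm2=area_cm2)
        if np.max(v) > 0.0:
            return amp
        amp *= 2.0
    raise ValueError("no spike found within the doubling ladder")


@dataclass(frozen=True)
class OscillationThreshold:
    """Result of the oscillation-threshold grid search."""

    found: bool
    gbar_na: float | None
    spike_counts: dict[float, int]


def _count_post_stimulus_spikes(
    p: MembraneParams, stim: StimulusPulse, duration: float, dt: float
) -> int:
    from .analysis import detect_spikes  # local import to avoid a cycle

    t, v = simulate_isopotential_cell(p, stim, duration=duration, dt=dt)
    train = detect_spikes(t, v, threshold=0.0, min_interval=1.0 / p.q10_factor)
    offset = stim.onset + stim.duration
    return int(np.sum(train.times > offset))


def find_oscillation_threshold(
    p_base: MembraneParams,
    gna_grid: Sequence[float],
    window_ms: float = 500.0,
    min_spikes: int = 10,
    dt: float = 0.025,
) -> OscillationThreshold:
    """Minimal peak sodium conductance on ``gna_grid`` giving sustained oscillation.

    A cell oscillates if it fires at least ``min_spikes`` spikes after
    stimulus offset within ``window_ms``.  The grid must be strictly
    increasing; oscillation is checked at every grid point so the expected
    monotonicity (all values above threshold oscillate) can be asserted by
    callers.  Returns a not-found result (rather than raising) when no grid
    value oscillates.
    """
    grid = np.asarray(list(gna_grid), dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("gna_grid must be a non-empty strictly increasing sequence")
    counts: dict[float, int] = {}
    threshold = None
    for gna in grid:
        p = p_base.with_gbar_na(float(gna))
        amp = 2.0 * rheobase(p)
        stim = StimulusPulse(onset=1.0, duration=1.0, amplitude=amp)
        counts[float(gna)] = _count_post_stimulus_spikes(
            p, stim, duration=stim.onset + stim.duration + window_ms, dt=dt
        )
        if threshold is None and counts[float(gna)] >= min_spikes:
            threshold = float(gna)
    return OscillationThreshold(threshold is not None, threshold, counts)
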
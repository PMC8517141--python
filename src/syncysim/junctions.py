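"""Gap-junction coupling models: static conductances and voltage-gated connexins.

A gap junction between two cells is an aggregate of ``n_channels`` identical
channels.  Two coupling models are provided:

* :class:`StaticJunction` — a constant, voltage-insensitive conductance, used
  for the coupling-strength, size and location studies.
* :class:`ConnexinParams` + :class:`JunctionState` — a homotypic voltage-gated
  junction in the two-gate (Vogel-Weingart style) formalism.  Each hemichannel
  contributes one first-order gate sensing one polarity of the transjunctional
  voltage ``vj``; the gates are in series, so the junction conductance is

      g = n_channels * [g_residual + (g_main - g_residual) * w_pos * w_neg]

  where ``w_pos`` relaxes toward a Boltzmann of ``+vj`` and ``w_neg`` toward
  the same Boltzmann of ``-vj``.  With both gates open the junction sits at
  ``N_j * g_main``; full gating of either polarity leaves the residual floor
  ``N_j * g_residual``.  Subtypes (Cx40, Cx43, Cx45) differ in unitary
  conductances, half-inactivation voltage and — crucially for the emergent
  behaviour — the base rate scale ``lambda_rate``: Cx40 and Cx43 gate with
  similar, comparatively fast kinetics while Cx45 is an order of magnitude
  slower, which lets inactivation accumulate across repeated APs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "ConnexinParams",
    "JunctionState",
    "StaticJunction",
    "CONNEXINS",
    "junction_conductance",
    "gate_rates",
    "step_junction",
    "junction_current",
    "swap_kinetics",
]

_EXP_CLAMP = 60.0  # overflow guard on gate-rate exponents


@dataclass(frozen=True)
class ConnexinParams:
    """Per-subtype parameters of a homotypic voltage-gated junction.

    ``g_main``/``g_residual`` are unitary main- and residual-state
    conductances (pS), ``n_channels`` the channel count N_j per junction,
    ``v0`` the half-inactivation transjunctional voltage (mV), ``a_alpha`` /
    ``a_beta`` the exponential voltage sensitivities (1/mV) of the opening and
    closing rates, and ``lambda_rate`` the base rate scale (1/ms).
    """

    subtype: str
    g_main: float
    g_residual: float
    n_channels: int = 1000
    v0: float = 40.0
    a_alpha: float = 0.04
    a_beta: float = 0.04
    lambda_rate: float = 2e-3

    def __post_init__(self) -> None:
        if not (0 < self.g_residual < self.g_main):
            raise ValueError("need 0 < g_residual < g_main")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be > 0")

    @property
    def g_max_nS(self) -> float:
        """Fully open junction conductance, N_j * g_main (nS)."""
        return self.n_channels * self.g_main * 1e-3

    @property
    def g_min_nS(self) -> float:
        """Residual-floor junction conductance, N_j * g_residual (nS)."""
        return self.n_channels * self.g_residual * 1e-3


class JunctionState(NamedTuple):
    """Open fractions of the two polarity gates, each in [0, 1]; junctions
    start fully open (1, 1)."""

    w_pos: float = 1.0
    w_neg: float = 1.0


@dataclass(frozen=True)
class StaticJunction:
    """Constant, voltage-insensitive gap-junctional conductance (nS)."""

    g_total: float

    def __post_init__(self) -> None:
        if self.g_total < 0:
            raise ValueError("g_total must be >= 0")


# Unitary main-state conductances and N_j are the study's stated values; the
# residual conductances, half-inactivation voltages, voltage sensitivities and
# rate scales are pinned defaults drawn from the experimental connexin
# literature: Cx40 and Cx43 gate with similar, comparatively shallow and fast
# kinetics (Boltzmann slope ~13 mV, i.e. a_alpha + a_beta ~ 0.08/mV), while
# Cx45 is both the slowest (~10x smaller rate scale) and by far the steepest
# and most sensitive subtype (slope ~5 mV, low half-inactivation voltage).
# That steep, slow gating is what lets inactivation accumulate over repeated
# APs and drive Cx45 junctions toward their residual state.
CONNEXINS = {
    "cx40": ConnexinParams("cx40", g_main=162.0, g_residual=40.0, n_channels=1000,
                           v0=47.0, a_alpha=0.04, a_beta=0.04, lambda_rate=2e-3),
    "cx43": ConnexinParams("cx43", g_main=61.0, g_residual=18.0, n_channels=1000,
                           v0=61.0, a_alpha=0.04, a_beta=0.04, lambda_rate=2e-3),
    "cx45": ConnexinParams("cx45", g_main=32.0, g_residual=5.0, n_channels=1000,
                           v0=22.0, a_alpha=0.10, a_beta=0.10, lambda_rate=2e-4),
}


def junction_conductance(params: ConnexinParams, state: JunctionState) -> float:
    """Junction conductance (nS) for the given gate state."""
    w_pos, w_neg = state
    g_unit = params.g_residual + (params.g_main - params.g_residual) * w_pos * w_neg
    return params.n_channels * g_unit * 1e-3


def gate_rates(vj, params: ConnexinParams):
    """Opening/closing rates ``(alpha, beta)`` (1/ms) of one polarity gate.

    ``alpha = lambda * exp(-a_alpha (vj - v0))`` and
    ``beta = lambda * exp(+a_beta (vj - v0))``, exponents clamped to avoid
    overflow.  The steady state ``alpha/(alpha+beta)`` is a falling Boltzmann
    in ``vj`` with midpoint ``v0``; the mirror gate is evaluated at ``-vj``.
    """
    vj = np.asarray(vj, dtype=float)
    if not np.all(np.isfinite(vj)):
        raise ValueError("transjunctional voltage must be finite")
    x = vj - params.v0
    alpha = params.lambda_rate * np.exp(np.clip(-params.a_alpha * x, -_EXP_CLAMP, _EXP_CLAMP))
    beta = params.lambda_rate * np.exp(np.clip(params.a_beta * x, -_EXP_CLAMP, _EXP_CLAMP))
    if vj.ndim == 0:
        return float(alpha), float(beta)
    return alpha, beta


def step_junction(state: JunctionState, vj: float, dt: float,
                  params: ConnexinParams) -> JunctionState:
    """Advance both gates by ``dt`` ms with ``vj`` frozen at its start value.

    Exact exponential relaxation of each gate toward its steady state
    ``w_inf = alpha/(alpha+beta)`` with time constant ``1/(alpha+beta)``; the
    update is a contraction into [0, 1] and obeys the exact semigroup property
    (two half steps equal one full step at constant ``vj``).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")

    def relax(w: float, v: float) -> float:
        a, b = gate_rates(v, params)
        s = a + b
        w_inf = a / s
        return w_inf + (w - w_inf) * np.exp(-s * dt)

    return JunctionState(relax(state.w_pos, vj), relax(state.w_neg, -vj))


def junction_current(g_nS: float, v_a: float, v_b: float) -> tuple[float, float]:
    """Paired junctional currents (nA) into compartments a and b.

    Ohmic: a current ``g (v_a - v_b)`` flows out of the more depolarised side
    into the other, so the pair ``(into_a, into_b)`` sums to exactly zero.
    """
    if np.any(np.asarray(g_nS) < 0):
        raise ValueError("junction conductance must be >= 0")
    i = g_nS * 1e-3 * (v_a - v_b)  # uS * mV = nA
    return -i, i


def swap_kinetics(params_target: ConnexinParams,
                  params_source: ConnexinParams) -> ConnexinParams:
    """Target subtype with its gating kinetics replaced by the source's.

    Only the kinetic fields (``lambda_rate``, ``a_alpha``, ``a_beta``) are
    taken from the source; conductances, channel count and the
    half-inactivation voltage stay with the target.
    """
    return replace(
        params_target,
        lambda_rate=params_source.lambda_rate,
        a_alpha=params_source.a_alpha,
        a_beta=params_source.a_beta,
    )
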
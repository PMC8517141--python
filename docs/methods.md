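# Methods

## Model overview

`syncysim` simulates electrically coupled smooth-muscle tissue as a network
of multi-compartment excitable cells joined by gap junctions. Three layers
make up the model:

1. **Membrane.** Each compartment carries the classical squid-axon
   Hodgkin–Huxley mechanism: `I_Na = ḡ_Na m³h (V−E_Na)`,
   `I_K = ḡ_K n⁴ (V−E_K)` and an ohmic leak, with the standard rate
   functions (the removable singularities of α_m at −40 mV and α_n at
   −55 mV are evaluated by their analytic limits). A single multiplicative
   factor on all six rates — a Q10 temperature-coefficient rescaling with
   the temperature exponent fixed at 1 — produces the slowed AP variants
   HH-50 (factor 0.0556) and HH-500 (0.00524). Because the factor cancels
   in α/(α+β), all steady states, resting potentials and thresholds are
   identical across variants; only the time scale stretches. Consequently
   the variant AP durations are validated by *ordering*
   (HH < HH-50 < HH-500), not by absolute value; the duration statistic
   itself (time between −20 mV crossings) is a package convention.

2. **Cell geometry.** A cell is an unbranched cylinder: length 200 µm,
   diameter 6 µm, 51 segments, axial resistivity 181 Ω·cm, specific
   capacitance 1 µF/cm², leak 0.0003 S/cm² to −54.3 mV, E_Na = 50 mV,
   E_K = −77 mV. The odd segment count gives a well-defined central
   compartment, which is where voltages are recorded and stimuli injected.

3. **Junctions.** A junction aggregates N_j = 1000 channels
   deterministically (N_j enters as a multiplier, not as stochastic
   channels). Static junctions are fixed conductances. Dynamic junctions
   follow a two-gate series formalism for homotypic channels: gate
   open-fractions w₊ and w₋ sense +vj and −vj respectively with
   first-order kinetics, rates `α = λ e^(−a_α(vj−V₀))`,
   `β = λ e^(+a_β(vj−V₀))` (exponents clamped at ±60 to guard overflow),
   and the conductance is
   `N_j [g_residual + (g_main − g_residual) w₊ w₋]`, bounded between the
   residual floor and the fully open value.

### Junction parameter defaults

Unitary main-state conductances and N_j: Cx40 162 pS, Cx43 61 pS, Cx45
32 pS, N_j = 1000 each. The gating parameters are pinned defaults chosen
from the experimental connexin literature:

| subtype | g_residual (pS) | V₀ (mV) | a_α = a_β (1/mV) | λ (1/ms) |
|---------|-----------------|---------|------------------|----------|
| Cx40    | 40              | 47      | 0.04             | 2×10⁻³   |
| Cx43    | 18              | 61      | 0.04             | 2×10⁻³   |
| Cx45    | 5               | 22      | 0.10             | 2×10⁻⁴   |

Cx40 and Cx43 gate with similar, shallow (Boltzmann slope ≈ 13 mV) and
comparatively fast kinetics; Cx45 is both an order of magnitude slower and
much steeper (slope ≈ 5 mV, low half-inactivation voltage), as reported
for this subtype. The steepness matters qualitatively: with symmetric
exponential rates the recovery rate at vj = 0 scales as `λ e^(a V₀)`, so a
shallow gate always recovers between APs and never accumulates
inactivation. Only a steep, slow gate loses more conductance during each
brief vj excursion than it regains between spikes — that imbalance is what
drives Cx45 junctions to their residual state (a ~70% conductance fall at
the chain centre, plateauing at ≈ 1.6 s) while Cx40/Cx43 stay within 0.2%.
The kinetics-swap control (Cx45 conductances with Cx40/43 gating) removes
the collapse, confirming the mechanism. The swap replaces the rate fields
(λ, a_α, a_β) and keeps conductances and V₀.

In assembled networks junction gates start at their vj = 0 steady state
w∞(0) (0.977/0.992/0.988 for Cx40/43/45) rather than exactly 1: starting
fully open would superimpose a spurious rest-relaxation decay of a few
percent on every conductance trace, obscuring the spike-driven dynamics
the subtype studies measure.

## Network construction

Chains of n cells have n−1 junctions between consecutive cells; k-cubes
have k³ cells with 6-neighbour face adjacency (3k²(k−1) junctions, one per
adjacent pair). Cube cells are classed by how many coordinates lie on the
boundary — vertex (3), edge (2), surface (1), interior (0), with the
unique middle cell of an odd cube the *center* — and the canonical
representative of a class is the cell nearest its edge/face midpoint with
lexicographically smallest coordinates, so location studies are
reproducible. "Opposite extremes" for dual vertex oscillators means the
two main-diagonal corners.

**Junction attachment.** In chains, junctions connect the *facing end
compartments* of consecutive cells — a chain of elongated cells joined end
to end is a 1-D cable, and this matters quantitatively: attaching strong
junctions directly to the recording compartment at the cell centre clamps
the pacemaker so hard that oscillation dies outright at 500 nS, whereas
end attachment leaves the intracellular axial resistance (≈ 6.3 MΩ per
half-cell) in series and preserves the graded, monotone frequency fall.
In cubic lattices a cell has six neighbours but only two ends, so all
junctions attach to the central compartment, keeping the lattice isotropic.

**Pacemakers.** A pacemaker is a cell whose ḡ_Na is raised above the
baseline 0.12 S/cm². The isolated-cell oscillation threshold is
0.19 S/cm²; network pacemakers need more because the junctions shunt
charge. The 3-D studies use the fast oscillator 0.75 S/cm² (uncoupled
63.4 spikes/s) and slow oscillator 0.4 S/cm² (58.8 spikes/s). For the 1-D
chain the package also uses 0.4 S/cm²: the chain readouts are far more
load-sensitive than the cube's, and the fast 0.75 oscillator is too stiff
to reproduce the graded frequency fall across 5–500 nS, while 0.4 matches
the weak- and mid-coupling chain rates to within ~3%.

**Initialisation.** All compartments start at the baseline cell's resting
potential (≈ −65 mV) with gates at their steady states there — the
standard simulator convention. This is not innocuous: a strong pacemaker
cell has no hyperpolarised fixed point, and initialising it at its
depolarised pseudo-rest would leave its sodium channels inactivated and
the cell unable to pace under load.

**Trigger.** Each pacemaker receives one rectangular pulse (1 ms for HH,
scaled by 1/Q10 for slow variants) at t = 1 ms into its central
compartment, amplitude twice the isolated-cell rheobase found by a
doubling search from 0.0125 nA. The syncytial frequency is insensitive to
this amplitude over at least two orders of magnitude (the pacemaker's
limit cycle, not the trigger, sets the rhythm).

## Numerical scheme

One operator-split step per dt (default 0.025 ms):

1. membrane gates advance by Rush–Larsen exact-exponential relaxation at
   frozen voltage (unconditionally stable; gates provably stay in [0,1]);
2. junction gates advance the same way at frozen vj;
3. the voltage system is solved implicitly in a single linear solve:
   capacitance, ionic conductances at the updated gates, axial coupling
   and stimulus with trapezoidal (θ = 1/2) weighting, and the junctional
   Laplacian at backward-Euler weight. Trapezoidal weighting keeps the
   dt-halving spike-time drift below 0.1 ms over 200 ms runs; the
   junction term is taken L-stable because at strong coupling its substep
   time constant falls far below dt and a θ = 1/2 treatment would ring.

The solve is exact for the implicit system and O(N): cell interiors are
tridiagonal blocks touching the network only at their attachment
compartment, so each interior is eliminated by Thomas sweeps (static
condensation), the condensed system on the cell graph — one unknown per
cell, junction conductances off-diagonal — is solved by banded Cholesky
in a reverse Cuthill–McKee ordering, and interiors are recovered by back
substitution. Chains with end attachment reduce to one global tridiagonal
solve. Arbitrarily strong coupling is therefore stable, and the series
resistance between a junction and the cell interior carries no splitting
error. The integrator was validated against an adaptive high-accuracy ODE
solution of the same equations on a three-cell network (frequency
agreement to 0.05%, trace deviation < 0.5 mV).

A numba-compiled kernel executes the step when numba is importable, with
gate steady states and per-step relaxation factors interpolated from
tables on a 0.05 mV grid; a pure-numpy reference path implements the same
scheme with closed-form rates. The two agree to below the dt
discretisation error, and every run is bit-for-bit reproducible for a
fixed configuration — the model has no stochastic elements (the config
seed is provenance only).

## Readouts

Spikes are upward crossings of 0 mV (first sample at/above threshold) with
a refractory lockout of 1 ms, scaled to 10/100 ms for the HH-50/HH-500
variants. Frequency is `3000/(t₆ − t₃)` spikes/s — the mean of the three
inter-spike intervals spanning spikes 3 to 6, discarding the settling
transient — and a run with fewer than six spikes yields an *invalid*
result rather than an exception; sweeps flag such rows and continue.
Junction-conductance falls are `100·(g_start − g_plateau)/g_start` with the
plateau the mean over the final 10% of the trace, and time-to-plateau the
first time a 10%-window moving average comes within 1% of the plateau.
Synchrony across recorded cells is the spread `(f_max − f_min)/f_min` of
their 3-to-6 frequencies.

## Simulated protocols and problem sizes

The bundled studies use: 181-cell chains (300 ms for static coupling,
500 ms for dynamic subtypes, 2.5 s for the Cx45 collapse, which plateaus
by ≈ 1.6 s); 5-cubes (125 cells, 300 ms) for location and dual-oscillator
studies; 3/5/7-cubes for the size study (the 15-cube runs the same code
path and is available by passing `sizes=(3, 5, 7, 15)`). The smoke-test
fixtures (two-cell, three-chain, 3-cube) run in under a second each.

## Known limitations

* The passive cell parameters and the fitted connexin hemichannel
  functions of the original experimental literature are represented by
  the pinned defaults above, not by refits to raw data. The largest
  visible consequence is at extreme 1-D coupling: the HH oscillator's
  frequency-versus-load curve is nearly flat until close to a fold-like
  cutoff, so the chain rate at 500 nS comes out ≈ 43 spikes/s where a
  softer load response would give ≈ 38; and the simulated Cx45 collapse
  at the chain centre is ≈ 70% against a residual-state limit of 84%.
* Junctions are homotypic and voltage-gated only: no heterotypic or
  heteromeric assemblies, no chemical gating, no Ca²⁺ permeation, no
  stochastic single-channel behaviour.
* Q10 rescaling applies to the HH gates only; nothing else in the model is
  temperature dependent.
* The tissue is a regular lattice of identical cells — no geometric
  irregularity, no extracellular fields, no ephaptic coupling.
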
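"""Config-driven pipelines for the five syncytial studies.

Each study wires together the topology builders, membrane/junction models,
network integrator and spike analysis into one reproducible protocol:

* **coupling** — 1-D chain, static junctions over a conductance grid; the
  oscillation frequency at the central pacemaker falls as coupling rises.
* **subtype** — 1-D chain with dynamic Cx40/Cx43/Cx45 junctions (and the
  Cx45-with-fast-kinetics control); early vs late frequency and the fall of
  junctional conductance at the chain centre.
* **size** — k-cube lattices of several sizes across a coupling grid.
* **location** — 5-cube with the pacemaker at center/vertex/edge/surface.
* **multiosc** — 5-cube with two pacemakers in the four canonical
  fast/slow x center/vertex configurations.

All runs are deterministic: the trigger pulse amplitude is derived from the
pacemaker's isolated-cell rheobase (doubling search), never from randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (conductance_drop, detect_spikes, frequency_3to6,
                       synchrony_check)
from .config import ExperimentConfig, PacemakerConfig
from .junctions import CONNEXINS, ConnexinParams, swap_kinetics
from .membrane import AP_VARIANTS, MembraneParams, rheobase
from .network import (CellGeometry, Network, SimulationResult, StimulusSpec,
                      assemble_system, run_simulation)
from .topology import PacemakerSpec, Topology, build_chain, build_cube, \
    place_pacemakers, site_cell

__all__ = [
    "SweepResult",
    "run_coupling_sweep",
    "run_subtype_study",
    "run_size_study",
    "run_location_study",
    "run_multi_oscillator_study",
    "generate_fixture",
    "PACEMAKER_GNA_1D",
    "PACEMAKER_GNA_FAST",
    "PACEMAKER_GNA_SLOW",
]

#: peak Na conductance of the fast / slow 3-D oscillator cells (S/cm^2)
PACEMAKER_GNA_FAST = 0.75
PACEMAKER_GNA_SLOW = 0.4
#: peak Na conductance of the 1-D chain pacemaker (S/cm^2)
PACEMAKER_GNA_1D = 0.4

#: fixed spike-detection lockout per AP variant (scales with the AP width)
LOCKOUT_MS = {"HH": 1.0, "HH-50": 10.0, "HH-500": 100.0}


@dataclass
class SweepResult:
    """One row per simulated condition, plus resolved-config provenance."""

    rows: pd.DataFrame
    config_digest: str
    traces: dict = field(default_factory=dict)

    def save(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def _resolve_variant(cfg: ExperimentConfig) -> MembraneParams:
    return MembraneParams().with_variant(AP_VARIANTS[cfg.ap_variant])


def _pacemaker_cells(topology: Topology, cfg: ExperimentConfig,
                     default_gna: float) -> list[PacemakerSpec]:
    specs = []
    for p in cfg.pacemakers:
        if p.cell is not None:
            cell = topology.central_cell if p.cell == -1 else p.cell
        else:
            cell = site_cell(topology, p.site)
        gna = p.gbar_na if p.gbar_na is not None else default_gna
        specs.append(PacemakerSpec(cell, gna))
    return specs


def _trigger(network: Network, specs: list[PacemakerSpec],
             cfg: ExperimentConfig) -> list[StimulusSpec]:
    """One short pulse at t=1 ms into each pacemaker's central compartment.

    The amplitude is twice the isolated-cell rheobase of the *baseline*
    membrane: a pacemaker's own rheobase is vanishingly small (the cell is
    nearly spontaneous in isolation) and such a pulse cannot launch the
    first AP once strong junctional coupling loads the cell, whereas the
    syncytial frequency itself is insensitive to the trigger amplitude over
    orders of magnitude.
    """
    geometry = network.geometry
    area = geometry.segment_area_cm2 * geometry.n_segments
    variant = AP_VARIANTS[cfg.ap_variant]
    p = MembraneParams().with_variant(variant)
    amp = 2.0 * rheobase(p, area_cm2=area,
                         pulse_duration=1.0 / variant.q10)
    return [StimulusSpec(cell=s.cell, onset=1.0 / variant.q10,
                         duration=1.0 / variant.q10, amplitude=amp)
            for s in specs]


def _frequency_row(result: SimulationResult, cell: int, lockout: float) -> dict:
    train = detect_spikes(result.t, result.v[cell], min_interval=lockout)
    freq = frequency_3to6(train)
    return {"cell": cell, "frequency": freq.frequency, "valid": freq.valid,
            "n_spikes": len(train)}


def run_coupling_sweep(cfg: ExperimentConfig) -> SweepResult:
    """Static-coupling frequency sweep on the 1-D chain (one AP variant)."""
    if cfg.topology != "chain":
        raise ValueError("the coupling sweep runs on a chain topology")
    topology = build_chain(cfg.size)
    baseline = _resolve_variant(cfg)
    specs = _pacemaker_cells(topology, cfg, PACEMAKER_GNA_1D)
    membrane_map = place_pacemakers(topology, specs, baseline)
    lockout = LOCKOUT_MS[cfg.ap_variant]
    rows = []
    for g in cfg.coupling_nS:
        network = assemble_system(topology, membrane_map=membrane_map,
                                  coupling=float(g))
        stimuli = _trigger(network, specs, cfg)
        result = run_simulation(network, stimuli, cfg.duration, cfg.dt,
                                record_cells=[specs[0].cell],
                                sample_every=cfg.sample_every)
        row = _frequency_row(result, specs[0].cell, lockout)
        row.update(experiment="coupling", coupling_nS=g,
                   ap_variant=cfg.ap_variant)
        rows.append(row)
    return SweepResult(pd.DataFrame(rows), cfg.digest)


def _subtype_params(name: str) -> ConnexinParams:
    if name == "cx45-swapped":
        return swap_kinetics(CONNEXINS["cx45"], CONNEXINS["cx43"])
    return CONNEXINS[name]


def run_subtype_study(cfg: ExperimentConfig,
                      subtypes: tuple[str, ...] = ("cx40", "cx43", "cx45",
                                                   "cx45-swapped")) -> SweepResult:
    """Dynamic-junction study on the 1-D chain.

    For each subtype: the 3rd-to-6th-spike ("early") frequency, the
    late-run frequency over the final spikes, and the junctional-conductance
    fall at the central junction and at the junction 20 cells from centre.
    """
    if cfg.topology != "chain":
        raise ValueError("the subtype study runs on a chain topology")
    topology = build_chain(cfg.size)
    baseline = _resolve_variant(cfg)
    specs = _pacemaker_cells(topology, cfg, PACEMAKER_GNA_1D)
    membrane_map = place_pacemakers(topology, specs, baseline)
    lockout = LOCKOUT_MS[cfg.ap_variant]
    center = specs[0].cell
    # junction i couples cells (i, i+1); central junction = (center, center+1)
    j_center = center
    j_distal = min(center + 20, topology.n_junctions - 1)
    rows, traces = [], {}
    for name in subtypes:
        params = _subtype_params(name)
        network = assemble_system(topology, membrane_map=membrane_map,
                                  coupling=params)
        stimuli = _trigger(network, specs, cfg)
        result = run_simulation(network, stimuli, cfg.duration, cfg.dt,
                                record_cells=[center],
                                record_junctions=[j_center, j_distal],
                                sample_every=cfg.sample_every)
        train = detect_spikes(result.t, result.v[center], min_interval=lockout)
        early = frequency_3to6(train)
        if len(train) >= 4:
            tail = train.times[-4:]
            late_f = 3000.0 / (tail[-1] - tail[0])
        else:
            late_f = 0.0
        drop_c = conductance_drop(result.t, result.g[j_center])
        drop_d = conductance_drop(result.t, result.g[j_distal])
        rows.append({
            "experiment": "subtype", "subtype": name,
            "frequency_early": early.frequency, "frequency_late": late_f,
            "valid": early.valid, "n_spikes": len(train),
            "drop_center_pct": drop_c.percent,
            "drop_distal_pct": drop_d.percent,
            "time_to_plateau_ms": drop_c.time_to_plateau,
        })
        traces[name] = result
    return SweepResult(pd.DataFrame(rows), cfg.digest, traces=traces)


def run_size_study(cfg: ExperimentConfig,
                   sizes: tuple[int, ...] = (3, 5, 7)) -> SweepResult:
    """Frequency vs lattice size across the static-coupling grid.

    The pacemaker sits at the centre of each cube.  The printed protocol
    also includes a 15-cube; pass ``sizes=(3, 5, 7, 15)`` for the full-scale
    version (markedly heavier).
    """
    baseline = _resolve_variant(cfg)
    lockout = LOCKOUT_MS[cfg.ap_variant]
    rows = []
    for k in sizes:
        topology = build_cube(k)
        specs = _pacemaker_cells(topology, cfg, PACEMAKER_GNA_FAST)
        membrane_map = place_pacemakers(topology, specs, baseline)
        for g in cfg.coupling_nS:
            network = assemble_system(topology, membrane_map=membrane_map,
                                      coupling=float(g))
            stimuli = _trigger(network, specs, cfg)
            result = run_simulation(network, stimuli, cfg.duration, cfg.dt,
                                    record_cells=[specs[0].cell],
                                    sample_every=cfg.sample_every)
            row = _frequency_row(result, specs[0].cell, lockout)
            row.update(experiment="size", cube=k, coupling_nS=g)
            rows.append(row)
    return SweepResult(pd.DataFrame(rows), cfg.digest)


def run_location_study(cfg: ExperimentConfig,
                       sites: tuple[str, ...] = ("center", "vertex", "edge",
                                                 "surface")) -> SweepResult:
    """Pacemaker-location study on the cube across the coupling grid.

    Records the pacemaker cell and one representative cell of every other
    site class, so synchrony across the syncytium can be checked per run.
    """
    if cfg.topology != "cube":
        raise ValueError("the location study runs on a cube topology")
    topology = build_cube(cfg.size)
    baseline = _resolve_variant(cfg)
    lockout = LOCKOUT_MS[cfg.ap_variant]
    rows = []
    for site in sites:
        pace_cell = site_cell(topology, site)
        specs = [PacemakerSpec(pace_cell, PACEMAKER_GNA_FAST)]
        membrane_map = place_pacemakers(topology, specs, baseline)
        probes = {s: site_cell(topology, s)
                  for s in ("center", "vertex", "edge", "surface")}
        record = sorted(set([pace_cell] + list(probes.values())))
        for g in cfg.coupling_nS:
            network = assemble_system(topology, membrane_map=membrane_map,
                                      coupling=float(g))
            stimuli = _trigger(network, specs, cfg)
            result = run_simulation(network, stimuli, cfg.duration, cfg.dt,
                                    record_cells=record,
                                    sample_every=cfg.sample_every)
            trains = [detect_spikes(result.t, result.v[c], min_interval=lockout,
                                    cell=c) for c in record]
            row = _frequency_row(result, pace_cell, lockout)
            try:
                sync = synchrony_check(trains)
                row["sync_max_rel_dev"] = sync.max_relative_deviation
            except ValueError:
                row["sync_max_rel_dev"] = np.nan
            row.update(experiment="location", site=site, coupling_nS=g)
            rows.append(row)
    return SweepResult(pd.DataFrame(rows), cfg.digest)


#: the four canonical dual-oscillator configurations: (name, [(site, gna), ...])
MULTI_OSC_CONFIGS = {
    "fV1=fV2": (("vertex", PACEMAKER_GNA_FAST),
                ("vertex-opposite", PACEMAKER_GNA_FAST)),
    "fC=fV": (("center", PACEMAKER_GNA_FAST), ("vertex", PACEMAKER_GNA_FAST)),
    "fV1>fV2": (("vertex", PACEMAKER_GNA_FAST),
                ("vertex-opposite", PACEMAKER_GNA_SLOW)),
    "fC>fV": (("center", PACEMAKER_GNA_FAST), ("vertex", PACEMAKER_GNA_SLOW)),
}


def _multi_osc_cells(topology: Topology, layout) -> list[PacemakerSpec]:
    k = round(topology.n_cells ** (1 / 3))
    specs = []
    for site, gna in layout:
        if site == "vertex-opposite":
            # the main-diagonal corner opposite the origin vertex
            cell = int(np.flatnonzero(
                (topology.coordinates == k - 1).all(axis=1))[0])
        else:
            cell = site_cell(topology, site)
        specs.append(PacemakerSpec(cell, gna))
    return specs


def run_multi_oscillator_study(cfg: ExperimentConfig,
                               configurations: tuple[str, ...] = tuple(
                                   MULTI_OSC_CONFIGS)) -> SweepResult:
    """Dual-pacemaker entrainment study on the cube.

    The syncytial frequency is read at a neutral probe cell (an edge cell,
    never itself a pacemaker) once the network has locked to the dominant
    oscillator.
    """
    if cfg.topology != "cube":
        raise ValueError("the multi-oscillator study runs on a cube topology")
    topology = build_cube(cfg.size)
    baseline = _resolve_variant(cfg)
    lockout = LOCKOUT_MS[cfg.ap_variant]
    probe = site_cell(topology, "edge")
    rows = []
    for name in configurations:
        specs = _multi_osc_cells(topology, MULTI_OSC_CONFIGS[name])
        membrane_map = place_pacemakers(topology, specs, baseline)
        for g in cfg.coupling_nS:
            network = assemble_system(topology, membrane_map=membrane_map,
                                      coupling=float(g))
            stimuli = _trigger(network, specs, cfg)
            record = sorted({probe, *[s.cell for s in specs]})
            result = run_simulation(network, stimuli, cfg.duration, cfg.dt,
                                    record_cells=record,
                                    sample_every=cfg.sample_every)
            row = _frequency_row(result, probe, lockout)
            row.update(experiment="multiosc", configuration=name,
                       coupling_nS=g)
            rows.append(row)
    return SweepResult(pd.DataFrame(rows), cfg.digest)


def generate_fixture(name: str):
    """Tiny deterministic smoke-test networks with sub-second runtimes.

    Returns ``(topology, config)`` for ``two-cell``, ``three-chain`` or
    ``3-cube-smoke``.
    """
    if name == "two-cell":
        return build_chain(2), ExperimentConfig(
            experiment="run", topology="chain", size=2, duration=50.0,
            coupling_nS=(10.0,),
            pacemakers=(PacemakerConfig(cell=0, gbar_na=0.75),))
    if name == "three-chain":
        return build_chain(3), ExperimentConfig(
            experiment="run", topology="chain", size=3, duration=50.0,
            coupling_nS=(10.0,),
            pacemakers=(PacemakerConfig(cell=1, gbar_na=0.75),))
    if name == "3-cube-smoke":
        return build_cube(3), ExperimentConfig(
            experiment="run", topology="cube", size=3, duration=50.0,
            coupling_nS=(25.0,),
            pacemakers=(PacemakerConfig(cell=-1, gbar_na=0.75),))
    raise ValueError(f"unknown fixture {name!r}")
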
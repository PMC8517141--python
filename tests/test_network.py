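"""Compartmental assembly, the implicit integrator, recording."""

import numpy as np
import pytest

from syncysim import (CellGeometry, MembraneParams, PacemakerSpec,
                      StimulusPulse, StimulusSpec, assemble_system,
                      build_chain, build_cube, detect_spikes, frequency_3to6,
                      place_pacemakers, run_simulation,
                      simulate_isopotential_cell)
from syncysim.junctions import CONNEXINS
from syncysim.membrane import IntegrationError


def uniform_stimulus(cell, amplitude, n_seg=51):
    """Distribute one pulse over all compartments, keeping a cell spatially
    uniform so it can be compared against the isopotential oracle."""
    return [StimulusSpec(cell, 1.0, 1.0, amplitude / n_seg, compartment=s)
            for s in range(n_seg)]


class TestGeometry:
    def test_axial_conductance_scales_with_diameter_squared(self):
        g1 = CellGeometry(diameter=6.0).axial_conductance_uS
        g2 = CellGeometry(diameter=6.0 * np.sqrt(2)).axial_conductance_uS
        assert g2 == pytest.approx(2 * g1)

    def test_even_segment_count_rejected(self):
        with pytest.raises(ValueError):
            CellGeometry(n_segments=50)

    def test_two_cell_chain_compartment_count(self):
        net = assemble_system(build_chain(2))
        assert net.n_comp == 102
        assert net.topology.n_junctions == 1


class TestAssembly:
    def test_membrane_map_length_checked(self):
        with pytest.raises(ValueError):
            assemble_system(build_chain(3),
                            membrane_map=[MembraneParams()] * 2)

    def test_junction_model_count_checked(self):
        from syncysim.junctions import StaticJunction

        with pytest.raises(ValueError):
            assemble_system(build_chain(3),
                            coupling=[StaticJunction(1.0)] * 5)

    def test_end_attachment_requires_chain(self):
        with pytest.raises(ValueError):
            assemble_system(build_cube(3), junction_attachment="ends")

    def test_chains_attach_at_ends_cubes_at_centers(self):
        chain = assemble_system(build_chain(3))
        cube = assemble_system(build_cube(3))
        assert chain.junction_attachment == "ends"
        assert cube.junction_attachment == "center"


class TestDecoupledEquivalence:
    def test_each_cell_reproduces_isopotential_oracle(self, baseline,
                                                      baseline_rheobase):
        """With zero coupling a uniformly stimulated cell is exactly the
        isopotential single cell."""
        net = assemble_system(build_chain(2), coupling=0.0)
        amp = 2 * baseline_rheobase
        res = run_simulation(net, uniform_stimulus(0, amp), 50.0, 0.025,
                             record_cells=[0, 1])
        t, v_iso = simulate_isopotential_cell(
            baseline, StimulusPulse(1.0, 1.0, amp), 50.0, 0.025)
        assert np.max(np.abs(res.v[0] - v_iso)) < 0.1
        assert np.ptp(res.v[1]) < 1e-3  # unstimulated cell stays at rest

    def test_identical_cells_stay_identical_under_symmetric_coupling(self):
        net = assemble_system(build_chain(2), coupling=50.0)
        stims = (uniform_stimulus(0, 0.8) + uniform_stimulus(1, 0.8))
        res = run_simulation(net, stims, 60.0, 0.025, record_cells=[0, 1])
        assert np.max(np.abs(res.v[0] - res.v[1])) < 1e-9


class TestNumerics:
    def test_dt_halving_shifts_spike_times_less_than_100us(self):
        """First-order-in-dt error must stay below 0.1 ms per spike time
        over a 200 ms oscillating run."""
        top = build_chain(3)
        mm = place_pacemakers(top, [PacemakerSpec(1, 0.4)])
        spike_sets = []
        for dt in (0.025, 0.0125):
            net = assemble_system(top, membrane_map=mm, coupling=10.0)
            res = run_simulation(net, [StimulusSpec(1, 1.0, 1.0, 0.5)],
                                 200.0, dt, record_cells=[1])
            spike_sets.append(detect_spikes(res.t, res.v[1]).times)
        a, b = spike_sets
        assert len(a) == len(b)
        assert np.max(np.abs(a - b)) < 0.1

    def test_mirror_symmetry_about_central_pacemaker(self):
        """Cells at +-k from the centre of a chain see identical histories."""
        top = build_chain(7)
        mm = place_pacemakers(top, [PacemakerSpec(3, 0.4)])
        net = assemble_system(top, membrane_map=mm, coupling=20.0)
        res = run_simulation(net, [StimulusSpec(3, 1.0, 1.0, 0.5)], 100.0,
                             0.025, record_cells=[0, 1, 2, 4, 5, 6])
        for k in (1, 2, 3):
            assert np.max(np.abs(res.v[3 - k] - res.v[3 + k])) < 1e-6

    def test_spatial_resolution_robustness(self):
        """Frequency readout moves < 2% between 51 and 101 segments."""
        top = build_chain(3)
        mm = place_pacemakers(top, [PacemakerSpec(1, 0.4)])
        freqs = []
        for n_seg in (51, 101):
            geo = CellGeometry(n_segments=n_seg)
            net = assemble_system(top, geometry=geo, membrane_map=mm,
                                  coupling=10.0)
            res = run_simulation(net, [StimulusSpec(1, 1.0, 1.0, 0.5)],
                                 250.0, 0.025, record_cells=[1])
            freqs.append(frequency_3to6(detect_spikes(res.t, res.v[1])).frequency)
        assert abs(freqs[1] - freqs[0]) / freqs[0] < 0.02

    def test_divergence_reported_as_integration_error(self):
        net = assemble_system(build_chain(2), coupling=10.0)
        with pytest.raises((IntegrationError, ValueError)):
            run_simulation(net, [StimulusSpec(0, 1.0, 1.0, 1e9)], 10.0, 0.025,
                           record_cells=[0])

    def test_numpy_fallback_matches_kernel(self):
        """The pure-numpy reference path and the compiled kernel integrate
        the same trajectory (to rate-table interpolation accuracy)."""
        import syncysim.network as nw

        top = build_chain(3)
        mm = place_pacemakers(top, [PacemakerSpec(1, 0.4)])

        def trace():
            net = assemble_system(top, membrane_map=mm,
                                  coupling=CONNEXINS["cx43"])
            return run_simulation(net, [StimulusSpec(1, 1.0, 1.0, 0.5)],
                                  40.0, 0.025, record_cells=[1]).v[1]

        with_kernel = trace()
        saved = nw.HAVE_NUMBA
        nw.HAVE_NUMBA = False
        try:
            without = trace()
        finally:
            nw.HAVE_NUMBA = saved
        assert np.max(np.abs(with_kernel - without)) < 0.25


class TestJunctionDynamicsInNetwork:
    def test_conductance_bounds_hold_throughout(self):
        top = build_chain(5)
        mm = place_pacemakers(top, [PacemakerSpec(2, 0.4)])
        p = CONNEXINS["cx45"]
        net = assemble_system(top, membrane_map=mm, coupling=p)
        res = run_simulation(net, [StimulusSpec(2, 1.0, 1.0, 0.5)], 200.0,
                             0.025, record_junctions=list(range(4)))
        for g in res.g.values():
            assert np.all(g >= p.g_min_nS - 1e-9)
            assert np.all(g <= p.g_max_nS + 1e-9)

    def test_static_junction_constant_to_machine_precision(self):
        net = assemble_system(build_chain(3), coupling=25.0)
        res = run_simulation(net, [StimulusSpec(1, 1.0, 1.0, 0.5)], 50.0,
                             0.025, record_junctions=[0, 1])
        for g in res.g.values():
            assert np.ptp(g) == 0.0

    def test_transjunctional_voltage_antisymmetry_and_rest(self):
        net = assemble_system(build_chain(3), coupling=10.0)
        state = net.initial_state()
        assert net.transjunctional_voltage(state, 0) == pytest.approx(0.0)
        state.v[0, :] = 40.0
        state.v[1, :] = -65.0
        assert net.transjunctional_voltage(state, 0) == pytest.approx(105.0)

    def test_junction_pair_currents_cancel(self):
        """Paired junctional currents are exact opposites at every sample."""
        from syncysim.junctions import junction_current

        net = assemble_system(build_chain(3), coupling=30.0)
        state = net.initial_state()
        state.v[0, :] = -20.0
        g = net.junction_conductances(state)
        for j in range(net.topology.n_junctions):
            vj = net.transjunctional_voltage(state, j)
            ia, ib = junction_current(g[j], vj, 0.0)
            assert ia + ib == 0.0


class TestRecording:
    def test_zero_duration_gives_empty_result(self):
        net = assemble_system(build_chain(2), coupling=1.0)
        res = run_simulation(net, [], 0.0, 0.025, record_cells=[0])
        assert len(res.t) == 0

    def test_unknown_recorder_rejected(self):
        net = assemble_system(build_chain(2), coupling=1.0)
        with pytest.raises(ValueError):
            run_simulation(net, [], 10.0, 0.025, record_cells=[7])
        with pytest.raises(ValueError):
            run_simulation(net, [], 10.0, 0.025, record_junctions=[3])

    def test_unknown_stimulus_target_rejected(self):
        net = assemble_system(build_chain(2), coupling=1.0)
        with pytest.raises(ValueError):
            run_simulation(net, [StimulusSpec(9, 1.0, 1.0, 1.0)], 10.0, 0.025)

    def test_bitwise_reproducibility(self):
        top = build_chain(3)
        mm = place_pacemakers(top, [PacemakerSpec(1, 0.4)])

        def go():
            net = assemble_system(top, membrane_map=mm, coupling=15.0)
            return run_simulation(net, [StimulusSpec(1, 1.0, 1.0, 0.5)],
                                  80.0, 0.025, record_cells=[1]).v[1]

        assert np.array_equal(go(), go())

    def test_sample_every_thins_time_base(self):
        net = assemble_system(build_chain(2), coupling=1.0)
        res = run_simulation(net, [], 10.0, 0.025, record_cells=[0],
                             sample_every=4)
        assert np.allclose(np.diff(res.t), 0.1)

    def test_trace_files_written_as_text(self, tmp_path):
        net = assemble_system(build_chain(2), coupling=5.0)
        res = run_simulation(net, [], 5.0, 0.025, record_cells=[0],
                             record_junctions=[0])
        res.save(tmp_path)
        v_file = tmp_path / "v_cell0.tsv"
        assert v_file.exists()
        data = np.loadtxt(v_file, skiprows=1)
        assert data.shape[1] == 2
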
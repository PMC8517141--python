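"""Config handling, study pipelines at smoke scale, fixtures and the CLI."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from syncysim.cli import main as cli_main
from syncysim.config import (ExperimentConfig, PacemakerConfig, load_config,
                             resolve_config)
from syncysim.experiments import (generate_fixture, run_coupling_sweep,
                                  run_location_study,
                                  run_multi_oscillator_study, run_size_study,
                                  run_subtype_study)


class TestConfig:
    def test_defaults_resolved_and_dumped(self, tmp_path):
        cfg = resolve_config({"experiment": "coupling", "coupling_nS": 25.0})
        path = tmp_path / "resolved.yaml"
        cfg.dump(path)
        raw = yaml.safe_load(path.read_text())
        assert raw["dt"] == 0.025          # defaults made explicit
        assert raw["coupling_nS"] == [25.0]
        assert load_config(path) == cfg    # round trip

    def test_digest_stable_and_sensitive(self):
        a = resolve_config({"size": 21})
        b = resolve_config({"size": 21})
        c = resolve_config({"size": 23})
        assert a.digest == b.digest
        assert a.digest != c.digest

    @pytest.mark.parametrize("bad", [
        {"experiment": "nope"},
        {"topology": "ring"},
        {"ap_variant": "HH-5000"},
        {"coupling_model": "cx99"},
        {"dt": 0.0},
        {"coupling_nS": ()},
    ])
    def test_schema_violations_rejected(self, bad):
        with pytest.raises(ValueError):
            resolve_config(bad)

    def test_pacemaker_site_xor_cell(self):
        with pytest.raises(ValueError):
            PacemakerConfig(site="vertex", cell=3)
        with pytest.raises(ValueError):
            PacemakerConfig()


class TestFixtures:
    @pytest.mark.parametrize("name,cells,junctions", [
        ("two-cell", 2, 1), ("three-chain", 3, 2), ("3-cube-smoke", 27, 54),
    ])
    def test_known_networks(self, name, cells, junctions):
        topology, cfg = generate_fixture(name)
        assert topology.n_cells == cells
        assert topology.n_junctions == junctions
        assert cfg.duration <= 50.0  # smoke scale

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            generate_fixture("mega-cube")

    def test_three_chain_mirror_symmetric_end_cells(self):
        """A central pacemaker drives both ends of a 3-chain identically."""
        from syncysim import (StimulusSpec, assemble_system, place_pacemakers,
                              run_simulation)
        from syncysim.topology import PacemakerSpec

        topology, cfg = generate_fixture("three-chain")
        mm = place_pacemakers(topology, [PacemakerSpec(1, 0.75)])
        net = assemble_system(topology, membrane_map=mm,
                              coupling=cfg.coupling_nS[0])
        res = run_simulation(net, [StimulusSpec(1, 1.0, 1.0, 0.5)],
                             cfg.duration, cfg.dt, record_cells=[0, 2])
        assert np.max(np.abs(res.v[0] - res.v[2])) < 1e-6


@pytest.fixture(scope="module")
def sweep():
    cfg = resolve_config(dict(experiment="coupling", topology="chain",
                              size=21, coupling_nS=(5.0, 50.0, 50.0),
                              duration=250.0))
    return run_coupling_sweep(cfg)


class TestCouplingSweep:
    def test_frequency_falls_with_coupling(self, sweep):
        rows = sweep.rows
        f5 = rows[rows.coupling_nS == 5.0].iloc[0].frequency
        f50 = rows[rows.coupling_nS == 50.0].iloc[0].frequency
        assert f5 > f50 > 0

    def test_duplicated_grid_point_gives_identical_rows(self, sweep):
        dup = sweep.rows[sweep.rows.coupling_nS == 50.0]
        assert len(dup) == 2
        assert dup.iloc[0].frequency == dup.iloc[1].frequency

    def test_rows_flagged_valid(self, sweep):
        assert sweep.rows.valid.all()

    def test_requires_chain(self):
        with pytest.raises(ValueError):
            run_coupling_sweep(resolve_config(dict(experiment="coupling",
                                                   topology="cube", size=3)))


class TestSubtypeSmoke:
    def test_cx45_falls_hardest_and_swap_rescues(self):
        """Even at smoke scale the steep slow Cx45 gating loses conductance
        while Cx40 and the kinetics-swapped Cx45 barely move."""
        cfg = resolve_config(dict(experiment="subtype", topology="chain",
                                  size=21, duration=600.0, sample_every=4))
        res = run_subtype_study(cfg, subtypes=("cx40", "cx45", "cx45-swapped"))
        rows = res.rows.set_index("subtype")
        assert rows.loc["cx45"].drop_center_pct > \
            5 * rows.loc["cx40"].drop_center_pct
        assert rows.loc["cx45-swapped"].drop_center_pct < \
            rows.loc["cx45"].drop_center_pct
        # junction traces recorded for every subtype
        assert set(res.traces) == {"cx40", "cx45", "cx45-swapped"}


class TestLocationSmoke:
    def test_sparser_site_oscillates_faster_on_3_cube(self):
        cfg = resolve_config(dict(experiment="location", topology="cube",
                                  size=3, coupling_nS=(25.0,), duration=300.0))
        rows = run_location_study(cfg, sites=("center", "vertex")).rows
        f = rows.set_index("site").frequency
        assert f["vertex"] > f["center"] > 0

    def test_requires_cube(self):
        with pytest.raises(ValueError):
            run_location_study(resolve_config(dict(experiment="location",
                                                   topology="chain")))


class TestSizeSmoke:
    def test_smaller_lattice_fires_faster(self):
        cfg = resolve_config(dict(experiment="size", topology="cube", size=3,
                                  coupling_nS=(25.0,), duration=300.0))
        rows = run_size_study(cfg, sizes=(1, 3)).rows
        f = rows.set_index("cube").frequency
        assert f[1] > f[3] > 0


class TestMultiOscillatorSmoke:
    def test_two_equal_vertex_oscillators_match_single(self):
        """With two identical vertex oscillators at opposite corners the
        syncytium locks to (within 3% of) the single-oscillator rhythm."""
        cfg = resolve_config(dict(experiment="multiosc", topology="cube",
                                  size=3, coupling_nS=(25.0,), duration=300.0))
        dual = run_multi_oscillator_study(cfg, configurations=("fV1=fV2",))
        single = run_location_study(
            resolve_config(dict(experiment="location", topology="cube",
                                size=3, coupling_nS=(25.0,), duration=300.0)),
            sites=("vertex",))
        f_dual = dual.rows.iloc[0].frequency
        f_single = single.rows.iloc[0].frequency
        assert abs(f_dual - f_single) / f_single < 0.03


class TestCLI:
    def test_fixture_command_dumps_topology(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["fixture", "3-cube-smoke",
                                          "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert "27 cells, 54 junctions" in result.output
        adj = (tmp_path / "adjacency.tsv").read_text()
        assert len(adj.strip().splitlines()) == 54

    def test_run_command_writes_summary_and_resolved_config(self, tmp_path):
        config = tmp_path / "cfg.yaml"
        config.write_text(yaml.safe_dump(dict(
            experiment="coupling", topology="chain", size=11,
            coupling_nS=[10.0], duration=200.0)))
        runner = CliRunner()
        result = runner.invoke(cli_main, ["run", str(config),
                                          "--out", str(tmp_path / "out")])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "summary.tsv").exists()
        resolved = yaml.safe_load(
            (tmp_path / "out" / "resolved_config.yaml").read_text())
        assert resolved["size"] == 11 and resolved["dt"] == 0.025

    def test_analyze_recomputes_frequency_from_traces(self, tmp_path):
        from syncysim import (StimulusSpec, assemble_system, build_chain,
                              place_pacemakers, run_simulation)
        from syncysim.topology import PacemakerSpec

        top = build_chain(3)
        mm = place_pacemakers(top, [PacemakerSpec(1, 0.4)])
        net = assemble_system(top, membrane_map=mm, coupling=10.0)
        res = run_simulation(net, [StimulusSpec(1, 1.0, 1.0, 0.5)], 200.0,
                             0.025, record_cells=[1])
        res.save(tmp_path)
        runner = CliRunner()
        result = runner.invoke(cli_main, ["analyze", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert "spikes/s" in result.output
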
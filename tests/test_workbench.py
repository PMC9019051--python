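import json

import numpy as np
import pytest
from click.testing import CliRunner

from prochir.cli import main
from prochir.config import ConfigError, RunConfig, load_config
from prochir.fixtures import make_fixtures
from prochir.io import (
    XYZParseError,
    read_g_curve_csv,
    read_hessian_text,
    read_molden_frequencies,
    read_transitions_csv,
    read_xyz,
    write_xyz,
)
from prochir.wigner import MolecularGeometry


def random_frames(n, rng):
    frames = []
    for _ in range(n):
        coords = rng.uniform(-5, 5, size=(4, 3))
        frames.append(
            MolecularGeometry(["C", "C", "H", "O"],
                              np.array([12.011, 12.011, 1.008, 15.999]), coords)
        )
    return frames


class TestXYZ:
    def test_roundtrip_at_written_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = random_frames(3, rng)
        p = tmp_path / "frames.xyz"
        write_xyz(frames, p, precision=8)
        back = read_xyz(p)
        assert len(back) == 3
        for a, b in zip(frames, back):
            assert a.symbols == b.symbols
            np.testing.assert_allclose(a.coords, b.coords, atol=5e-9)

    def test_count_mismatch_reports_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("3\ncomment\nC 0 0 0\nC 1 0 0\n")
        with pytest.raises(XYZParseError, match="line 1"):
            read_xyz(p)

    def test_unknown_element_reports_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\ncomment\nXx 0 0 0\n")
        with pytest.raises(XYZParseError, match="line 3"):
            read_xyz(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        assert read_xyz(p) == []


class TestReaders:
    def test_hessian_text_roundtrip(self, tmp_path):
        H = np.arange(9.0).reshape(3, 3)
        H = H + H.T
        p = tmp_path / "hess.txt"
        np.savetxt(p, H)
        np.testing.assert_allclose(read_hessian_text(p), H)

    def test_hessian_must_be_square(self, tmp_path):
        p = tmp_path / "hess.txt"
        np.savetxt(p, np.zeros((2, 3)))
        with pytest.raises(ValueError, match="square"):
            read_hessian_text(p)

    def test_molden_frequency_sections(self, tmp_path):
        text = """[Molden Format]
[FREQ]
100.0
2500.5
[FR-COORD]
C 0.0 0.0 0.0
O 0.0 0.0 2.2
[FR-NORM-COORD]
vibration 1
0.0 0.0 1.0
0.0 0.0 -1.0
vibration 2
0.0 1.0 0.0
0.0 -1.0 0.0
"""
        p = tmp_path / "freq.molden"
        p.write_text(text)
        out = read_molden_frequencies(p)
        np.testing.assert_allclose(out["frequencies_cm"], [100.0, 2500.5])
        assert out["symbols"] == ["C", "O"]
        assert out["modes"].shape == (2, 2, 3)
        # Bohr -> Angstrom conversion applied
        assert out["coords_aa"][1, 2] == pytest.approx(2.2 * 0.529177210903)

    def test_transitions_csv(self, tmp_path):
        p = tmp_path / "trans.csv"
        p.write_text("energy_eV,strength,rotatory_strength\n4.3,1.0,0.001\n")
        recs = read_transitions_csv(p)
        assert len(recs) == 1 and recs[0].energy_ev == 4.3

    def test_g_curve_csv(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("wavelength_nm,g\n250,0.001\n260,0.002\n")
        lam, g = read_g_curve_csv(p)
        np.testing.assert_allclose(lam, [250, 260])


class TestFixtures:
    def test_same_seed_same_checksum(self):
        assert make_fixtures(5).checksum() == make_fixtures(5).checksum()

    def test_different_seed_different_checksum(self):
        assert make_fixtures(5).checksum() != make_fixtures(6).checksum()

    def test_mirror_pair_structure(self, fixture_set):
        for tp, tm in zip(fixture_set.transitions_P, fixture_set.transitions_M):
            assert tp.dipole_strength == tm.dipole_strength
            assert tp.rotatory_strength == -tm.rotatory_strength

    def test_g_curves_bounded(self, fixture_set):
        for g in (fixture_set.g_stil, fixture_set.g_dhp):
            assert np.nanmax(np.abs(g)) < 0.01


class TestConfig:
    def test_valid_config_loads(self, tmp_path):
        p = tmp_path / "run.yaml"
        p.write_text(
            "preset: stilbene\nseeds:\n  sampling: 3\ndynamics:\n  dt: 0.05\n"
        )
        cfg = load_config(p)
        assert cfg.preset == "stilbene"
        assert cfg.seeds["sampling"] == 3
        assert len(cfg.config_hash()) == 12

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "run.yaml"
        p.write_text("preset: stilbene\nbogus: 1\n")
        with pytest.raises(ConfigError, match="bogus"):
            load_config(p)

    def test_unknown_nested_key_rejected(self, tmp_path):
        p = tmp_path / "run.yaml"
        p.write_text("dynamics:\n  timestep: 0.1\n")
        with pytest.raises(ConfigError, match="dynamics.timestep"):
            load_config(p)

    def test_non_integer_seed_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig(seeds={"sampling": "three"})


class TestCLI:
    def test_unknown_flag_exits_nonzero(self):
        r = CliRunner().invoke(main, ["demo", "--bogus"])
        assert r.exit_code != 0

    def test_kinetics_zero_g_gives_zero_ee(self, tmp_path):
        out = tmp_path / "ee.json"
        r = CliRunner().invoke(
            main, ["kinetics", "--gstil", "0", "--gdhp", "0", "--out", str(out)]
        )
        assert r.exit_code == 0, r.output
        assert json.loads(out.read_text())["ee"] == 0.0

    def test_pes_characterize(self, tmp_path):
        out = tmp_path / "cp.csv"
        r = CliRunner().invoke(
            main, ["pes", "characterize", "--preset", "stilbene", "--out", str(out)]
        )
        assert r.exit_code == 0, r.output
        assert "1.6000" in r.output and "19.0000" in r.output

    def test_scan_on_fixture_curves(self, tmp_path, fixture_set):
        import pandas as pd

        gs = tmp_path / "gstil.csv"
        gd = tmp_path / "gdhp.csv"
        pd.DataFrame({"wavelength_nm": fixture_set.wavelength_nm,
                      "g": fixture_set.g_stil}).to_csv(gs, index=False)
        pd.DataFrame({"wavelength_nm": fixture_set.wavelength_nm,
                      "g": fixture_set.g_dhp}).to_csv(gd, index=False)
        r = CliRunner().invoke(
            main,
            ["scan", "--regime", "fast_isomerization", "--gstil", str(gs),
             "--gdhp", str(gd), "--out-prefix", str(tmp_path / "scan")],
        )
        assert r.exit_code == 0, r.output
        res = json.loads((tmp_path / "scan.json").read_text())
        assert 0 < res["ee_max_percent"] < 1.0

    def test_demo_deterministic_and_unidirectional(self, tmp_path):
        """`demo --seed 7` twice gives byte-identical summaries with a
        clockwise-dominated P swarm and no helicity inversions."""
        outs = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            r = CliRunner().invoke(
                main, ["demo", "--seed", "7", "--n", "12", "--out-dir", str(d)]
            )
            assert r.exit_code == 0, r.output
            outs.append((d / "summary.json").read_bytes())
        assert outs[0] == outs[1]
        summ = json.loads(outs[0])
        assert summ["swarm_P"]["fraction_cw"] >= 0.95
        assert summ["swarm_P"]["helicity_inversion_count"] == 0
        assert summ["swarm_M"]["fraction_acw"] >= 0.95
        assert summ["spectra"]["enantiomer_antisymmetric"]
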
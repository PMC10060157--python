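"""File-format round trips, model reading and atom selections, CLI
subcommands and the umbrella pipeline."""

import json
import warnings

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from trxmap.cli import main
from trxmap.io import (
    read_model,
    read_reflections,
    read_reflections_mmcif,
    read_reflections_mtz,
    read_reflections_tsv,
    select_atoms,
    write_crystal_pdb,
    write_map_ccp4,
    write_reflections_mmcif,
    write_reflections_mtz,
    write_reflections_tsv,
)
from trxmap.pipeline import PipelineConfig, run_pipeline
from trxmap.synthetic import make_toy_crystal


@pytest.fixture()
def runner():
    return CliRunner()


class TestTsvDialect:
    def test_roundtrip_is_lossless(self, f_dark, tmp_path):
        path = tmp_path / "refl.tsv"
        write_reflections_tsv(f_dark, path)
        back = read_reflections_tsv(path)
        assert np.array_equal(back.hkl, f_dark.hkl)
        assert np.allclose(back.value, f_dark.value)
        assert np.allclose(back.phase, f_dark.phase)
        assert back.observable == "F"

    def test_cell_comment_parsed(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("#CELL 20 25 30 90 90 90\n#SG P1\nH K L I SIGI\n"
                        "1 0 0 10.0 1.0\n")
        rs = read_reflections_tsv(path)
        assert (rs.cell.a, rs.cell.b, rs.cell.c) == (20, 25, 30)
        assert rs.observable == "I"

    @pytest.mark.parametrize("content,match", [
        ("#SG P1\nH K L I SIGI\n1 0 0 1 1\n", "CELL"),
        ("#CELL 10 10 10 90 90 90\n#SG P1\nH K L Q R\n1 0 0 1 1\n", "observable"),
        ("#CELL 10 10 10 90 90 90\nH K L I SIGI\n1 0 0 1 1\n", "SG"),
    ])
    def test_malformed_files_raise_descriptive_errors(self, tmp_path, content,
                                                      match):
        path = tmp_path / "bad.tsv"
        path.write_text(content)
        with pytest.raises(ValueError, match=match):
            read_reflections_tsv(path)


class TestMtzAndMmcif:
    def test_mtz_roundtrip_count_and_values(self, i_dark, tmp_path):
        path = tmp_path / "refl.mtz"
        write_reflections_mtz(i_dark, path)
        back = read_reflections_mtz(path)
        assert back.n == i_dark.n
        assert back.observable == "I"
        assert np.allclose(back.value, i_dark.value, rtol=1e-6)
        assert back.spacegroup == "P1"

    def test_format_dispatch_by_suffix(self, i_dark, tmp_path):
        path = tmp_path / "refl.mtz"
        write_reflections_mtz(i_dark, path)
        rs = read_reflections(path)
        assert rs.n == i_dark.n

    def test_sf_mmcif_roundtrip(self, i_dark, tmp_path):
        path = tmp_path / "refl.cif"
        write_reflections_mmcif(i_dark, path)
        back = read_reflections_mmcif(path)
        assert back.n == i_dark.n
        assert np.allclose(back.value, i_dark.value, rtol=1e-5)


class TestModelIo:
    def test_pdb_roundtrip_positions(self, toy_crystal, tmp_path):
        path = tmp_path / "model.pdb"
        write_crystal_pdb(toy_crystal, path)
        atoms, cell, sg = read_model(path)
        assert len(atoms) == len(toy_crystal.atoms_dark)
        assert sg == "P1"
        for got, ref in zip(atoms, toy_crystal.atoms_dark):
            assert np.allclose(got.frac_xyz % 1.0, ref.frac_xyz, atol=1e-3)
            assert got.element == ref.element

    def test_selection_resolves_single_atom(self, toy_crystal, tmp_path):
        path = tmp_path / "model.pdb"
        write_crystal_pdb(toy_crystal, path)
        atoms, _, _ = read_model(path)
        hits = select_atoms(atoms, "TOY/C1")
        assert len(hits) == 1
        assert hits[0].name == "C1"

    def test_absent_selection_raises(self, toy_crystal, tmp_path):
        path = tmp_path / "model.pdb"
        write_crystal_pdb(toy_crystal, path)
        atoms, _, _ = read_model(path)
        with pytest.raises(KeyError, match="XYZ/Q9"):
            select_atoms(atoms, "XYZ/Q9")

    def test_map_export(self, f_dark, tmp_path):
        from trxmap.reflections import synthesize_map

        grid = synthesize_map(f_dark, 0.8)
        path = tmp_path / "map.ccp4"
        write_map_ccp4(grid, path)
        import gemmi

        back = gemmi.read_ccp4_map(str(path))
        assert np.allclose(np.array(back.grid), grid.values, atol=1e-5)


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    """CLI-generated noisy fixture with an injected LTD."""
    out = tmp_path_factory.mktemp("fixture")
    runner = CliRunner()
    result = runner.invoke(main, [
        "simulate", "--seed", "7", "--alpha", "0.2", "--noise", "0.03",
        "--ltd-t", "0", "0.245", "0", "--ltd-kappa", "0.25",
        "--outdir", str(out)])
    assert result.exit_code == 0, result.output
    return out


class TestCli:
    def test_ltd_detect_reports_injected_vector(self, runner, fixture_dir):
        result = runner.invoke(main, ["ltd", "detect",
                                      str(fixture_dir / "dark.tsv")])
        assert result.exit_code == 0, result.output
        report = json.loads(result.output)
        assert abs(report["t"][1] - 0.245) < 0.03
        assert report["peak_height_sigma"] > 5

    def test_dose_prints_labelled_table(self, runner):
        result = runner.invoke(main, [
            "dose", "--pulse-energy", "5e-6", "--fwhm", "47e-4",
            "--duration", "100e-15", "--wavelength", "480e-9",
            "--epsilon", "34000"])
        assert result.exit_code == 0, result.output
        assert "59.6 kcal/mol" in result.output
        assert "45.3" in result.output

    def test_xss_heat_table(self, runner, tmp_path):
        q = np.linspace(0.05, 0.8, 30)
        basis = np.exp(-((q - 0.4) ** 2) / 0.03)
        fluences = [110.0, 260.0]
        dts = [0.016, 0.028]
        curves = np.column_stack([basis * dt * 4.0 for dt in dts])
        with open(tmp_path / "curves.tsv", "w") as fh:
            fh.write("q " + " ".join(str(f) for f in fluences) + "\n")
            for row_q, row in zip(q, curves):
                fh.write(f"{row_q} " + " ".join(f"{v:.8g}" for v in row) + "\n")
        amp = 4.0 * np.linalg.norm(basis)
        with open(tmp_path / "cal.tsv", "w") as fh:
            fh.write("amplitude delta_T\n0 0\n" + f"{amp * 0.05} 0.05\n")
        result = runner.invoke(main, ["xss-heat", str(tmp_path / "curves.tsv"),
                                      str(tmp_path / "cal.tsv")])
        assert result.exit_code == 0, result.output
        assert "0.01600" in result.output
        assert "0.02800" in result.output


class TestPipeline:
    def test_summary_contains_key_results(self, fixture_dir, tmp_path):
        config = PipelineConfig(
            light=str(fixture_dir / "light.tsv"),
            dark=str(fixture_dir / "dark.tsv"),
            model=str(fixture_dir / "model.pdb"),
            output_dir=str(tmp_path / "out"),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = run_pipeline(config)
        assert abs(summary["kappa_star"] - 0.25) <= 0.02
        assert 10.0 <= summary["A_star"] <= 50.0
        assert (tmp_path / "out" / "summary.json").exists()
        assert (tmp_path / "out" / "activation_scan.tsv").exists()

    def test_rerun_is_byte_identical(self, fixture_dir, tmp_path):
        outputs = []
        for name in ("a", "b"):
            config = PipelineConfig(
                light=str(fixture_dir / "light.tsv"),
                dark=str(fixture_dir / "dark.tsv"),
                model=str(fixture_dir / "model.pdb"),
                output_dir=str(tmp_path / name),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                run_pipeline(config)
            outputs.append((tmp_path / name / "summary.json").read_bytes())
        assert outputs[0] == outputs[1]

    def test_yaml_config_roundtrip(self, fixture_dir, tmp_path):
        data = {"light": str(fixture_dir / "light.tsv"),
                "dark": str(fixture_dir / "dark.tsv"),
                "model": str(fixture_dir / "model.pdb"),
                "output_dir": str(tmp_path / "out"),
                "run_extrapolation": False}
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.dump(data))
        config = PipelineConfig.from_yaml(path)
        assert config.run_extrapolation is False
        with pytest.raises(ValueError, match="unknown config keys"):
            path.write_text(yaml.dump({**data, "bogus": 1}))
            PipelineConfig.from_yaml(path)
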
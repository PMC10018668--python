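"""Tests for case-file I/O, run reports, reproduction helpers and the CLI."""

import json

import numpy as np
import pydantic
import pytest
from click.testing import CliRunner

import isomargin as im
from isomargin.cli import main as cli_main
from isomargin.interface import _two_sphere_cell

MINIMAL_CASE = {
    "targets": [
        {"label": "a", "sphere": {"center": [0, 0, 0], "diameter": 6}},
        {"label": "b", "sphere": {"center": [30, 0, 0], "diameter": 10}},
    ],
    "uncertainty": {"m_s": 2.0, "sigma_d": 1.5},
}

FAST_GRID = {"inner_spacing": 1.5, "final_spacing": 1.0}


def fast_case(**overrides) -> im.CaseSpec:
    data = json.loads(json.dumps(MINIMAL_CASE))
    data["optimizer"] = {"method": "grid", "grid_step": 2.0}
    data["grid"] = dict(FAST_GRID)
    data.update(overrides)
    return im.CaseSpec.model_validate(data)


class TestCaseSpec:
    def test_defaults_filled(self):
        case = im.CaseSpec.model_validate(MINIMAL_CASE)
        assert case.uncertainty.alpha == 0.95
        assert case.optimizer.method == "asa"
        assert case.optimizer.seed == 0
        assert case.grid.final_spacing == 0.5

    def test_both_margin_parameterizations_rejected(self):
        bad = json.loads(json.dumps(MINIMAL_CASE))
        bad["uncertainty"] = {"m_s": 2.0, "sigma_s": 1.0, "sigma_d": 1.0}
        with pytest.raises(pydantic.ValidationError, match="m_s or sigma_s"):
            im.CaseSpec.model_validate(bad)

    def test_neither_margin_parameterization_rejected(self):
        bad = json.loads(json.dumps(MINIMAL_CASE))
        bad["uncertainty"] = {"sigma_d": 1.0}
        with pytest.raises(pydantic.ValidationError):
            im.CaseSpec.model_validate(bad)

    def test_target_needs_exactly_one_source(self):
        bad = json.loads(json.dumps(MINIMAL_CASE))
        bad["targets"][0]["mesh_path"] = "x.stl"
        with pytest.raises(pydantic.ValidationError, match="exactly one"):
            im.CaseSpec.model_validate(bad)

    def test_duplicate_labels_rejected(self):
        bad = json.loads(json.dumps(MINIMAL_CASE))
        bad["targets"][1]["label"] = "a"
        with pytest.raises(pydantic.ValidationError, match="unique"):
            im.CaseSpec.model_validate(bad)

    def test_save_load_round_trip(self, tmp_path):
        case = fast_case()
        path = tmp_path / "case.json"
        im.save_case(case, path)
        assert im.load_case(path) == case


class TestRunCase:
    def test_report_structure_and_cog_row(self):
        report = im.run_case(fast_case())
        labels = [r.label for r in report.rows]
        assert labels == ["COG", "COV", "COS", "NSO"]
        assert report.row("COG").normalized_to_cog == 1.0
        assert report.version == im.__version__

    def test_no_rotation_all_rows_unity(self):
        case = fast_case()
        case = case.model_copy(
            update={"uncertainty": im.interface.UncertaintySpec(m_s=2.0, sigma_d=0.0)}
        )
        report = im.run_case(case)
        assert all(r.normalized_to_cog == 1.0 for r in report.rows)

    def test_rerun_is_deterministic(self):
        case = fast_case(optimizer={"method": "asa", "seed": 9, "max_evaluations": 150})
        a = im.run_case(case).model_dump()
        b = im.run_case(case).model_dump()
        assert a == b

    def test_report_round_trips_through_json(self):
        report = im.run_case(fast_case())
        restored = im.RunReport.model_validate_json(report.model_dump_json())
        assert restored == report

    def test_tsv_has_all_rows(self):
        report = im.run_case(fast_case())
        tsv = im.report_to_tsv(report)
        for label in ("COG", "COV", "COS", "NSO"):
            assert f"\n{label}\t" in tsv or tsv.startswith(f"{label}\t") or f"\n{label}\t" in "\n" + tsv


class TestReproductionHelpers:
    def test_diagonal_cell_is_unity(self):
        cell = _two_sphere_cell(5.0, 5.0, 0.5)
        assert cell["normalized_optimal"] == pytest.approx(1.0, abs=1e-3)

    def test_table_subset_shape(self):
        df = im.reproduce_table1(cells=[(5.0, 5.0, 0.5)], inner_spacing=2.0, final_spacing=1.5)
        assert list(df.columns)[:4] == ["sigma_d", "d1", "d2", "normalized_optimal"]
        assert len(df) == 1

    def test_sweep_symmetric_for_equal_spheres(self):
        ts = im.two_sphere_phantom(8.0, 8.0, separation=40.0)
        u = im.SetupUncertainty.from_margin(2.0, 1.0)
        df, marks = im.sweep_line(ts, u, step=4.0, spacing=0.5)
        vals = df["normalized"].to_numpy()
        # mirror symmetry holds to voxel staircase noise at this spacing
        np.testing.assert_allclose(vals, vals[::-1], atol=5e-3)
        assert marks["cog"] == pytest.approx(20.0)
        assert abs(marks["optimal"] - 20.0) <= 4.0
        assert vals.min() >= 1.0 - 5e-3  # midpoint is essentially optimal

    def test_sweep_no_rotation_curve_identically_one(self):
        ts = im.two_sphere_phantom(6.0, 10.0, separation=30.0)
        u = im.SetupUncertainty.from_margin(2.0, 0.0)
        df, _ = im.sweep_line(ts, u, step=5.0, spacing=1.0)
        assert (df["normalized"] == 1.0).all()

    def test_sweep_value_unity_at_cog(self):
        ts = im.two_sphere_phantom(6.0, 12.0, separation=40.0)
        u = im.SetupUncertainty.from_margin(2.0, 1.5)
        df, marks = im.sweep_line(ts, u, step=4.0, spacing=1.0)
        at_cog = df.loc[df["position_mm"] == marks["cog"], "normalized"]
        assert at_cog.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_heatmap_columns_and_cog_value(self):
        ts = im.two_sphere_phantom(6.0, 10.0, separation=30.0)
        u = im.SetupUncertainty.from_margin(2.0, 1.0)
        df = im.heatmap_table(ts, u, step=15.0, spacing=1.5, half_width=15.0)
        assert list(df.columns) == ["x", "y", "z", "value"]
        mid = df[(df.x == 15.0) & (df.y == 0.0) & (df.z == 0.0)]
        assert mid["value"].iloc[0] == pytest.approx(1.0, abs=1e-12)


class TestCLI:
    def write_case(self, tmp_path, data=None):
        path = tmp_path / "case.json"
        payload = data if data is not None else {
            **MINIMAL_CASE,
            "optimizer": {"method": "grid", "grid_step": 2.0},
            "grid": dict(FAST_GRID),
        }
        path.write_text(json.dumps(payload))
        return str(path)

    def test_compare_success(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["compare", "--case", self.write_case(tmp_path)])
        assert result.exit_code == 0
        assert "COG\t" in result.output

    def test_optimize_writes_report(self, tmp_path):
        out = tmp_path / "report.json"
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["optimize", "--case", self.write_case(tmp_path), "--out", str(out)],
        )
        assert result.exit_code == 0
        report = im.RunReport.model_validate_json(out.read_text())
        assert report.row("NSO").v_margin > 0

    def test_validation_failure_exit_code_2(self, tmp_path):
        bad = json.loads(json.dumps(MINIMAL_CASE))
        bad["uncertainty"] = {"m_s": 2.0, "sigma_s": 1.0, "sigma_d": 1.0}
        runner = CliRunner()
        result = runner.invoke(cli_main, ["compare", "--case", self.write_case(tmp_path, bad)])
        assert result.exit_code == 2

    def test_unknown_phantom_exit_code_2(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["phantom", "nonsense"])
        assert result.exit_code == 2

    def test_phantom_emits_valid_case_skeleton(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["phantom", "two-6-15"])
        assert result.exit_code == 0
        case = im.CaseSpec.model_validate(json.loads(result.output))
        assert len(case.targets) == 2

    def test_sweep_tsv(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["sweep", "--case", self.write_case(tmp_path), "--step", "10", "--spacing", "1.5"],
        )
        assert result.exit_code == 0
        assert "position_mm" in result.output
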
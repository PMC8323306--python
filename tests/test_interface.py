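"""I/O round trips, configuration loading, pipeline orchestration and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoflex import io
from mitoflex.cli import main as cli_main
from mitoflex.errors import ConfigurationError
from mitoflex.pipeline import PipelineConfig, run_pipeline
from mitoflex.synth import generate_ogtt


class TestTables:
    def test_well_formed_fixture_parses(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("# values: fmol/ug\nprotein\ts1\ts2\nCpt1b\t1.5\t2.0\n")
        df = io.read_matrix(path, index_name="protein")
        expected = pd.DataFrame([[1.5, 2.0]],
                                index=pd.Index(["Cpt1b"], name="protein"),
                                columns=["s1", "s2"])
        pd.testing.assert_frame_equal(df, expected)

    def test_duplicate_row_error_names_the_duplicate(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("protein\ts1\nCpt1b\t1\nCpt1b\t2\n")
        with pytest.raises(ConfigurationError, match="Cpt1b"):
            io.read_matrix(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample\tage\tdiet\tvalue\ns1\tyoung\tLFD\toops\n")
        with pytest.raises(ConfigurationError, match="value"):
            io.read_table(path, required_columns=("value",),
                          numeric_columns=("value",))

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ConfigurationError, match="c"):
            io.read_table(path, required_columns=("c",))

    def test_missing_file(self, tmp_path):
        with pytest.raises(ConfigurationError):
            io.read_table(tmp_path / "absent.tsv")

    @settings(max_examples=20, deadline=None)
    @given(
        values=st.lists(
            st.lists(st.floats(0, 1e6, allow_nan=False, width=32),
                     min_size=3, max_size=3),
            min_size=1, max_size=8,
        )
    )
    def test_write_read_round_trip(self, tmp_path_factory, values):
        tmp = tmp_path_factory.mktemp("rt")
        frame = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index([f"a{i}" for i in range(len(values))], name="analyte"),
            columns=["s1", "s2", "s3"],
        )
        path = tmp / "m.tsv"
        io.write_matrix(frame, path)
        back = io.read_matrix(path)
        pd.testing.assert_frame_equal(back, frame)

    def test_sample_sheet_label_validation(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("sample\tage\tdiet\nm1\tmiddle\tLFD\n")
        with pytest.raises(ConfigurationError, match="middle"):
            io.read_sample_sheet(path)

    def test_ogtt_round_trip(self, tmp_path, small_config):
        series = generate_ogtt(small_config)
        path = tmp_path / "ogtt.tsv"
        io.write_ogtt(series, path)
        back = io.read_ogtt(path)
        assert len(back) == len(series)
        by_animal = {s.animal: s for s in back}
        for s in series:
            restored = by_animal[s.animal]
            assert np.allclose(restored.glucose, s.glucose)
            assert np.allclose(restored.insulin, s.insulin)
            assert restored.insulin_unit == s.insulin_unit


class TestPipelineConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(seed=4, substrate_points=5, stages=["synth"])
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert PipelineConfig.from_yaml(path) == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 1\nbogus_key: 2\n")
        with pytest.raises(ConfigurationError, match="bogus_key"):
            PipelineConfig.from_yaml(path)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig(stages=["synth", "teleport"])

    def test_missing_input_path_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError):
            PipelineConfig(proteomics_path=str(tmp_path / "nope.tsv"))


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    cfg = PipelineConfig(
        seed=7, out_dir=str(out), substrate_points=3,
        synth={"n_young": 3, "n_old": 3},
    )
    artifacts = run_pipeline(cfg)
    return cfg, artifacts


class TestPipeline:
    def test_all_artifacts_present(self, pipeline_run):
        cfg, artifacts = pipeline_run
        for name in ("samples", "proteomics", "lipidomics", "fluxes", "fcc",
                     "insulin_indices", "differential_old", "differential_young",
                     "manifest"):
            assert artifacts[name].exists(), name

    def test_row_counts(self, pipeline_run):
        cfg, artifacts = pipeline_run
        samples = io.read_sample_sheet(artifacts["samples"])
        assert len(samples) == 12
        prot = io.read_matrix(artifacts["proteomics"])
        assert prot.shape == (47, 12)
        lip = io.read_matrix(artifacts["lipidomics"])
        assert lip.shape == (443, 12)
        indices = io.read_table(artifacts["insulin_indices"],
                                required_columns=("animal", "misi", "homa_ir"))
        assert len(indices) == 12

    def test_manifest_provenance(self, pipeline_run):
        cfg, artifacts = pipeline_run
        manifest = json.loads(artifacts["manifest"].read_text())
        assert manifest["seed"] == cfg.seed
        assert manifest["config_sha256"] == cfg.digest()
        assert set(manifest["stages"]) == set(cfg.stages)

    def test_rerun_is_byte_identical(self, pipeline_run, tmp_path):
        cfg, artifacts = pipeline_run
        rerun_cfg = PipelineConfig(
            seed=7, out_dir=str(tmp_path / "rerun"), substrate_points=3,
            synth={"n_young": 3, "n_old": 3},
        )
        rerun = run_pipeline(rerun_cfg)
        for name in ("proteomics", "lipidomics", "fluxes", "fcc",
                     "insulin_indices", "differential_old"):
            assert rerun[name].read_bytes() == artifacts[name].read_bytes()

    def test_disabling_lipidiff_skips_differential(self, tmp_path):
        cfg = PipelineConfig(
            seed=7, out_dir=str(tmp_path / "partial"), substrate_points=3,
            stages=["synth", "ogtt"], synth={"n_young": 3, "n_old": 3},
        )
        artifacts = run_pipeline(cfg)
        assert "differential_old" not in artifacts
        assert artifacts["insulin_indices"].exists()


@pytest.fixture(scope="module")
def cohort_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("cli")
    result = CliRunner().invoke(
        cli_main, ["synth", "--seed", "3", "--out", str(out)]
    )
    assert result.exit_code == 0, result.output
    return out


class TestCli:
    def invoke(self, *args):
        runner = CliRunner()
        return runner.invoke(cli_main, list(args), catch_exceptions=False)

    def test_synth_writes_tables(self, cohort_dir):
        for name in ("samples.tsv", "proteomics.tsv", "lipidomics.tsv",
                     "lipid_classes.tsv", "lipid_standards.tsv", "ogtt.tsv"):
            assert (cohort_dir / name).exists()

    def test_parameterize_and_simulate(self, cohort_dir, tmp_path):
        pdir = tmp_path / "params"
        result = self.invoke(
            "parameterize", "--proteomics", str(cohort_dir / "proteomics.tsv"),
            "--samples", str(cohort_dir / "samples.tsv"), "--out", str(pdir),
        )
        assert result.exit_code == 0, result.output
        inis = sorted(pdir.glob("*.ini"))
        assert len(inis) == 32
        scan = tmp_path / "scan.tsv"
        result = self.invoke(
            "simulate", "--params", str(inis[0]), "--points", "3",
            "--malonyl", "0.2", "--out", str(scan),
        )
        assert result.exit_code == 0, result.output
        table = io.read_table(scan, required_columns=(
            "S_cyt_uM", "malonylCoA_uM", "flux", "acylcarnitine_C16_uM",
            "converged"))
        assert len(table) == 3
        assert table["converged"].all()

    def test_fcc_command(self, cohort_dir, tmp_path):
        pdir = tmp_path / "params"
        result = self.invoke(
            "parameterize", "--proteomics", str(cohort_dir / "proteomics.tsv"),
            "--samples", str(cohort_dir / "samples.tsv"), "--out", str(pdir),
        )
        assert result.exit_code == 0, result.output
        # keep two animals for a fast control-analysis run
        keep = sorted(pdir.glob("*.ini"))[:2]
        mini = tmp_path / "mini"
        mini.mkdir()
        for ini in keep:
            (mini / ini.name).write_bytes(ini.read_bytes())
        out = tmp_path / "fcc.tsv"
        result = self.invoke(
            "fcc", "--cohort", str(mini),
            "--samples", str(cohort_dir / "samples.tsv"),
            "--enzymes", "CPT1B,MCKAT", "--malonyl", "0",
            "--grid-log", "0.5:5:3", "--out", str(out),
        )
        assert result.exit_code == 0, result.output
        table = io.read_table(out, required_columns=("animal", "enzyme", "fcc"))
        assert len(table) == 2 * 3 * 2  # animals x grid x enzymes
        assert np.allclose(table["fcc_sum"], 1.0, atol=0.02)

    def test_fit_ogtt_command(self, cohort_dir, tmp_path):
        out = tmp_path / "indices.tsv"
        result = self.invoke("fit-ogtt", "--in", str(cohort_dir / "ogtt.tsv"),
                             "--out", str(out))
        assert result.exit_code == 0, result.output
        table = io.read_table(out, required_columns=("animal", "misi", "homa_ir"))
        assert len(table) == 32

    def test_lipidiff_scatter_correlate(self, cohort_dir, tmp_path):
        out = tmp_path / "diff.tsv"
        result = self.invoke(
            "lipidiff", "--table", str(cohort_dir / "lipidomics.tsv"),
            "--classes", str(cohort_dir / "lipid_classes.tsv"),
            "--samples", str(cohort_dir / "samples.tsv"),
            "--standards", str(cohort_dir / "lipid_standards.tsv"),
            "--age", "old", "--out", str(out),
        )
        assert result.exit_code == 0, result.output
        assert "significant" in result.output
        result = self.invoke(
            "scatter", "--table", str(cohort_dir / "lipidomics.tsv"),
            "--samples", str(cohort_dir / "samples.tsv"),
            "--out", str(tmp_path / "scatter.tsv"),
        )
        assert result.exit_code == 0, result.output

    def test_correlate_command(self, cohort_dir, tmp_path):
        indices = tmp_path / "indices.tsv"
        result = self.invoke("fit-ogtt", "--in", str(cohort_dir / "ogtt.tsv"),
                             "--out", str(indices))
        assert result.exit_code == 0, result.output
        out = tmp_path / "corr.tsv"
        result = self.invoke(
            "correlate", "--table", str(cohort_dir / "lipidomics.tsv"),
            "--samples", str(cohort_dir / "samples.tsv"),
            "--index", str(indices), "--out", str(out),
        )
        assert result.exit_code == 0, result.output
        table = io.read_table(out, required_columns=("analyte", "r", "p"))
        assert len(table) == 443

    def test_run_command(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "substrate_points: 3\n"
            "synth:\n  n_young: 2\n  n_old: 2\n"
            f"out_dir: {tmp_path / 'run_out'}\n"
        )
        result = self.invoke("run", "--config", str(cfg), "--seed", "5")
        assert result.exit_code == 0, result.output
        assert (tmp_path / "run_out" / "manifest.json").exists()
        assert (tmp_path / "run_out" / "differential_old.tsv").exists()

    def test_validation_error_exit_code(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.tsv"
        bad.write_text("protein\ts1\nCpt1b\t1\nCpt1b\t2\n")
        sheet = tmp_path / "s.tsv"
        sheet.write_text("sample\tage\tdiet\ns1\tyoung\tLFD\n")
        result = runner.invoke(cli_main, [
            "parameterize", "--proteomics", str(bad), "--samples", str(sheet),
            "--out", str(tmp_path / "o")])
        assert result.exit_code == 1
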
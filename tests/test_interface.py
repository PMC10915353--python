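"""File I/O round trips, config validation, and CLI smoke tests."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from netard import io
from netard.cli import main
from netard.config import RunConfig, load_config


class TestExpressionIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "x.tsv"
        values = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        io.write_expression_matrix(path, values, ["g1", "g2"],
                                   ["s1", "s2", "s3"])
        out, genes, samples = io.read_expression_matrix(path)
        assert np.array_equal(out, values)
        assert genes == ["g1", "g2"]
        assert samples == ["s1", "s2", "s3"]

    def test_transpose_flag(self, tmp_path):
        path = tmp_path / "x.tsv"
        values = np.arange(6.0).reshape(3, 2)
        io.write_expression_matrix(path, values.T, ["s1", "s2", "s3"],
                                   ["g1", "g2"])
        out, genes, _ = io.read_expression_matrix(path, transpose=True)
        assert np.array_equal(out, values)
        assert genes == ["g1", "g2"]

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text("sample,gA,gA\ns1,1,2\ns2,3,4\n")
        with pytest.raises(ValueError, match="gA"):
            io.read_expression_matrix(path)

    def test_missing_value_rejected(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text("sample,gA,gB\ns1,1,\ns2,3,4\n")
        with pytest.raises(ValueError, match="gB"):
            io.read_expression_matrix(path)


class TestEdgeListIO:
    def test_reversed_duplicates_collapse(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("a\tb\nb\ta\n")
        edges, _ = io.read_edge_list(path)
        assert edges == [("a", "b")]

    def test_self_loop_dropped_with_warning(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("a\ta\na\tb\n")
        with pytest.warns(RuntimeWarning, match="self-loop"):
            edges, _ = io.read_edge_list(path)
        assert edges == [("a", "b")]

    def test_round_trip_with_weights(self, tmp_path):
        path = tmp_path / "e.tsv"
        io.write_edge_list(path, [("b", "a"), ("a", "c")],
                           weights={("a", "b"): 0.5, ("a", "c"): 0.25})
        edges, weights = io.read_edge_list(path)
        assert set(edges) == {("a", "b"), ("a", "c")}
        assert weights[("a", "b")] == 0.5

    def test_comments_and_malformed_rows(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("# comment\na\tb\n")
        edges, _ = io.read_edge_list(path)
        assert edges == [("a", "b")]
        bad = tmp_path / "bad.tsv"
        bad.write_text("a\tb\nonlyone\n")
        with pytest.raises(ValueError, match="2"):
            io.read_edge_list(bad)


class TestRunConfig:
    def test_defaults_valid(self):
        cfg = RunConfig()
        assert cfg.xi == 0.1 and cfg.gamma == 0.0

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("xi: 0.2\nbogus_knob: 3\n")
        with pytest.raises(ValueError, match="bogus_knob"):
            load_config(path)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("xi: 0.5\ngamma: 0.2\nmin_cluster_size: 7\n")
        cfg = load_config(path)
        assert cfg.xi == 0.5 and cfg.min_cluster_size == 7

    def test_invalid_value_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(xi=1.5)


class TestCli:
    def test_simulate_infer_evaluate_pipeline(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        r = runner.invoke(main, ["simulate", "--p", "12", "--hubs", "1",
                                 "--n", "80", "--seed", "5",
                                 "--hub-degree", "6", "--nonhub-degree", "1",
                                 "--out", str(sim_dir)])
        assert r.exit_code == 0, r.output
        for name in ("expression.tsv", "true_edges.tsv", "true_precision.csv",
                     "hubs.txt"):
            assert (sim_dir / name).exists()

        inf_dir = tmp_path / "inf"
        r = runner.invoke(main, ["infer", "--expr",
                                 str(sim_dir / "expression.tsv"),
                                 "--out", str(inf_dir)])
        assert r.exit_code == 0, r.output
        report = json.loads((inf_dir / "report.json").read_text())
        assert report["n_edges"] >= 0 and "lambda_selected" in report

        # weights CSV for evaluation
        from netard.io import read_matrix_csv, write_matrix_csv
        prec, genes = read_matrix_csv(inf_dir / "precision.csv")
        from netard.ggm_refit import reestimate_weights
        write_matrix_csv(inf_dir / "weights.csv", reestimate_weights(prec),
                         genes)
        out_json = tmp_path / "eval.json"
        r = runner.invoke(main, ["evaluate", "--weights",
                                 str(inf_dir / "weights.csv"),
                                 "--truth", str(sim_dir / "true_edges.tsv"),
                                 "--out", str(out_json)])
        assert r.exit_code == 0, r.output
        scores = json.loads(out_json.read_text())
        assert 0.0 <= scores["auroc"] <= 1.0

    def test_infer_with_config_file(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(main, ["simulate", "--p", "10", "--hubs", "1",
                             "--n", "60", "--seed", "3", "--hub-degree", "5",
                             "--nonhub-degree", "1", "--out", str(sim_dir)])
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("xi: 0.0\nlam_grid: [20.0, 80.0]\n")
        inf_dir = tmp_path / "inf"
        r = runner.invoke(main, ["infer", "--expr",
                                 str(sim_dir / "expression.tsv"),
                                 "--config", str(cfg), "--out", str(inf_dir)])
        assert r.exit_code == 0, r.output
        report = json.loads((inf_dir / "report.json").read_text())
        assert {p["lambda"] for p in report["path"]} == {20.0, 80.0}

    def test_invalid_flag_exits_with_usage_error(self):
        r = CliRunner().invoke(main, ["infer", "--no-such-flag"])
        assert r.exit_code == 2

    def test_hub_constrained_inference(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(main, ["simulate", "--p", "10", "--hubs", "1",
                             "--n", "80", "--seed", "7", "--hub-degree", "6",
                             "--nonhub-degree", "1", "--out", str(sim_dir)])
        inf_dir = tmp_path / "inf"
        r = runner.invoke(main, ["infer", "--expr",
                                 str(sim_dir / "expression.tsv"),
                                 "--hubs", str(sim_dir / "hubs.txt"),
                                 "--c-shrink", "0", "--out", str(inf_dir)])
        assert r.exit_code == 0, r.output
        hubs = set((sim_dir / "hubs.txt").read_text().split())
        lines = (inf_dir / "edges.tsv").read_text().strip().splitlines()[1:]
        for line in lines:
            a, b = line.split("\t")[:2]
            assert a in hubs or b in hubs


def test_json_report_serializes_numpy_types(tmp_path):
    path = tmp_path / "r.json"
    io.write_json_report(path, {"a": np.int64(3), "b": np.float64(0.5),
                                "c": np.arange(3)})
    data = json.loads(path.read_text())
    assert data == {"a": 3, "b": 0.5, "c": [0, 1, 2]}
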
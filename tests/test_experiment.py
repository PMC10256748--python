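"""End-to-end orchestration: NIfTI persistence, experiment reproducibility,
method comparison, and the command-line surface."""

import json
from dataclasses import replace

import numpy as np
import pytest
import yaml

import contiseg as cs
from contiseg.cli import cli
from contiseg.experiment import ExperimentConfig, compare_methods, run_experiment
from contiseg.io import read_task, write_task
from contiseg.model import TrainConfig


def _small_cfg(tmp_path, name, method="sequential", order=None, seed=3, **mp):
    specs = cs.high_shift_pair(n_cases=8, image_shape=(16, 16))
    return ExperimentConfig(
        tasks=specs, order=order,
        train=TrainConfig(epochs=2, steps_per_epoch=4, seed=seed,
                          method=method, method_params=mp),
        output_dir=str(tmp_path / name), seed=seed)


class TestNiftiRoundTrip:
    def test_write_read_preserves_cases_and_split(self, tiny_task, tmp_path):
        write_task(tiny_task, tmp_path / "t")
        back = read_task(tmp_path / "t")
        assert back.task_id == tiny_task.task_id
        assert back.train_idx == tiny_task.train_idx
        assert back.test_idx == tiny_task.test_idx
        for (ca, ia, ma), (cb, ib, mb) in zip(tiny_task.cases, back.cases):
            assert ca == cb
            assert np.allclose(ia, ib)
            assert (ma == mb).all()

    def test_3d_round_trip(self, tmp_path):
        ds = cs.generate_task(cs.TaskSpec(task_id="v", n_cases=2,
                                          image_shape=(12, 12, 12)), seed=0)
        write_task(ds, tmp_path / "v")
        back = read_task(tmp_path / "v")
        assert back.cases[0][1].shape == (12, 12, 12)
        assert (back.cases[0][2] == ds.cases[0][2]).all()


class TestRunExperiment:
    def test_deterministic_reports(self, tmp_path):
        rec1 = run_experiment(_small_cfg(tmp_path, "run1"))
        rec2 = run_experiment(_small_cfg(tmp_path, "run2"))
        for fname in ("perf_matrix.csv", "final_report.csv", "summary.json",
                      "trajectory.jsonl", "alignment_report.json"):
            b1 = (rec1.output_dir / fname).read_bytes()
            b2 = (rec2.output_dir / fname).read_bytes()
            assert b1 == b2, fname

    def test_order_changes_results_not_data(self, tmp_path):
        fwd = run_experiment(_small_cfg(tmp_path, "fwd", order=["siteA", "siteB"]))
        rev = run_experiment(_small_cfg(tmp_path, "rev", order=["siteB", "siteA"]))
        assert fwd.summary["tasks"] == ["siteA", "siteB"]
        assert rev.summary["tasks"] == ["siteB", "siteA"]
        assert fwd.perf.stage_order != rev.perf.stage_order

    def test_bad_order_rejected(self, tmp_path):
        cfg = _small_cfg(tmp_path, "bad", order=["siteA", "nope"])
        with pytest.raises(RuntimeError, match="load_tasks"):
            run_experiment(cfg)

    def test_failure_persists_partial_provenance(self, tmp_path):
        cfg = _small_cfg(tmp_path, "fail", order=["siteA", "nope"])
        with pytest.raises(RuntimeError):
            run_experiment(cfg)
        prov = json.loads((tmp_path / "fail" / "provenance.json").read_text())
        assert prov["failed_stage"] == "load_tasks"

    def test_provenance_carries_config_hash_and_versions(self, tmp_path):
        rec = run_experiment(_small_cfg(tmp_path, "prov"))
        prov = json.loads((rec.output_dir / "provenance.json").read_text())
        assert prov["config_hash"] == rec.config.config_hash()
        assert prov["numpy"] == np.__version__


class TestExperimentConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = _small_cfg(tmp_path, "yaml", method="rehearsal")
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = ExperimentConfig.from_file(path)
        assert back.config_hash() == cfg.config_hash()

    def test_preset_name_expands(self):
        cfg = ExperimentConfig.from_dict({"tasks": "no_shift_pair"})
        assert [t.task_id for t in cfg.tasks] == ["site1", "site2"]


class TestCompareMethods:
    def test_single_config_single_row(self, tmp_path):
        df = compare_methods([_small_cfg(tmp_path, "solo")])
        assert len(df) == 1 and df.index[0] == "sequential"

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        df = compare_methods([_small_cfg(tmp_path, "m1"),
                              _small_cfg(tmp_path, "m2", method="rehearsal")])
        path = tmp_path / "cmp.csv"
        df.to_csv(path)
        back = pd.read_csv(path, index_col="method")
        assert list(back.index) == list(df.index)
        assert np.allclose(back.to_numpy(), df.to_numpy())

    def test_mismatched_tasks_rejected(self, tmp_path):
        a = _small_cfg(tmp_path, "a")
        b = _small_cfg(tmp_path, "b")
        b.tasks = cs.no_shift_pair(n_cases=8, image_shape=(16, 16))
        with pytest.raises(ValueError, match="different task sets"):
            compare_methods([a, b])


class TestCli:
    @pytest.fixture()
    def runner(self):
        from click.testing import CliRunner
        return CliRunner()

    def test_simulate_then_heads_and_evaluate(self, runner, tmp_path):
        res = runner.invoke(cli, ["simulate", "--preset", "no_shift_pair",
                                  "--seed", "1", "--out", str(tmp_path / "tasks")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "tasks" / "site1" / "manifest.json").exists()

    def test_align_subcommand_never_overwrites(self, runner, tmp_path):
        ds = cs.generate_task(cs.TaskSpec(task_id="q", n_cases=3,
                                          shape_family="bilobed",
                                          label_scheme=(1, 2),
                                          image_shape=(16, 16)), seed=0)
        write_task(ds, tmp_path / "q")
        mapping = tmp_path / "map.json"
        mapping.write_text(json.dumps({"task_id": "q", "map": {"1": 1, "2": 1}}))
        res = runner.invoke(cli, ["align", "--task-dir", str(tmp_path / "q"),
                                  "--mapping", str(mapping),
                                  "--out", str(tmp_path / "q")])
        assert res.exit_code != 0  # refuses in-place overwrite
        res = runner.invoke(cli, ["align", "--task-dir", str(tmp_path / "q"),
                                  "--mapping", str(mapping),
                                  "--out", str(tmp_path / "q_aligned")])
        assert res.exit_code == 0, res.output
        aligned = read_task(tmp_path / "q_aligned")
        assert aligned.labels_present() <= {0, 1}

    def test_train_writes_summary(self, runner, tmp_path):
        for ds in cs.generate_sequence(
                cs.high_shift_pair(n_cases=8, image_shape=(16, 16)), seed=2):
            write_task(ds, tmp_path / ds.task_id)
        res = runner.invoke(cli, [
            "train", "--method", "rehearsal",
            "--tasks", str(tmp_path / "siteA"), "--tasks", str(tmp_path / "siteB"),
            "--seed", "2", "--epochs", "1", "--steps-per-epoch", "3",
            "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert summary["method"] == "rehearsal"
        res = runner.invoke(cli, ["heads", "--model",
                                  str(tmp_path / "out" / "model_final.npz")])
        assert res.exit_code == 0 and "siteB" in res.output
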
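"""Training loop, results object, cross-validation and file orchestration."""

import numpy as np
import pandas as pd
import pytest

from suturepoint.codec import DistributionSpec, PointSet, encode_heatmap
from suturepoint.layers import ModelConfig
from suturepoint.losses import LossConfig
from suturepoint.model import (Adam, RunConfig, SutureDetectionModel,
                               cross_validate, group_kfold)
from suturepoint.synthetic import SceneSpec, generate_dataset, generate_scene

TINY_MODEL = ModelConfig(input_height=32, input_width=32, depth=2, base_filters=4)


def tiny_config(**kwargs):
    defaults = dict(model=TINY_MODEL,
                    dist=DistributionSpec("gaussian", sigma1=2.0),
                    epochs=2, batch_size=4, seed=0)
    defaults.update(kwargs)
    return RunConfig(**defaults)


def tiny_dataset(n=8, seed=0):
    from dataclasses import replace

    spec = SceneSpec(height=32, width=32, n_points=(1, 2),
                     close_pair_fraction=0.0, min_separation=4.0, seed=seed)
    data = [generate_scene(replace(spec, seed=seed + i)) for i in range(n)]
    return np.stack([d[0] for d in data]), [d[1] for d in data]


class TestFit:
    def test_two_epochs_produce_log_and_results(self, tmp_path):
        imgs, pts = tiny_dataset()
        res = SutureDetectionModel(imgs, pts, tiny_config()).fit()
        assert list(res.log.columns) == ["epoch", "train_loss", "val_loss", "lr"]
        assert len(res.log) == 2
        assert np.isfinite(res.best_loss)
        res.save(tmp_path / "ckpt")
        assert (tmp_path / "ckpt.npz").exists()
        assert (tmp_path / "ckpt.json").exists()
        assert (tmp_path / "ckpt_log.csv").exists()

    def test_single_batch_loss_decreases_over_steps(self):
        """Overfit-one-batch sanity: 50 optimisation steps reduce the loss."""
        imgs, pts = tiny_dataset(n=4)
        cfg = tiny_config(epochs=50, batch_size=4)
        res = SutureDetectionModel(imgs, pts, cfg).fit()
        losses = res.log.train_loss.to_numpy()
        assert losses[-1] < losses[0] - 0.02
        # and the trend is downward, not a lucky endpoint
        assert losses[25:].mean() < losses[:25].mean()

    def test_determinism_same_seed(self):
        imgs, pts = tiny_dataset()
        a = SutureDetectionModel(imgs, pts, tiny_config()).fit()
        b = SutureDetectionModel(imgs, pts, tiny_config()).fit()
        pd.testing.assert_frame_equal(a.log, b.log)
        for pa, pb in zip(a.detector.parameters(), b.detector.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_plateau_reduces_learning_rate(self):
        """A frozen loss triggers the factor-0.1 decay after the patience."""

        class FrozenAdam(Adam):
            def step(self):  # keep parameters fixed so the loss plateaus
                self.t += 1

        imgs, pts = tiny_dataset(n=4)
        cfg = tiny_config(epochs=13, plateau_patience=10)
        model = SutureDetectionModel(imgs, pts, cfg)
        import suturepoint.model as model_mod

        orig = model_mod.Adam
        model_mod.Adam = FrozenAdam
        try:
            res = model.fit()
        finally:
            model_mod.Adam = orig
        lrs = res.log.lr.to_numpy()
        assert lrs[0] == pytest.approx(0.001)
        assert lrs[-1] == pytest.approx(0.0001)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            SutureDetectionModel(np.empty((0, 3, 32, 32)), [], tiny_config())

    def test_augmented_fit_runs(self):
        from suturepoint.synthetic import AugmentConfig

        imgs, pts = tiny_dataset(n=4)
        cfg = tiny_config(epochs=1, augment=AugmentConfig(p_apply=0.5, seed=0))
        res = SutureDetectionModel(imgs, pts, cfg).fit()
        assert len(res.log) == 1


class TestResults:
    def test_predict_shapes_and_determinism(self):
        imgs, pts = tiny_dataset()
        res = SutureDetectionModel(imgs, pts, tiny_config(epochs=1)).fit()
        out1 = res.predict(imgs[:3])
        out2 = res.predict(imgs[:3])
        assert len(out1) == 3
        for (h1, p1), (h2, p2) in zip(out1, out2):
            assert h1.shape == (32, 32)
            np.testing.assert_array_equal(h1, h2)
            np.testing.assert_array_equal(p1.points, p2.points)

    def test_injected_perfect_heatmap_recovers_points(self):
        """Decoding a ground-truth stage-2 map recovers the planted points."""
        from suturepoint.codec import decode_points

        spec = DistributionSpec("gaussian", sigma1=2.0)
        ps = PointSet(np.array([[10.0, 8.0], [25.0, 20.0]]), 32, 32)
        hm = encode_heatmap(ps, spec)
        dec = decode_points(hm, 0.5)
        assert len(dec) == 2
        d = np.linalg.norm(ps.points[:, None] - dec.points[None], axis=-1)
        assert d.min(axis=1).max() < 1.0

    def test_summary_mentions_key_settings(self):
        imgs, pts = tiny_dataset()
        res = SutureDetectionModel(imgs, pts, tiny_config(epochs=1)).fit()
        text = res.summary()
        assert "gaussian" in text and "parameters" in text
        assert "loss variant" in text

    def test_evaluate_reports_all_radii(self):
        imgs, pts = tiny_dataset()
        res = SutureDetectionModel(imgs, pts, tiny_config(epochs=1)).fit()
        report = res.evaluate(imgs, pts)
        assert list(report["metrics"].radius) == [6.0, 8.0, 10.0]
        assert report["rmse"].n_images_total == len([p for p in pts if len(p)])


class TestRunConfigYaml:
    def test_round_trip(self, tmp_path):
        cfg = tiny_config(epochs=7, radii=(6.0, 8.0))
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        back = RunConfig.from_yaml(path)
        assert back == cfg

    def test_validation(self):
        with pytest.raises(ValueError):
            tiny_config(learning_rate=-1.0)
        with pytest.raises(ValueError):
            tiny_config(plateau_factor=1.5)


class TestGroupKFold:
    def test_partition_properties(self):
        groups = [f"g{i % 10}" for i in range(40)]
        folds = group_kfold(groups, 5)
        assert len(folds) == 5
        all_val = []
        for train, val in folds:
            train_groups = {groups[i] for i in train}
            val_groups = {groups[i] for i in val}
            assert not train_groups & val_groups  # no leakage
            assert len(val_groups) == 2  # 10 groups over 5 folds
            all_val.extend(val)
        assert sorted(all_val) == list(range(40))

    def test_fewer_groups_than_folds_rejected(self):
        with pytest.raises(ValueError):
            group_kfold(["a", "b"], 3)


def test_cross_validation_aggregates_fold_metrics():
    imgs, pts = tiny_dataset(n=8)
    groups = ["s0", "s0", "s1", "s1", "s2", "s2", "s3", "s3"]
    cfg = tiny_config(epochs=1, folds=2)
    out = cross_validate(imgs, pts, groups, cfg)
    assert len(out["folds"]) == 2
    agg = out["aggregate"].set_index("metric")
    assert agg.loc["f1", "mean"] == pytest.approx(out["folds"].f1.mean())


class TestPipelineFiles:
    def test_train_predict_evaluate_round_trip(self, tmp_path):
        from suturepoint import pipeline

        spec = SceneSpec(height=32, width=32, n_points=(1, 2),
                         close_pair_fraction=0.0, seed=1)
        generate_dataset(spec, 6, tmp_path / "data", n_groups=3)
        cfg = tiny_config(epochs=1)
        pipeline.train(cfg, tmp_path / "data", tmp_path / "ckpt")
        preds = pipeline.predict(tmp_path / "ckpt", tmp_path / "data",
                                 tmp_path / "pred.csv")
        assert len(preds) == 6
        report = pipeline.evaluate(tmp_path / "pred.csv", tmp_path / "data",
                                   out_prefix=tmp_path / "report")
        assert (tmp_path / "report_metrics.csv").exists()
        assert (tmp_path / "report_metrics.json").exists()
        # orchestration equals calling the library directly
        from suturepoint.matching import radius_sweep
        from suturepoint.model import load_dataset

        imgs, gts, _ = load_dataset(tmp_path / "data")
        ids = sorted(preds)
        direct = radius_sweep([preds[i] for i in ids], gts, (6.0, 8.0, 10.0))
        pd.testing.assert_frame_equal(report["metrics"], direct)

    def test_predictions_identical_to_annotations_score_perfectly(self, tmp_path):
        from suturepoint import pipeline
        from suturepoint.synthetic import read_labelme

        spec = SceneSpec(height=32, width=32, n_points=(1, 2),
                         close_pair_fraction=0.0, seed=2)
        generate_dataset(spec, 4, tmp_path / "data")
        gts = {p.stem: read_labelme(p)
               for p in (tmp_path / "data").glob("image_*.json")}
        pipeline.write_predictions_csv(gts, tmp_path / "pred.csv")
        report = pipeline.evaluate(tmp_path / "pred.csv", tmp_path / "data")
        assert (report["metrics"].f1 == 1.0).all()
        # zero up to the CSV round-trip's decimal representation
        assert report["rmse"].rmse == pytest.approx(0.0, abs=1e-9)

    def test_empty_predictions_file(self, tmp_path):
        from suturepoint import pipeline

        spec = SceneSpec(height=32, width=32, n_points=(1, 2), close_pair_fraction=0.0, seed=3)
        generate_dataset(spec, 3, tmp_path / "data")
        pipeline.write_predictions_csv({}, tmp_path / "pred.csv")
        report = pipeline.evaluate(tmp_path / "pred.csv", tmp_path / "data")
        assert (report["metrics"].tpr == 0.0).all()
        assert report["rmse"].n_images_scored == 0

    def test_missing_annotation_listed(self, tmp_path):
        from suturepoint import pipeline

        spec = SceneSpec(height=32, width=32, n_points=(1, 2), close_pair_fraction=0.0, seed=4)
        generate_dataset(spec, 2, tmp_path / "data")
        fake = {"not_an_image": PointSet(np.array([[1.0, 1.0]]), 32, 32)}
        pipeline.write_predictions_csv(fake, tmp_path / "pred.csv")
        with pytest.raises(ValueError, match="not_an_image"):
            pipeline.evaluate(tmp_path / "pred.csv", tmp_path / "data")


def test_cli_generate_and_help(tmp_path):
    from click.testing import CliRunner

    from suturepoint.cli import main

    runner = CliRunner()
    assert runner.invoke(main, ["--help"]).exit_code == 0
    result = runner.invoke(main, [
        "generate", "--out", str(tmp_path / "ds"), "--n-images", "2",
        "--height", "32", "--width", "32", "--n-points", "1", "2",
        "--seed", "5"])
    assert result.exit_code == 0, result.output
    assert (tmp_path / "ds" / "manifest.json").exists()
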